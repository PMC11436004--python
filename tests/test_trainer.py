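"""Differentiable rendering, the training loop, and early stopping."""

import numpy as np
import pytest

import mufield as mf
import mufield.trainer as trainer_mod
from mufield.autodiff import Tensor
from mufield.fields import build_field
from mufield.geometry import generate_rays
from mufield.trainer import (
    TrainConfig,
    TrainHistory,
    evaluate_views,
    integrate_mu_function,
    loss,
    render_rays_differentiable,
    train,
)


class TestLoss:
    def test_identities(self):
        x = np.array([1.0, 2.0, 3.0])
        assert loss(x, x) == 0.0
        assert loss(x + 1.0, x) == pytest.approx(1.0)

    def test_hand_computed_three_rays(self):
        pred = np.array([1.1, 1.8, 2.3], dtype=np.float32)
        target = np.array([1.0, 2.0, 2.0], dtype=np.float32)
        # residuals (0.1, -0.2, 0.3) -> mean square 0.14/3
        assert loss(pred, target) == pytest.approx(0.14 / 3, rel=1e-5)
        assert float(loss(Tensor(pred), target).data) == pytest.approx(0.14 / 3, rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss(np.zeros(3), np.zeros(4))


class _ConstantField:
    """Minimal field stub returning a constant mu everywhere."""

    variant = "vanilla"
    scene_center = np.zeros(3)
    scene_half_extent = np.full(3, 16.0)

    def __init__(self, c):
        self.c = c

    def encode(self, points, context=None):
        return Tensor(np.asarray(points, dtype=np.float32))

    def forward(self, encoded):
        return Tensor(np.full((encoded.data.shape[0], 1), self.c, dtype=np.float32))

    def query_mu(self, points, context=None):
        return np.full(len(np.atleast_2d(points)), self.c)


class TestRenderRays:
    def test_zero_field_renders_zero_and_i0(self, tiny_geometry, tiny_phantom):
        rays = generate_rays(tiny_geometry, 0, tiny_phantom)[:40]
        field = _ConstantField(0.0)
        p = render_rays_differentiable(field, rays, 16)
        assert np.allclose(p.data, 0.0)
        i = render_rays_differentiable(field, rays, 16, supervision="intensity")
        assert np.allclose(i.data, 1.0)

    def test_constant_field_chord_product(self, tiny_geometry, tiny_phantom):
        rays = generate_rays(tiny_geometry, 0, tiny_phantom)
        rays = rays[np.flatnonzero(rays.hits)[:50]]
        c = 0.013
        p = render_rays_differentiable(_ConstantField(c), rays, 64)
        assert np.allclose(p.data, c * (rays.t_far - rays.t_near), rtol=1e-5)

    def test_matches_projector_for_interpolant_field(self, tiny_phantom, tiny_geometry):
        """Integrating mu(x) = trilinear(phantom) reproduces the projector."""
        rays = generate_rays(tiny_geometry, 3, tiny_phantom)
        rays = rays[np.flatnonzero(rays.hits)[::7][:80]]
        p_field = integrate_mu_function(
            lambda pts: mf.interpolate_mu(tiny_phantom, pts), rays, 256
        )
        p_proj = mf.line_integral(tiny_phantom, rays, 256)
        assert np.allclose(p_field, p_proj, atol=1e-12)

    def test_zero_samples_rejected(self, tiny_geometry, tiny_phantom):
        rays = generate_rays(tiny_geometry, 0, tiny_phantom)[:4]
        with pytest.raises(ValueError):
            render_rays_differentiable(_ConstantField(0.1), rays, 0)


class TestHistory:
    def test_monotone_iterations_enforced(self):
        h = TrainHistory()
        h.append(iteration=10, loss=1.0)
        with pytest.raises(ValueError):
            h.append(iteration=10, loss=0.5)


class TestEarlyStopping:
    def _run_with_metric_series(self, series, tiny_projections, monkeypatch):
        calls = iter(series)
        monkeypatch.setattr(
            trainer_mod, "evaluate_views", lambda *a, **k: [next(calls)]
        )
        field = build_field(
            "ingp",
            scene_center=(0, 0, 0),
            scene_half_extent=(16.0, 16.0, 16.0),
            seed=0,
        )
        cfg = TrainConfig(
            batch_rays=8,
            max_iterations=len(series),
            eval_every=1,
            n_samples=4,
            holdout_views=2,
            seed=0,
        )
        _, history = train(field, tiny_projections, cfg)
        return history

    def test_three_small_changes_stop_at_fourth_eval(self, tiny_projections, monkeypatch):
        """Metric series 30.0, 30.1, 30.15, 30.18 stops right after eval 4."""
        history = self._run_with_metric_series(
            [30.0, 30.1, 30.15, 30.18, 31.0, 32.0], tiny_projections, monkeypatch
        )
        assert history.records[-1]["iteration"] == 4

    def test_never_fires_before_patience_evals(self, tiny_projections, monkeypatch):
        history = self._run_with_metric_series(
            [10.0, 10.0, 10.0, 10.0, 10.0], tiny_projections, monkeypatch
        )
        # identical metric: stop as soon as 3 consecutive evals after the first
        assert history.records[-1]["iteration"] == 4

    def test_large_changes_never_stop(self, tiny_projections, monkeypatch):
        history = self._run_with_metric_series(
            [10.0, 12.0, 14.0, 17.0, 21.0, 26.0], tiny_projections, monkeypatch
        )
        assert history.records[-1]["iteration"] == 6


class TestTraining:
    @pytest.fixture(scope="class")
    def short_run(self, tiny_projections, tiny_phantom):
        field = build_field(
            "ingp",
            scene_center=tiny_phantom.center,
            scene_half_extent=0.5 * tiny_phantom.extent,
            seed=0,
        )
        init_psnr = np.mean(
            evaluate_views(field, tiny_projections.subset([5, 15]), 32)
        )
        cfg = TrainConfig(
            batch_rays=256, max_iterations=250, eval_every=50, n_samples=32, seed=0
        )
        field, history = train(field, tiny_projections, cfg)
        return field, history, init_psnr

    def test_determinism_same_seed(self, tiny_projections, tiny_phantom):
        results = []
        for _ in range(2):
            field = build_field(
                "ingp",
                scene_center=tiny_phantom.center,
                scene_half_extent=0.5 * tiny_phantom.extent,
                seed=3,
            )
            cfg = TrainConfig(
                batch_rays=64, max_iterations=30, eval_every=0, n_samples=16, seed=3
            )
            _, history = train(field, tiny_projections, cfg)
            results.append(history.final_loss)
        assert results[0] == results[1]

    def test_holdout_psnr_improves(self, short_run):
        _, history, init_psnr = short_run
        assert history.records[-1]["holdout_psnr"] > init_psnr

    def test_loss_trend_decreases(self, short_run):
        _, history, _ = short_run
        losses = [r["loss"] for r in history.records]
        assert losses[-1] < losses[0]

    def test_too_few_views_rejected(self, tiny_projections):
        field = build_field(
            "vanilla", scene_center=(0, 0, 0), scene_half_extent=(16.0,) * 3
        )
        cfg = TrainConfig(holdout_views=19)
        with pytest.raises(ValueError, match="training views"):
            train(field, tiny_projections, cfg)


class TestEvaluateViews:
    def test_interpolant_field_quadrature_limited(self, tiny_phantom, tiny_projections):
        """A field equal to the phantom interpolant renders near-perfect views."""

        class _InterpolantField(_ConstantField):
            def __init__(self, vol):
                self.vol = vol

            def forward(self, encoded):
                return Tensor(
                    mf.interpolate_mu(self.vol, encoded.data.astype(np.float64))[
                        :, None
                    ].astype(np.float32)
                )

        field = _InterpolantField(tiny_phantom)
        psnrs = evaluate_views(field, tiny_projections.subset([0, 7]), 1024)
        assert min(psnrs) > 40.0

    def test_view_order_invariance(self, tiny_phantom, tiny_projections):
        field = _ConstantField(0.01)
        a = evaluate_views(field, tiny_projections.subset([2, 9]), 16)
        b = evaluate_views(field, tiny_projections.subset([9, 2]), 16)
        assert a == b[::-1]
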