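"""Encoder pathways: Fourier, integrated conical, hash grid, reference features."""

import numpy as np
import pytest

import mufield as mf
import mufield.autodiff as ad
from mufield.autodiff import Tensor
from mufield.encoders import (
    ConvFeatureExtractor,
    FrustumGaussian,
    _bilinear_sample_map,
    project_to_detector,
)


class TestFourier:
    def test_origin_encoding(self):
        cfg = mf.FourierEncodingConfig(num_frequencies=2, include_input=False)
        out = mf.fourier_encode(np.array([[0.0]]), cfg)
        assert np.allclose(out, [[0.0, 1.0, 0.0, 1.0]])

    def test_output_length_with_input(self):
        cfg = mf.FourierEncodingConfig(num_frequencies=10, include_input=True)
        out = mf.fourier_encode(np.zeros((5, 3)), cfg)
        assert out.shape == (5, 63)  # 3 + 3 * 2 * 10
        assert cfg.output_dim(3) == 63

    def test_parity(self, rng):
        cfg = mf.FourierEncodingConfig(num_frequencies=4, include_input=False)
        x = rng.uniform(-1, 1, size=(7, 3))
        plus = mf.fourier_encode(x, cfg)
        minus = mf.fourier_encode(-x, cfg)
        # layout per frequency block: [sin(3), cos(3)]
        sin_cols = np.concatenate([np.arange(6 * k, 6 * k + 3) for k in range(4)])
        cos_cols = np.concatenate([np.arange(6 * k + 3, 6 * k + 6) for k in range(4)])
        assert np.allclose(plus[:, sin_cols], -minus[:, sin_cols], atol=1e-12)
        assert np.allclose(plus[:, cos_cols], minus[:, cos_cols], atol=1e-12)

    def test_rejects_out_of_range(self):
        cfg = mf.FourierEncodingConfig(num_frequencies=2)
        with pytest.raises(ValueError):
            mf.fourier_encode(np.array([[1.5, 0, 0]]), cfg)


class TestFrustumGaussian:
    def test_zero_radius_zero_radial_variance(self):
        g = mf.conical_frustum_to_gaussian([0, 0, 0], [1, 0, 0], 1.0, 2.0, 0.0)
        assert g.r_var == pytest.approx(0.0)
        # all variance lies along the ray
        assert np.allclose(g.variance, [g.t_var, 0.0, 0.0])

    def test_short_segment_mean_converges_to_midpoint(self):
        t0 = 3.0
        for dt in (1.0, 0.1, 0.01):
            g = mf.conical_frustum_to_gaussian([0, 0, 0], [0, 1, 0], t0, t0 + dt, 0.01)
            assert abs(g.mean[1] - (t0 + dt / 2)) < dt**2
        with pytest.raises(ValueError):
            mf.conical_frustum_to_gaussian([0, 0, 0], [0, 1, 0], 2.0, 2.0, 0.01)

    def test_moments_match_monte_carlo(self, rng):
        """Closed-form frustum moments vs 1e6 uniformly drawn cone points."""
        t0, t1, rdot = 1.0, 2.5, 0.3
        d = np.array([0.0, 0.0, 1.0])
        n = 1_000_000
        # t has density ~ t^2 on [t0, t1] (cone cross-section area)
        u = rng.random(n)
        t = (t0**3 + u * (t1**3 - t0**3)) ** (1 / 3)
        r = np.sqrt(rng.random(n)) * rdot * t
        phi = rng.uniform(0, 2 * np.pi, n)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi), t], axis=1)
        g = mf.conical_frustum_to_gaussian([0, 0, 0], d, t0, t1, rdot)
        mc_mean = pts.mean(axis=0)
        mc_var = pts.var(axis=0)
        assert np.allclose(g.mean, mc_mean, atol=0.01 * np.abs(mc_mean).max())
        assert np.allclose(g.variance, mc_var, rtol=0.01, atol=1e-4)


class TestIntegratedFourier:
    def test_zero_variance_equals_plain(self, rng):
        cfg = mf.FourierEncodingConfig(num_frequencies=6)
        x = rng.uniform(-0.9, 0.9, size=(5, 3))
        g = FrustumGaussian(x, np.zeros_like(x))
        assert np.allclose(
            mf.integrated_fourier_encode(g, cfg), mf.fourier_encode(x, cfg), atol=1e-12
        )

    def test_large_variance_damps_to_zero(self):
        cfg = mf.FourierEncodingConfig(num_frequencies=4, include_input=False)
        g = FrustumGaussian(np.full((1, 3), 0.3), np.full((1, 3), 100.0))
        assert np.max(np.abs(mf.integrated_fourier_encode(g, cfg))) < 1e-12

    def test_matches_monte_carlo_expectation(self, rng):
        """Damped features vs the empirical mean over 1e5 Gaussian draws."""
        cfg = mf.FourierEncodingConfig(num_frequencies=3, include_input=False)
        mean = np.array([0.21, -0.4, 0.05])
        var = np.array([0.004, 0.001, 0.0025])
        draws = rng.normal(mean, np.sqrt(var), size=(100_000, 3))
        feats = np.stack(
            [
                np.concatenate(
                    [
                        np.concatenate([np.sin(f * d), np.cos(f * d)])
                        for f in (2.0 ** np.arange(3)) * np.pi
                    ]
                )
                for d in [mean]
            ]
        )
        # empirical expectation computed directly from the definition
        freqs = (2.0 ** np.arange(3)) * np.pi
        ang = draws[:, None, :] * freqs[None, :, None]
        emp = np.concatenate(
            [np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0)], axis=-1
        ).reshape(-1)
        closed = mf.integrated_fourier_encode(
            FrustumGaussian(mean[None], var[None]), cfg
        )[0]
        assert np.allclose(closed, emp, atol=0.01)

    def test_monotone_damping(self, rng):
        """Larger variance never increases any feature magnitude."""
        cfg = mf.FourierEncodingConfig(num_frequencies=5, include_input=False)
        mean = rng.uniform(-0.9, 0.9, size=(4, 3))
        small = np.abs(
            mf.integrated_fourier_encode(FrustumGaussian(mean, np.full((4, 3), 1e-4)), cfg)
        )
        large = np.abs(
            mf.integrated_fourier_encode(FrustumGaussian(mean, np.full((4, 3), 1e-2)), cfg)
        )
        assert np.all(large <= small + 1e-12)


class TestHashEncoder:
    @pytest.fixture(scope="class")
    def encoder(self):
        return mf.HashEncoder(
            mf.HashEncodingConfig(
                num_levels=4,
                features_per_level=2,
                log2_hashmap_size=10,
                base_resolution=4,
                finest_resolution=32,
                seed=3,
            )
        )

    def test_origin_uses_row_zero(self, encoder):
        idx, wgt = encoder.corner_weights(np.zeros((1, 3)))
        # corner (0,0,0) of each level hashes/indexes to its slice's row 0
        assert np.all(idx[0, :, 0] == encoder.offsets[:-1])
        assert wgt[0, :, 0] == pytest.approx(1.0)

    def test_grid_vertex_returns_exact_row(self, encoder):
        res0 = encoder.resolutions[0]
        x = np.array([[1.0 / res0, 0.0, 0.0]])  # vertex (1, 0, 0) at level 0
        out = encoder.encode(x).data
        expected = encoder.table_rows(0)[encoder._corner_indices(np.array([[1, 0, 0]]), 0)[0]]
        assert np.allclose(out[0, :2], expected, atol=1e-6)

    def test_output_length_and_determinism(self, encoder, rng):
        x = rng.random((10, 3))
        a = encoder.encode(x).data
        b = encoder.encode(x).data
        assert a.shape == (10, 8)  # 4 levels * 2 features
        assert np.array_equal(a, b)

    def test_resolutions_grow_geometrically(self, encoder):
        r = encoder.resolutions
        assert r[0] == 4 and r[-1] == 32
        ratios = r[1:] / r[:-1].astype(float)
        assert np.all(ratios > 1.0)

    def test_rejects_outside_unit_cube(self, encoder):
        with pytest.raises(ValueError):
            encoder.encode(np.array([[1.2, 0.0, 0.0]]))

    def test_gradient_reaches_only_touched_rows(self, encoder):
        out = encoder.encode(np.array([[0.9, 0.1, 0.3]]))
        out.sum().backward()
        g = encoder.table.grad
        assert g is not None
        assert 0 < np.count_nonzero(np.any(g != 0, axis=1)) <= 4 * 8


class TestReferenceFeatures:
    @pytest.fixture(scope="class")
    def setup(self):
        geom = mf.ConeBeamGeometry.circular(
            n_views=6, detector_shape=(33, 33), detector_spacing=(3.0, 3.0)
        )
        return geom

    def test_isocenter_projects_to_center_pixel(self, setup):
        for k in range(setup.n_views):
            pix = project_to_detector(np.zeros((1, 3)), setup, k)
            assert np.allclose(pix, [[16.0, 16.0]], atol=1e-9)

    def test_constant_feature_map_passthrough(self, setup):
        maps = Tensor(np.full((3, 5, 8, 8), 2.5, dtype=np.float32))
        pts = np.random.default_rng(0).uniform(-10, 10, size=(6, 3))
        out = mf.extract_reference_features(pts, maps, setup, [0, 2, 4], downsample=4)
        assert np.allclose(out.data, 2.5, atol=1e-6)

    def test_identical_maps_average_equals_single(self, setup, rng):
        fm = rng.random((1, 4, 8, 8)).astype(np.float32)
        maps3 = Tensor(np.repeat(fm, 3, axis=0))
        maps1 = Tensor(fm)
        pts = rng.uniform(-5, 5, size=(4, 3))
        # all three views identical maps but different geometry -> not equal;
        # instead compare the same single view repeated
        a = mf.extract_reference_features(pts, maps3, setup, [1, 1, 1], downsample=4)
        b = mf.extract_reference_features(pts, maps1, setup, [1], downsample=4)
        assert np.allclose(a.data, b.data, atol=1e-6)

    def test_zero_views_rejected(self, setup):
        with pytest.raises(ValueError):
            mf.extract_reference_features(
                np.zeros((1, 3)), Tensor(np.zeros((1, 2, 4, 4))), setup, []
            )

    def test_outside_detector_contributes_zero(self, setup):
        maps = Tensor(np.ones((1, 2, 8, 8), dtype=np.float32))
        far = np.array([[0.0, 400.0, 300.0]])  # projects far off-panel
        out = mf.extract_reference_features(far, maps, setup, [0], downsample=4)
        assert np.allclose(out.data, 0.0)

    def test_extractor_shapes_and_joint_training(self, rng):
        ext = ConvFeatureExtractor(feature_channels=6, hidden=4, seed=0)
        imgs = rng.random((3, 16, 16))
        maps = ext(imgs)
        assert maps.data.shape == (3, 6, 4, 4)  # downsample 4
        (maps * maps).sum().backward()
        assert all(p.grad is not None for p in ext.params)


def test_bilinear_sample_interpolates(rng):
    h, w, c = 4, 5, 2
    fm = rng.random((h * w, c)).astype(np.float32)
    t = Tensor(fm)
    # at integer coords returns the exact row
    out = _bilinear_sample_map(t, h, w, np.array([[2.0, 1.0]]))
    assert np.allclose(out.data[0], fm[1 * w + 2])
    # halfway between two pixels: their mean
    out = _bilinear_sample_map(t, h, w, np.array([[2.5, 1.0]]))
    assert np.allclose(out.data[0], 0.5 * (fm[1 * w + 2] + fm[1 * w + 3]), atol=1e-6)
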