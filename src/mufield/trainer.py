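"""Fit an attenuation field to a projection set by differentiable rendering.

Each iteration draws a uniformly random batch of rays over all training
pixels, integrates the field along them with the same midpoint rule the DRR
simulator uses, and minimizes the mean squared error between predicted and
measured targets.  Supervision defaults to the log-converted line integral
``p = -ln(I/I0)`` — linear in mu and much better conditioned than raw
intensity — with intensity supervision available behind a flag.

Early stopping follows the rule of stopping once the evaluation metric
(held-out-view PSNR) has changed by less than ``early_stop_tolerance``
(default 1%) for ``early_stop_patience`` (default 3) consecutive
evaluations.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dfield

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .encoders import conical_frustum_to_gaussian, extract_reference_features
from .fields import AttenuationField
from .geometry import ConeBeamGeometry, RayBundle, generate_rays
from .projector import ProjectionSet, sample_uniform, to_line_integrals

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "loss",
    "render_rays_differentiable",
    "integrate_mu_function",
    "train",
    "evaluate_views",
]


@dataclass
class TrainConfig:
    batch_rays: int = 1024
    max_iterations: int = 30_000
    eval_every: int = 500
    early_stop_tolerance: float = 0.01
    early_stop_patience: int = 3
    seed: int = 0
    supervision: str = "line_integral"  # or "intensity"
    holdout_views: int = 2
    n_samples: int | None = None  # None -> volume-diagonal heuristic of the caller
    learning_rate: float | None = None  # None -> the variant preset

    def __post_init__(self):
        if self.batch_rays < 1:
            raise ValueError("batch_rays must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.supervision not in ("line_integral", "intensity"):
            raise ValueError(f"unknown supervision {self.supervision!r}")


@dataclass
class TrainHistory:
    """Per-evaluation training records."""

    records: list[dict] = dfield(default_factory=list)

    def append(self, **record) -> None:
        if self.records and record["iteration"] <= self.records[-1]["iteration"]:
            raise ValueError("history iterations must be strictly increasing")
        self.records.append(record)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @property
    def final_loss(self) -> float:
        return self.records[-1]["loss"] if self.records else float("nan")


def loss(predicted, target):
    """Mean squared error over a ray batch (Tensor-aware)."""
    t = target.data if isinstance(target, Tensor) else np.asarray(target)
    if isinstance(predicted, Tensor):
        if predicted.data.shape != t.shape:
            raise ValueError(
                f"shape mismatch: predicted {predicted.data.shape} vs target {t.shape}"
            )
        diff = predicted - Tensor(t.astype(predicted.data.dtype))
        return (diff * diff).mean()
    predicted = np.asarray(predicted)
    if predicted.shape != t.shape:
        raise ValueError(f"shape mismatch: predicted {predicted.shape} vs target {t.shape}")
    return float(np.mean((predicted - t) ** 2))


class _SceneBounds:
    """Duck-typed stand-in for a VolumeGrid when only the AABB matters."""

    def __init__(self, center, half_extent):
        self.world_min = np.asarray(center) - np.asarray(half_extent)
        self.world_max = np.asarray(center) + np.asarray(half_extent)


def _make_context(field: AttenuationField, rays: RayBundle, t, delta, extra):
    """Variant-specific query context for a sampled ray batch."""
    if (
        field.variant == "mip"
        and extra.get("use_frustums", True)
        and "cone_radius_rate" in extra
    ):
        edges0 = t - 0.5 * delta[:, None]
        edges1 = t + 0.5 * delta[:, None]
        # guard degenerate (miss) segments
        bad = edges1 <= edges0
        edges1 = np.where(bad, edges0 + 1e-6, edges1)
        g = conical_frustum_to_gaussian(
            rays.origins[:, None, :],
            rays.directions[:, None, :],
            edges0,
            edges1,
            extra["cone_radius_rate"],
        )
        from .encoders import FrustumGaussian

        return {
            "frustum": FrustumGaussian(
                g.mean.reshape(-1, 3), g.variance.reshape(-1, 3)
            )
        }
    if field.variant == "pixel":
        positions = extra["positions"]
        return {
            "reference_features": extract_reference_features(
                positions.reshape(-1, 3),
                extra["feature_maps"],
                extra["geometry"],
                extra["reference_view_indices"],
                downsample=field.feature_extractor.downsample,
            )
        }
    return None


def render_rays_differentiable(
    field: AttenuationField,
    rays: RayBundle,
    n_samples: int,
    supervision: str = "line_integral",
    i0: float = 1.0,
    context_extra: dict | None = None,
):
    """Differentiable Beer-Lambert rendering of a ray batch.

    Returns a Tensor of per-ray line integrals ``p`` (or intensities
    ``I0*exp(-p)`` when supervising intensity); gradients reach every field
    parameter, including hash-table rows and extractor weights.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    t, delta = sample_uniform(rays, n_samples)
    positions = rays.origins[:, None, :] + t[..., None] * rays.directions[:, None, :]
    extra = dict(context_extra or {})
    extra["positions"] = positions
    context = _make_context(field, rays, t, delta, extra)
    encoded = field.encode(positions.reshape(-1, 3), context)
    mu = field.forward(encoded)  # (B*S, 1)
    b, s = t.shape
    mu = mu.reshape(b, s)
    p = (mu * delta[:, None].astype(np.float32)).sum(axis=1)
    if supervision == "intensity":
        return ad.exp(-p) * i0
    return p


def integrate_mu_function(mu_fn, rays: RayBundle, n_samples: int) -> np.ndarray:
    """Midpoint-rule integral of an arbitrary mu(x) callable along rays."""
    t, delta = sample_uniform(rays, n_samples)
    pos = rays.origins[:, None, :] + t[..., None] * rays.directions[:, None, :]
    mu = np.asarray(mu_fn(pos.reshape(-1, 3))).reshape(t.shape)
    return (mu * delta[:, None]).sum(axis=1)


def _split_views(n_views: int, holdout: int) -> tuple[list[int], list[int]]:
    if holdout <= 0:
        return list(range(n_views)), []
    idx = np.round(np.linspace(0, n_views, holdout, endpoint=False) + n_views / (2 * holdout)).astype(int)
    holdout_idx = sorted(set(int(i) % n_views for i in idx))
    train_idx = [i for i in range(n_views) if i not in holdout_idx]
    return train_idx, holdout_idx


def _reference_view_indices(train_idx: list[int], k: int) -> list[int]:
    pos = np.linspace(0, len(train_idx), k, endpoint=False).astype(int)
    return [train_idx[p] for p in pos]


def train(
    field: AttenuationField,
    projections: ProjectionSet,
    config: TrainConfig,
) -> tuple[AttenuationField, TrainHistory]:
    """Optimize the field on a projection set; returns the field + history.

    The view split, ray targets, batch order and parameter initialization are
    all derived from ``config.seed``, so a run is reproducible on the same
    platform.
    """
    geometry = projections.geometry
    if geometry.n_views - config.holdout_views < 2:
        raise ValueError("need at least 2 training views")
    supervise_li = config.supervision == "line_integral"
    li_set = to_line_integrals(projections)
    target_stack = (li_set if supervise_li else projections).stack()

    train_idx, holdout_idx = _split_views(geometry.n_views, config.holdout_views)
    bounds = _SceneBounds(field.scene_center, field.scene_half_extent)

    # precompute every training ray and its target once
    bundles, targets = [], []
    for k in train_idx:
        rb = generate_rays(geometry, k, bounds)
        bundles.append(rb)
        targets.append(target_stack[k].reshape(-1))
    origins = np.concatenate([b.origins for b in bundles]).astype(np.float64)
    directions = np.concatenate([b.directions for b in bundles])
    t_near = np.concatenate([b.t_near for b in bundles])
    t_far = np.concatenate([b.t_far for b in bundles])
    ray_targets = np.concatenate(targets).astype(np.float32)
    n_rays = len(ray_targets)

    n_samples = config.n_samples
    if n_samples is None:
        n_samples = int(
            np.ceil(np.linalg.norm(2 * field.scene_half_extent) / 1.0)
        )  # ~1 mm steps as a fallback

    extra: dict = {"geometry": geometry}
    if field.variant == "mip":
        extra["cone_radius_rate"] = geometry.detector_spacing[0] / geometry.sdd
    ref_images = None
    if field.variant == "pixel":
        ref_idx = _reference_view_indices(train_idx, field.reference_views)
        extra["reference_view_indices"] = ref_idx
        ref_stack = target_stack[ref_idx]
        ref_scale = max(float(np.abs(ref_stack).max()), 1e-12)
        ref_images = ref_stack / ref_scale

    lr = config.learning_rate if config.learning_rate is not None else field.learning_rate
    optimizer = Adam(field.params, lr=lr)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()

    eval_metric_prev = None
    streak = 0
    t_start = time.monotonic()
    running_loss = float("nan")
    for iteration in range(1, config.max_iterations + 1):
        batch = rng.integers(0, n_rays, size=min(config.batch_rays, n_rays))
        rb = RayBundle(origins[batch], directions[batch], t_near[batch], t_far[batch])
        if ref_images is not None:
            extra["feature_maps"] = field.feature_extractor(ref_images)
        pred = render_rays_differentiable(
            field, rb, n_samples, config.supervision, geometry.i0, extra
        )
        batch_loss = loss(pred, ray_targets[batch])
        value = float(batch_loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite training loss at iteration {iteration}"
            )
        running_loss = value
        optimizer.zero_grad()
        batch_loss.backward()
        optimizer.step()

        if config.eval_every and iteration % config.eval_every == 0:
            metric = None
            if holdout_idx:
                heldout = projections.subset(holdout_idx)
                psnrs = evaluate_views(
                    field, heldout, n_samples, config.supervision, extra
                )
                metric = float(np.mean(psnrs))
            history.append(
                iteration=iteration,
                loss=running_loss,
                holdout_psnr=metric if metric is not None else float("nan"),
                wall_time=time.monotonic() - t_start,
            )
            if metric is not None:
                if eval_metric_prev is not None:
                    rel = abs(metric - eval_metric_prev) / max(abs(eval_metric_prev), 1e-12)
                    streak = streak + 1 if rel < config.early_stop_tolerance else 0
                eval_metric_prev = metric
                if streak >= config.early_stop_patience:
                    break
    if not history.records or history.records[-1]["iteration"] != iteration:
        history.append(
            iteration=iteration,
            loss=running_loss,
            holdout_psnr=float("nan"),
            wall_time=time.monotonic() - t_start,
        )
    if field.variant == "pixel":
        # freeze the final feature maps so the field stays queryable
        # (volume extraction, later evaluation) without the training loop
        final_maps = field.feature_extractor(ref_images)
        ref_idx = extra["reference_view_indices"]
        downsample = field.feature_extractor.downsample

        def build_context(points, _maps=final_maps):
            return {
                "reference_features": extract_reference_features(
                    np.atleast_2d(points), _maps, geometry, ref_idx, downsample
                )
            }

        field.default_context_builder = build_context
    return field, history


def evaluate_views(
    field: AttenuationField,
    heldout: ProjectionSet,
    n_samples: int,
    supervision: str = "line_integral",
    context_extra: dict | None = None,
    chunk: int = 4096,
) -> list[float]:
    """Per-view PSNR of renders from the frozen field against held-out targets."""
    from .metrics import psnr

    geometry = heldout.geometry
    supervise_li = supervision == "line_integral"
    target_set = to_line_integrals(heldout) if supervise_li else heldout
    bounds = _SceneBounds(field.scene_center, field.scene_half_extent)
    extra = dict(context_extra or {})
    # reference geometry stays the *training* geometry if provided
    extra.setdefault("geometry", geometry)
    if field.variant == "pixel" and "feature_maps" not in extra:
        raise ValueError("pixel-variant evaluation needs precomputed feature maps")
    out = []
    for k in range(geometry.n_views):
        rb = generate_rays(geometry, k, bounds)
        preds = []
        for start in range(0, len(rb), chunk):
            sub = rb[start : start + chunk]
            pred = render_rays_differentiable(
                field, sub, n_samples, supervision, geometry.i0, extra
            )
            preds.append(pred.data)
        img = np.concatenate(preds).reshape(rb.image_shape)
        target = target_set.images[k].pixels
        rng_val = max(float(target.max()), 1e-12)
        out.append(psnr(img, target, data_range=rng_val))
    return out
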