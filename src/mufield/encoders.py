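"""Input-feature pathways for the attenuation-field variants.

Four encodings are provided, one per field variant:

* **Fourier positional encoding** — ``(sin(2^k pi x), cos(2^k pi x))`` for
  ``k = 0..L-1`` per component, the classic coordinate lifting that lets a
  small MLP represent high-frequency structure.
* **Integrated encoding over conical frustums** — each ray segment is widened
  to a cone slice, approximated by a Gaussian whose exact first/second
  moments are known in closed form; the expected Fourier features under that
  Gaussian damp each frequency by ``exp(-0.5 * (2^k pi)^2 * var)``.
* **Multiresolution hash encoding** — learnable feature tables indexed by
  spatially hashed grid vertices at geometrically growing resolutions,
  trilinearly blended; gradients flow only to the touched rows.
* **Reference-image feature conditioning** — each 3D sample is projected into
  a handful of reference views and bilinearly samples a feature map produced
  by a pluggable image-to-feature extractor (default: a small conv stack
  trained jointly with the field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ConeBeamGeometry

__all__ = [
    "FourierEncodingConfig",
    "HashEncodingConfig",
    "FrustumGaussian",
    "fourier_encode",
    "integrated_fourier_encode",
    "conical_frustum_to_gaussian",
    "HashEncoder",
    "ConvFeatureExtractor",
    "project_to_detector",
    "extract_reference_features",
]

_HASH_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.uint64)


@dataclass(frozen=True)
class FourierEncodingConfig:
    """L geometric frequencies per component; optionally prepend the raw input."""

    num_frequencies: int = 10
    include_input: bool = True

    def __post_init__(self):
        if self.num_frequencies < 1:
            raise ValueError("num_frequencies must be >= 1")

    def output_dim(self, input_dim: int) -> int:
        return input_dim * (2 * self.num_frequencies + int(self.include_input))


@dataclass(frozen=True)
class HashEncodingConfig:
    num_levels: int = 8
    features_per_level: int = 2
    log2_hashmap_size: int = 20
    base_resolution: int = 16
    finest_resolution: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.num_levels < 1 or self.features_per_level < 1:
            raise ValueError("num_levels and features_per_level must be >= 1")
        if self.finest_resolution < self.base_resolution:
            raise ValueError("finest_resolution must be >= base_resolution")

    @property
    def output_dim(self) -> int:
        return self.num_levels * self.features_per_level

    def level_resolutions(self) -> np.ndarray:
        """Per-level grid resolutions growing geometrically base -> finest."""
        if self.num_levels == 1:
            return np.array([self.base_resolution])
        b = np.exp(
            (np.log(self.finest_resolution) - np.log(self.base_resolution))
            / (self.num_levels - 1)
        )
        res = np.floor(self.base_resolution * b ** np.arange(self.num_levels) + 0.5)
        return res.astype(int)


@dataclass
class FrustumGaussian:
    """Gaussian approximation of a conical-frustum ray segment."""

    mean: np.ndarray  # (..., 3) world point
    variance: np.ndarray  # (..., 3) per-axis second moments
    t_mean: np.ndarray | float = 0.0
    t_var: np.ndarray | float = 0.0
    r_var: np.ndarray | float = 0.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.variance = np.asarray(self.variance, dtype=np.float64)
        if np.any(self.variance < -1e-12):
            raise ValueError("frustum variances must be non-negative")
        self.variance = np.clip(self.variance, 0.0, None)


def fourier_encode(x: np.ndarray, config: FourierEncodingConfig) -> np.ndarray:
    """Fourier features of points scaled to [-1, 1]^d.

    Output layout: ``[x?] + [sin(2^0 pi x), cos(2^0 pi x), ..., cos(2^{L-1} pi x)]``
    where each sin/cos block holds all d components.
    """
    x = np.asarray(x)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        raise ValueError("fourier_encode expects inputs scaled to [-1, 1]")
    freqs = (2.0 ** np.arange(config.num_frequencies)) * np.pi
    ang = x[..., None, :] * freqs[:, None]  # (..., L, d)
    parts = np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)  # (..., L, 2d)
    flat = parts.reshape(*x.shape[:-1], -1)
    if config.include_input:
        flat = np.concatenate([x, flat], axis=-1)
    return flat


def integrated_fourier_encode(
    g: FrustumGaussian, config: FourierEncodingConfig
) -> np.ndarray:
    """Expected Fourier encoding under the frustum Gaussian.

    Each frequency-k sin/cos pair is damped by ``exp(-0.5 (2^k pi)^2 var)``;
    zero variance reproduces :func:`fourier_encode` of the mean exactly.
    """
    mean = np.clip(g.mean, -1.0, 1.0)
    var = np.asarray(g.variance)
    freqs = (2.0 ** np.arange(config.num_frequencies)) * np.pi
    ang = mean[..., None, :] * freqs[:, None]
    damp = np.exp(-0.5 * (freqs[:, None] ** 2) * var[..., None, :])
    parts = np.concatenate([np.sin(ang) * damp, np.cos(ang) * damp], axis=-1)
    flat = parts.reshape(*mean.shape[:-1], -1)
    if config.include_input:
        flat = np.concatenate([mean, flat], axis=-1)
    return flat


def conical_frustum_to_gaussian(origin, direction, t0, t1, base_radius):
    """Closed-form moments of a conical frustum along a ray.

    The cone has radius ``base_radius * t`` at parameter ``t``; ``t1 > t0 >= 0``.
    Returns the Gaussian with the frustum's exact mean distance ``t_mean``,
    along-ray variance ``t_var`` and radial variance ``r_var``, projected to
    per-axis world variances ``t_var * d^2 + r_var * (1 - d^2)``.  With
    ``base_radius = 0`` the radial variance vanishes and the mean sits at the
    cone-weighted (not arithmetic) segment center.
    """
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    t0 = np.asarray(t0, dtype=np.float64)
    t1 = np.asarray(t1, dtype=np.float64)
    if np.any(t1 <= t0):
        raise ValueError("need t1 > t0 for a frustum segment")
    if np.any(np.asarray(base_radius) < 0):
        raise ValueError("base_radius must be >= 0")
    t_mu = (t0 + t1) / 2.0
    t_d = (t1 - t0) / 2.0
    denom = 3 * t_mu**2 + t_d**2
    t_mean = t_mu + (2.0 * t_mu * t_d**2) / denom
    t_var = t_d**2 / 3.0 - (4.0 * t_d**4) * (12.0 * t_mu**2 - t_d**2) / (
        15.0 * denom**2
    )
    r_var = np.asarray(base_radius) ** 2 * (
        t_mu**2 / 4.0 + (5.0 * t_d**2) / 12.0 - (4.0 * t_d**4) / (15.0 * denom)
    )
    mean = origin + t_mean[..., None] * direction
    d2 = direction**2
    variance = t_var[..., None] * d2 + r_var[..., None] * (1.0 - d2)
    return FrustumGaussian(mean, variance, t_mean, t_var, r_var)


class HashEncoder:
    """Learnable multiresolution hash-grid encoding on the unit cube.

    Per level, the enclosing grid cell's 8 corners are hashed with the XOR
    spatial hash (coordinate-times-prime products, primes
    ``{1, 2654435761, 805459861}``, mod table size); when a level's full
    vertex grid fits in the table, dense row indexing is used instead.
    Corner features are trilinearly blended and levels concatenated.
    """

    def __init__(self, config: HashEncodingConfig):
        self.config = config
        self.resolutions = config.level_resolutions()
        max_rows = 2**config.log2_hashmap_size
        rng = np.random.default_rng(config.seed)
        # all level tables live in one array (rows offset per level) so a
        # point batch needs a single gather across every level and corner
        self.level_rows: list[int] = []
        self.dense: list[bool] = []
        for res in self.resolutions:
            n_vertices = int(res + 1) ** 3
            self.level_rows.append(min(n_vertices, max_rows))
            self.dense.append(n_vertices <= max_rows)
        self.offsets = np.concatenate([[0], np.cumsum(self.level_rows)])
        init = rng.uniform(
            -1e-4, 1e-4, size=(int(self.offsets[-1]), config.features_per_level)
        )
        self.table = Tensor(init.astype(np.float32), requires_grad=True)
        # the 8 cell-corner offsets, bit-ordered (x, y, z)
        self._corners = np.array(
            [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)]
        )

    @property
    def params(self) -> list[Tensor]:
        return [self.table]

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def table_rows(self, level: int) -> np.ndarray:
        """This level's slice of the merged feature table (view)."""
        return self.table.data[self.offsets[level] : self.offsets[level + 1]]

    def _corner_indices(self, corners: np.ndarray, level: int) -> np.ndarray:
        """Row index (within the level's slice) of integer grid vertices."""
        res = int(self.resolutions[level])
        rows = self.level_rows[level]
        c = corners.astype(np.uint64)
        if self.dense[level]:
            stride = np.uint64(res + 1)
            idx = (c[..., 0] * stride + c[..., 1]) * stride + c[..., 2]
        else:
            idx = (
                c[..., 0] * _HASH_PRIMES[0]
                ^ c[..., 1] * _HASH_PRIMES[1]
                ^ c[..., 2] * _HASH_PRIMES[2]
            ) % np.uint64(rows)
        return idx.astype(np.int64)

    def corner_weights(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Merged-table indices and trilinear weights, both (n, L, 8)."""
        x = np.asarray(x, dtype=np.float32)
        if np.any(x < -1e-6) or np.any(x > 1.0 + 1e-6):
            raise ValueError("hash encoding expects inputs in the unit cube")
        x = np.clip(x, 0.0, 1.0)
        n = x.shape[0]
        res = self.resolutions.astype(np.float32)[None, :, None]  # (1, L, 1)
        scaled = x[:, None, :] * res  # (n, L, 3)
        i0 = np.minimum(np.floor(scaled), res - 1).astype(np.int64)
        frac = scaled - i0
        corners = i0[:, :, None, :] + self._corners[None, None, :, :]  # (n, L, 8, 3)
        # per-axis weight pairs (1-f, f) gathered by each corner's bit pattern
        wgt = np.ones((n, len(self.resolutions), 8), dtype=np.float32)
        for axis in range(3):
            pair = np.stack([1.0 - frac[..., axis], frac[..., axis]], axis=-1)
            wgt *= pair[:, :, self._corners[:, axis]]
        idx = np.empty((n, len(self.resolutions), 8), dtype=np.int64)
        for level in range(len(self.resolutions)):
            idx[:, level, :] = (
                self._corner_indices(corners[:, level], level) + self.offsets[level]
            )
        return idx, wgt

    def encode(self, x: np.ndarray) -> Tensor:
        """Encode points in [0, 1]^3 -> Tensor (n_points, num_levels * F)."""
        idx, wgt = self.corner_weights(x)
        n = idx.shape[0]
        blended = ad.gather_blend(self.table, idx, wgt)  # (n, L, F)
        return blended.reshape(n, self.config.output_dim)


class ConvFeatureExtractor:
    """Default feature extractor: a small conv stack trained jointly.

    Satisfies the extractor contract — any image-to-feature-map function with
    a stated downsampling factor may be dropped in (e.g. a pretrained
    backbone); nothing in the package requires pretrained weights.  The stack
    is conv3x3 -> ReLU -> pool2 -> conv3x3 -> ReLU -> pool2 -> conv3x3, so
    ``downsample = 4``.
    """

    downsample = 4

    def __init__(self, feature_channels: int = 128, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.feature_channels = feature_channels

        def init_conv(c_out, c_in, k=3):
            fan_in = c_in * k * k
            bound = 1.0 / np.sqrt(fan_in)
            w = rng.uniform(-bound, bound, size=(c_out, c_in, k, k)).astype(np.float32)
            b = rng.uniform(-bound, bound, size=(c_out,)).astype(np.float32)
            return Tensor(w, requires_grad=True), Tensor(b, requires_grad=True)

        self.w1, self.b1 = init_conv(hidden, 1)
        self.w2, self.b2 = init_conv(2 * hidden, hidden)
        self.w3, self.b3 = init_conv(feature_channels, 2 * hidden)

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    def __call__(self, images: np.ndarray) -> Tensor:
        """(V, H, W) images -> feature maps Tensor (V, C, H/4, W/4)."""
        x = Tensor(np.asarray(images, dtype=np.float32)[:, None, :, :])
        h = ad.relu(ad.conv2d(x, self.w1, self.b1))
        h = ad.avg_pool2x2(h)
        h = ad.relu(ad.conv2d(h, self.w2, self.b2))
        h = ad.avg_pool2x2(h)
        return ad.conv2d(h, self.w3, self.b3)


def project_to_detector(
    points: np.ndarray, geometry: ConeBeamGeometry, angle_index: int
) -> np.ndarray:
    """Pixel coordinates ``(iu, iv)`` where world points land on a view's panel."""
    points = np.asarray(points, dtype=np.float64)
    t = geometry.angles[angle_index]
    source = geometry.source_position(angle_index)
    axis = -np.array([np.cos(t), np.sin(t), 0.0])  # source -> detector center
    u_hat = np.array([-np.sin(t), np.cos(t), 0.0])
    rel = points - source
    depth = rel @ axis
    depth = np.where(np.abs(depth) < 1e-9, 1e-9, depth)
    scale = geometry.sdd / depth
    u_mm = (rel @ u_hat) * scale
    v_mm = rel[..., 2] * scale
    nu, nv = geometry.detector_shape
    du, dv = geometry.detector_spacing
    iu = u_mm / du + (nu - 1) / 2.0
    iv = v_mm / dv + (nv - 1) / 2.0
    return np.stack([iu, iv], axis=-1)


def _bilinear_sample_map(
    feat_flat: Tensor, h: int, w: int, coords: np.ndarray
) -> Tensor:
    """Differentiable bilinear sampling of a (h*w, C) flattened feature map.

    ``coords`` is (n, 2) in (col, row) = (x, y) map pixel units.  Samples
    outside the map return zeros (handled by zero weights).
    """
    x = coords[:, 0]
    y = coords[:, 1]
    inside = (x >= 0) & (x <= w - 1) & (y >= 0) & (y <= h - 1)
    xc = np.clip(x, 0, w - 1)
    yc = np.clip(y, 0, h - 1)
    x0 = np.minimum(np.floor(xc), w - 2 if w > 1 else 0).astype(np.int64)
    y0 = np.minimum(np.floor(yc), h - 2 if h > 1 else 0).astype(np.int64)
    fx = (xc - x0).astype(np.float32)
    fy = (yc - y0).astype(np.float32)
    out = None
    for dy in (0, 1):
        for dx in (0, 1):
            wgt = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            wgt = (wgt * inside).astype(np.float32)
            idx = (y0 + dy) * w + (x0 + dx)
            term = ad.take_rows(feat_flat, idx) * wgt[:, None]
            out = term if out is None else out + term
    return out


def extract_reference_features(
    points: np.ndarray,
    feature_maps: Tensor,
    geometry: ConeBeamGeometry,
    view_indices,
    downsample: int = 4,
) -> Tensor:
    """Average pixel-aligned features over the reference views.

    ``feature_maps`` is the extractor output Tensor (V, C, Hf, Wf) for the
    views listed in ``view_indices``.  Each point is projected through each
    reference view's geometry, bilinearly samples its feature map, and the
    per-view features are averaged; points projecting outside a detector
    contribute a zero vector for that view.
    """
    view_indices = list(view_indices)
    if len(view_indices) == 0:
        raise ValueError("at least one reference view is required")
    v, c, hf, wf = feature_maps.data.shape
    acc = None
    for slot, view in enumerate(view_indices):
        pix = project_to_detector(points, geometry, view)
        coords = pix / downsample  # detector pixels -> feature-map pixels
        fmap = feature_maps.reshape(v, c, hf * wf).transpose(0, 2, 1)
        # slice this view's flattened map: (hf*wf, c)
        flat = ad.take_rows(
            fmap.reshape(v * hf * wf, c), slot * hf * wf + np.arange(hf * wf)
        )
        term = _bilinear_sample_map(flat, hf, wf, coords)
        acc = term if acc is None else acc + term
    return acc * (1.0 / len(view_indices))
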