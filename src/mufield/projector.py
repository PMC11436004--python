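"""Forward DRR model: uniform ray sampling, trilinear lookup, Beer-Lambert.

A digitally reconstructed radiograph (DRR) is produced per view by casting one
ray per detector pixel, integrating the attenuation coefficient along it with
the midpoint rule,

    p = sum_i mu(x_i) * delta,      delta = (t_far - t_near) / n,

and attenuating the beam as ``I = I0 * exp(-p)`` (Beer-Lambert).  Sampling is
strictly uniform — every region of the anatomy contributes to the image, so
importance-weighted sampling buys nothing here.  Projections carry an explicit
representation flag: ``"intensity"`` (I) or ``"line_integral"`` (p); the two
are exact inverses through ``p = -ln(I / I0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import ConeBeamGeometry, Ray, RayBundle, VolumeGrid, generate_rays

__all__ = [
    "ProjectionImage",
    "ProjectionSet",
    "default_n_samples",
    "sample_uniform",
    "interpolate_mu",
    "line_integral",
    "render_drr",
    "to_line_integrals",
    "to_intensities",
    "save_projections",
    "load_projections",
]


@dataclass
class ProjectionImage:
    """One 2D view: ``pixels`` is ``(nv, nu)``; representation flags the scale."""

    pixels: np.ndarray
    representation: str
    angle: float

    def __post_init__(self) -> None:
        if self.representation not in ("intensity", "line_integral"):
            raise ValueError(
                f"representation must be 'intensity' or 'line_integral', "
                f"got {self.representation!r}"
            )
        self.pixels = np.asarray(self.pixels)


@dataclass
class ProjectionSet:
    """Ordered per-view images bound to a geometry (one image per angle)."""

    geometry: ConeBeamGeometry
    images: list[ProjectionImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != self.geometry.n_views:
            raise ValueError(
                f"{len(self.images)} images for {self.geometry.n_views} angles"
            )
        reps = {im.representation for im in self.images}
        if len(reps) > 1:
            raise ValueError(f"mixed representations in one set: {reps}")
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"mixed image shapes in one set: {shapes}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def representation(self) -> str:
        return self.images[0].representation

    def stack(self) -> np.ndarray:
        """(n_views, nv, nu) array of all views."""
        return np.stack([im.pixels for im in self.images])

    def subset(self, view_indices) -> "ProjectionSet":
        idx = list(view_indices)
        return ProjectionSet(
            self.geometry.with_angles(self.geometry.angles[idx]),
            [self.images[i] for i in idx],
        )


def default_n_samples(volume: VolumeGrid) -> int:
    """Samples per ray: volume diagonal over the finest voxel pitch.

    Covers the longest oblique chord at roughly one sample per voxel.
    """
    return int(math.ceil(volume.diagonal / min(volume.spacing)))


def sample_uniform(ray, n_samples: int):
    """Midpoint-rule sample parameters along a ray (or bundle).

    Returns ``(t_values, delta)``; for a bundle, ``t_values`` is ``(N, S)``
    and ``delta`` is ``(N,)``.  Miss rays yield empty samples / delta 0 (for
    a single ray) or delta 0 rows (for a bundle).
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if isinstance(ray, RayBundle):
        delta = (ray.t_far - ray.t_near) / n_samples
        offsets = (np.arange(n_samples) + 0.5)[None, :]
        t = ray.t_near[:, None] + offsets * delta[:, None]
        return t, delta
    if ray.t_far <= ray.t_near:
        return np.empty(0), 0.0
    delta = (ray.t_far - ray.t_near) / n_samples
    t = ray.t_near + (np.arange(n_samples) + 0.5) * delta
    return t, delta


def interpolate_mu(volume: VolumeGrid, positions: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of voxel-center values at world points.

    Positions outside the grid contribute 0 (air).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    idx = volume.world_to_index(positions)
    # voxels are constant-value cells: interpolate between centers, hold the
    # edge value across the outer half-voxel, and return 0 beyond the faces
    out = map_coordinates(
        volume.values, idx.T, order=1, mode="nearest", prefilter=False
    )
    outside = np.any(
        (positions < volume.world_min) | (positions > volume.world_max), axis=-1
    )
    out[outside] = 0.0
    return out


def line_integral(volume: VolumeGrid, ray, n_samples: int):
    """Midpoint-rule approximation of the path integral of mu along the ray."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if isinstance(ray, RayBundle):
        t, delta = sample_uniform(ray, n_samples)
        pos = ray.origins[:, None, :] + t[..., None] * ray.directions[:, None, :]
        mu = interpolate_mu(volume, pos.reshape(-1, 3)).reshape(t.shape)
        return (mu * delta[:, None]).sum(axis=1)
    t, delta = sample_uniform(ray, n_samples)
    if len(t) == 0:
        return 0.0
    pos = ray.origin + t[:, None] * ray.direction
    return float(interpolate_mu(volume, pos).sum() * delta)


def render_drr(
    volume: VolumeGrid,
    geometry: ConeBeamGeometry,
    n_samples: int | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    representation: str = "intensity",
) -> ProjectionSet:
    """Render the full projection set of a volume (one DRR per gantry angle).

    Optional zero-mean Gaussian noise of standard deviation ``noise_sd`` is
    added to the line integrals (before exponentiation), seeded for
    reproducibility; ``noise_sd = 0`` renders are bit-deterministic.
    """
    if n_samples is None:
        n_samples = default_n_samples(volume)
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    images = []
    for k in range(geometry.n_views):
        rays = generate_rays(geometry, k, volume)
        p = line_integral(volume, rays, n_samples)
        if noise_sd > 0:
            p = np.clip(p + rng.normal(0.0, noise_sd, size=p.shape), 0.0, None)
        p = p.reshape(rays.image_shape)
        if representation == "intensity":
            pix = geometry.i0 * np.exp(-p)
        elif representation == "line_integral":
            pix = p
        else:
            raise ValueError(f"unknown representation {representation!r}")
        images.append(ProjectionImage(pix, representation, float(geometry.angles[k])))
    return ProjectionSet(geometry, images)


def to_line_integrals(projections: ProjectionSet) -> ProjectionSet:
    """Convert an intensity set to line integrals, ``p = -ln(I / I0)``."""
    if projections.representation == "line_integral":
        return projections
    i0 = projections.geometry.i0
    images = []
    for k, im in enumerate(projections.images):
        if np.any(im.pixels <= 0):
            raise ValueError(
                f"view {k} (angle {im.angle:.4f} rad) has non-positive intensities; "
                "cannot take the log"
            )
        images.append(
            ProjectionImage(-np.log(im.pixels / i0), "line_integral", im.angle)
        )
    return ProjectionSet(projections.geometry, images)


def to_intensities(projections: ProjectionSet) -> ProjectionSet:
    """Inverse of :func:`to_line_integrals`: ``I = I0 * exp(-p)``."""
    if projections.representation == "intensity":
        return projections
    i0 = projections.geometry.i0
    images = [
        ProjectionImage(i0 * np.exp(-im.pixels), "intensity", im.angle)
        for im in projections.images
    ]
    return ProjectionSet(projections.geometry, images)


def save_projections(projections: ProjectionSet, path, geometry_path=None, seed=None):
    """Multi-page float32 TIFF stack plus a JSON geometry sidecar."""
    import tifffile

    from .geometry import save_geometry

    tifffile.imwrite(str(path), projections.stack().astype(np.float32))
    if geometry_path is not None:
        extra = {"representation": projections.representation}
        if seed is not None:
            extra["seed"] = seed
        save_geometry(projections.geometry, geometry_path, **extra)


def load_projections(path, geometry_path) -> ProjectionSet:
    import json

    import tifffile

    from .geometry import load_geometry

    stack = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    geometry = load_geometry(geometry_path)
    rep = json.loads(open(geometry_path).read()).get("representation", "intensity")
    images = [
        ProjectionImage(stack[k], rep, float(geometry.angles[k]))
        for k in range(geometry.n_views)
    ]
    return ProjectionSet(geometry, images)
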