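"""Cone-beam acquisition geometry and the attenuation volume container.

Conventions (fixed for the whole package):

* Right-handed world frame in millimetres; the gantry rotates about +z.
* A :class:`VolumeGrid` stores linear attenuation coefficients mu (mm^-1) on a
  regular voxel grid; a voxel's world position is its *center*, 0-based
  indexing, ``origin`` is the world position of voxel (0, 0, 0).
* At gantry angle ``theta`` the X-ray source sits at
  ``sad * (cos t, sin t, 0)`` and the flat-panel detector center at
  ``-(sdd - sad) * (cos t, sin t, 0)``; the detector's u axis is the in-plane
  direction ``(-sin t, cos t, 0)`` and its v axis is +z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VolumeGrid",
    "ConeBeamGeometry",
    "Ray",
    "RayBundle",
    "generate_rays",
    "volume_aabb_intersect",
    "fit_detector",
    "save_volume",
    "load_volume",
    "save_geometry",
    "load_geometry",
]


@dataclass
class VolumeGrid:
    """3D array of linear attenuation coefficients with world placement.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)``, mu in mm^-1, finite and >= 0.
    spacing
        Voxel size ``(sx, sy, sz)`` in mm, strictly positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("attenuation values must be non-negative")
        if self.origin is None:
            # center the grid on the rotation axis (world origin)
            self.origin = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.values.shape, self.spacing)
            )
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def world_min(self) -> np.ndarray:
        """Lower corner of the volume's world extent (voxel faces, not centers)."""
        return np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)

    @property
    def world_max(self) -> np.ndarray:
        return self.world_min + np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def extent(self) -> np.ndarray:
        """World size (mm) along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.extent))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.world_min + self.world_max)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (mm)."""
        points = np.asarray(points, dtype=np.float64)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=np.float64) * np.asarray(self.spacing) + np.asarray(
            self.origin
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


@dataclass
class ConeBeamGeometry:
    """Circular cone-beam acquisition: point source + flat-panel detector.

    ``sad`` is the source-to-rotation-axis distance, ``sdd`` the
    source-to-detector distance (both mm, ``sdd > sad > 0``).  The detector
    raster is ``detector_shape = (nu, nv)`` pixels of ``detector_spacing =
    (du, dv)`` mm; ``angles`` are the ordered gantry angles in ``[0, 2*pi)``.
    ``i0`` is the unattenuated beam intensity.
    """

    sad: float = 500.0
    sdd: float = 1000.0
    detector_shape: tuple[int, int] = (64, 64)
    detector_spacing: tuple[float, float] = (2.0, 2.0)
    angles: np.ndarray = field(default_factory=lambda: np.zeros(1))
    i0: float = 1.0

    def __post_init__(self) -> None:
        self.sad = float(self.sad)
        self.sdd = float(self.sdd)
        if not (self.sdd > self.sad > 0):
            raise ValueError(f"need sdd > sad > 0, got sad={self.sad}, sdd={self.sdd}")
        self.detector_shape = (int(self.detector_shape[0]), int(self.detector_shape[1]))
        self.detector_spacing = (
            float(self.detector_spacing[0]),
            float(self.detector_spacing[1]),
        )
        if min(self.detector_shape) < 1 or min(self.detector_spacing) <= 0:
            raise ValueError("detector shape and spacing must be strictly positive")
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=np.float64))
        if np.any(self.angles < 0) or np.any(self.angles >= 2 * np.pi):
            raise ValueError("angles must lie in [0, 2*pi)")
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")

    @classmethod
    def circular(
        cls,
        n_views: int = 50,
        arc: float = 2 * np.pi,
        **kwargs,
    ) -> "ConeBeamGeometry":
        """Equally spaced views covering ``arc`` radians (endpoint excluded)."""
        angles = (arc * np.arange(n_views) / n_views) % (2 * np.pi)
        return cls(angles=angles, **kwargs)

    @property
    def n_views(self) -> int:
        return len(self.angles)

    def source_position(self, angle_index: int) -> np.ndarray:
        t = self.angles[angle_index]
        return self.sad * np.array([np.cos(t), np.sin(t), 0.0])

    def detector_frame(self, angle_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(detector center, u axis, v axis) at one view."""
        t = self.angles[angle_index]
        radial = np.array([np.cos(t), np.sin(t), 0.0])
        center = -(self.sdd - self.sad) * radial
        u_hat = np.array([-np.sin(t), np.cos(t), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        return center, u_hat, v_hat

    def detector_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (u, v) offsets (mm) of pixel centers from the detector center."""
        nu, nv = self.detector_shape
        du, dv = self.detector_spacing
        u = (np.arange(nu) - (nu - 1) / 2.0) * du
        v = (np.arange(nv) - (nv - 1) / 2.0) * dv
        return u, v

    def with_angles(self, angles: np.ndarray) -> "ConeBeamGeometry":
        return replace(self, angles=np.asarray(angles, dtype=np.float64))


@dataclass
class Ray:
    """A single ray; ``t_near == t_far`` flags a miss."""

    origin: np.ndarray
    direction: np.ndarray
    t_near: float = 0.0
    t_far: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"ray direction must be unit-norm, |d| = {n}")


@dataclass
class RayBundle:
    """Struct-of-arrays ray batch: one ray per detector pixel (or arbitrary set)."""

    origins: np.ndarray  # (N, 3)
    directions: np.ndarray  # (N, 3), unit
    t_near: np.ndarray  # (N,)
    t_far: np.ndarray  # (N,)
    image_shape: tuple[int, int] | None = None  # (nv, nu) when pixel-ordered

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def hits(self) -> np.ndarray:
        return self.t_far > self.t_near

    def __getitem__(self, idx) -> "RayBundle":
        return RayBundle(
            self.origins[idx], self.directions[idx], self.t_near[idx], self.t_far[idx]
        )


def _aabb_intersect_arrays(
    origins: np.ndarray,
    directions: np.ndarray,
    world_min: np.ndarray,
    world_max: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Slab-method ray/AABB intersection; misses get t_near = t_far = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / directions
        t0 = (world_min - origins) * inv
        t1 = (world_max - origins) * inv
    tmin = np.minimum(t0, t1)
    tmax = np.maximum(t0, t1)
    # rays parallel to a slab: inside -> (-inf, inf); outside -> empty interval
    parallel = directions == 0.0
    inside = (origins >= world_min) & (origins <= world_max)
    tmin = np.where(parallel, np.where(inside, -np.inf, np.inf), tmin)
    tmax = np.where(parallel, np.where(inside, np.inf, -np.inf), tmax)
    lo = tmin.max(axis=-1)
    hi = tmax.min(axis=-1)
    lo = np.maximum(lo, 0.0)
    miss = hi <= lo
    lo = np.where(miss, 0.0, lo)
    hi = np.where(miss, 0.0, hi)
    return lo, hi


def volume_aabb_intersect(ray, volume: VolumeGrid):
    """Entry/exit parameters of a ray (or bundle) against the volume's box.

    Returns ``(t_near, t_far)``; a miss is reported as ``t_near == t_far == 0``
    (a value, not an error).
    """
    if isinstance(ray, RayBundle):
        lo, hi = _aabb_intersect_arrays(
            ray.origins, ray.directions, volume.world_min, volume.world_max
        )
        return lo, hi
    lo, hi = _aabb_intersect_arrays(
        ray.origin[None], ray.direction[None], volume.world_min, volume.world_max
    )
    return float(lo[0]), float(hi[0])


def generate_rays(
    geometry: ConeBeamGeometry, angle_index: int, volume: VolumeGrid
) -> RayBundle:
    """One ray per detector pixel at a view, clipped to the volume's box.

    Pixels are ordered row-major as ``(iv, iu)`` so images are ``(nv, nu)``
    arrays.  Rays missing the volume carry ``t_near == t_far``.
    """
    if not (0 <= angle_index < geometry.n_views):
        raise IndexError(
            f"angle_index {angle_index} out of range [0, {geometry.n_views})"
        )
    source = geometry.source_position(angle_index)
    center, u_hat, v_hat = geometry.detector_frame(angle_index)
    u, v = geometry.detector_coords()
    uu, vv = np.meshgrid(u, v)  # (nv, nu)
    pixels = center + uu[..., None] * u_hat + vv[..., None] * v_hat
    directions = pixels - source
    directions /= np.linalg.norm(directions, axis=-1, keepdims=True)
    nv, nu = directions.shape[:2]
    origins = np.broadcast_to(source, (nv * nu, 3)).copy()
    directions = directions.reshape(-1, 3)
    t_near, t_far = _aabb_intersect_arrays(
        origins, directions, volume.world_min, volume.world_max
    )
    return RayBundle(origins, directions, t_near, t_far, image_shape=(nv, nu))


def fit_detector(
    volume: VolumeGrid,
    sad: float = 500.0,
    sdd: float = 1000.0,
    n_pixels: int = 64,
    margin: float = 0.1,
    square: bool = True,
) -> tuple[tuple[int, int], tuple[float, float]]:
    """Detector raster sized so the volume's projection fits with a margin.

    The worst-case magnification of a point at distance R from the axis is
    ``sdd / (sad - R)``; the detector half-size is that times ``R`` times
    ``1 + margin``.
    """
    corners = np.array(
        [
            [x, y, z]
            for x in (volume.world_min[0], volume.world_max[0])
            for y in (volume.world_min[1], volume.world_max[1])
            for z in (volume.world_min[2], volume.world_max[2])
        ]
    )
    r = float(np.max(np.linalg.norm(corners, axis=1)))
    if r >= sad:
        raise ValueError("volume does not fit between source and rotation axis")
    half = (1.0 + margin) * r * sdd / (sad - r)
    pitch = 2 * half / n_pixels
    shape = (n_pixels, n_pixels)
    spacing = (pitch, pitch)
    if not square:
        return shape, spacing
    return shape, spacing


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes, JSON geometry sidecars
# ---------------------------------------------------------------------------


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI; spacing goes in the affine/header, origin in the affine."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin)


def save_geometry(geometry: ConeBeamGeometry, path: str | Path, **extra) -> None:
    payload = {
        "sad": geometry.sad,
        "sdd": geometry.sdd,
        "detector_shape": list(geometry.detector_shape),
        "detector_spacing": list(geometry.detector_spacing),
        "angles": [float(a) for a in geometry.angles],
        "i0": geometry.i0,
    }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry(path: str | Path) -> ConeBeamGeometry:
    payload = json.loads(Path(path).read_text())
    return ConeBeamGeometry(
        sad=payload["sad"],
        sdd=payload["sdd"],
        detector_shape=tuple(payload["detector_shape"]),
        detector_spacing=tuple(payload["detector_spacing"]),
        angles=np.asarray(payload["angles"]),
        i0=payload.get("i0", 1.0),
    )
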