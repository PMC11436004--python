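"""Inverse outputs: field-to-volume extraction and the FDK baseline.

``extract_volume`` samples a trained attenuation field at every voxel center
of an arbitrary grid — the field is continuous, so the extraction resolution
is decoupled from the training data.

``fdk_reconstruct`` is the classical Feldkamp-Davis-Kress filtered
backprojection for circular cone-beam data, implemented from first
principles:

1. convert projections to line integrals;
2. scale detector coordinates to the isocenter plane
   (``u' = u * sad / sdd``) and apply the cosine pre-weight
   ``sad / sqrt(sad^2 + u'^2 + v'^2)``;
3. convolve each detector row with the discrete ramp kernel (Ram-Lak; Hann
   apodization optional) using zero-padded FFT convolution;
4. backproject with the magnification weight ``(sad / L)^2`` where
   ``L = sad - x . s_hat`` is the voxel's distance-to-source along the
   central axis, integrating over angles with weight ``delta_theta / 2``.

Full-scan (360 degree) data is assumed; there is no short-scan weighting.
Negative output values are clamped to zero (attenuation cannot be negative)
and the clamp count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import VolumeGrid
from .projector import ProjectionSet, to_line_integrals

__all__ = ["GridSpec", "extract_volume", "fdk_reconstruct", "ramp_kernel"]

log = logging.getLogger(__name__)


@dataclass
class GridSpec:
    """Shape/spacing/origin of an output grid (a VolumeGrid without values)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.shape = tuple(int(n) for n in np.broadcast_to(self.shape, (3,)))
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if min(self.spacing) <= 0:
            raise ValueError("grid spacing must be strictly positive")
        if self.origin is None:
            self.origin = tuple(
                -(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing)
            )
        else:
            self.origin = tuple(float(o) for o in self.origin)

    @classmethod
    def like(cls, volume: VolumeGrid) -> "GridSpec":
        return cls(volume.shape, volume.spacing, volume.origin)

    def empty(self) -> VolumeGrid:
        return VolumeGrid(np.zeros(self.shape), self.spacing, self.origin)

    def voxel_centers(self) -> np.ndarray:
        return self.empty().voxel_centers()


def extract_volume(
    field,
    grid: GridSpec,
    batch_size: int = 65536,
) -> VolumeGrid:
    """Sample mu at every voxel center of ``grid``, in batches.

    The grid must lie within the field's declared scene bounds; the offending
    axis is named otherwise.  Output is deterministic and independent of
    ``batch_size``.
    """
    tmp = grid.empty()
    lo = tmp.world_min + 0.499 * np.asarray(grid.spacing)  # voxel centers only
    hi = tmp.world_max - 0.499 * np.asarray(grid.spacing)
    smin = np.asarray(field.scene_center) - np.asarray(field.scene_half_extent)
    smax = np.asarray(field.scene_center) + np.asarray(field.scene_half_extent)
    for axis, name in enumerate("xyz"):
        if lo[axis] < smin[axis] - 1e-9 or hi[axis] > smax[axis] + 1e-9:
            raise ValueError(
                f"extraction grid exceeds the field's scene bounds along {name}"
            )
    points = grid.voxel_centers().reshape(-1, 3)
    out = np.empty(len(points), dtype=np.float64)
    for start in range(0, len(points), batch_size):
        out[start : start + batch_size] = field.query_mu(points[start : start + batch_size])
    return VolumeGrid(out.reshape(grid.shape), grid.spacing, grid.origin)


def ramp_kernel(n: int, pitch: float, filter_name: str = "ramlak") -> np.ndarray:
    """Frequency response (rfft) of the discrete ramp filter on 2n samples.

    Built from the exact space-domain Ram-Lak kernel
    ``h(0) = 1/(4 pitch^2)``, ``h(odd k) = -1/(pi k pitch)^2``, ``h(even) = 0``
    so the DC behaviour is correct; ``hann`` multiplies the response by a
    Hann window over frequency.
    """
    if filter_name not in ("ramlak", "hann"):
        raise ValueError(f"unknown filter {filter_name!r}; use 'ramlak' or 'hann'")
    size = 2 * n
    k = np.concatenate([np.arange(0, n), np.arange(-n, 0)])
    h = np.zeros(size)
    h[0] = 1.0 / (4.0 * pitch**2)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * pitch) ** 2
    response = np.fft.rfft(h)
    if filter_name == "hann":
        f = np.linspace(0, 1, len(response))
        response = response * (0.5 + 0.5 * np.cos(np.pi * f))
    return response


def fdk_reconstruct(
    projections: ProjectionSet,
    grid: GridSpec,
    filter_name: str = "ramlak",
    clamp_negative: bool = True,
) -> VolumeGrid:
    """Feldkamp filtered backprojection of a circular cone-beam set."""
    geometry = projections.geometry
    if geometry.n_views < 2:
        raise ValueError("FDK needs at least 2 views")
    li = to_line_integrals(projections)
    sad, sdd = geometry.sad, geometry.sdd
    u, v = geometry.detector_coords()
    u_iso = u * sad / sdd
    v_iso = v * sad / sdd
    du_iso = geometry.detector_spacing[0] * sad / sdd
    cosw = sad / np.sqrt(sad**2 + u_iso[None, :] ** 2 + v_iso[:, None] ** 2)

    nu = geometry.detector_shape[0]
    pad = 1 << int(np.ceil(np.log2(max(2 * nu, 4))))
    response = ramp_kernel(pad // 2, du_iso, filter_name)

    # filter all views: rows are along u
    filtered = np.empty((geometry.n_views,) + li.images[0].pixels.shape)
    for k in range(geometry.n_views):
        weighted = li.images[k].pixels * cosw
        spec = np.fft.rfft(weighted, n=pad, axis=1)
        conv = np.fft.irfft(spec * response, n=pad, axis=1)[:, :nu]
        filtered[k] = conv * du_iso

    # backproject
    out = grid.empty()
    coords = out.voxel_centers()
    x = coords[..., 0]
    y = coords[..., 1]
    z = coords[..., 2]
    recon = np.zeros(grid.shape)
    d_theta = 2 * np.pi / geometry.n_views
    nu_c = (nu - 1) / 2.0
    nv_c = (geometry.detector_shape[1] - 1) / 2.0
    for k in range(geometry.n_views):
        t = geometry.angles[k]
        ct, st = np.cos(t), np.sin(t)
        ell = sad - (x * ct + y * st)
        ratio = sad / ell
        uu = (-x * st + y * ct) * ratio  # isocenter-plane u of each voxel
        vv = z * ratio
        col = uu / du_iso + nu_c
        row = vv / (geometry.detector_spacing[1] * sad / sdd) + nv_c
        sample = map_coordinates(
            filtered[k], [row.ravel(), col.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(grid.shape)
        recon += ratio**2 * sample
    recon *= d_theta / 2.0

    negatives = int(np.count_nonzero(recon < 0))
    if clamp_negative:
        if negatives:
            log.info("FDK: clamped %d negative voxels to 0", negatives)
        recon = np.clip(recon, 0.0, None)
        return VolumeGrid(recon, grid.spacing, grid.origin)
    # unclamped output for linearity analysis: bypass the >= 0 invariant
    vol = VolumeGrid(np.zeros(grid.shape), grid.spacing, grid.origin)
    vol.values = recon
    return vol
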