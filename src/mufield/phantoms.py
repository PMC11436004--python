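"""Deterministic synthetic phantoms for cone-beam reconstruction studies.

Four archetypes mirror the structural regimes encountered in clinical CT
studies of this kind:

``hard_thin``
    a soft-tissue body containing thin, high-contrast bone-like rods
    (extremity bones: thin hard structures).
``hard_multi``
    a body containing an arc of dense tooth-like inserts of diverse shape
    (dental anatomy: multi-part hard structures).
``soft_adjacent``
    adjacent organ-like blobs whose attenuation differs from their
    surroundings by at most ~20% (abdominal soft tissue).
``soft_fine``
    fine, low-contrast filaments branching through a lung-like background
    (pulmonary vasculature).

All phantoms are built from analytic primitives (ellipsoids, capsules,
superellipsoids) rasterized onto the grid; the only randomness is primitive
placement/size through the seed, so output is bit-reproducible.  Values are
linear attenuation coefficients in mm^-1, clipped to ``MU_MAX``; the scale is
chosen so typical line integrals fall in roughly [0.5, 5], keeping
``exp(-p)`` well conditioned.
"""

from __future__ import annotations

import numpy as np

from .geometry import VolumeGrid

__all__ = ["ARCHETYPES", "MU_MAX", "make_phantom", "cylinder_phantom"]

ARCHETYPES = ("hard_thin", "hard_multi", "soft_adjacent", "soft_fine")

#: documented upper bound on phantom attenuation (mm^-1)
MU_MAX = 0.1

_MU_SOFT_BODY = 0.015  # surrounding soft tissue for the hard archetypes
_MU_BONE = 0.09
_MU_ORGAN_BODY = 0.020  # body for the soft archetypes


def _ellipsoid_mask(coords, center, radii, rotation=None):
    d = coords - np.asarray(center)
    if rotation is not None:
        d = d @ rotation.T
    return np.sum((d / np.asarray(radii)) ** 2, axis=-1) <= 1.0


def _superellipsoid_mask(coords, center, radii, power):
    d = np.abs((coords - np.asarray(center)) / np.asarray(radii))
    return np.sum(d**power, axis=-1) <= 1.0


def _capsule_mask(coords, p0, p1, radius):
    """Points within ``radius`` of the segment p0-p1."""
    p0 = np.asarray(p0, dtype=np.float64)
    seg = np.asarray(p1, dtype=np.float64) - p0
    seg_len2 = float(seg @ seg)
    rel = coords - p0
    t = np.clip((rel @ seg) / max(seg_len2, 1e-12), 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    return np.linalg.norm(coords - closest, axis=-1) <= radius


def _random_rotation(rng):
    # QR of a Gaussian matrix gives a Haar-ish rotation; sign-fix determinant
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _body(coords, extent):
    return _ellipsoid_mask(coords, (0, 0, 0), 0.42 * extent)


def _hard_thin(values, coords, extent, rng):
    body = _body(coords, extent)
    values[body] = _MU_SOFT_BODY
    n_rods = rng.integers(3, 6)
    for _ in range(n_rods):
        # rods span most of the body, randomly oriented, thin radius
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = rng.uniform(-0.15, 0.15, size=3) * extent
        half_len = rng.uniform(0.25, 0.38) * float(np.min(extent))
        radius = rng.uniform(0.02, 0.04) * float(np.min(extent))
        rod = _capsule_mask(
            coords, center - half_len * direction, center + half_len * direction, radius
        )
        values[rod & body] = _MU_BONE * rng.uniform(0.95, 1.05)


def _hard_multi(values, coords, extent, rng):
    body = _body(coords, extent)
    values[body] = _MU_SOFT_BODY
    n_teeth = rng.integers(6, 10)
    arc_r = 0.28 * float(np.min(extent))
    phis = np.linspace(-2.0, 2.0, n_teeth) + rng.uniform(-0.05, 0.05, size=n_teeth)
    for phi in phis:
        center = np.array([arc_r * np.cos(phi), arc_r * np.sin(phi), 0.0])
        center += rng.uniform(-0.02, 0.02, size=3) * extent
        radii = rng.uniform(0.03, 0.07, size=3) * float(np.min(extent))
        radii[2] *= 1.6  # teeth are taller than wide
        power = rng.uniform(2.0, 4.0)
        tooth = _superellipsoid_mask(coords, center, radii, power)
        values[tooth & body] = rng.uniform(0.85, 1.1) * _MU_BONE


def _soft_adjacent(values, coords, extent, rng):
    body = _body(coords, extent)
    values[body] = _MU_ORGAN_BODY
    # adjacent but disjoint organ blobs; contrast to body <= ~20%
    n_organs = 3
    centers = np.array(
        [[-0.18, -0.1, 0.0], [0.18, -0.1, 0.02], [0.0, 0.17, -0.02]]
    ) * extent
    for k in range(n_organs):
        center = centers[k] + rng.uniform(-0.02, 0.02, size=3) * extent
        radii = rng.uniform(0.10, 0.14, size=3) * extent
        mu = _MU_ORGAN_BODY * (1.0 + rng.uniform(0.10, 0.18))
        mask = _ellipsoid_mask(coords, center, radii, _random_rotation(rng))
        values[mask & body] = mu


def _soft_fine(values, coords, extent, rng):
    body = _body(coords, extent)
    values[body] = _MU_ORGAN_BODY
    mu_vessel = _MU_ORGAN_BODY * 1.15
    # branching filaments grown from the center outward
    n_trunks = rng.integers(4, 7)
    for _ in range(n_trunks):
        point = rng.uniform(-0.05, 0.05, size=3) * extent
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(0.015, 0.03) * float(np.min(extent))
        for _depth in range(3):
            length = rng.uniform(0.12, 0.2) * float(np.min(extent))
            end = point + length * direction
            seg = _capsule_mask(coords, point, end, radius)
            values[seg & body] = mu_vessel
            point = end
            # branch: deflect the direction
            deflect = rng.normal(size=3)
            direction = direction + 0.7 * deflect / np.linalg.norm(deflect)
            direction /= np.linalg.norm(direction)
            radius *= 0.8


_BUILDERS = {
    "hard_thin": _hard_thin,
    "hard_multi": _hard_multi,
    "soft_adjacent": _soft_adjacent,
    "soft_fine": _soft_fine,
}


def make_phantom(
    kind: str,
    shape: int | tuple[int, int, int] = (64, 64, 64),
    spacing: float | tuple[float, float, float] = 1.0,
    seed: int = 0,
) -> VolumeGrid:
    """Build one of the four phantom archetypes, centered on the rotation axis.

    Deterministic given ``(kind, shape, spacing, seed)``.  Background mu is 0
    outside an ellipsoidal body envelope; hard kinds contain inserts with at
    least a 5x contrast over the surrounding body, soft kinds contain
    structures within ~20% of their surround.
    """
    if kind not in _BUILDERS:
        raise ValueError(
            f"unknown phantom kind {kind!r}; valid kinds: {sorted(_BUILDERS)}"
        )
    shape = tuple(int(n) for n in np.broadcast_to(shape, (3,)))
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    if min(shape) < 16:
        raise ValueError(f"shape must be >= 16 per axis, got {shape}")
    if min(spacing) <= 0:
        raise ValueError(f"spacing must be strictly positive, got {spacing}")

    grid = VolumeGrid(np.zeros(shape, dtype=np.float64), spacing)
    coords = grid.voxel_centers()
    extent = grid.extent
    rng = np.random.default_rng([seed, ARCHETYPES.index(kind)])
    _BUILDERS[kind](grid.values, coords, extent, rng)
    np.clip(grid.values, 0.0, MU_MAX, out=grid.values)
    return grid


def cylinder_phantom(
    shape: int | tuple[int, int, int] = (64, 64, 64),
    spacing: float = 1.0,
    radius_frac: float = 0.35,
    height_frac: float = 0.7,
    mu: float = 0.02,
) -> VolumeGrid:
    """Homogeneous axis-aligned cylinder, handy for analytic reconstructions."""
    shape = tuple(int(n) for n in np.broadcast_to(shape, (3,)))
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    grid = VolumeGrid(np.zeros(shape, dtype=np.float64), spacing)
    coords = grid.voxel_centers()
    extent = grid.extent
    r = radius_frac * float(min(extent[0], extent[1]))
    h = 0.5 * height_frac * float(extent[2])
    mask = (coords[..., 0] ** 2 + coords[..., 1] ** 2 <= r * r) & (
        np.abs(coords[..., 2]) <= h
    )
    grid.values[mask] = mu
    return grid
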