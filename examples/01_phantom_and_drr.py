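"""Simulate a cone-beam acquisition of a synthetic phantom.

Builds a 32^3 soft-tissue phantom, fits a detector around it, renders 20
digitally reconstructed radiographs (DRRs) over a full circle, and prints
the transmission statistics.  Transmission I/I0 = 1 means the ray only saw
air; smaller values mean more accumulated attenuation (p = -ln(I/I0)).
"""

import numpy as np

import mufield as mf

phantom = mf.make_phantom("soft_adjacent", shape=32, spacing=1.0, seed=7)
print(f"phantom: {phantom.shape} voxels, mu in [0, {phantom.values.max():.4f}] /mm")

det_shape, det_spacing = mf.fit_detector(phantom, sad=500, sdd=1000, n_pixels=32)
geometry = mf.ConeBeamGeometry.circular(
    n_views=20, sad=500, sdd=1000,
    detector_shape=det_shape, detector_spacing=det_spacing,
)
projections = mf.render_drr(phantom, geometry, n_samples=64)
stack = projections.stack()
p = mf.to_line_integrals(projections).stack()
print(f"{len(projections)} views of {stack.shape[1:]} pixels")
print(f"transmission I/I0: min {stack.min():.3f} (densest path), max {stack.max():.3f}")
print(f"line integrals p:  max {p.max():.3f} (dimensionless attenuation length)")
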