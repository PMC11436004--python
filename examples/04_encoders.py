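"""The four input encodings, side by side on the same 3D point.

Shows the feature vectors the field variants actually consume: plain
Fourier features, their variance-damped integrated counterpart for a
conical ray segment, the learnable multiresolution hash features, and
pixel-aligned reference-image features.
"""

import numpy as np

import mufield as mf
from mufield.autodiff import Tensor

x = np.array([[0.3, -0.5, 0.1]])  # a point in the normalized [-1, 1]^3 cube

fourier_cfg = mf.FourierEncodingConfig(num_frequencies=10, include_input=True)
plain = mf.fourier_encode(x, fourier_cfg)
print(f"Fourier encoding: {plain.shape[1]} features (3 + 3*2*10), |max| = {np.abs(plain).max():.3f}")

g = mf.conical_frustum_to_gaussian(
    origin=[0, 0, 0], direction=[0, 0, 1.0], t0=100.0, t1=104.0, base_radius=0.002
)
print(f"frustum gaussian: mean z = {g.mean[2]:.2f} mm, along-ray var = {g.t_var:.3f} mm^2")
damped = mf.integrated_fourier_encode(
    mf.FrustumGaussian(x, np.full((1, 3), 1e-3)), fourier_cfg
)
print(
    "integrated encoding damps high frequencies: "
    f"top-band |max| {np.abs(damped[0, -6:]).max():.2e} vs plain {np.abs(plain[0, -6:]).max():.2f}"
)

hash_enc = mf.HashEncoder(mf.HashEncodingConfig(finest_resolution=32, seed=0))
feats = hash_enc.encode((x + 1) / 2)
print(f"hash encoding: {feats.data.shape[1]} features from {len(hash_enc.resolutions)} levels, "
      f"resolutions {[int(r) for r in hash_enc.resolutions]}")

geometry = mf.ConeBeamGeometry.circular(6, detector_shape=(32, 32), detector_spacing=(3.0, 3.0))
extractor = mf.ConvFeatureExtractor(feature_channels=8, seed=0)
maps = extractor(np.random.default_rng(0).random((3, 32, 32)))
cond = mf.extract_reference_features(
    np.zeros((1, 3)), maps, geometry, [0, 2, 4], downsample=extractor.downsample
)
print(f"reference conditioning: {cond.data.shape[1]} channels averaged over 3 views")
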