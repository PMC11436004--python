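"""Attenuation-field function approximators: per-variant MLP presets.

A field maps a world position to a non-negative linear attenuation
coefficient mu(x).  There is no view-direction input anywhere: attenuation is
isotropic, a deliberate departure from the natural-image architectures the
variants descend from.  Four presets are provided:

========  ==========================  ======  =====  ====  =======
variant   encoder                     layers  skip   chan  lr
========  ==========================  ======  =====  ====  =======
vanilla   Fourier, L = 10             8       5      128   5e-4
mip       integrated Fourier, L = 10  8       5      128   5e-4
ingp      hash grid, 2^20 table       4       3      128   1e-3
pixel     Fourier + 3 ref. views      3       2      128   5e-4
========  ==========================  ======  =====  ====  =======

Hidden activation is ReLU; the skip connection concatenates the raw encoded
input to the given (1-based) layer's input; the output head is a single
linear unit through a softplus, which keeps mu strictly non-negative at any
training stage.  World coordinates are normalized to [-1, 1]^3 as
``(x - center) / half_extent`` against the declared scene bounds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dfield
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import (
    ConvFeatureExtractor,
    FourierEncodingConfig,
    FrustumGaussian,
    HashEncoder,
    HashEncodingConfig,
    fourier_encode,
    integrated_fourier_encode,
)

__all__ = ["MLPConfig", "VARIANTS", "AttenuationField", "build_field"]

VARIANTS = ("vanilla", "mip", "ingp", "pixel")


@dataclass(frozen=True)
class MLPConfig:
    num_layers: int = 8
    hidden_channels: int = 128
    skip_layer: int = 5  # 1-based; this layer's input gets the encoding concatenated
    output_activation: str = "softplus"

    def __post_init__(self):
        if not (1 <= self.skip_layer <= self.num_layers):
            raise ValueError(
                f"skip_layer must be in [1, {self.num_layers}], got {self.skip_layer}"
            )
        if self.hidden_channels < 1:
            raise ValueError("hidden_channels must be >= 1")


_PRESETS = {
    "vanilla": dict(
        mlp=MLPConfig(num_layers=8, skip_layer=5),
        learning_rate=5e-4,
        encoder="fourier",
    ),
    "mip": dict(
        mlp=MLPConfig(num_layers=8, skip_layer=5),
        learning_rate=5e-4,
        encoder="integrated_fourier",
    ),
    "ingp": dict(
        mlp=MLPConfig(num_layers=4, skip_layer=3),
        learning_rate=1e-3,
        encoder="hash",
    ),
    "pixel": dict(
        mlp=MLPConfig(num_layers=3, skip_layer=2),
        learning_rate=5e-4,
        encoder="fourier+reference",
    ),
}

_REFERENCE_VIEWS = 3


class AttenuationField:
    """A trainable position -> mu mapping with a variant-bound encoder."""

    def __init__(
        self,
        variant: str,
        scene_center,
        scene_half_extent,
        fourier: FourierEncodingConfig | None = None,
        hash_config: HashEncodingConfig | None = None,
        mlp: MLPConfig | None = None,
        learning_rate: float | None = None,
        reference_views: int = _REFERENCE_VIEWS,
        feature_extractor: ConvFeatureExtractor | None = None,
        seed: int = 0,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; valid: {list(VARIANTS)}")
        preset = _PRESETS[variant]
        self.variant = variant
        self.scene_center = np.asarray(scene_center, dtype=np.float64)
        self.scene_half_extent = np.asarray(scene_half_extent, dtype=np.float64)
        self.fourier = fourier or FourierEncodingConfig(num_frequencies=10)
        self.hash_config = hash_config
        self.mlp = mlp or preset["mlp"]
        self.learning_rate = (
            learning_rate if learning_rate is not None else preset["learning_rate"]
        )
        self.reference_views = reference_views
        self.seed = seed

        self.hash_encoder = None
        self.feature_extractor = None
        in_dim = 0
        if variant in ("vanilla", "mip", "pixel"):
            in_dim += self.fourier.output_dim(3)
        if variant == "ingp":
            if self.hash_config is None:
                self.hash_config = HashEncodingConfig(seed=seed)
            self.hash_encoder = HashEncoder(self.hash_config)
            in_dim += self.hash_encoder.output_dim
        if variant == "pixel":
            self.feature_extractor = feature_extractor or ConvFeatureExtractor(
                seed=seed + 1
            )
            in_dim += self.feature_extractor.feature_channels
        self.input_dim = in_dim
        # optional points -> context callable, bound by the trainer so that
        # context-dependent variants (pixel) stay queryable after training
        self.default_context_builder = None
        self._init_mlp(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------

    def _init_mlp(self, rng) -> None:
        """Fan-in uniform initialization of every dense layer."""
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        dim = self.input_dim
        for layer in range(1, self.mlp.num_layers + 1):
            d_in = dim + (self.input_dim if layer == self.mlp.skip_layer and layer > 1 else 0)
            d_out = self.mlp.hidden_channels
            bound = 1.0 / np.sqrt(d_in)
            self.weights.append(
                Tensor(
                    rng.uniform(-bound, bound, size=(d_in, d_out)).astype(np.float32),
                    requires_grad=True,
                )
            )
            self.biases.append(
                Tensor(
                    rng.uniform(-bound, bound, size=(d_out,)).astype(np.float32),
                    requires_grad=True,
                )
            )
            dim = d_out
        bound = 1.0 / np.sqrt(dim)
        self.w_out = Tensor(
            rng.uniform(-bound, bound, size=(dim, 1)).astype(np.float32),
            requires_grad=True,
        )
        # start the field at ~0.01 mm^-1 (soft-tissue scale): a head biased
        # at softplus(0) ~ 0.7 over-predicts line integrals ~40x, and the
        # resulting first updates drive softplus into its dead tail
        self.b_out = Tensor(
            np.array([np.log(np.expm1(0.01))], dtype=np.float32),
            requires_grad=True,
        )

    @property
    def params(self) -> list[Tensor]:
        p = list(self.weights) + list(self.biases) + [self.w_out, self.b_out]
        if self.hash_encoder is not None:
            p += self.hash_encoder.params
        if self.feature_extractor is not None:
            p += self.feature_extractor.params
        return p

    # -- coordinate handling -------------------------------------------------

    def normalize(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World mm -> [-1, 1]^3; out-of-bounds points are clamped and flagged."""
        x = (np.asarray(points, dtype=np.float64) - self.scene_center) / (
            self.scene_half_extent
        )
        outside = np.any(np.abs(x) > 1.0 + 1e-9, axis=-1)
        return np.clip(x, -1.0, 1.0), outside

    # -- forward -------------------------------------------------------------

    def encode(self, points: np.ndarray, context=None) -> Tensor:
        """Encoded (and optionally conditioned) input features for a point batch."""
        x, _ = self.normalize(points)
        blocks: list[Tensor] = []
        if self.variant == "vanilla":
            blocks.append(Tensor(fourier_encode(x, self.fourier).astype(np.float32)))
        elif self.variant == "mip":
            if context is not None and "frustum" in context:
                g: FrustumGaussian = context["frustum"]
                mean_n, _ = self.normalize(g.mean)
                var_n = g.variance / self.scene_half_extent**2
                enc = integrated_fourier_encode(
                    FrustumGaussian(mean_n, var_n), self.fourier
                )
            else:  # point query: zero-variance limit
                enc = fourier_encode(x, self.fourier)
            blocks.append(Tensor(enc.astype(np.float32)))
        elif self.variant == "ingp":
            blocks.append(self.hash_encoder.encode((x + 1.0) / 2.0))
        elif self.variant == "pixel":
            blocks.append(Tensor(fourier_encode(x, self.fourier).astype(np.float32)))
            if context is None or "reference_features" not in context:
                raise ValueError(
                    "the pixel variant requires reference-image features in the "
                    "query context (key 'reference_features')"
                )
            blocks.append(context["reference_features"])
        if len(blocks) == 1:
            return blocks[0]
        return ad.concat(blocks, axis=-1)

    def forward(self, encoded: Tensor) -> Tensor:
        """MLP head: encoded features -> mu, shape (n, 1)."""
        h = encoded
        for layer in range(1, self.mlp.num_layers + 1):
            if layer == self.mlp.skip_layer and layer > 1:
                h = ad.concat([h, encoded], axis=-1)
            h = ad.relu(ad.affine(h, self.weights[layer - 1], self.biases[layer - 1]))
        return ad.softplus(ad.affine(h, self.w_out, self.b_out))

    def query_mu(self, points: np.ndarray, context=None) -> np.ndarray:
        """Evaluate mu at world points (no gradient bookkeeping kept)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if context is None and self.default_context_builder is not None:
            context = self.default_context_builder(points)
        out = self.forward(self.encode(points, context))
        return out.data.reshape(-1).astype(np.float64)

    # -- introspection / persistence ------------------------------------------

    def config_dump(self) -> dict:
        cfg = {
            "variant": self.variant,
            "mlp": asdict(self.mlp),
            "learning_rate": self.learning_rate,
            "scene_center": self.scene_center.tolist(),
            "scene_half_extent": self.scene_half_extent.tolist(),
            "seed": self.seed,
        }
        if self.variant in ("vanilla", "mip", "pixel"):
            cfg["fourier"] = asdict(self.fourier)
        if self.variant == "ingp":
            cfg["hash"] = asdict(self.hash_config)
        if self.variant == "pixel":
            cfg["reference_views"] = self.reference_views
            cfg["feature_channels"] = self.feature_extractor.feature_channels
        return cfg

    def save(self, path: str | Path) -> None:
        """Checkpoint: one .npz holding parameter arrays + the JSON config."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params)}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.config_dump()).encode(), dtype=np.uint8
        )
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AttenuationField":
        with np.load(str(path)) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            field = cls(
                cfg["variant"],
                cfg["scene_center"],
                cfg["scene_half_extent"],
                fourier=FourierEncodingConfig(**cfg["fourier"])
                if "fourier" in cfg
                else None,
                hash_config=HashEncodingConfig(**cfg["hash"]) if "hash" in cfg else None,
                mlp=MLPConfig(**cfg["mlp"]),
                learning_rate=cfg["learning_rate"],
                seed=cfg["seed"],
            )
            for i, p in enumerate(field.params):
                p.data = data[f"param_{i}"].copy()
        return field


def build_field(
    variant: str,
    scene_center=(0.0, 0.0, 0.0),
    scene_half_extent=(64.0, 64.0, 64.0),
    seed: int = 0,
    **overrides,
) -> AttenuationField:
    """Build a preset field variant; keyword overrides adjust any knob.

    For ``ingp`` the hash grid's finest resolution defaults to the scene's
    largest dimension (in voxel-ish units of the half extent), unless a full
    :class:`HashEncodingConfig` is supplied.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {list(VARIANTS)}")
    if variant == "ingp" and "hash_config" not in overrides:
        # finest level ~ one cell per voxel of the training volume's largest axis
        finest = int(max(16, round(2 * float(np.max(np.asarray(scene_half_extent))))))
        overrides["hash_config"] = HashEncodingConfig(
            finest_resolution=finest, seed=seed
        )
    return AttenuationField(variant, scene_center, scene_half_extent, seed=seed, **overrides)
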