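"""Compositional and vanilla autoencoders as pure array computations.

The compositional autoencoder (CAE) processes one *genotype group* — the
P = E*N plots sharing a genotype — at a time:

1. a shared MLP encoder maps each plot's spectrum to a per-plant latent of
   width d = zg + ze + zp;
2. a single linear *fusion* layer maps the concatenation of the P per-plant
   latents (length P*d) to a group-level *fused* latent of length
   D = zg + E*ze + P*zp, whose slots are, in order, one genotype block Zg,
   E macro-environment blocks Ze(e), and P micro-environment blocks Zp(p);
3. *composition* reassembles a per-plant latent [Zg | Ze(env(p)) | Zp(p)]
   for each plant p, where env(p) = p // N;
4. a shared MLP decoder (sigmoid output) reconstructs each plant's spectrum
   from its composed latent.

All parameters live in a flat numpy vector so the trainer can hand them to
scipy's L-BFGS-B; the functions here are deterministic given parameters.
Hidden layers use SELU, the encoder output is linear, the decoder output is
a sigmoid.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

# SELU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


class ShapeError(ValueError):
    """Array width/row-count contract violation."""


# ---------------------------------------------------------------------------
# Layout and architecture descriptions


@dataclasses.dataclass(frozen=True)
class LatentLayout:
    """Slot bookkeeping for the partitioned latent space.

    zg/ze/zp are the widths of the genotype, macro-environment and
    micro-environment blocks; E and N the environment and replicate counts.
    The per-plant latent has width ``d = zg + ze + zp``; the fused latent
    has width ``D = zg + E*ze + P*zp`` with P = E*N.
    """

    zg: int
    ze: int
    zp: int
    E: int = 2
    N: int = 2

    def __post_init__(self) -> None:
        for name in ("zg", "ze", "zp", "E", "N"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def P(self) -> int:
        return self.E * self.N

    @property
    def d(self) -> int:
        return self.zg + self.ze + self.zp

    @property
    def D(self) -> int:
        return self.zg + self.E * self.ze + self.P * self.zp

    # -- fused-vector slot map (total and non-overlapping) ------------------

    def zg_slice(self) -> slice:
        return slice(0, self.zg)

    def ze_slice(self, e: int) -> slice:
        if not 0 <= e < self.E:
            raise IndexError(f"environment index {e} out of range [0, {self.E})")
        start = self.zg + e * self.ze
        return slice(start, start + self.ze)

    def zp_slice(self, p: int) -> slice:
        if not 0 <= p < self.P:
            raise IndexError(f"plant index {p} out of range [0, {self.P})")
        start = self.zg + self.E * self.ze + p * self.zp
        return slice(start, start + self.zp)

    def environment_of(self, p: int) -> int:
        if not 0 <= p < self.P:
            raise IndexError(f"plant index {p} out of range [0, {self.P})")
        return p // self.N

    def compose_indices(self, p: int) -> np.ndarray:
        """Fused-vector indices forming plant p's composed latent [Zg|Ze(env)|Zp(p)]."""
        e = self.environment_of(p)
        return np.concatenate([
            np.arange(self.zg),
            np.arange(self.ze_slice(e).start, self.ze_slice(e).stop),
            np.arange(self.zp_slice(p).start, self.zp_slice(p).stop),
        ])

    def compose_index_matrix(self) -> np.ndarray:
        """``[P, d]`` index matrix; row p gathers plant p's composed latent."""
        return np.stack([self.compose_indices(p) for p in range(self.P)])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Encoder/decoder architecture: the decoder mirrors ``hidden_dims`` reversed.

    Defaults follow the study architecture for 2151-band spectra; the first
    hidden width (2150) is kept as printed there even though it is one less
    than the input width.
    """

    input_dim: int = 2151
    hidden_dims: tuple[int, ...] = (2150, 1024, 512)

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be non-empty")

    def encoder_dims(self, d: int) -> list[tuple[int, int]]:
        dims = (self.input_dim, *self.hidden_dims, d)
        return list(zip(dims[:-1], dims[1:]))

    def decoder_dims(self, d: int) -> list[tuple[int, int]]:
        dims = (d, *reversed(self.hidden_dims), self.input_dim)
        return list(zip(dims[:-1], dims[1:]))

    def n_parameters(self, d: int, layout: LatentLayout | None = None) -> int:
        """Total trainable parameter count (encoder + decoder, + fusion if layout given)."""
        n = sum((fi + 1) * fo for fi, fo in self.encoder_dims(d))
        n += sum((fi + 1) * fo for fi, fo in self.decoder_dims(d))
        if layout is not None:
            n += (layout.P * layout.d + 1) * layout.D
        return n

    def to_dict(self) -> dict:
        return {"input_dim": self.input_dim, "hidden_dims": list(self.hidden_dims)}


# ---------------------------------------------------------------------------
# Parameter vector layout

# Parameters are stored as one flat float64 vector:
#   encoder layers (W then b, in order), fusion (W, b) if present,
#   decoder layers (W then b, in order).
# W for a layer (fan_in, fan_out) is stored row-major with shape [fan_in, fan_out].


@dataclasses.dataclass(frozen=True)
class ParamShapes:
    encoder: list[tuple[int, int]]
    fusion: tuple[int, int] | None
    decoder: list[tuple[int, int]]

    @property
    def total(self) -> int:
        n = sum((fi + 1) * fo for fi, fo in self.encoder)
        n += sum((fi + 1) * fo for fi, fo in self.decoder)
        if self.fusion is not None:
            fi, fo = self.fusion
            n += (fi + 1) * fo
        return n


def param_shapes(spec: NetworkSpec, layout: LatentLayout | None, d: int | None = None) -> ParamShapes:
    """Shapes for a CAE (layout given) or vanilla AE (layout None, d given)."""
    if layout is not None:
        d = layout.d
        fusion = (layout.P * layout.d, layout.D)
    else:
        if d is None:
            raise ValueError("vanilla AE needs an explicit latent width d")
        fusion = None
    return ParamShapes(encoder=spec.encoder_dims(d), fusion=fusion, decoder=spec.decoder_dims(d))


def init_params(shapes: ParamShapes, seed: int, identity_fusion: bool = False) -> np.ndarray:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in)).

    The encoder and decoder are drawn first, in a fixed order, and the
    fusion layer last — so a CAE and a vanilla AE sharing a seed start from
    identical encoder/decoder weights.  ``identity_fusion`` overwrites the
    fusion block with the identity map (requires square fusion), used for
    the degenerate E=N=1 layout.
    """
    rng = np.random.default_rng(seed)

    def draw(fi: int, fo: int) -> tuple[np.ndarray, np.ndarray]:
        bound = 1.0 / np.sqrt(fi)
        w = rng.uniform(-bound, bound, size=(fi, fo))
        b = rng.uniform(-bound, bound, size=fo)
        return w, b

    chunks: list[np.ndarray] = []
    enc = [draw(fi, fo) for fi, fo in shapes.encoder]
    dec = [draw(fi, fo) for fi, fo in shapes.decoder]
    for w, b in enc:
        chunks.extend([w.ravel(), b])
    if shapes.fusion is not None:
        fi, fo = shapes.fusion
        if identity_fusion:
            if fi != fo:
                raise ValueError("identity fusion requires a square fusion layer (P=1, D=d)")
            w, b = np.eye(fi), np.zeros(fo)
        else:
            w, b = draw(fi, fo)
        chunks.extend([w.ravel(), b])
    for w, b in dec:
        chunks.extend([w.ravel(), b])
    return np.concatenate(chunks)


def unpack_params(theta: np.ndarray, shapes: ParamShapes):
    """Split the flat vector into (encoder, fusion, decoder) weight lists."""
    if theta.size != shapes.total:
        raise ShapeError(f"parameter vector has {theta.size} entries, expected {shapes.total}")
    pos = 0

    def take(fi: int, fo: int) -> tuple[np.ndarray, np.ndarray]:
        nonlocal pos
        w = theta[pos:pos + fi * fo].reshape(fi, fo)
        pos += fi * fo
        b = theta[pos:pos + fo]
        pos += fo
        return w, b

    enc = [take(fi, fo) for fi, fo in shapes.encoder]
    fuse = take(*shapes.fusion) if shapes.fusion is not None else None
    dec = [take(fi, fo) for fi, fo in shapes.decoder]
    return enc, fuse, dec


# ---------------------------------------------------------------------------
# Activations and MLP forward


def selu(x: np.ndarray) -> np.ndarray:
    # expm1 only sees the non-positive branch, avoiding spurious overflow
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))


def selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _mlp_forward(x: np.ndarray, layers, final: str, want_cache: bool):
    """Stack of linear layers, SELU between, ``final`` in {'linear','sigmoid'}."""
    cache = [] if want_cache else None
    h = x
    n = len(layers)
    for i, (w, b) in enumerate(layers):
        if h.shape[1] != w.shape[0]:
            raise ShapeError(f"layer {i}: input width {h.shape[1]} != fan-in {w.shape[0]}")
        z = h @ w + b
        if i < n - 1:
            a = selu(z)
        elif final == "sigmoid":
            a = sigmoid(z)
        else:
            a = z
        if want_cache:
            cache.append((h, z))
        h = a
    return (h, cache) if want_cache else h


def _mlp_backward(d_out: np.ndarray, layers, cache, final: str):
    """Backprop through :func:`_mlp_forward`; returns (d_input, grads)."""
    grads = [None] * len(layers)
    g = d_out
    n = len(layers)
    for i in range(n - 1, -1, -1):
        h, z = cache[i]
        if i < n - 1:
            g = g * selu_grad(z)
        elif final == "sigmoid":
            s = sigmoid(z)
            g = g * s * (1.0 - s)
        w, _ = layers[i]
        grads[i] = (h.T @ g, g.sum(axis=0))
        g = g @ w.T
    return g, grads


# ---------------------------------------------------------------------------
# Model operations


def encode(spectra: np.ndarray, spec: NetworkSpec, theta_enc) -> np.ndarray:
    """Per-plant latents ``[k, d]`` from normalized spectra ``[k, input_dim]``."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if spectra.shape[1] != spec.input_dim:
        raise ShapeError(f"input width {spectra.shape[1]} != spec.input_dim {spec.input_dim}")
    return _mlp_forward(spectra, theta_enc, "linear", False)


def decode(latents: np.ndarray, spec: NetworkSpec, theta_dec) -> np.ndarray:
    """Reconstructions ``[k, input_dim]`` in (0,1) from latents ``[k, d]``."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if latents.shape[1] != theta_dec[0][0].shape[0]:
        raise ShapeError(
            f"latent width {latents.shape[1]} != decoder fan-in {theta_dec[0][0].shape[0]}"
        )
    return _mlp_forward(latents, theta_dec, "sigmoid", False)


def fuse(group_latents: np.ndarray, layout: LatentLayout, theta_fuse) -> np.ndarray:
    """Fused latent of length D from the P per-plant latents of one group.

    A single linear map (no activation) from the concatenation of the P
    latents in canonical environment-major order.
    """
    group_latents = np.asarray(group_latents, dtype=float)
    if group_latents.shape != (layout.P, layout.d):
        raise ShapeError(
            f"group latents have shape {group_latents.shape}, expected ({layout.P}, {layout.d})"
        )
    w, b = theta_fuse
    return group_latents.reshape(-1) @ w + b


def compose(fused: np.ndarray, plant_index: int, layout: LatentLayout) -> np.ndarray:
    """Per-plant latent [Zg | Ze(env(p)) | Zp(p)] gathered from the fused vector."""
    fused = np.asarray(fused, dtype=float)
    if fused.shape[-1] != layout.D:
        raise ShapeError(f"fused width {fused.shape[-1]} != layout D {layout.D}")
    return fused[..., layout.compose_indices(plant_index)]


def cae_forward(
    group: np.ndarray, spec: NetworkSpec, layout: LatentLayout, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Full CAE pass for one group: (reconstructions ``[P, input_dim]``, fused ``[D]``)."""
    recon, fused = cae_forward_batch(np.asarray(group, dtype=float)[None], spec, layout, theta)
    return recon[0], fused[0]


def cae_forward_batch(
    groups: np.ndarray, spec: NetworkSpec, layout: LatentLayout, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized CAE pass over ``[B, P, input_dim]`` -> (recons, fused ``[B, D]``)."""
    groups = np.asarray(groups, dtype=float)
    if groups.ndim != 3 or groups.shape[1] != layout.P:
        raise ShapeError(f"groups must be [B, {layout.P}, input_dim], got {groups.shape}")
    shapes = param_shapes(spec, layout)
    enc, fusion, dec = unpack_params(theta, shapes)
    B = groups.shape[0]
    z = encode(groups.reshape(B * layout.P, -1), spec, enc)
    wf, bf = fusion
    fused = z.reshape(B, layout.P * layout.d) @ wf + bf
    idx = layout.compose_index_matrix()  # [P, d]
    composed = fused[:, idx]  # [B, P, d]
    recon = decode(composed.reshape(B * layout.P, layout.d), spec, dec)
    return recon.reshape(B, layout.P, spec.input_dim), fused


def vanilla_forward(
    spectra: np.ndarray, spec: NetworkSpec, d: int, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Plain AE pass: each sample independent; returns (reconstructions, latents)."""
    shapes = param_shapes(spec, None, d=d)
    enc, _, dec = unpack_params(theta, shapes)
    z = encode(spectra, spec, enc)
    return decode(z, spec, dec), z


# ---------------------------------------------------------------------------
# Checkpoints


@dataclasses.dataclass
class Checkpoint:
    """Everything needed to reload a model and exactly reproduce inference."""

    model_type: str  # 'cae' | 'vanilla'
    theta: np.ndarray
    spec: NetworkSpec
    layout: LatentLayout | None
    d: int
    environment_order: list[str] | None = None
    norm_constants: tuple[float, float] | None = None
    seed: int | None = None
    config: dict | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), theta=self.theta)
        sidecar = {
            "model_type": self.model_type,
            "network": self.spec.to_dict(),
            "layout": self.layout.to_dict() if self.layout else None,
            "d": self.d,
            "environment_order": self.environment_order,
            "norm_constants": list(self.norm_constants) if self.norm_constants else None,
            "seed": self.seed,
            "config": self.config,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        theta = np.load(path.with_suffix(".npz"))["theta"]
        layout = LatentLayout(**meta["layout"]) if meta["layout"] else None
        return cls(
            model_type=meta["model_type"],
            theta=theta,
            spec=NetworkSpec(meta["network"]["input_dim"], tuple(meta["network"]["hidden_dims"])),
            layout=layout,
            d=meta["d"],
            environment_order=meta["environment_order"],
            norm_constants=tuple(meta["norm_constants"]) if meta["norm_constants"] else None,
            seed=meta["seed"],
            config=meta["config"],
        )
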