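"""Disentanglement evaluation: factor-specific reflectance and KL separation.

*Factor-specific reflectance* reconstructs spectra after replacing all
latent slots except the factor of interest by their averages: keeping only
the genotype block isolates the genotype's spectral signature (identical
across a group's replicates), keeping an environment block isolates the
macro-environment signature, and so on.

*KL separation* quantifies how distinguishable the two macro-environments'
reflectance distributions are, wavelength by wavelength: a symmetrized
KL divergence between histogram density estimates, averaged over a list of
evaluated wavelengths.  Comparing the report for raw spectra against
environment-specific reconstructions measures the separation gained by
disentanglement.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import entropy

from . import model
from .model import Checkpoint, LatentLayout


class EvalError(ValueError):
    pass


@dataclasses.dataclass
class FactorSpectra:
    """Factor-specific reconstructions, one block per factor."""

    genotype_specific: np.ndarray  # [n_groups, W]
    env_specific: np.ndarray  # [n_groups, E, W]
    micro_specific: np.ndarray  # [n_groups, P, W]
    provenance: str


@dataclasses.dataclass
class KLReport:
    per_wavelength_kl: np.ndarray
    average_kl: float
    estimator: str
    source: str = ""

    def as_dict(self) -> dict:
        return {
            "average_kl": self.average_kl,
            "per_wavelength_kl": self.per_wavelength_kl.tolist(),
            "estimator": self.estimator,
            "source": self.source,
        }


# ---------------------------------------------------------------------------
# Latent surgery helpers


def _require_cae(ckpt: Checkpoint) -> LatentLayout:
    if ckpt.model_type != "cae" or ckpt.layout is None:
        raise EvalError("factor-specific reflectance needs a CAE checkpoint")
    return ckpt.layout


def fused_latents(ckpt: Checkpoint, x_groups: np.ndarray) -> np.ndarray:
    """Fused latent ``[n_groups, D]`` for each group of normalized spectra."""
    layout = _require_cae(ckpt)
    x_groups = np.asarray(x_groups, dtype=float)
    if x_groups.ndim != 3 or x_groups.shape[1] != layout.P:
        raise EvalError(f"expected [n_groups, {layout.P}, W] spectra, got {x_groups.shape}")
    if x_groups.shape[2] != ckpt.spec.input_dim:
        raise EvalError(
            f"checkpoint expects {ckpt.spec.input_dim} wavelengths, data has {x_groups.shape[2]}"
        )
    _, fused = model.cae_forward_batch(x_groups, ckpt.spec, layout, ckpt.theta)
    return fused


def _decoder_params(ckpt: Checkpoint):
    shapes = model.param_shapes(ckpt.spec, ckpt.layout, d=ckpt.d)
    _, _, dec = model.unpack_params(ckpt.theta, shapes)
    return dec


def _mean_ze(fused: np.ndarray, layout: LatentLayout) -> np.ndarray:
    """Per-group mean of the Ze blocks over environments: [B, ze]."""
    return np.mean([fused[:, layout.ze_slice(e)] for e in range(layout.E)], axis=0)


def _mean_zp(fused: np.ndarray, layout: LatentLayout) -> np.ndarray:
    """Per-group mean of the Zp blocks over plants: [B, zp]."""
    return np.mean([fused[:, layout.zp_slice(p)] for p in range(layout.P)], axis=0)


def genotype_specific_reflectance(ckpt: Checkpoint, x_groups: np.ndarray) -> np.ndarray:
    """Reconstructions keeping only genotype effects: ``[n_groups, W]``.

    Each group's Ze blocks are replaced by their mean over environments and
    Zp blocks by their mean over plants, then composed and decoded; all P
    plants of a group yield the same spectrum, reported once per group.
    """
    layout = _require_cae(ckpt)
    fused = fused_latents(ckpt, x_groups)
    zg = fused[:, layout.zg_slice()]
    composed = np.concatenate([zg, _mean_ze(fused, layout), _mean_zp(fused, layout)], axis=1)
    return model.decode(composed, ckpt.spec, _decoder_params(ckpt))


def environment_specific_reflectance(ckpt: Checkpoint, x_groups: np.ndarray) -> np.ndarray:
    """Reconstructions keeping only macro-environment effects: ``[n_groups, E, W]``.

    The genotype block is replaced by its mean over *all* groups of the
    evaluation set and the Zp blocks by the global mean over groups and
    plants; each environment's own Ze block is retained.
    """
    layout = _require_cae(ckpt)
    fused = fused_latents(ckpt, x_groups)
    B = fused.shape[0]
    mean_zg = fused[:, layout.zg_slice()].mean(axis=0)
    mean_zp = _mean_zp(fused, layout).mean(axis=0)
    dec = _decoder_params(ckpt)
    out = np.empty((B, layout.E, ckpt.spec.input_dim))
    for e in range(layout.E):
        ze = fused[:, layout.ze_slice(e)]
        composed = np.concatenate(
            [np.tile(mean_zg, (B, 1)), ze, np.tile(mean_zp, (B, 1))], axis=1
        )
        out[:, e, :] = model.decode(composed, ckpt.spec, dec)
    return out


def micro_specific_reflectance(ckpt: Checkpoint, x_groups: np.ndarray) -> np.ndarray:
    """Reconstructions keeping only micro-environment effects: ``[n_groups, P, W]``.

    The genotype block is replaced by the global mean over groups and each
    group's Ze blocks by their within-group mean; each plant's own Zp block
    is retained.
    """
    layout = _require_cae(ckpt)
    fused = fused_latents(ckpt, x_groups)
    B = fused.shape[0]
    mean_zg = np.tile(fused[:, layout.zg_slice()].mean(axis=0), (B, 1))
    mean_ze = _mean_ze(fused, layout)
    dec = _decoder_params(ckpt)
    out = np.empty((B, layout.P, ckpt.spec.input_dim))
    for p in range(layout.P):
        zp = fused[:, layout.zp_slice(p)]
        composed = np.concatenate([mean_zg, mean_ze, zp], axis=1)
        out[:, p, :] = model.decode(composed, ckpt.spec, dec)
    return out


def factor_spectra(ckpt: Checkpoint, x_groups: np.ndarray) -> FactorSpectra:
    """All three factor-specific reconstruction blocks for an evaluation set."""
    return FactorSpectra(
        genotype_specific=genotype_specific_reflectance(ckpt, x_groups),
        env_specific=environment_specific_reflectance(ckpt, x_groups),
        micro_specific=micro_specific_reflectance(ckpt, x_groups),
        provenance=(
            "slot averages over the evaluation set: genotype-specific averages Ze over "
            "environments and Zp over plants within each group; environment-specific "
            "averages Zg and Zp globally; micro-specific averages Zg globally and Ze "
            "within each group"
        ),
    )


# ---------------------------------------------------------------------------
# KL-divergence environment separation


def default_wavelength_indices(n_wavelengths: int, step: int = 50) -> list[int]:
    """Every ``step``-th wavelength index (a representative subset)."""
    return list(range(0, n_wavelengths, step))


def symmetrized_kl_histogram(
    a: np.ndarray, b: np.ndarray, bins: int = 50, eps: float = 0.5
) -> float:
    """0.5*[KL(P||Q) + KL(Q||P)] between histogram densities of two samples.

    Shared equal-width bin edges span the pooled range; ``eps`` pseudo-counts
    are added to every bin (Jeffreys-style smoothing).  Vanishingly small
    smoothing would let near-empty tail bins dominate the estimate — with
    half a pseudo-count the estimator lands within ~15% of the closed form
    for well-separated Gaussians at n=2000.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    p = (pa + eps) / (pa.sum() + bins * eps)
    q = (pb + eps) / (pb.sum() + bins * eps)
    return float(0.5 * (entropy(p, q) + entropy(q, p)))


def kl_environment_separation(
    spectra_env1: np.ndarray,
    spectra_env2: np.ndarray,
    wavelength_indices: Sequence[int] | None = None,
    bins: int = 50,
    eps: float = 0.5,
    min_samples: int = 20,
    source: str = "",
) -> KLReport:
    """Average symmetrized KL between the two environments' reflectance densities.

    ``spectra_env1`` / ``spectra_env2`` are ``[n_i, W]`` matrices; the KL is
    estimated independently at each evaluated wavelength and averaged.
    """
    a = np.atleast_2d(np.asarray(spectra_env1, dtype=float))
    b = np.atleast_2d(np.asarray(spectra_env2, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise EvalError("environment matrices must share the wavelength grid")
    if a.shape[0] < min_samples or b.shape[0] < min_samples:
        raise EvalError(
            f"need >= {min_samples} samples per environment, got {a.shape[0]} and {b.shape[0]}"
        )
    if wavelength_indices is None:
        wavelength_indices = default_wavelength_indices(a.shape[1])
    wavelength_indices = list(wavelength_indices)
    if not wavelength_indices:
        raise EvalError("empty wavelength list")
    kl = np.array(
        [symmetrized_kl_histogram(a[:, w], b[:, w], bins=bins, eps=eps) for w in wavelength_indices]
    )
    return KLReport(
        per_wavelength_kl=kl,
        average_kl=float(kl.mean()),
        estimator=f"histogram, {bins} equal-width bins over pooled range, "
        f"pseudo-count eps={eps:g} per bin, symmetrized 0.5*(KL(P||Q)+KL(Q||P))",
        source=source,
    )
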