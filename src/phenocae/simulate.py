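"""Synthetic replicated-panel spectra with known G x E structure.

The generator emulates the structure the compositional autoencoder assumes:
smooth reflectance spectra in (0, 1) built from additive genotype,
macro-environment (field-level) and micro-environment (plot-level)
components with controllable variance shares, laid out as a replicated
panel of G genotypes x E environments x N replicates, plus traits that are
functions of the latent genotype factors (optionally with an additive
environment effect).

Each additive component is a low-rank expansion over smooth Gaussian-bump
spectral bases — mimicking the broad absorption features of leaf
reflectance — and is rescaled so the empirical variance shares match the
configured (v_g, v_e, v_p); the remainder is white sensor noise.  The sum
is passed through a logistic squash centred on a smooth baseline, with a
signal amplitude small enough that the squash stays near-linear and the
shares survive into the observed spectra.

A one-way/two-way ANOVA decomposition (:func:`variance_decomposition`)
estimates the realized shares from a generated panel and serves as the
ground-truth oracle for the rest of the test suite.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import SpectraPanel


class SimConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TraitSpec:
    """How a trait is derived from the latent genotype factors.

    ``weights`` (length k_g) default to a seeded random draw; ``noise_sd_frac``
    is the trait noise standard deviation as a fraction of the noiseless trait
    standard deviation; ``env_effects`` (length E) adds a per-environment
    offset, making the trait G+E rather than purely genotypic.
    """

    weights: tuple[float, ...] | None = None
    noise_sd_frac: float = 0.1
    env_effects: tuple[float, ...] | None = None


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic panel; config + seed determine it exactly."""

    G: int = 200
    E: int = 2
    N: int = 2
    W: int = 500
    variance_shares: tuple[float, float, float] = (0.4, 0.3, 0.1)
    smoothness: float = 25.0  # spectral correlation length, wavelength-index units
    k_g: int = 5
    k_e: int = 3
    k_p: int = 5
    #: place the micro-environment factors in the same spectral subspace as the
    #: leading genotype factors.  Plot-level stress and genotype modulate the
    #: same absorption features, so a single plot's spectrum is a *noisy*
    #: readout of its genotype — the reason replicated measurements (and a
    #: model that pools them) carry information a per-plot encoder cannot get.
    micro_shares_genotype_bases: bool = True
    amplitude: float = 0.22  # pre-squash total signal sd (logit units)
    traits: Mapping[str, TraitSpec] = dataclasses.field(
        default_factory=lambda: {"trait_g": TraitSpec()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.G, self.E, self.N, self.W) < 1:
            raise SimConfigError("G, E, N, W must all be >= 1")
        vg, ve, vp = self.variance_shares
        if min(vg, ve, vp) < 0:
            raise SimConfigError("variance shares must be non-negative")
        if vg + ve + vp > 1 + 1e-12:
            raise SimConfigError(
                f"variance shares sum to {vg + ve + vp:.3f} > 1 (remainder is noise)"
            )


@dataclasses.dataclass
class SimTruth:
    """Latent ground truth behind a simulated panel."""

    genotype_factors: np.ndarray  # [G, k_g]
    environment_factors: np.ndarray  # [E, k_e]
    micro_factors: np.ndarray  # [G*E*N, k_p]
    bases_g: np.ndarray  # [k_g, W]
    bases_e: np.ndarray
    bases_p: np.ndarray
    baseline: np.ndarray  # [W]
    trait_values: pd.DataFrame  # one column per trait, row-aligned with the panel
    trait_weights: dict[str, np.ndarray]


def _smooth_bases(
    rng: np.random.Generator, k: int, W: int, width: float, orthonormal: bool = True
) -> np.ndarray:
    """k unit-norm smooth rows built from Gaussian bumps.

    Bump centers are stratified (evenly spaced with jitter) and the rows are
    orthonormalized within the block (QR), so every latent factor owns a
    distinct spectral direction — i.i.d. random centers can nearly coincide,
    which would make some factors spectrally invisible and the ground truth
    unrecoverable by construction.
    """
    grid = np.arange(W)
    strata = (np.arange(k) + 0.5) / k * W
    centers = strata + rng.uniform(-0.5, 0.5, size=k) * W / k
    bases = np.exp(-((grid[None, :] - centers[:, None]) ** 2) / (2.0 * width**2))
    if orthonormal and k > 1:
        q, r = np.linalg.qr(bases.T)  # [W, k], orthonormal columns spanning the bumps
        bases = (q * np.sign(np.diag(r))).T
    norms = np.linalg.norm(bases, axis=1, keepdims=True)
    return bases / np.maximum(norms, 1e-12)


def _factor_bases(
    rng: np.random.Generator, ks: tuple[int, ...], W: int, width: float
) -> list[np.ndarray]:
    """Jointly orthonormal smooth basis blocks, one per factor type.

    All k_g + k_e + k_p bumps share one stratified-center draw and one QR,
    then the rows are dealt round-robin into the blocks; factors of
    different blocks are therefore mutually orthogonal too, which keeps
    each factor spectrally identifiable.
    """
    k_total = sum(ks)
    if k_total > W:
        raise SimConfigError(f"{k_total} factors cannot be orthogonal on {W} wavelengths")
    joint = _smooth_bases(rng, k_total, W, width)
    order = rng.permutation(k_total)
    blocks, pos = [], 0
    for k in ks:
        blocks.append(joint[order[pos:pos + k]])
        pos += k
    return blocks


def _rescale_to_share(component: np.ndarray, target_var: float) -> np.ndarray:
    """Scale a [n_samples, W] component so its mean per-wavelength variance hits target."""
    if target_var <= 0:
        return np.zeros_like(component)
    var = component.var(axis=0).mean()
    if var <= 1e-30:
        return component
    return component * np.sqrt(target_var / var)


def simulate_panel(config: SimConfig) -> tuple[SpectraPanel, SimTruth]:
    """Generate a replicated panel and its latent ground truth.

    Sample order is genotype-major, then environment, then replicate —
    so each genotype's rows are already in the canonical environment-major
    group order.
    """
    rng = np.random.default_rng(config.seed)
    G, E, N, W = config.G, config.E, config.N, config.W
    n = G * E * N
    vg, ve, vp = config.variance_shares
    v_noise = max(0.0, 1.0 - (vg + ve + vp))

    # smooth baseline around logit 0: broad bumps, centered
    baseline = _smooth_bases(rng, 3, W, width=max(W / 4.0, config.smoothness))
    baseline = baseline.sum(axis=0) * np.sqrt(W) * 0.3
    baseline = baseline - baseline.mean()

    # one joint orthonormal system across the factor blocks: every latent
    # factor owns a distinct spectral direction, so no factor is masked by
    # another block's variation.  The micro block optionally reuses the
    # leading genotype directions instead (see SimConfig).
    if config.micro_shares_genotype_bases:
        if config.k_p > config.k_g:
            raise SimConfigError("k_p cannot exceed k_g when sharing genotype bases")
        bases_g, bases_e = _factor_bases(rng, (config.k_g, config.k_e), W, config.smoothness)
        bases_p = bases_g[: config.k_p].copy()
    else:
        bases_g, bases_e, bases_p = _factor_bases(
            rng, (config.k_g, config.k_e, config.k_p), W, config.smoothness
        )

    a_g = rng.standard_normal((G, config.k_g))
    b_e = rng.standard_normal((E, config.k_e))
    c_p = rng.standard_normal((n, config.k_p))

    # replicate factor rows out to the n samples (genotype-major layout)
    g_idx = np.repeat(np.arange(G), E * N)
    e_idx = np.tile(np.repeat(np.arange(E), N), G)

    amp2 = config.amplitude**2
    comp_g = _rescale_to_share((a_g @ bases_g)[g_idx], vg * amp2)
    comp_e = _rescale_to_share((b_e @ bases_e)[e_idx], ve * amp2)
    comp_p = _rescale_to_share(c_p @ bases_p, vp * amp2)
    noise = rng.standard_normal((n, W)) * np.sqrt(v_noise * amp2)

    logits = baseline + comp_g + comp_e + comp_p + noise
    values = 1.0 / (1.0 + np.exp(-logits))

    meta = pd.DataFrame(
        {
            "genotype": [f"G{g:04d}" for g in g_idx],
            "environment": [f"E{e + 1}" for e in e_idx],
            "replicate": [f"R{r + 1}" for r in np.tile(np.arange(N), G * E)],
        }
    )

    trait_values = {}
    trait_weights = {}
    for name, tspec in config.traits.items():
        if tspec.weights is None:
            w = rng.standard_normal(config.k_g)
        else:
            w = np.asarray(tspec.weights, dtype=float)
            if w.size != config.k_g:
                raise SimConfigError(
                    f"trait {name!r}: {w.size} weights for {config.k_g} genotype factors"
                )
        raw = (a_g @ w)[g_idx]
        if tspec.env_effects is not None:
            eff = np.asarray(tspec.env_effects, dtype=float)
            if eff.size != E:
                raise SimConfigError(f"trait {name!r}: env_effects must have length E={E}")
            raw = raw + eff[e_idx]
        sd = raw.std()
        noise_t = rng.standard_normal(n) * tspec.noise_sd_frac * (sd if sd > 0 else 1.0)
        trait_values[name] = raw + noise_t
        trait_weights[name] = w

    traits = pd.DataFrame(trait_values)
    panel = SpectraPanel(meta=meta, wavelengths=np.arange(W, dtype=float), values=values, traits=traits)
    truth = SimTruth(
        genotype_factors=a_g,
        environment_factors=b_e,
        micro_factors=c_p,
        bases_g=bases_g,
        bases_e=bases_e,
        bases_p=bases_p,
        baseline=baseline,
        trait_values=traits.copy(),
        trait_weights=trait_weights,
    )
    return panel, truth


def simulate_study_shape(seed: int = 0) -> tuple[SpectraPanel, SimTruth]:
    """Convenience preset matching the field study's dimensions:
    578 genotypes x 2 environments x 2 replicates, 2151 wavelengths."""
    return simulate_panel(dataclasses.replace(SimConfig(), G=578, E=2, N=2, W=2151, seed=seed))


# ---------------------------------------------------------------------------
# Variance-component oracle


def variance_decomposition(panel: SpectraPanel) -> dict[str, float]:
    """Estimate the variance shares of a balanced G x E x N panel.

    Per wavelength, a balanced two-way crossed random-effects ANOVA without
    interaction gives unbiased component estimates from expected mean
    squares:

        E[MS_G]   = sigma²_res + E*N * sigma²_G
        E[MS_E]   = sigma²_res + G*N * sigma²_E
        E[MS_res] = sigma²_res

    The plot-level residual confounds the smooth micro-environment signal
    with white sensor noise; the two are separated across wavelengths via
    the lag-1 difference of the residual spectra (white noise doubles under
    differencing, a smooth component nearly vanishes).  Returns shares of
    total variance: ``v_g``, ``v_e``, ``v_p``, ``v_noise``.
    """
    meta, Y = panel.meta, panel.values
    genos = np.unique(meta["genotype"])
    envs = np.unique(meta["environment"])
    G, E = genos.size, envs.size
    n = Y.shape[0]
    N = n // (G * E)
    if G * E * N != n:
        raise SimConfigError("panel is not a balanced G x E x N layout")

    g_codes = pd.Categorical(meta["genotype"], categories=genos).codes
    e_codes = pd.Categorical(meta["environment"], categories=envs).codes

    grand = Y.mean(axis=0)
    g_means = np.stack([Y[g_codes == g].mean(axis=0) for g in range(G)])
    e_means = np.stack([Y[e_codes == e].mean(axis=0) for e in range(E)])

    ms_g = E * N * ((g_means - grand) ** 2).sum(axis=0) / max(G - 1, 1)
    ms_e = G * N * ((e_means - grand) ** 2).sum(axis=0) / max(E - 1, 1)
    resid = Y - g_means[g_codes] - e_means[e_codes] + grand
    df_res = max(n - G - E + 1, 1)
    ms_res = (resid**2).sum(axis=0) / df_res

    # finite-population (realized) components: the generator calibrates the
    # empirical variance of the realized factor draws, so the superpopulation
    # estimate is shrunk by (levels-1)/levels — a factor of 2 for E=2
    var_g = np.maximum((ms_g - ms_res) / (E * N), 0.0) * (G - 1) / G
    var_e = np.maximum((ms_e - ms_res) / (G * N), 0.0) * (E - 1) / E
    # split residual: white-noise variance from lag-1 differences along the
    # wavelength axis (smooth micro signal nearly cancels, white noise doubles);
    # n/df_res undoes the variance lost to mean removal in the residuals
    if Y.shape[1] >= 2:
        noise_var = np.var(np.diff(resid, axis=1), ddof=0) / 2.0 * (n / df_res)
    else:
        noise_var = 0.0
    var_res = ms_res.mean()
    var_noise = min(noise_var, var_res)
    var_p = var_res - var_noise

    total = var_g.mean() + var_e.mean() + var_res
    return {
        "v_g": float(var_g.mean() / total),
        "v_e": float(var_e.mean() / total),
        "v_p": float(var_p / total),
        "v_noise": float(var_noise / total),
    }
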