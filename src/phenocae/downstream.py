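"""Downstream trait prediction from latent representations.

Feature sources: per-plant composed CAE latents, vanilla-AE latents, PCA
scores on the raw spectra, or the raw spectra themselves.  Each is scored
by genotype-grouped 5-fold cross-validated R² (all plots of a genotype
share a fold, so replicates never leak across the split) over a grid of
regressors — ridge, PLSR, random forest, gradient boosting.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LogisticRegression, RidgeCV
from xgboost import XGBRegressor

from . import model
from .model import Checkpoint
from .panel import GenotypeGroup, SpectraPanel, stack_groups

logger = logging.getLogger("phenocae")

REGRESSORS = ("ridge", "plsr", "random_forest", "gradient_boosting")


class DownstreamError(ValueError):
    pass


@dataclasses.dataclass
class FeatureSet:
    """Per-plot feature matrix aligned with a panel's sample rows."""

    source: str  # cae_composed | vanilla_latent | pca | raw
    matrix: np.ndarray  # [n_samples, n_features]
    sample_indices: np.ndarray  # panel row index of each feature row

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclasses.dataclass
class CVResult:
    trait: str
    model: str
    source: str
    folds: int
    r2_mean: float
    r2_sd: float
    per_fold: list[float]
    seed: int


# ---------------------------------------------------------------------------
# Feature extraction


def extract_cae_features(
    ckpt: Checkpoint, panel: SpectraPanel, groups: Sequence[GenotypeGroup]
) -> FeatureSet:
    """Per-plant composed latent [Zg | Ze(env(p)) | Zp(p)] for every plot.

    One row per plot of every complete group, width d = zg + ze + zp.
    """
    if ckpt.model_type != "cae" or ckpt.layout is None:
        raise DownstreamError("CAE features need a CAE checkpoint")
    layout = ckpt.layout
    x_groups = stack_groups(panel, groups)
    _, fused = model.cae_forward_batch(x_groups, ckpt.spec, layout, ckpt.theta)
    idx = layout.compose_index_matrix()
    composed = fused[:, idx]  # [n_groups, P, d]
    rows = np.concatenate([np.asarray(g.members) for g in groups])
    feats = composed.reshape(-1, layout.d)
    return FeatureSet(source="cae_composed", matrix=feats, sample_indices=rows)


def extract_vanilla_features(ckpt: Checkpoint, panel: SpectraPanel) -> FeatureSet:
    """Vanilla-AE latent for every panel row."""
    if ckpt.model_type != "vanilla":
        raise DownstreamError("vanilla features need a vanilla-AE checkpoint")
    _, z = model.vanilla_forward(panel.values, ckpt.spec, ckpt.d, ckpt.theta)
    return FeatureSet("vanilla_latent", z, np.arange(panel.n_samples))


def pca_features(panel: SpectraPanel, k: int) -> FeatureSet:
    """Top-k PCA scores of the centered spectra, sign-fixed.

    Deterministic: full SVD solver, and each component's sign is chosen so
    its largest-magnitude loading is positive.
    """
    n, w = panel.values.shape
    if not 1 <= k <= min(n, w):
        raise DownstreamError(f"k={k} out of range for a {n} x {w} panel")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(panel.values)
    flip = np.sign(
        pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    return FeatureSet("pca", scores * flip, np.arange(panel.n_samples))


def raw_features(panel: SpectraPanel) -> FeatureSet:
    return FeatureSet("raw", panel.values.copy(), np.arange(panel.n_samples))


# ---------------------------------------------------------------------------
# Scoring


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise DownstreamError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise DownstreamError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DownstreamError("R² undefined: observed values have zero variance")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def make_regressor(name: str, seed: int, n_features: int | None = None):
    """Regressor factory; hyperparameters are library defaults with a fixed
    seed, except ridge whose penalty is chosen by internal CV over 1e-3..1e3."""
    if name == "ridge":
        return RidgeCV(alphas=np.logspace(-3, 3, 13))
    if name == "plsr":
        k = 10 if n_features is None else max(1, min(10, n_features))
        return PLSRegression(n_components=k)
    if name == "random_forest":
        return RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    if name == "gradient_boosting":
        return XGBRegressor(
            n_estimators=200, random_state=seed, n_jobs=1, verbosity=0
        )
    raise DownstreamError(f"unknown regressor {name!r}; choose from {REGRESSORS}")


def genotype_fold_assignment(
    genotype_ids: Sequence[str], n_folds: int, seed: int
) -> np.ndarray:
    """Fold id per sample; all samples of a genotype share a fold.

    Unique genotypes are shuffled with the seed and split into n_folds
    nearly equal parts — disjoint, exhaustive, deterministic.
    """
    genotype_ids = np.asarray(genotype_ids)
    unique = np.unique(genotype_ids)
    if unique.size < n_folds:
        raise DownstreamError(
            f"{unique.size} genotypes cannot fill {n_folds} folds"
        )
    order = np.random.default_rng(seed).permutation(unique.size)
    fold_of = {}
    for fold, part in enumerate(np.array_split(unique[order], n_folds)):
        for g in part:
            fold_of[g] = fold
    return np.array([fold_of[g] for g in genotype_ids])


def cross_validate(
    features: FeatureSet,
    panel: SpectraPanel,
    trait: str,
    model_name: str = "ridge",
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Genotype-grouped k-fold cross-validated R² for one trait and regressor."""
    if panel.traits is None or trait not in panel.traits.columns:
        raise DownstreamError(f"panel has no trait {trait!r}")
    y_all = panel.traits[trait].to_numpy(dtype=float)[features.sample_indices]
    genos = panel.meta["genotype"].to_numpy()[features.sample_indices]
    keep = np.isfinite(y_all)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing %r values", n_dropped, trait)
    x = features.matrix[keep]
    y = y_all[keep]
    genos = genos[keep]
    if y.size < folds:
        raise DownstreamError(f"only {y.size} usable rows for {folds} folds")

    fold_ids = genotype_fold_assignment(genos, folds, seed)
    per_fold = []
    for f in range(folds):
        test = fold_ids == f
        reg = make_regressor(model_name, seed, n_features=x.shape[1])
        reg.fit(x[~test], y[~test])
        yhat = np.asarray(reg.predict(x[test])).ravel()
        per_fold.append(r_squared(y[test], yhat))
    per_fold = [float(v) for v in per_fold]
    return CVResult(
        trait=trait,
        model=model_name,
        source=features.source,
        folds=folds,
        r2_mean=float(np.mean(per_fold)),
        r2_sd=float(np.std(per_fold)),
        per_fold=per_fold,
        seed=seed,
    )


def classify_environment(
    features: FeatureSet,
    panel: SpectraPanel,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Genotype-grouped CV accuracy of predicting the environment id from
    a feature slice — the operational probe of where environment
    information lives in the latent space."""
    env = panel.meta["environment"].to_numpy()[features.sample_indices]
    genos = panel.meta["genotype"].to_numpy()[features.sample_indices]
    fold_ids = genotype_fold_assignment(genos, folds, seed)
    correct = 0
    for f in range(folds):
        test = fold_ids == f
        clf = LogisticRegression(max_iter=2000)
        clf.fit(features.matrix[~test], env[~test])
        correct += int((clf.predict(features.matrix[test]) == env[test]).sum())
    return correct / env.size


def composed_slice_features(features: FeatureSet, ckpt: Checkpoint, block: str) -> FeatureSet:
    """Restrict composed CAE features to one latent block ('zg', 'ze' or 'zp')."""
    layout = ckpt.layout
    if layout is None:
        raise DownstreamError("slicing needs a CAE checkpoint")
    start = {"zg": 0, "ze": layout.zg, "zp": layout.zg + layout.ze}[block]
    width = {"zg": layout.zg, "ze": layout.ze, "zp": layout.zp}[block]
    return FeatureSet(
        source=f"{features.source}:{block}",
        matrix=features.matrix[:, start:start + width],
        sample_indices=features.sample_indices,
    )


# ---------------------------------------------------------------------------
# Benchmark harness


def benchmark(
    panel: SpectraPanel,
    groups: Sequence[GenotypeGroup],
    cae_ckpt: Checkpoint | None,
    vanilla_ckpt: Checkpoint | None,
    traits: Sequence[str] | None = None,
    models: Sequence[str] = REGRESSORS,
    pca_k: int | None = None,
    include_raw: bool = True,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated R² grid over {feature source} x {regressor} x {trait}.

    PCA width defaults to the CAE per-plant latent width for parity.
    Returns a tidy frame; ``best_per_source`` summarizes it the way the
    comparison tables are usually reported.
    """
    if panel.traits is None:
        raise DownstreamError("panel carries no traits to benchmark")
    if traits is None:
        traits = list(panel.traits.columns)

    sources: list[FeatureSet] = []
    if cae_ckpt is not None:
        sources.append(extract_cae_features(cae_ckpt, panel, groups))
        if pca_k is None:
            pca_k = cae_ckpt.layout.d
    if vanilla_ckpt is not None:
        sources.append(extract_vanilla_features(vanilla_ckpt, panel))
    sources.append(pca_features(panel, pca_k or 20))
    if include_raw:
        sources.append(raw_features(panel))

    rows = []
    for fs in sources:
        for trait in traits:
            for m in models:
                res = cross_validate(fs, panel, trait, m, folds=folds, seed=seed)
                rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def best_per_source(results: pd.DataFrame) -> pd.DataFrame:
    """Best regressor per (source, trait) by mean R² — the headline summary."""
    idx = results.groupby(["source", "trait"])["r2_mean"].idxmax()
    return results.loc[idx].reset_index(drop=True)


def consistency_table(results_by_seed: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Pivot per-initialization benchmark results into one column per seed."""
    frames = []
    for s, df in results_by_seed.items():
        best = best_per_source(df)[["source", "trait", "model", "r2_mean"]].copy()
        best["init"] = s
        frames.append(best)
    allf = pd.concat(frames)
    return allf.pivot_table(
        index=["source", "trait"], columns="init", values="r2_mean"
    ).reset_index()
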