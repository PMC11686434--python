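"""Training for the compositional and vanilla autoencoders.

Training is full-batch quasi-Newton: each *epoch* draws a fresh random
input mask (the denoising augmentation), then runs a bounded number of
L-BFGS inner iterations (scipy's L-BFGS-B with strong-Wolfe line search)
on the masked objective, warm-starting from the previous epoch.  The
reconstruction target is always the unmasked spectrum.  Validation loss is
computed without masking; early stopping halts training once it has not
improved for ``patience`` consecutive epochs, and the best-validation
parameters (not the last) are returned.

Gradients are analytic (backprop through the encoder, fusion, composition
and decoder, plus the correlation-penalty gradient from
:mod:`phenocae.losses`); the test suite checks them against finite
differences.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import losses, model
from .losses import LossBreakdown
from .model import Checkpoint, LatentLayout, NetworkSpec

logger = logging.getLogger("phenocae")


class TrainConfigError(ValueError):
    pass


class TrainDivergenceError(RuntimeError):
    """Non-finite loss encountered (optimizer divergence guard)."""


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Knobs of the training protocol.

    Defaults follow the study protocol: 85/15 train-validation split at the
    genotype-group level, full-batch LBFGS, early-stopping patience 15, 20%
    input masking.  The correlation weight defaults to 1e-4 because the
    penalty is an unnormalized sum over D(D-1)/2 latent-dimension pairs,
    orders of magnitude larger than the reconstruction MSE; an unweighted
    sum would drown the reconstruction term entirely.
    """

    split_fraction: float = 0.85
    optimizer: str = "lbfgs"  # lbfgs | adam | sgd
    max_epochs: int = 500
    patience: int = 15
    mask_fraction: float = 0.20
    weight: float = 3e-5  # correlation-loss weight (lambda)
    #: early-stopping monitor: "reconstruction" (validation MSE) or "total".
    #: The correlation term on a small validation split is dominated by
    #: sampling noise (E|r| ~ 1/sqrt(B) over D(D-1)/2 pairs), which makes
    #: "total" fire prematurely; the MSE monitor tracks real progress.
    early_stop_metric: str = "reconstruction"
    #: return the best-validation parameters instead of the final epoch's.
    #: Off by default: once the validation MSE plateaus its minimum is a
    #: noise dip, and the representation keeps improving under the masked
    #: objective after the plateau — restoring the "best" epoch then picks
    #: a systematically worse model.
    restore_best: bool = False
    seed: int = 0
    lbfgs_history: int = 10
    lbfgs_max_inner: int = 400  # inner L-BFGS iterations per epoch
    learning_rate: float = 1e-3  # adam / sgd only
    inner_steps: int = 20  # adam / sgd steps per epoch
    identity_fusion: bool = False  # freeze fusion at identity (needs P=1, D=d)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise TrainConfigError("split_fraction must be in (0, 1)")
        if self.patience < 1:
            raise TrainConfigError("patience must be >= 1")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise TrainConfigError("mask_fraction must be in [0, 1)")
        if self.weight < 0:
            raise TrainConfigError("correlation weight must be >= 0")
        if self.optimizer not in ("lbfgs", "adam", "sgd"):
            raise TrainConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.early_stop_metric not in ("reconstruction", "total"):
            raise TrainConfigError(
                f"unknown early_stop_metric {self.early_stop_metric!r}"
            )


@dataclasses.dataclass
class TrainResult:
    checkpoint: Checkpoint
    history: list[dict]  # per-epoch {"train": LossBreakdown, "val": LossBreakdown}
    stopped_epoch: int
    best_epoch: int
    best_val_loss: float  # minimum of the monitored validation metric

    def history_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, h in enumerate(self.history):
            rows.append(
                {
                    "epoch": i,
                    "train_mse": h["train"].reconstruction,
                    "train_corr": h["train"].correlation,
                    "train_total": h["train"].total,
                    "val_mse": h["val"].reconstruction,
                    "val_corr": h["val"].correlation,
                    "val_total": h["val"].total,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splitting and masking


def split_groups(groups: Sequence, fraction: float, seed: int) -> tuple[list, list]:
    """Disjoint, exhaustive train/validation partition at the group level.

    ``floor(fraction * n)`` groups go to training; deterministic given seed.
    """
    n = len(groups)
    if n < 2:
        raise TrainConfigError("need at least 2 groups to split")
    n_train = int(np.floor(fraction * n))
    if n_train < 1 or n_train >= n:
        raise TrainConfigError(
            f"fraction {fraction} leaves an empty side for {n} groups"
        )
    order = np.random.default_rng(seed).permutation(n)
    train = [groups[i] for i in sorted(order[:n_train])]
    val = [groups[i] for i in sorted(order[n_train:])]
    return train, val


def mask_input(
    spectra: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Zero each entry independently with probability ``fraction``.

    Returns ``(masked, mask)`` with ``mask`` True where an entry was zeroed.
    A fresh mask is drawn on every call (per-epoch augmentation).
    """
    if not 0.0 <= fraction < 1.0:
        raise TrainConfigError(f"mask fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return spectra, np.zeros(spectra.shape, dtype=bool)
    mask = rng.random(spectra.shape) < fraction
    return np.where(mask, 0.0, spectra), mask


# ---------------------------------------------------------------------------
# Early stopping


def early_stop_epoch(val_losses: Sequence[float], patience: int) -> int | None:
    """Index of the epoch at which training stops, or None if it never does.

    Training stops at the first epoch ``e`` with ``e - best_epoch >= patience``,
    where ``best_epoch`` is the last strict improvement of the running best.
    A flat trace therefore stops at ``best_epoch + patience``.
    """
    best = np.inf
    best_i = 0
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_i = v, i
        elif i - best_i >= patience:
            return i
    return None


# ---------------------------------------------------------------------------
# Objective + gradient (analytic backprop)


def _cae_loss_and_grad(
    theta: np.ndarray,
    x_in: np.ndarray,  # [B, P, W] encoder inputs (possibly masked)
    x_tgt: np.ndarray,  # [B, P, W] unmasked targets
    spec: NetworkSpec,
    layout: LatentLayout,
    weight: float,
    freeze_fusion: bool = False,
) -> tuple[float, np.ndarray]:
    shapes = model.param_shapes(spec, layout)
    enc, fusion, dec = model.unpack_params(theta, shapes)
    B, P, W = x_in.shape
    d, D = layout.d, layout.D
    idx = layout.compose_index_matrix()

    z, enc_cache = model._mlp_forward(x_in.reshape(B * P, W), enc, "linear", True)
    zcat = z.reshape(B, P * d)
    wf, bf = fusion
    fused = zcat @ wf + bf
    composed = fused[:, idx]  # [B, P, d]
    xhat, dec_cache = model._mlp_forward(composed.reshape(B * P, d), dec, "sigmoid", True)

    resid = xhat - x_tgt.reshape(B * P, W)
    n_el = resid.size
    mse = float(np.mean(resid**2))

    corr = 0.0
    d_fused_corr = 0.0
    if weight > 0 and B >= 3:
        corr, d_fused_corr = losses.correlation_loss_grad(fused)
    loss = mse + weight * corr

    d_xhat = (2.0 / n_el) * resid
    d_composed_flat, dec_grads = model._mlp_backward(d_xhat, dec, dec_cache, "sigmoid")
    d_composed = d_composed_flat.reshape(B, P, d)

    d_fused = np.zeros((B, D))
    rows = np.arange(B)[:, None]
    for p in range(P):  # slots overlap across plants (shared Zg/Ze) -> accumulate
        np.add.at(d_fused, (rows, idx[p][None, :]), d_composed[:, p, :])
    if weight > 0 and B >= 3:
        d_fused += weight * d_fused_corr

    d_zcat = d_fused @ wf.T
    d_wf = zcat.T @ d_fused
    d_bf = d_fused.sum(axis=0)
    if freeze_fusion:
        d_wf = np.zeros_like(d_wf)
        d_bf = np.zeros_like(d_bf)
    _, enc_grads = model._mlp_backward(d_zcat.reshape(B * P, d), enc, enc_cache, "linear")

    chunks: list[np.ndarray] = []
    for dw, db in enc_grads:
        chunks.extend([dw.ravel(), db])
    chunks.extend([d_wf.ravel(), d_bf])
    for dw, db in dec_grads:
        chunks.extend([dw.ravel(), db])
    return loss, np.concatenate(chunks)


def _vanilla_loss_and_grad(
    theta: np.ndarray,
    x_in: np.ndarray,  # [n, W]
    x_tgt: np.ndarray,
    spec: NetworkSpec,
    d: int,
) -> tuple[float, np.ndarray]:
    shapes = model.param_shapes(spec, None, d=d)
    enc, _, dec = model.unpack_params(theta, shapes)
    z, enc_cache = model._mlp_forward(x_in, enc, "linear", True)
    xhat, dec_cache = model._mlp_forward(z, dec, "sigmoid", True)
    resid = xhat - x_tgt
    mse = float(np.mean(resid**2))
    d_xhat = (2.0 / resid.size) * resid
    d_z, dec_grads = model._mlp_backward(d_xhat, dec, dec_cache, "sigmoid")
    _, enc_grads = model._mlp_backward(d_z, enc, enc_cache, "linear")
    chunks: list[np.ndarray] = []
    for dw, db in enc_grads:
        chunks.extend([dw.ravel(), db])
    for dw, db in dec_grads:
        chunks.extend([dw.ravel(), db])
    return mse, np.concatenate(chunks)


def _evaluate_cae(theta, x, spec, layout, weight) -> LossBreakdown:
    recon, fused = model.cae_forward_batch(x, spec, layout, theta)
    return losses.evaluate_loss(x, recon, fused, weight)


def _evaluate_vanilla(theta, x, spec, d, weight=0.0) -> LossBreakdown:
    recon, _ = model.vanilla_forward(x, spec, d, theta)
    return losses.evaluate_loss(x, recon, None, weight)


# ---------------------------------------------------------------------------
# Optimizer epochs


def _lbfgs_epoch(fun, theta, config: TrainConfig) -> np.ndarray:
    res = scipy.optimize.minimize(
        fun,
        theta,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.lbfgs_max_inner,
            "maxcor": config.lbfgs_history,
            "ftol": 1e-14,
            "gtol": 1e-12,
        },
    )
    return res.x


def _sgd_like_epoch(fun, theta, config: TrainConfig, state: dict) -> np.ndarray:
    lr = config.learning_rate
    for _ in range(config.inner_steps):
        _, g = fun(theta)
        if config.optimizer == "sgd":
            theta = theta - lr * g
        else:  # adam
            state.setdefault("m", np.zeros_like(theta))
            state.setdefault("v", np.zeros_like(theta))
            state["t"] = state.get("t", 0) + 1
            b1, b2, eps = 0.9, 0.999, 1e-8
            state["m"] = b1 * state["m"] + (1 - b1) * g
            state["v"] = b2 * state["v"] + (1 - b2) * g**2
            mhat = state["m"] / (1 - b1 ** state["t"])
            vhat = state["v"] / (1 - b2 ** state["t"])
            theta = theta - lr * mhat / (np.sqrt(vhat) + eps)
    return theta


# ---------------------------------------------------------------------------
# Training loops


def _train_loop(
    theta: np.ndarray,
    make_objective: Callable[[np.ndarray], Callable],
    evaluate: Callable[[np.ndarray, np.ndarray], LossBreakdown],
    x_train: np.ndarray,
    x_val: np.ndarray,
    config: TrainConfig,
) -> tuple[np.ndarray, list[dict], int, int, float]:
    mask_rng = np.random.default_rng(config.seed + 1_000_003)
    history: list[dict] = []
    best_theta = theta.copy()
    best_val = np.inf
    best_epoch = 0
    opt_state: dict = {}
    stopped = -1
    for epoch in range(config.max_epochs):
        masked, _ = mask_input(x_train, config.mask_fraction, mask_rng)
        fun = make_objective(masked)
        if config.optimizer == "lbfgs":
            theta = _lbfgs_epoch(fun, theta, config)
        else:
            theta = _sgd_like_epoch(fun, theta, config, opt_state)
        train_loss = evaluate(theta, x_train)
        val_loss = evaluate(theta, x_val)
        if not (np.isfinite(train_loss.total) and np.isfinite(val_loss.total)):
            raise TrainDivergenceError(
                f"non-finite loss at epoch {epoch}: train={train_loss.total}, val={val_loss.total}"
            )
        history.append({"train": train_loss, "val": val_loss})
        monitored = (
            val_loss.reconstruction
            if config.early_stop_metric == "reconstruction"
            else val_loss.total
        )
        if monitored < best_val:
            best_val = monitored
            best_theta = theta.copy()
            best_epoch = epoch
        stopped = epoch
        if epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
            break
    if not config.restore_best:
        best_theta = theta
    return best_theta, history, stopped, best_epoch, best_val


def train_cae(
    x_groups: np.ndarray,
    spec: NetworkSpec,
    layout: LatentLayout,
    config: TrainConfig,
    environment_order: list[str] | None = None,
    norm_constants: tuple[float, float] | None = None,
) -> TrainResult:
    """Train a compositional autoencoder on ``[n_groups, P, input_dim]`` spectra.

    The group axis is split 85/15 (per ``config``), encoder inputs are
    masked per epoch while targets stay unmasked, and the objective is
    MSE + weight * correlation penalty over the fused latents of the
    training batch.
    """
    x_groups = np.asarray(x_groups, dtype=float)
    if x_groups.ndim != 3 or x_groups.shape[1] != layout.P:
        raise TrainConfigError(
            f"expected [n_groups, {layout.P}, input_dim] spectra, got {x_groups.shape}"
        )
    if x_groups.shape[0] < 2:
        raise TrainConfigError("need at least 2 groups to train")
    if config.identity_fusion and (layout.P != 1 or layout.D != layout.d):
        raise TrainConfigError("identity_fusion requires P == 1 and D == d")

    idx_train, idx_val = split_groups(list(range(x_groups.shape[0])), config.split_fraction, config.seed)
    x_train, x_val = x_groups[idx_train], x_groups[idx_val]

    shapes = model.param_shapes(spec, layout)
    theta0 = model.init_params(shapes, config.seed, identity_fusion=config.identity_fusion)

    def make_objective(masked: np.ndarray):
        def fun(theta: np.ndarray):
            return _cae_loss_and_grad(
                theta, masked, x_train, spec, layout, config.weight,
                freeze_fusion=config.identity_fusion,
            )
        return fun

    def evaluate(theta: np.ndarray, x: np.ndarray) -> LossBreakdown:
        return _evaluate_cae(theta, x, spec, layout, config.weight)

    best_theta, history, stopped, best_epoch, best_val = _train_loop(
        theta0, make_objective, evaluate, x_train, x_val, config
    )
    ckpt = Checkpoint(
        model_type="cae",
        theta=best_theta,
        spec=spec,
        layout=layout,
        d=layout.d,
        environment_order=environment_order,
        norm_constants=norm_constants,
        seed=config.seed,
        config=dataclasses.asdict(config),
    )
    return TrainResult(ckpt, history, stopped, best_epoch, best_val)


def train_vanilla(
    x_samples: np.ndarray,
    spec: NetworkSpec,
    d: int,
    config: TrainConfig,
    norm_constants: tuple[float, float] | None = None,
) -> TrainResult:
    """Train a vanilla autoencoder on ``[n_samples, input_dim]`` spectra.

    Reconstruction-only objective: a positive correlation weight is
    rejected (the vanilla baseline is MSE-only by definition).
    """
    if config.weight != 0.0:
        raise TrainConfigError(
            "vanilla training is reconstruction-only; set weight=0 in TrainConfig"
        )
    x_samples = np.asarray(x_samples, dtype=float)
    if x_samples.ndim != 2:
        raise TrainConfigError(f"expected [n_samples, input_dim] spectra, got {x_samples.shape}")
    if x_samples.shape[0] < 2:
        raise TrainConfigError("need at least 2 samples to train")

    idx_train, idx_val = split_groups(list(range(x_samples.shape[0])), config.split_fraction, config.seed)
    x_train, x_val = x_samples[idx_train], x_samples[idx_val]

    shapes = model.param_shapes(spec, None, d=d)
    theta0 = model.init_params(shapes, config.seed)

    def make_objective(masked: np.ndarray):
        def fun(theta: np.ndarray):
            return _vanilla_loss_and_grad(theta, masked, x_train, spec, d)
        return fun

    def evaluate(theta: np.ndarray, x: np.ndarray) -> LossBreakdown:
        return _evaluate_vanilla(theta, x, spec, d)

    best_theta, history, stopped, best_epoch, best_val = _train_loop(
        theta0, make_objective, evaluate, x_train, x_val, config
    )
    ckpt = Checkpoint(
        model_type="vanilla",
        theta=best_theta,
        spec=spec,
        layout=None,
        d=d,
        norm_constants=norm_constants,
        seed=config.seed,
        config=dataclasses.asdict(config),
    )
    return TrainResult(ckpt, history, stopped, best_epoch, best_val)


def validation_loss(result_or_ckpt, x_val: np.ndarray, weight: float | None = None) -> LossBreakdown:
    """Recompute the validation loss of a checkpoint on given spectra."""
    ckpt = result_or_ckpt.checkpoint if isinstance(result_or_ckpt, TrainResult) else result_or_ckpt
    if ckpt.model_type == "cae":
        w = ckpt.config["weight"] if weight is None else weight
        return _evaluate_cae(ckpt.theta, x_val, ckpt.spec, ckpt.layout, w)
    return _evaluate_vanilla(ckpt.theta, x_val, ckpt.spec, ckpt.d)


# ---------------------------------------------------------------------------
# Hyperparameter sweeps


def sweep(
    axis: str,
    values: Sequence,
    x_groups: np.ndarray,
    spec: NetworkSpec,
    layout: LatentLayout,
    config: TrainConfig,
    downstream_eval: Callable[[Checkpoint], float] | None = None,
) -> pd.DataFrame:
    """One full train (+ optional downstream evaluation) per value of one axis.

    ``axis`` is ``mask_fraction`` (floats), ``depth`` (hidden-dim tuples) or
    ``latent_layout`` ((zg, ze, zp) tuples).  Returns a tidy table with one
    row per value: value, best validation loss, downstream R² (if a
    callback is supplied).
    """
    if not values:
        raise TrainConfigError("sweep needs a non-empty list of values")
    if axis not in ("mask_fraction", "depth", "latent_layout"):
        raise TrainConfigError(f"unknown sweep axis {axis!r}")
    rows = []
    for v in values:
        cfg, sp, lay = config, spec, layout
        if axis == "mask_fraction":
            cfg = dataclasses.replace(config, mask_fraction=float(v))
        elif axis == "depth":
            sp = dataclasses.replace(spec, hidden_dims=tuple(v))
        else:
            zg, ze, zp = v
            lay = LatentLayout(zg=zg, ze=ze, zp=zp, E=layout.E, N=layout.N)
        result = train_cae(x_groups, sp, lay, cfg)
        row = {"axis": axis, "value": str(v), "val_loss": result.best_val_loss}
        if downstream_eval is not None:
            row["downstream_r2"] = downstream_eval(result.checkpoint)
        rows.append(row)
    return pd.DataFrame(rows)
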