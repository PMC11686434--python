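"""Two-part training objective: reconstruction MSE + Pearson decorrelation penalty.

The correlation loss sums |r_ij| over the upper triangle (i <= j) of the
D x D Pearson correlation matrix of the fused latent dimensions, computed
across the groups of the current batch; the diagonal contributes exactly
zero (|1| - 1).  Driving it to zero keeps the genotype, macro-environment
and micro-environment blocks mutually uncorrelated during training.

Analytic gradients are provided for the trainer; they are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger("phenocae")

#: additive guard on correlation denominators so dead (zero-variance) latent
#: units early in training cannot produce NaN losses
EPS = 1e-8


class LossInputError(ValueError):
    """Shape or sample-size violation in a loss computation."""


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """Reconstruction MSE, correlation penalty, and their weighted total."""

    reconstruction: float
    correlation: float
    weight: float  # lambda, the correlation weight

    @property
    def total(self) -> float:
        return self.reconstruction + self.weight * self.correlation

    def as_dict(self) -> dict:
        return {
            "reconstruction": self.reconstruction,
            "correlation": self.correlation,
            "weight": self.weight,
            "total": self.total,
        }


def reconstruction_mse(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Mean over all elements of the squared difference."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise LossInputError(
            f"shape mismatch: {original.shape} vs {reconstructed.shape}"
        )
    return float(np.mean((original - reconstructed) ** 2))


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation r = sum((x-x̄)(y-ȳ)) / sqrt(sum((x-x̄)²) sum((y-ȳ)²)).

    A zero-variance input yields 0 via the epsilon-guarded denominator
    rather than NaN.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise LossInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise LossInputError("need at least 2 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc)) * np.sqrt((yc @ yc)) + EPS
    return float((xc @ yc) / denom)


def correlation_matrix(batch: np.ndarray) -> np.ndarray:
    """Epsilon-guarded Pearson matrix over the columns of ``[B, D]``."""
    batch = np.asarray(batch, dtype=float)
    centered = batch - batch.mean(axis=0)
    cov = centered.T @ centered
    scale = np.sqrt(np.diag(cov))
    return cov / (np.outer(scale, scale) + EPS)


def correlation_loss(batch: np.ndarray) -> float:
    """Sum of |r_ij| over the off-diagonal upper triangle of the Pearson matrix.

    ``batch`` is ``[B, D]`` — B fused latents (one per group) by D latent
    dimensions.  Requires B >= 3 (Pearson estimated from fewer points is
    degenerate).  The value lies in [0, D(D-1)/2].
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2:
        raise LossInputError("latent batch must be a 2-D matrix [B, D]")
    if batch.shape[0] < 3:
        raise LossInputError(
            f"need >= 3 groups in a batch to estimate correlations, got {batch.shape[0]}"
        )
    corr = correlation_matrix(batch)
    return float(np.sum(np.abs(np.triu(corr, k=1))))


def correlation_loss_grad(batch: np.ndarray) -> tuple[float, np.ndarray]:
    """Correlation loss and its gradient with respect to the latent batch.

    With centered columns Fc, s_i = ||Fc_i||, C = Fc^T Fc and
    r_ij = C_ij / (s_i s_j + eps), the gradient of sum_{i<j} |r_ij| is

        dL/dFc = Fc (S / Den) - Fc * w,
        w_i = sum_j S_ij C_ij s_j / (Den_ij^2 s_i),

    with S = sign(r) zeroed on the diagonal, followed by the centering
    backward pass (subtract the column mean).
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[0] < 3:
        raise LossInputError("latent batch must be [B>=3, D]")
    fc = batch - batch.mean(axis=0)
    cov = fc.T @ fc
    s = np.sqrt(np.diag(cov))
    den = np.outer(s, s) + EPS
    r = cov / den
    np.fill_diagonal(r, 1.0)
    loss = float(np.sum(np.abs(np.triu(r, k=1))))

    sign = np.sign(r)
    np.fill_diagonal(sign, 0.0)
    term1 = fc @ (sign / den)
    s_safe = np.maximum(s, EPS)
    w = np.einsum("ij,ij,j->i", sign, cov / den**2, s) / s_safe
    d_fc = term1 - fc * w
    d_batch = d_fc - d_fc.mean(axis=0)
    return loss, d_batch


def total_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    latent_batch: np.ndarray,
    weight: float = 1.0,
) -> LossBreakdown:
    """MSE + weight * correlation penalty; weight 0 recovers pure reconstruction."""
    if weight < 0:
        raise LossInputError(f"correlation weight must be >= 0, got {weight}")
    mse = reconstruction_mse(original, reconstructed)
    corr = correlation_loss(latent_batch) if weight > 0 else 0.0
    return LossBreakdown(reconstruction=mse, correlation=corr, weight=weight)


def evaluate_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    latent_batch: np.ndarray | None,
    weight: float,
) -> LossBreakdown:
    """Like :func:`total_loss` but always reports the correlation term when
    a latent batch is available (even at weight 0), for logging."""
    mse = reconstruction_mse(original, reconstructed)
    corr = 0.0
    if latent_batch is not None and latent_batch.shape[0] >= 3:
        corr = correlation_loss(latent_batch)
    return LossBreakdown(reconstruction=mse, correlation=corr, weight=weight)
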