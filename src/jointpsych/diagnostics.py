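"""Goodness-of-fit and posterior-agreement diagnostics.

Deviance quantifies the fit of one condition:

    D = 2 * sum_i [ k_i log(k_i / (n_i p_i)) + (n_i - k_i) log((n_i - k_i) / (n_i (1 - p_i))) ]

with the convention 0*log(0) = 0 for blocks at the boundary.  Signed
deviance residuals carry the sign of ``k/n - p`` and square-sum to D;
deviance is additive over blocks and over conditions.

The overlap statistic compares two distributions through their first and
third quartiles only:

    q = (min(Q3_a, Q3_b) - max(Q1_a, Q1_b)) / (max(Q3_a, Q3_b) - min(Q1_a, Q1_b))

It is 1 when both quartile pairs coincide, 0 when one interquartile range
ends exactly where the other begins, and tends to -1 as two fixed-width
distributions separate.  It is symmetric and invariant under common affine
rescaling of all four quartiles — a robust measure that ignores tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .exceptions import DataValidationError
from .model import BlockDataset, PsychometricParams, predict
from .sampling import PosteriorSample

__all__ = [
    "OverlapInput",
    "DevianceReport",
    "deviance",
    "overlap",
    "posterior_overlap",
    "posterior_correlation",
]


@dataclass(frozen=True)
class OverlapInput:
    """First/third quartiles of two distributions, in parameter units."""

    q1_a: float
    q3_a: float
    q1_b: float
    q3_b: float

    def __post_init__(self) -> None:
        if self.q1_a > self.q3_a or self.q1_b > self.q3_b:
            raise DataValidationError(
                "first quartile must not exceed third quartile"
            )


@dataclass
class DevianceReport:
    """Per-block signed deviance residuals and the total deviance."""

    condition_id: str
    residuals: np.ndarray
    block_deviances: np.ndarray
    total: float

    @property
    def finite(self) -> bool:
        return bool(np.isfinite(self.total))


def deviance(data: BlockDataset, params: PsychometricParams) -> DevianceReport:
    """Binomial deviance of a fitted psychometric function on one condition.

    D = 0 exactly when the predicted probability equals the observed
    proportion ``k/n`` in every block.  A predicted probability of exactly
    0 or 1 that contradicts the counts yields infinite deviance (flagged via
    ``report.finite``), not an exception.
    """
    p = predict(params, data.x)
    k = data.k.astype(float)
    n = data.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = xlogy(k, k / (n * p))
        term2 = xlogy(n - k, (n - k) / (n * (1.0 - p)))
    block_dev = 2.0 * (term1 + term2)
    # xlogy handles k=0 / k=n (0*log 0 = 0); contradictory p=0 or 1 -> inf
    block_dev = np.where(np.isnan(block_dev), np.inf, block_dev)
    with np.errstate(invalid="ignore"):
        resid = np.sign(k / n - p) * np.sqrt(np.maximum(block_dev, 0.0))
    resid = np.where(np.isnan(resid), 0.0, resid)  # sign 0 on an inf block
    return DevianceReport(
        condition_id=data.condition_id,
        residuals=resid,
        block_deviances=block_dev,
        total=float(block_dev.sum()),
    )


def summed_deviance(reports: list[DevianceReport]) -> float:
    """Deviance of a multi-condition fit: the sum over the model components."""
    return float(sum(r.total for r in reports))


def overlap(q: OverlapInput) -> float:
    """Quartile-overlap statistic in (-inf, 1]; see module docstring."""
    num = min(q.q3_a, q.q3_b) - max(q.q1_a, q.q1_b)
    den = max(q.q3_a, q.q3_b) - min(q.q1_a, q.q1_b)
    if den == 0.0:
        # both interquartile ranges degenerate to the same point
        return 1.0
    return num / den


def _quartiles(draws: np.ndarray) -> tuple[float, float]:
    # linear interpolation of order statistics (the "type 7" convention)
    q1, q3 = np.quantile(draws, [0.25, 0.75])
    return float(q1), float(q3)


def posterior_overlap(a: PosteriorSample, b: PosteriorSample, param: str = "w") -> float:
    """Overlap of two posteriors' marginal interquartile ranges for ``param``."""
    for post in (a, b):
        if param not in post.draws.columns:
            raise DataValidationError(f"posterior has no parameter {param!r}")
        if len(post.draws) < 4:
            raise DataValidationError("need at least 4 draws to form quartiles")
    q1a, q3a = _quartiles(a.draws[param].to_numpy())
    q1b, q3b = _quartiles(b.draws[param].to_numpy())
    return overlap(OverlapInput(q1_a=q1a, q3_a=q3a, q1_b=q1b, q3_b=q3b))


def posterior_correlation(post: PosteriorSample, p1: str, p2: str) -> float:
    """Pearson correlation between two marginal draw vectors of a posterior."""
    for name in (p1, p2):
        if name not in post.draws.columns:
            raise DataValidationError(f"posterior has no parameter {name!r}")
    a = post.draws[p1].to_numpy()
    b = post.draws[p2].to_numpy()
    if a.size < 3:
        raise DataValidationError("need at least 3 draws for a correlation")
    if a.std() == 0 or b.std() == 0:
        raise DataValidationError("zero variance in a marginal; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
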