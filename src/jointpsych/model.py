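"""Psychometric (dose-rate) model: parameterization and binomial likelihood.

The success probability at stimulus intensity ``x`` is

    psi(x) = gamma + (1 - gamma - lam) * F(x; m, w)

where ``gamma`` is the guess rate (lower asymptote, fixed by the experimental
design, e.g. 0.5 in two-alternative forced choice), ``lam`` is the lapse rate
(upper-asymptote shortfall), ``m`` is the threshold (intensity at which the
curve is halfway between its asymptotes) and ``w`` the width: the range of
intensities over which the curve rises from 10% above the lower asymptote to
10% below the upper asymptote.  ``F`` is a logistic sigmoid scaled by
``2*ln(9)`` so that ``w`` is exactly that 10%-90% rise interval.

Responses in a block of ``n`` trials at one intensity are modelled as
binomial with success probability ``psi(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .exceptions import DataValidationError, ParameterError

#: Logistic scale constant making ``w`` the exact 10%-90% rise interval:
#: F(m + w/2) = 1/(1 + exp(-ln 81 / 2 * ... )) = 0.9.
RISE_SCALE = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameter vector (m, w, lam) plus the fixed guess rate gamma.

    Parameters
    ----------
    m : float
        Threshold: intensity at which performance is halfway between the
        asymptotes ``gamma`` and ``1 - lam``.
    w : float
        Width of the 10%-90% rise interval, in stimulus-intensity units.
        Strictly positive; inversely related to slope.
    lam : float
        Lapse rate in ``[0, 1)``: shortfall of the upper asymptote below 1.
    gamma : float
        Guess rate in ``[0, 1)``: the lower asymptote.  Fixed by design
        (0.5 for two-alternative forced choice), not estimated.
    """

    m: float
    w: float
    lam: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.m):
            raise ParameterError(f"threshold m must be finite, got {self.m}")
        if not (self.w > 0 and np.isfinite(self.w)):
            raise ParameterError(f"width w must be strictly positive, got {self.w}")
        if not 0.0 <= self.lam < 1.0:
            raise ParameterError(f"lapse rate lam must be in [0, 1), got {self.lam}")
        if not 0.0 <= self.gamma < 1.0:
            raise ParameterError(f"guess rate gamma must be in [0, 1), got {self.gamma}")
        if self.gamma + self.lam >= 1.0:
            raise ParameterError(
                f"gamma + lam must be < 1, got {self.gamma} + {self.lam}"
            )

    def as_dict(self) -> dict[str, float]:
        return {"m": self.m, "w": self.w, "lam": self.lam, "gamma": self.gamma}


@dataclass
class BlockDataset:
    """One experimental condition: blocks of (intensity, correct, trials).

    Attributes
    ----------
    condition_id : str
        Label for the condition.
    x, k, n : ndarray
        Per-block stimulus intensity, number of correct responses and number
        of trials.  ``0 <= k <= n``, ``n >= 1``; at least 3 blocks.
    """

    condition_id: str
    x: np.ndarray
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if not (self.x.shape == self.k.shape == self.n.shape) or self.x.ndim != 1:
            raise DataValidationError("x, k, n must be 1-d arrays of equal length")
        if self.x.size < 3:
            raise DataValidationError(
                f"need at least 3 blocks, got {self.x.size}"
            )
        if not np.all(np.isfinite(self.x)):
            raise DataValidationError("intensities must be finite")
        if np.any(self.n < 1):
            raise DataValidationError("every block needs at least one trial")
        if np.any(self.k < 0) or np.any(self.k > self.n):
            bad = int(np.flatnonzero((self.k < 0) | (self.k > self.n))[0])
            raise DataValidationError(
                f"block {bad}: k={self.k[bad]} outside [0, n={self.n[bad]}]"
            )

    @classmethod
    def from_blocks(
        cls, blocks: list[tuple[float, int, int]], condition_id: str = "cond"
    ) -> "BlockDataset":
        x, k, n = (np.array(col) for col in zip(*blocks))
        return cls(condition_id=condition_id, x=x, k=k, n=n)

    @property
    def n_blocks(self) -> int:
        return int(self.x.size)

    @property
    def total_trials(self) -> int:
        return int(self.n.sum())


def psi_grid(m, w, lam, gamma, x):
    """Vectorized success probability for draws x blocks.

    ``m``, ``w``, ``lam`` are arrays of shape (S,) (or scalars), ``x`` of
    shape (B,); the result broadcasts to (S, B).  No domain validation is
    performed here: invalid draws are the caller's concern.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))[:, None]
    w = np.atleast_1d(np.asarray(w, dtype=float))[:, None]
    lam = np.atleast_1d(np.asarray(lam, dtype=float))[:, None]
    x = np.asarray(x, dtype=float)[None, :]
    return gamma + (1.0 - gamma - lam) * expit(RISE_SCALE * (x - m) / w)


def predict(params: PsychometricParams, x) -> np.ndarray | float:
    """Success probability psi(x) of the psychometric function.

    Monotone nondecreasing in ``x``; ``psi(m)`` is the midpoint of
    ``[gamma, 1 - lam]`` and the limits are ``gamma`` and ``1 - lam``.
    """
    scalar = np.isscalar(x)
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    out = psi_grid(params.m, params.w, params.lam, params.gamma, xs)[0]
    return float(out[0]) if scalar else out


def log_likelihood(params: PsychometricParams, data: BlockDataset) -> float:
    """Binomial log-likelihood of one condition's blocks.

    Returns ``-inf`` (never raises) when a block probability of exactly 0 or
    1 contradicts the observed counts.
    """
    p = predict(params, data.x)
    return float(np.sum(stats.binom.logpmf(data.k, data.n, p)))


def log_likelihood_draws(m, w, lam, gamma: float, data: BlockDataset) -> np.ndarray:
    """Binomial log-likelihood for S parameter draws at once, shape (S,).

    Draws violating the parameter domain (w <= 0, lam outside [0, 1 - gamma))
    get log-likelihood ``-inf`` rather than raising, so that importance
    weights can be formed for proposals from unbounded priors.
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    valid = (w > 0) & (lam >= 0) & (lam + gamma < 1) & np.isfinite(m)
    ll = np.full(m.shape, -np.inf)
    if np.any(valid):
        p = psi_grid(m[valid], w[valid], lam[valid], gamma, data.x)
        ll[valid] = stats.binom.logpmf(data.k[None, :], data.n[None, :], p).sum(axis=1)
    return ll
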