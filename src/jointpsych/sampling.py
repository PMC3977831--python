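"""Sampling-importance-resampling (SIR) posterior estimation for one
condition, and parametric Gamma summaries of marginal posteriors.

Proposals are drawn from the prior, each proposal is weighted by its
likelihood, and the final draws are resampled (with replacement) from the
proposals with probabilities proportional to the importance weights.  With
prior proposals the mean proposal likelihood is a consistent estimator of
the marginal likelihood p(data), which model selection builds on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import DegenerateFitWarning, SamplingError
from .model import BlockDataset, log_likelihood_draws

__all__ = [
    "NormalPrior",
    "GammaPrior",
    "TruncatedBetaPrior",
    "PriorSpec",
    "GammaSummary",
    "PosteriorSample",
    "SIRResult",
    "sir",
    "sir_sample",
    "fit_gamma_summary",
    "marginal_loglik",
]

DEFAULT_N_PROPOSALS = 25_000
DEFAULT_N_FINAL = 2_000
DEFAULT_ESS_FLOOR = 50.0


@dataclass(frozen=True)
class NormalPrior:
    """Gaussian prior, used for the threshold m (location family)."""

    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size)

    def logpdf(self, x) -> np.ndarray:
        return stats.norm.logpdf(x, self.mean, self.sd)


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior with shape/rate parameterization, supported on (0, inf)."""

    shape: float
    rate: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, 1.0 / self.rate, size)

    def logpdf(self, x) -> np.ndarray:
        return stats.gamma.logpdf(x, self.shape, scale=1.0 / self.rate)

    @property
    def mean(self) -> float:
        return self.shape / self.rate


@dataclass(frozen=True)
class TruncatedBetaPrior:
    """Beta(a, b) prior rescaled by truncation to [0, upper], for the lapse
    rate; sampling is by inverse-CDF on the truncated support."""

    a: float
    b: float
    upper: float = 0.1

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        f_up = stats.beta.cdf(self.upper, self.a, self.b)
        u = rng.uniform(0.0, f_up, size)
        return stats.beta.ppf(u, self.a, self.b)

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f_up = stats.beta.cdf(self.upper, self.a, self.b)
        out = stats.beta.logpdf(x, self.a, self.b) - np.log(f_up)
        return np.where((x >= 0) & (x <= self.upper), out, -np.inf)


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter priors for (m, w, lam).

    Defaults are weakly informative and anchored on the tested intensity
    range: m ~ Normal(midrange, sd = range); w ~ Gamma(2, rate) with mean
    half the range; lam ~ Beta(2, 20) truncated to [0, 0.1].
    """

    m: NormalPrior
    w: GammaPrior
    lam: TruncatedBetaPrior | GammaPrior

    @classmethod
    def default(cls, data: BlockDataset) -> "PriorSpec":
        lo, hi = float(data.x.min()), float(data.x.max())
        span = hi - lo
        if span <= 0:
            raise SamplingError(
                "cannot build a default prior: all intensities are equal"
            )
        return cls(
            m=NormalPrior(mean=(lo + hi) / 2.0, sd=span),
            w=GammaPrior(shape=2.0, rate=4.0 / span),  # mean = span / 2
            lam=TruncatedBetaPrior(a=2.0, b=20.0, upper=0.1),
        )

    def sample(self, rng: np.random.Generator, size: int) -> dict[str, np.ndarray]:
        return {
            "m": self.m.sample(rng, size),
            "w": self.w.sample(rng, size),
            "lam": self.lam.sample(rng, size),
        }

    def replace(self, **kwargs) -> "PriorSpec":
        cfg = {"m": self.m, "w": self.w, "lam": self.lam}
        cfg.update(kwargs)
        return PriorSpec(**cfg)


@dataclass(frozen=True)
class GammaSummary:
    """Maximum-likelihood Gamma(shape, rate) summary of a one-parameter
    marginal posterior sample."""

    shape: float
    rate: float
    parameter_name: str = "w"

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise SamplingError(
                f"Gamma summary needs positive shape/rate, got "
                f"({self.shape}, {self.rate})"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    def to_prior(self) -> GammaPrior:
        return GammaPrior(shape=self.shape, rate=self.rate)


@dataclass
class SIRResult:
    """Raw output of one sampling-importance-resampling pass."""

    draws: dict[str, np.ndarray]
    proposal_log_weights: np.ndarray
    marginal_loglik: float
    ess: float
    degenerate: bool
    resample_index: np.ndarray


@dataclass
class PosteriorSample:
    """Resampled posterior draws for one condition.

    ``draws`` is a DataFrame with one column per parameter (equally-weighted
    resampled draws); ``proposal_log_weights`` are the unnormalized
    log-importance-weights of all proposals (the per-proposal log-likelihood
    when proposals come from the prior), retained for the marginal-likelihood
    estimate.
    """

    draws: pd.DataFrame
    proposal_log_weights: np.ndarray
    marginal_loglik_estimate: float
    seed: int
    n_proposals: int
    n_final: int
    ess: float
    degenerate: bool = False
    proposal_is_prior: bool = True
    gamma: float = 0.5
    condition_id: str = "cond"

    def mean_params(self):
        from .model import PsychometricParams

        return PsychometricParams(
            m=float(self.draws["m"].mean()),
            w=float(self.draws["w"].mean()),
            lam=float(self.draws["lam"].mean()),
            gamma=self.gamma,
        )


def sir(
    propose: Callable[[np.random.Generator, int], dict[str, np.ndarray]],
    log_likelihood_fn: Callable[[dict[str, np.ndarray]], np.ndarray],
    n_proposals: int,
    n_final: int,
    rng: np.random.Generator,
    ess_floor: float = DEFAULT_ESS_FLOOR,
) -> SIRResult:
    """Generic SIR pass with proposals from the prior.

    ``propose`` draws proposal parameter vectors, ``log_likelihood_fn``
    scores them; the importance weight of each proposal is its likelihood.
    Resampling is with replacement, so every final draw is one of the
    proposals.  The recorded marginal log-likelihood is
    ``log(mean likelihood of proposals)``.
    """
    if not (n_proposals >= n_final >= 1):
        raise SamplingError(
            f"need n_proposals >= n_final >= 1, got {n_proposals}, {n_final}"
        )
    proposals = propose(rng, n_proposals)
    logw = np.asarray(log_likelihood_fn(proposals), dtype=float)
    if logw.shape != (n_proposals,):
        raise SamplingError("log-likelihood must return one value per proposal")
    if not np.any(np.isfinite(logw)):
        raise SamplingError("all importance weights are zero; no viable proposal")
    marginal = float(special.logsumexp(logw) - np.log(n_proposals))
    logw_norm = logw - special.logsumexp(logw)
    weights = np.exp(logw_norm)
    ess = float(1.0 / np.sum(weights**2))
    degenerate = ess < ess_floor
    if degenerate:
        warnings.warn(
            f"effective sample size {ess:.1f} below floor {ess_floor:.1f}; "
            "posterior approximation flagged degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
    idx = rng.choice(n_proposals, size=n_final, replace=True, p=weights)
    draws = {name: vals[idx] for name, vals in proposals.items()}
    return SIRResult(
        draws=draws,
        proposal_log_weights=logw,
        marginal_loglik=marginal,
        ess=ess,
        degenerate=degenerate,
        resample_index=idx,
    )


def sir_sample(
    data: BlockDataset,
    prior: PriorSpec | None = None,
    n_proposals: int = DEFAULT_N_PROPOSALS,
    n_final: int = DEFAULT_N_FINAL,
    seed: int = 0,
    gamma: float = 0.5,
    ess_floor: float = DEFAULT_ESS_FLOOR,
) -> PosteriorSample:
    """Posterior of (m, w, lam) for one condition by SIR with prior proposals."""
    if prior is None:
        prior = PriorSpec.default(data)
    rng = np.random.default_rng(seed)
    res = sir(
        propose=prior.sample,
        log_likelihood_fn=lambda d: log_likelihood_draws(
            d["m"], d["w"], d["lam"], gamma, data
        ),
        n_proposals=n_proposals,
        n_final=n_final,
        rng=rng,
        ess_floor=ess_floor,
    )
    return PosteriorSample(
        draws=pd.DataFrame(res.draws),
        proposal_log_weights=res.proposal_log_weights,
        marginal_loglik_estimate=res.marginal_loglik,
        seed=seed,
        n_proposals=n_proposals,
        n_final=n_final,
        ess=res.ess,
        degenerate=res.degenerate,
        proposal_is_prior=True,
        gamma=gamma,
        condition_id=data.condition_id,
    )


def fit_gamma_summary(
    samples, parameter_name: str = "w", tol: float = 1e-8, max_iter: int = 100
) -> GammaSummary:
    """Maximum-likelihood Gamma fit to one-parameter posterior draws.

    Solves ``log(a) - digamma(a) = log(mean) - mean(log x)`` for the shape
    by Newton iteration from a moment-matching start; ``rate = a / mean``.
    The fitted mean (shape/rate) equals the sample mean by construction.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 10:
        raise SamplingError(f"need at least 10 samples, got {x.size}")
    if np.any(x <= 0):
        raise SamplingError("Gamma summary requires strictly positive samples")
    mean = x.mean()
    if x.std() / mean < 1e-8:
        raise SamplingError("near-degenerate sample variance; cannot fit Gamma")
    s = np.log(mean) - np.mean(np.log(x))
    # standard closed-form starting approximation for the shape
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_iter):
        f = np.log(a) - special.digamma(a) - s
        fprime = 1.0 / a - special.polygamma(1, a)
        step = f / fprime
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < tol * a:
            a = a_new
            break
        a = a_new
    return GammaSummary(shape=float(a), rate=float(a / mean), parameter_name=parameter_name)


def marginal_loglik(post: PosteriorSample) -> float:
    """Log marginal likelihood estimate: log mean proposal likelihood.

    Valid only when the SIR proposals were drawn from the prior (so that the
    importance weight of a proposal is its likelihood).
    """
    if not post.proposal_is_prior:
        raise SamplingError(
            "marginal likelihood estimator requires prior-drawn proposals"
        )
    return post.marginal_loglik_estimate
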