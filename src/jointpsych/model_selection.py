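"""Model selection between the isolated models and the joint model.

The model indicator is treated as one more parameter with two values,
"isolated" and "joint".  Under a flat model prior its posterior follows
from the marginal likelihoods, so the decision is equivalent to one based
on the Bayes factor Z_joint / Z_isolated.

Marginal likelihoods come from the prior-proposal SIR estimator (mean
likelihood of prior draws).  The isolated model factorizes over conditions:
Z_iso is the product of per-condition marginal likelihoods under the
original priors.  The joint model is assembled sequentially: fit the first
condition under its original priors, Gamma-summarize the shared marginal,
then estimate the next condition's marginal likelihood with that summary as
the shared-parameter prior, and so on; each step's marginal log-likelihood
adds to log Z_joint.  Because the order of conditions should not matter in
theory but does affect the Monte Carlo estimate, log Z_joint is averaged
over the forward and reversed orders.

A two-state Gibbs chain over the model indicator is provided as a
cross-check: its stationary distribution is the analytic posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .exceptions import DataValidationError
from .joint import SHAREABLE
from .model import BlockDataset
from .sampling import (
    DEFAULT_ESS_FLOOR,
    DEFAULT_N_FINAL,
    DEFAULT_N_PROPOSALS,
    PosteriorSample,
    PriorSpec,
    fit_gamma_summary,
    marginal_loglik,
    sir_sample,
)

__all__ = ["ModelComparison", "compare_models", "auc", "gibbs_model_chain", "posterior_model_probs"]


@dataclass
class ModelComparison:
    """Posterior probabilities of the isolated vs joint model."""

    p_isolated: float
    p_joint: float
    log_marglik_isolated: float
    log_marglik_joint: float
    method: str = "analytic-stationary"
    gibbs_p_isolated: float | None = None
    degenerate: bool = False
    isolated_posteriors: list[PosteriorSample] | None = None

    @property
    def log_bayes_factor_joint(self) -> float:
        """log(Z_joint / Z_isolated); positive favors the joint model."""
        return self.log_marglik_joint - self.log_marglik_isolated

    def verdict(self) -> str:
        winner = "joint" if self.p_joint >= self.p_isolated else "isolated"
        p = max(self.p_joint, self.p_isolated)
        return (
            f"the {winner} model is favored with posterior probability {p:.3f} "
            f"(log Bayes factor joint vs isolated: {self.log_bayes_factor_joint:+.2f})"
        )


def posterior_model_probs(
    log_z_iso: float, log_z_joint: float, model_prior: tuple[float, float] = (0.5, 0.5)
) -> tuple[float, float]:
    """(p_isolated, p_joint) from log marginal likelihoods and a model prior."""
    pri_iso, pri_joint = model_prior
    logs = np.array([np.log(pri_iso) + log_z_iso, np.log(pri_joint) + log_z_joint])
    p = np.exp(logs - logsumexp(logs))
    return float(p[0]), float(p[1])


def compare_models(
    datasets: list[BlockDataset],
    shared: str = "w",
    *,
    priors: list[PriorSpec] | None = None,
    gamma: float = 0.5,
    n_proposals: int = DEFAULT_N_PROPOSALS,
    n_final: int = DEFAULT_N_FINAL,
    seed: int = 0,
    ess_floor: float = DEFAULT_ESS_FLOOR,
    model_prior: tuple[float, float] = (0.5, 0.5),
    n_gibbs: int = 0,
) -> ModelComparison:
    """Posterior model probabilities for isolated vs joint description.

    ``model_prior`` is (prior probability of isolated, of joint); the flat
    default makes the decision a pure Bayes-factor one.  With ``n_gibbs > 0``
    a two-state Gibbs chain over the model indicator is also run and its
    indicator frequency reported as a cross-check of the analytic value.
    """
    if len(datasets) < 2:
        raise DataValidationError("model comparison needs at least 2 datasets")
    if shared not in SHAREABLE:
        raise DataValidationError(f"shared parameter must be one of {SHAREABLE}")
    if priors is None:
        priors = [PriorSpec.default(d) for d in datasets]

    def seed_for(tag: int, i: int) -> int:
        return int(np.random.SeedSequence([seed, tag, i]).generate_state(1)[0] % 2**31)

    # isolated model: product over conditions under original priors
    iso_fits = [
        sir_sample(
            d,
            prior=pr,
            n_proposals=n_proposals,
            n_final=n_final,
            seed=seed_for(11, i),
            gamma=gamma,
            ess_floor=ess_floor,
        )
        for i, (d, pr) in enumerate(zip(datasets, priors))
    ]
    log_z_iso = float(sum(marginal_loglik(f) for f in iso_fits))

    # joint model: sequential chain, symmetrized over forward/reverse order
    def chain_log_z(order: list[int]) -> float:
        total = marginal_loglik(iso_fits[order[0]])
        summary = fit_gamma_summary(
            iso_fits[order[0]].draws[shared].to_numpy(), parameter_name=shared
        )
        for step, i in enumerate(order[1:], start=1):
            fit = sir_sample(
                datasets[i],
                prior=priors[i].replace(**{shared: summary.to_prior()}),
                n_proposals=n_proposals,
                n_final=n_final,
                seed=seed_for(20 + step, i),
                gamma=gamma,
                ess_floor=ess_floor,
            )
            total += marginal_loglik(fit)
            if step < len(order) - 1:
                summary = fit_gamma_summary(
                    fit.draws[shared].to_numpy(), parameter_name=shared
                )
        return float(total)

    order = list(range(len(datasets)))
    log_z_joint = 0.5 * (chain_log_z(order) + chain_log_z(order[::-1]))

    p_iso, p_joint = posterior_model_probs(log_z_iso, log_z_joint, model_prior)
    comparison = ModelComparison(
        p_isolated=p_iso,
        p_joint=p_joint,
        log_marglik_isolated=log_z_iso,
        log_marglik_joint=log_z_joint,
        method="analytic-stationary",
        degenerate=any(f.degenerate for f in iso_fits),
        isolated_posteriors=iso_fits,
    )
    if n_gibbs > 0:
        comparison.method = "gibbs-chain"
        comparison.gibbs_p_isolated = gibbs_model_chain(
            log_z_iso, log_z_joint, n_sweeps=n_gibbs, seed=seed_for(99, 0),
            model_prior=model_prior,
        )
    return comparison


def gibbs_model_chain(
    log_z_iso: float,
    log_z_joint: float,
    n_sweeps: int = 10_000,
    seed: int = 0,
    model_prior: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Frequency of the isolated model in a two-state Gibbs chain.

    Each sweep resamples the model indicator from its full conditional,
    which is proportional to prior times marginal likelihood; the chain's
    stationary distribution is therefore the analytic model posterior.
    Returned for use as a Monte Carlo cross-check of that value.
    """
    p_iso, _ = posterior_model_probs(log_z_iso, log_z_joint, model_prior)
    rng = np.random.default_rng(seed)
    states = rng.uniform(size=n_sweeps) < p_iso
    return float(states.mean())


def auc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve between two score samples.

    The probability that a random positive score exceeds a random negative
    one, counting ties as one half — the normalized rank-sum statistic.
    0.5 means complete overlap, 1.0 perfect separation.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataValidationError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))
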