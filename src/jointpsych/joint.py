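"""Joint inference across conditions by separate sampling.

A parameter believed to be shared across experimental conditions (by
default the width ``w``) is fit jointly without ever sampling the product
parameter space.  Step 1 fits every condition in isolation by SIR and
summarizes the shared parameter's marginal posterior with a Gamma MLE.
Step 2 refits each condition with the *product* of all other conditions'
Gamma summaries as the prior for the shared parameter (non-shared
parameters keep their original priors).  After step 2 every condition's
shared-parameter marginal targets one common posterior, so the second round
implicitly performs inference on all conditions simultaneously.

The product of k Gamma densities is itself proportional to a Gamma:
shapes a_i and rates b_i multiply to Gamma(sum a_i - (k - 1), sum b_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, SamplingError
from .model import BlockDataset
from .sampling import (
    DEFAULT_ESS_FLOOR,
    DEFAULT_N_FINAL,
    DEFAULT_N_PROPOSALS,
    GammaSummary,
    PosteriorSample,
    PriorSpec,
    fit_gamma_summary,
    sir_sample,
)

__all__ = ["JointFitResult", "gamma_product_prior", "joint_fit", "order_sanity_check"]

#: Parameters that may be shared: Gamma summaries need positive support, so
#: the threshold m (which can be negative) is excluded.
SHAREABLE = ("w", "lam")


@dataclass
class JointFitResult:
    """Outcome of the two-round joint inference procedure.

    ``posteriors`` are the second-round per-condition fits; condition i's
    shared-parameter prior (``shared_priors[i]``) is the normalized product
    of the round-1 Gamma summaries of all other conditions.
    """

    posteriors: list[PosteriorSample]
    round1_posteriors: list[PosteriorSample]
    round1_summaries: list[GammaSummary]
    round1_correlations: list[pd.DataFrame]
    shared_priors: list[GammaSummary]
    shared_param_name: str
    order: list[int]
    seed: int


def gamma_product_prior(summaries: list[GammaSummary]) -> GammaSummary:
    """Normalized product of Gamma densities, itself a Gamma.

    For summaries Gamma(a_i, b_i), i = 1..k, the product density is
    proportional to x^(sum a_i - k) exp(-x sum b_i), i.e.
    Gamma(sum a_i - (k - 1), sum b_i).
    """
    if not summaries:
        raise DataValidationError("need at least one Gamma summary")
    names = {s.parameter_name for s in summaries}
    if len(names) != 1:
        raise DataValidationError(
            f"summaries describe different parameters: {sorted(names)}"
        )
    k = len(summaries)
    shape = sum(s.shape for s in summaries) - (k - 1)
    rate = sum(s.rate for s in summaries)
    if shape <= 0:
        raise SamplingError(
            f"product prior has nonpositive shape {shape:.3g}: the individual "
            "marginals are too diffuse to multiply; collect more data or "
            "tighten the round-1 fits"
        )
    return GammaSummary(shape=shape, rate=rate, parameter_name=summaries[0].parameter_name)


def _condition_seeds(seed: int, n: int, round_tag: int) -> list[int]:
    # position-based, so identical datasets at the same position get
    # identical RNG streams regardless of what the other conditions are
    return [
        int(np.random.SeedSequence([seed, round_tag, i]).generate_state(1)[0] % 2**31)
        for i in range(n)
    ]


def joint_fit(
    datasets: list[BlockDataset],
    shared: str = "w",
    *,
    priors: list[PriorSpec] | None = None,
    gamma: float = 0.5,
    n_proposals: int = DEFAULT_N_PROPOSALS,
    n_final: int = DEFAULT_N_FINAL,
    seed: int = 0,
    ess_floor: float = DEFAULT_ESS_FLOOR,
) -> JointFitResult:
    """Two-round joint fit of several conditions with one shared parameter.

    With a single dataset no product prior can be formed: round 2 is
    skipped and the result degenerates to the isolated fit.
    """
    if shared == "m":
        raise DataValidationError(
            "the threshold m can be negative and has no Gamma summary; "
            "reparameterize (e.g. share exp(m)) or share 'w' or 'lam'"
        )
    if shared not in SHAREABLE:
        raise DataValidationError(f"shared parameter must be one of {SHAREABLE}")
    if not datasets:
        raise DataValidationError("need at least one dataset")
    if priors is None:
        priors = [PriorSpec.default(d) for d in datasets]
    if len(priors) != len(datasets):
        raise DataValidationError("one PriorSpec per dataset required")

    n = len(datasets)
    seeds1 = _condition_seeds(seed, n, round_tag=1)
    seeds2 = _condition_seeds(seed, n, round_tag=2)

    round1 = [
        sir_sample(
            d,
            prior=pr,
            n_proposals=n_proposals,
            n_final=n_final,
            seed=s,
            gamma=gamma,
            ess_floor=ess_floor,
        )
        for d, pr, s in zip(datasets, priors, seeds1)
    ]
    summaries = [
        fit_gamma_summary(p.draws[shared].to_numpy(), parameter_name=shared)
        for p in round1
    ]
    correlations = [p.draws[["m", "w", "lam"]].corr() for p in round1]

    if n == 1:
        return JointFitResult(
            posteriors=round1,
            round1_posteriors=round1,
            round1_summaries=summaries,
            round1_correlations=correlations,
            shared_priors=summaries,
            shared_param_name=shared,
            order=[0],
            seed=seed,
        )

    shared_priors = [
        gamma_product_prior([s for j, s in enumerate(summaries) if j != i])
        for i in range(n)
    ]
    round2 = [
        sir_sample(
            d,
            prior=pr.replace(**{shared: sp.to_prior()}),
            n_proposals=n_proposals,
            n_final=n_final,
            seed=s,
            gamma=gamma,
            ess_floor=ess_floor,
        )
        for d, pr, sp, s in zip(datasets, priors, shared_priors, seeds2)
    ]
    return JointFitResult(
        posteriors=round2,
        round1_posteriors=round1,
        round1_summaries=summaries,
        round1_correlations=correlations,
        shared_priors=shared_priors,
        shared_param_name=shared,
        order=list(range(n)),
        seed=seed,
    )


def order_sanity_check(
    datasets: list[BlockDataset],
    shared: str = "w",
    **config,
) -> float:
    """Overlap between shared-parameter marginals obtained in the two orders.

    Theoretically the order of conditions should not matter; a low overlap
    between the joint shared-parameter marginals computed in the two orders
    signals Monte Carlo under-sampling — generate more proposals.
    """
    if len(datasets) != 2:
        raise DataValidationError("order sanity check is pairwise: pass 2 datasets")
    from .diagnostics import OverlapInput, overlap

    priors = config.pop("priors", None)
    fwd = joint_fit(datasets, shared, priors=priors, **config)
    rev_priors = priors[::-1] if priors is not None else None
    rev = joint_fit(datasets[::-1], shared, priors=rev_priors, **config)

    pooled_fwd = np.concatenate([p.draws[shared].to_numpy() for p in fwd.posteriors])
    pooled_rev = np.concatenate([p.draws[shared].to_numpy() for p in rev.posteriors])
    q1a, q3a = np.quantile(pooled_fwd, [0.25, 0.75])
    q1b, q3b = np.quantile(pooled_rev, [0.25, 0.75])
    return overlap(OverlapInput(q1_a=q1a, q3_a=q3a, q1_b=q1b, q3_b=q3b))
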