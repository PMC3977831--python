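"""Synthetic data generation and the two simulation experiments.

Datasets emulate typical psychophysical block designs: six intensity
levels, 20-200 trials per level, binomial counts drawn from a known
generating psychometric function.  Randomly drawn sampling schemes are
rejection-resampled until they cover the lower asymptote, the rising part
and the upper asymptote of the generating function, as one would demand of
a well-designed experiment.

Two sweeps mirror the method's evaluation: a correlation sweep over pairs
of same-generator datasets (robustness of deviance and posterior overlap to
posterior w-lambda correlation, and the overlap gain from joint fitting),
and a delta-w sweep where the two generators differ in width and the model
posterior must detect it (summarized by ROC AUC against the delta-w = 0
reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import deviance, posterior_correlation, posterior_overlap
from .exceptions import DataValidationError, SamplingError
from .joint import joint_fit
from .model import BlockDataset, PsychometricParams, predict
from .model_selection import auc, compare_models

__all__ = [
    "SamplingScheme",
    "DEFAULT_GENERATOR",
    "random_scheme",
    "generate_dataset",
    "correlation_sweep",
    "delta_w_sweep",
]

#: Default generating function on a [0, 1] intensity scale, 2AFC design.
DEFAULT_GENERATOR = PsychometricParams(m=0.5, w=0.2, lam=0.02, gamma=0.5)

N_LEVELS = 6
TRIAL_RANGE = (20, 200)


@dataclass(frozen=True)
class SamplingScheme:
    """Block design: which intensities are tested and with how many trials."""

    intensities: tuple
    trials_per_block: tuple

    def __post_init__(self) -> None:
        if len(self.intensities) != len(self.trials_per_block):
            raise DataValidationError("one trial count per intensity required")
        if any(t < 1 for t in self.trials_per_block):
            raise DataValidationError("every block needs at least one trial")


def scheme_covers(gen: PsychometricParams, intensities) -> bool:
    """True if the intensities hit the lower asymptote, the central rise and
    the upper asymptote of the generating function.

    The asymptote regions are where the curve is within 10% of its span from
    an asymptote; the central rise is strictly between those bands.
    """
    psi = predict(gen, np.asarray(intensities, dtype=float))
    span = 1.0 - gen.gamma - gen.lam
    lo = gen.gamma + 0.1 * span
    hi = 1.0 - gen.lam - 0.1 * span
    return bool(
        np.any(psi < lo) and np.any(psi > hi) and np.any((psi > lo) & (psi < hi))
    )


def random_scheme(
    gen: PsychometricParams,
    rng: np.random.Generator,
    n_levels: int = N_LEVELS,
    trial_range: tuple[int, int] = TRIAL_RANGE,
    x_range: tuple[float, float] | None = None,
    max_tries: int = 1000,
) -> SamplingScheme:
    """Random block design satisfying the coverage requirement.

    Intensities are uniform on ``x_range`` (default m +- 2.5 w) and the
    trial counts uniform integers in ``trial_range``; schemes are redrawn
    until they cover asymptotes and rising part.
    """
    if x_range is None:
        x_range = (gen.m - 2.5 * gen.w, gen.m + 2.5 * gen.w)
    for _ in range(max_tries):
        xs = np.sort(rng.uniform(x_range[0], x_range[1], n_levels))
        if scheme_covers(gen, xs):
            trials = rng.integers(trial_range[0], trial_range[1] + 1, n_levels)
            return SamplingScheme(
                intensities=tuple(float(v) for v in xs),
                trials_per_block=tuple(int(t) for t in trials),
            )
    raise SamplingError(
        f"no covering sampling scheme found in {max_tries} tries; widen x_range"
    )


def generate_dataset(
    gen: PsychometricParams,
    scheme: SamplingScheme | str = "random",
    seed: int = 0,
    condition_id: str = "sim",
) -> BlockDataset:
    """Binomial responses from a known generating psychometric function."""
    rng = np.random.default_rng(seed)
    if isinstance(scheme, str):
        if scheme != "random":
            raise DataValidationError(f"unknown scheme {scheme!r}")
        scheme = random_scheme(gen, rng)
    x = np.asarray(scheme.intensities, dtype=float)
    n = np.asarray(scheme.trials_per_block, dtype=np.int64)
    k = rng.binomial(n, predict(gen, x))
    return BlockDataset(condition_id=condition_id, x=x, k=k, n=n)


def _pair_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % 2**31)


def correlation_sweep(
    n_pairs: int,
    *,
    gen: PsychometricParams = DEFAULT_GENERATOR,
    shared: str = "w",
    n_proposals: int = 5000,
    n_final: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairs of same-generator datasets, fit in isolation and jointly.

    Returns one row per pair with the round-1 posterior w-lambda
    correlations (r1, r2), summed deviance and shared-parameter posterior
    overlap for both the isolated and the joint fits, and the seeds needed
    to regenerate the pair.  By design the joint procedure is legitimate
    here (both members share one generating function).
    """
    records = []
    for i in range(n_pairs):
        s1, s2, sf = (_pair_seed(seed, i, t) for t in (1, 2, 3))
        data = [
            generate_dataset(gen, "random", seed=s1, condition_id="a"),
            generate_dataset(gen, "random", seed=s2, condition_id="b"),
        ]
        fit = joint_fit(
            data,
            shared,
            gamma=gen.gamma,
            n_proposals=n_proposals,
            n_final=n_final,
            seed=sf,
        )
        iso, jnt = fit.round1_posteriors, fit.posteriors
        d_iso = sum(deviance(d, p.mean_params()).total for d, p in zip(data, iso))
        d_jnt = sum(deviance(d, p.mean_params()).total for d, p in zip(data, jnt))
        records.append(
            {
                "pair": i,
                "seed_a": s1,
                "seed_b": s2,
                "seed_fit": sf,
                "r1": posterior_correlation(iso[0], "w", "lam"),
                "r2": posterior_correlation(iso[1], "w", "lam"),
                "d_sum_iso": d_iso,
                "d_sum_joint": d_jnt,
                "overlap_iso": posterior_overlap(iso[0], iso[1], shared),
                "overlap_joint": posterior_overlap(jnt[0], jnt[1], shared),
                "p_isolated": np.nan,
                "delta_w": 0.0,
                "total_trials": data[0].total_trials + data[1].total_trials,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "pair", "seed_a", "seed_b", "seed_fit", "r1", "r2",
            "d_sum_iso", "d_sum_joint", "overlap_iso", "overlap_joint",
            "p_isolated", "delta_w", "total_trials",
        ],
    )


def delta_w_sweep(
    delta_w_grid,
    n_pairs_per_delta: int,
    *,
    gen: PsychometricParams = DEFAULT_GENERATOR,
    shared: str = "w",
    corr_filter: float = 0.5,
    n_proposals: int = 5000,
    n_final: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Model-selection sensitivity to a true width difference delta-w.

    For each grid value, pairs are generated where the second member's
    width is ``gen.w + delta_w``; the posterior probability of the isolated
    models is recorded per pair.  Pairs whose round-1 posterior w-lambda
    correlation magnitude reaches ``corr_filter`` in either member are kept
    in the table but excluded (``selected = False``) from the AUC, which
    compares each delta-w > 0 score distribution against the delta-w = 0
    reference.  The grid must contain 0.
    """
    grid = [float(d) for d in delta_w_grid]
    if 0.0 not in grid:
        raise DataValidationError("delta_w grid must include 0 as the reference")
    records = []
    for gi, delta in enumerate(grid):
        gen2 = PsychometricParams(
            m=gen.m, w=gen.w + delta, lam=gen.lam, gamma=gen.gamma
        )
        for i in range(n_pairs_per_delta):
            s1, s2, sf = (_pair_seed(seed, gi, i, t) for t in (1, 2, 3))
            data = [
                generate_dataset(gen, "random", seed=s1, condition_id="a"),
                generate_dataset(gen2, "random", seed=s2, condition_id="b"),
            ]
            comp = compare_models(
                data,
                shared,
                gamma=gen.gamma,
                n_proposals=n_proposals,
                n_final=n_final,
                seed=sf,
            )
            r1, r2 = (
                posterior_correlation(p, "w", "lam")
                for p in comp.isolated_posteriors
            )
            records.append(
                {
                    "pair": i,
                    "seed_a": s1,
                    "seed_b": s2,
                    "seed_fit": sf,
                    "r1": r1,
                    "r2": r2,
                    "p_isolated": comp.p_isolated,
                    "delta_w": delta,
                    "selected": max(abs(r1), abs(r2)) < corr_filter,
                    "total_trials": data[0].total_trials + data[1].total_trials,
                }
            )
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "pair", "seed_a", "seed_b", "seed_fit", "r1", "r2",
            "p_isolated", "delta_w", "selected", "total_trials",
        ],
    )
    aucs: dict[float, float] = {}
    if len(table):
        ref = table[(table.delta_w == 0.0) & table.selected].p_isolated
        for delta in grid:
            if delta == 0.0:
                continue
            pos = table[(table.delta_w == delta) & table.selected].p_isolated
            if len(pos) and len(ref):
                aucs[delta] = auc(pos, ref)
    return table, aucs
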