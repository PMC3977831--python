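# Methods

## Model

One experimental condition consists of blocks (x, k, n): at stimulus
intensity x, k of n trials were answered correctly.  Counts are binomial
with success probability

Ψ(x) = γ + (1 − γ − λ) F(x; m, w),  F(x; m, w) = 1 / (1 + exp(−z (x − m)/w)),
z = 2 ln 9.

The scale constant z makes w the exact 10–90% rise interval:
F(m ± w/2) = 0.9 / 0.1, so Ψ(m − w/2) − γ = 0.1 (1 − γ − λ) and
(1 − λ) − Ψ(m + w/2) = 0.1 (1 − γ − λ).  The guess rate γ is fixed by the
experimental design (0.5 for two-alternative forced choice, the default
throughout) and is not estimated; estimating the lapse rate λ, although a
nuisance parameter, protects m and w from asymptote-driven bias.  The
logistic family is one of several sigmoids satisfying these constraints;
it is the conventional choice and the code keeps it behind a single
function (`model.psi_grid`) should another family be needed.  Intensities
are used exactly as given in the input; users who prefer a log-contrast
axis transform before writing the CSV.

## Posterior sampling

Each condition is fit by sampling-importance-resampling with proposals
drawn from the prior: n_proposals parameter vectors are sampled from the
prior, each receives an importance weight equal to its likelihood, and
n_final draws are resampled with replacement proportionally to the
weights.  Defaults are n_proposals = 25 000 and n_final = 2 000.  Prior
proposals are the simplest SIR variant and have a useful by-product: the
mean proposal likelihood is a consistent estimator of the marginal
likelihood p(D), which model selection consumes directly.

Priors default to weakly informative forms anchored on the tested
intensity range [x_min, x_max] with span s:

- m ~ Normal(midrange, sd = s) — the threshold is somewhere near the
  tested range;
- w ~ Gamma(shape 2, rate 4/s), mean s/2 — widths comparable to the
  tested range;
- λ ~ Beta(2, 20) truncated to [0, 0.1] — lapses are rare; sampling is by
  inverse CDF on the truncated support.

The effective sample size 1/Σ(normalized wᵢ²) is recorded; below the
configured floor (default 50) the fit is flagged degenerate and a warning
raised — typical well-sampled conditions at the default proposal count
land near or above this floor, so the flag marks fits whose quartiles
should not be trusted rather than merely noisy ones.  All randomness
derives from explicit integer seeds; nested routines derive per-condition
streams via `numpy.random.SeedSequence([master, round, index])`, keyed by
position so that reruns and order swaps are exactly reproducible.

## Gamma summaries and the product prior

Marginal posteriors of positive parameters are summarized by
maximum-likelihood Gamma fits.  The shape solves
log a − ψ(a) = log(mean) − mean(log x) by Newton iteration (tolerance
1e-8 relative, moment-matching start via the standard closed-form
approximation); the rate is a/mean, so the fitted mean equals the sample
mean by construction.  Degenerate inputs (fewer than 10 draws,
non-positive values, relative sd below 1e-8) raise.

The normalized product of k Gamma densities Gamma(aᵢ, bᵢ) is
Gamma(Σaᵢ − (k − 1), Σbᵢ); a nonpositive product shape (only possible
when the component shapes are below 1, i.e. the marginals pile up at
zero) raises with a diagnostic.  The joint fit gives condition i the
product over all j ≠ i as its shared-parameter prior, computed once from
the round-1 summaries.  Parametric summaries rather than kernel density
estimates carry the cross-condition information because the Gamma product
has this closed form and the multiplication is exact.

Only positive-support parameters (w, λ) may be shared; sharing m is
rejected with an error suggesting reparameterization, since a location
parameter with possibly negative support has no Gamma summary.

## Joint fit and its sanity check

Round 1 fits every condition in isolation and records, besides the
summaries, the posterior correlation matrix of (m, w, λ) — the method
assumes a-posteriori independence of the parameters, and the recorded
correlations let the user check rather than assume it.  Round 2 refits
each condition with the product prior on the shared parameter.  The order
of conditions should not matter in theory; `order_sanity_check` fits a
pair in both orders and reports the overlap statistic between the pooled
shared-parameter draws of the two runs.  Values well below 1 signal Monte
Carlo under-sampling: raise n_proposals/n_final.

## Diagnostics

Deviance of one condition, with p the model prediction per block:

D = 2 Σᵢ [kᵢ ln(kᵢ/(nᵢpᵢ)) + (nᵢ−kᵢ) ln((nᵢ−kᵢ)/(nᵢ(1−pᵢ)))]

with the 0·ln 0 = 0 convention for boundary blocks (implemented via
`scipy.special.xlogy`).  A prediction of exactly 0 or 1 contradicted by
the counts yields infinite deviance, flagged rather than raised.  Signed
residuals carry sign(k/n − p) and square-sum to D; deviance is additive
over blocks and conditions, and multi-condition fits are compared by the
summed deviance.  Sweep records evaluate deviance at the posterior-mean
parameter vector.

The overlap statistic between two distributions uses only their first and
third quartiles:

q = (min(Q3ᵃ, Q3ᵇ) − max(Q1ᵃ, Q1ᵇ)) / (max(Q3ᵃ, Q3ᵇ) − min(Q1ᵃ, Q1ᵇ)).

It is 1 iff the quartile pairs coincide, positive for partial overlap, 0
when one interquartile range starts where the other ends, and decreases
toward −1 as fixed-width distributions separate; it is symmetric and
invariant under common affine rescaling, and deliberately ignores tails
(robustness is the reason this statistic is used instead of
KL-divergence).  Sample quartiles use linear interpolation of order
statistics (numpy's default, the "type 7" convention).  When all four
quartiles coincide exactly the 0/0 form is defined as 1.

## Model selection

The model indicator ("isolated" vs "joint") is treated as a parameter
with a flat prior by default, making the posterior model probability a
Bayes-factor decision.  Z_iso is the product over conditions of the SIR
marginal-likelihood estimates under the original priors.  Z_joint uses
the factorization of the joint marginal likelihood into a chain: the
first condition's marginal likelihood under its original priors times
each subsequent condition's marginal likelihood under the Gamma summary
of the accumulated shared-parameter posterior.  Because the Monte Carlo
estimate (unlike the exact quantity) depends on the chain order, log
Z_joint is the average over the forward and reversed condition orders.
The two-state Gibbs chain (`gibbs_model_chain`) resamples the indicator
from its full conditional — proportional to prior × marginal likelihood —
so its stationary indicator frequency is the analytic value; it is
exposed as a Monte Carlo cross-check, not the primary route.

## Synthetic data

The generator emulates typical psychophysical block designs: 6 intensity
levels, 20–200 trials per level, binomial counts from a known generating
function, default (m = 0.5, w = 0.2, λ = 0.02, γ = 0.5) on a [0, 1]
intensity scale.  Random schemes draw intensities uniformly on m ± 2.5 w
and are rejection-resampled until they cover the lower asymptote, the
central rise and the upper asymptote (membership bands at 10% of the span
from each asymptote), as one would demand of a well-designed experiment;
an unattainable coverage raises after a retry cap.

What the generator does not emulate: sequential dependencies between
trials, observer learning or fatigue drifts, non-stationary lapsing, and
adaptive (staircase) placement of intensities.  Passing simulation tests
therefore demonstrates correctness of the inference machinery under the
stated binomial model, not robustness to those real-data violations.

Two experiments are provided.  The correlation sweep draws pairs of
same-generator datasets (so the joint procedure is legitimate by design),
fits both ways, and records summed deviance, shared-parameter overlap and
the posterior w–λ correlations; across such a sweep deviance and overlap
show no monotone trend in the correlation magnitude, while the overlap
distribution shifts right after joint fitting at essentially unchanged
deviance.  The width-difference sweep generates pairs whose generating
widths differ by Δw, runs model selection, and scores separability of
each Δw > 0 score distribution from the Δw = 0 reference by ROC AUC.
Pairs in which either member's posterior |corr(w, λ)| reaches 0.5 are
excluded from the AUC (kept in the table, marked unselected): large
correlations only arise when the function is poorly constrained by the
scheme, and such datasets would not be tolerated in a real experiment.
The 0.5 cut-off is a configurable default.

## Problem sizes and numerical choices

Sweeps default to reduced sampler sizes (n_proposals = 5 000,
n_final = 500) so that a 100-pair experiment completes in seconds; the
single-fit defaults stay at 25 000 / 2 000.  Per-replicate comparisons
(e.g. whether one pair's joint overlap exceeds its isolated overlap) are
noticeably noisier at reduced sizes than at the defaults, which is why
the replicate-level tests run at the default sizes while the
median-level sweep assertions use the reduced ones.  Other choices:
resampling is with replacement; ties in the AUC count one half; the Δw
grid in examples is {0, 0.5 w, 1.0 w}; the model prior is flat unless
configured otherwise.

## Limitations

- The shared parameter must have positive support; sharing the threshold
  requires a reparameterization the package intentionally does not guess.
- The Gamma summary is an approximation to the marginal posterior; when
  the marginal is strongly multimodal the product prior can misrepresent
  it (the order sanity check will typically reveal this as disagreement).
- Prior-proposal SIR degrades as data volume grows (the likelihood
  concentrates relative to the prior); the ESS flag warns, and very large
  datasets would need more proposals.
- With only two models compared, model selection cannot express "neither
  describes the data"; inspect deviance residuals alongside.
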