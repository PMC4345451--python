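# Methods

## Model

`multinbda` implements the continuous time-of-acquisition variant of
network-based diffusion analysis, extended to multiple co-indexed network
layers. Acquisition of the target behaviour is a competing-risks point
process: a naive individual *i* acquires at hazard

    lam_i(t) = lambda0(t) * (1 - z_i(t)) * f(S_i(t), A_i)
    S_i(t)   = sum_k s_k * sum_j a_ijk * z_j(t) * T_ij

with `f(S, A) = S + A` in additive covariate models and `f(S, A) =
A * (S + 1)` in multiplicative ones (`A_i = 1` without covariates). The
assumptions are those standard to this family of models:

* association strength `a_ijk` is proportional to the opportunity for *j*
  to transmit to *i* along relationship type *k*; networks are static over
  a trial;
* transmission events from distinct informed associates are independent and
  their hazards add;
* the informed state is absorbing (`lam_i = 0` once informed) and
  observed exactly at first arrival;
* trials are independent given shared parameters; individuals never seen to
  arrive are right-censored at the trial horizon.

Because `z(t)` is a step function of the arrival times, the hazard is
constant in state between consecutive arrivals and the log-likelihood has
the closed piecewise form

    ll = sum_events log lam_acquirer(t_e-)  -  sum_i  int_0^min(t_i, T) lam_i(u) du

where each integral piece is `lambda0 * coef * (t2 - t1)` for the constant
baseline and `lambda0 * coef * (t2^kappa - t1^kappa)` for the Weibull one.
The informed set at an event time uses strictly earlier arrivals (the left
limit), so exactly coincident arrivals cannot excite each other; genuine
near-simultaneity is handled by the tie mask instead.

### Tie masking

Pairs of individuals whose arrivals fall within the tie window (default
600 s) are taken to be co-discoveries: their mutual social terms are
zeroed (`T_ij = 0`) while both keep their recorded arrival times in the
event and survival terms. Ties are pairwise, never chained transitively,
and a censored individual is never tied. Setting `use_ties = False`
restores `T = 1` everywhere. The mask is an estimation-side conservatism —
it deliberately reclassifies fast follow-on arrivals as asocial — and is
therefore switched off when fitting data simulated from the bare hazard,
where fast co-arrivals are genuinely social (with the mask on, transmission
rates recover ~30% low in such simulations).

### Seeded demonstrators

A trial may declare demonstrators: individuals informed from `t = 0` that
are excluded from the risk set and contribute no event or survival term but
do transmit. The simulator uses the same mechanism for pure-transmission
experiments; by default innovators instead arise from the asocial rate.

## Parameters

| parameter | meaning | domain | default / convention |
|---|---|---|---|
| `lambda0` | baseline discovery rate | > 0, per second | fitted; start = events / exposure |
| `kappa` | Weibull shape (baseline trend) | > 0 | 1 = constant; fitted when `baseline: weibull` |
| `s_k` | transmission rate per unit connection in layer *k*, relative to baseline | >= 0, dimensionless | fitted; start = 1 |
| `beta_v` | log rate ratio per covariate unit | real | fitted; start = 0 |
| tie window | co-discovery horizon | >= 0 s | 600 s |
| sampling block | co-occurrence window for networks | s | 15 s |
| CI level | profile interval coverage | (0,1) | 0.95 |

Categorical covariates are dummy-coded against a declared reference level
(alphabetically first by default); the residency covariate (`n_obs`) is
standardized using whole-table statistics so encodings agree across sites —
raw entry is available via the `standardize` argument. The site indicator
is an ordinary covariate, so in additive models it scales the asocial rate
only and in multiplicative models the whole rate.

## Fitting and inference

Positive parameters are optimised on the log scale (an unconstrained
problem); L-BFGS-B with numerical gradients runs from a deterministic
start plus seeded perturbations (5 starts by default, sub-seeds derived
from one user seed), and the winner is polished with Nelder-Mead, which is
robust on the flat ridges that arise when layers are strongly correlated.
Non-finite objective values are clamped so the optimiser backtracks rather
than aborts; non-convergence is reported on the result, never silently.

AICc uses `n` = total acquisition events across trials as the sample size:
events are the units carrying likelihood information (censored individuals
contribute only survival mass). Akaike weights are computed with the usual
min-AICc shift; models with non-finite AICc are excluded with a warning.
Model-averaged estimates come in both conventions — conditional
(renormalised over models containing the parameter) and full (absent
models count 0) — and both are returned.

Hypothesis support sums weights over the six transmission classes
(different rates, same rate, each single-layer-only, homogeneous network,
asocial). Note that summed support depends on how many candidate models
fall in each class: with five social classes against one asocial class,
asocial data still leaves most summed weight on social models. Null-support
checks therefore use the minimal balanced pair (asocial vs. one shared
rate); the full grid is appropriate when the data are informative enough to
concentrate weight, which is also the regime the method is meant for.

Confidence intervals are profile-likelihood intervals: the target parameter
is fixed on a bracket expanded geometrically from the MLE, nuisance
parameters are re-optimised at each point (warm-started from the MLE), and
the crossing of `chi2_1(level)/2` (1.9207 at 95%) below the maximum is
found by Brent bisection (`xtol = 1e-6`). Rate parameters are clipped at 0
with an explicit boundary flag when the profile never crosses there; an end
that stays above the threshold within the search range is flagged open.
The difference of two transmission rates is profiled by reparameterising
`s_a = s_b + d` with `d` fixed and `s_b` constrained to keep both rates
non-negative.

### Social/asocial decomposition

For each acquisition event, the probability that it was social via layer
*k* is that layer's share of the acquirer's total hazard at the event time
(`s_k W_k / (S + A)` additively, `s_k W_k / (S + 1)` multiplicatively —
the baseline factor cancels). The asocial share is the remainder; the
first discoverer of a trial has no informed associates and is asocial by
construction. Shares are averaged over events overall, per layer and per
acquirer species, and respect the same tie mask as the likelihood.

## Simulator

Diffusions are drawn exactly from the model hazard. All individuals share
the baseline time factor, so between state changes the aggregate cumulative
hazard inverts in closed form: draw `E ~ Exp(1)`, solve
`lambda0 * total_coef * (t2^kappa - t1^kappa) = E` for the next event time,
pick the acquirer proportionally to its rate coefficient, update the
informed set, repeat until the horizon. This is exact for both baselines —
no discretisation and no thinning — and `kappa = 1` reproduces the
constant-baseline draw bit-for-bit. Per-trial RNG sub-streams derive
deterministically from the root seed. The generative process does not use
the tie mask; co-arrivals (and hence ties) occur naturally.

The default study conditions mirror a two-species winter-flock experiment:
30 individuals per site, two layers (conspecific/heterospecific) with
Bernoulli edges (p = 0.4 within, 0.3 between) and Beta-distributed weights
(Beta(2,4) within, Beta(2,6) between, so conspecific ties are stronger on
average), 3-day trials with censoring at the horizon, transmission rates
22.2 (within) and 12.5 (between) relative to baseline, and
`lambda0 = 4.5e-7 /s`, which forward-simulates to ~60% of individuals
acquiring per trial under those rates.

The observation-stream generator emulates RFID feeder logs: per sampling
period each individual attends one of `L` feeders, preferring its species'
home feeder with probability `a + (1-a)/L` (assortment knob `a`). The
analytic dyadic probability of sharing a feeder is returned with the
stream, giving an exact oracle for the SRI estimator. What it does *not*
emulate: temporal autocorrelation of flock membership, within-flock arrival
order, detection failure beyond independent attendance, or drifting group
composition — so SRI tests validate the estimator's counting logic and
consistency, not robustness to those field realities.

## Networks

Gathering events are defined by exact (location, time block) equality —
appropriate for coarse logger blocks; no burst detection is attempted. SRI
is counted block-wise per dyad: together `x`, A alone `yA`, B alone `yB`,
or both present in different simultaneous events `yAB`, giving
`x / (x + yA + yB + yAB)` with an empty denominator mapping to 0 (never
NaN). Metrics report mean weighted degree normalised by `(n-1)` (so a
clique of unit edges scores 1), binary edge density, degree assortativity
as the Pearson correlation of endpoint degrees over directed edges of the
thresholded (w > 0) graph — with a weighted-strength variant reported
alongside, since "degree" is ambiguous for weighted graphs — and
eigenvector centrality as the dominant eigenvector of the weight matrix
scaled to a maximum of 1. Assortativity on degenerate graphs (zero degree
variance, fewer than two edges) is flagged undefined rather than NaN.

## Numerical choices and degenerate inputs

* Optimiser vector entries above 700 (log scale) are rejected before
  exponentiation to avoid overflow.
* Exact arithmetic identities (AICc, weights, averaging) hold to 1e-12
  relative; likelihood reductions (`s = 0` survival form, `kappa = 1`,
  homogeneous = all-ones layer, duplicated-layer ridge) hold to 1e-10 or
  bit-for-bit; the closed-form likelihood matches adaptive quadrature of
  the same hazard to well under 1e-6 on random instances.
* Empty trials (`t_end = 0`, no arrivals) contribute exactly 0; a zero
  baseline with no demonstrators yields an empty simulated diffusion with a
  warning.
* Arrival floats are written with `repr` precision and parsed in
  round-trip mode, so CSV round trips are lossless.

## Test problem sizes

Validation simulations use 8 trials x 30 nodes per replicate (10
replicates for recovery/coverage, with profile intervals per replicate),
50 random <=5-node instances for the quadrature cross-check, 2000+ pooled
arrivals for the exponential-distribution check, and 1000 sampling periods
for SRI consistency. These sizes make per-replicate transmission-rate MLEs
noticeably noisy (a heavy right tail is intrinsic at ~150 events), which is
why recovery is judged on the across-replicate mean and interval coverage
rather than per-replicate error.

## Known limitations

* Networks are static within and across trials; no time-varying or
  bipartite structures.
* Only the order/timing variant with continuous arrival times is
  implemented (no order-of-acquisition likelihood, no latent informed
  states, no random effects, no Bayesian inference).
* The non-constant baseline is a Weibull hazard — a deliberate one-
  parameter family covering monotone rise and fall; other shapes (e.g.
  bathtub) are out of scope.
* Profile intervals assume the usual chi-square calibration; at hard
  parameter boundaries they are clipped and flagged rather than corrected.
* The tie mask is a conservative device for field co-discoveries; it
  biases transmission rates downward when applied to data whose fast
  co-arrivals are genuinely social.
EOF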