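# multinbda

Multi-network network-based diffusion analysis (NBDA) for co-observation
data: who learned what from whom, and along which kind of social tie?

Animal populations are often structured by several kinds of relationship at
once — for example conspecific and heterospecific associations in
mixed-species foraging flocks. When a behavioural innovation (say, the
location of a new food patch) spreads through such a population, a single
social network cannot tell whether transmission used one type of tie more
than another. `multinbda` builds layered association networks from
visit/co-observation logs and fits a continuous time-of-acquisition
diffusion model in which **each network layer carries its own social
transmission rate**, so the contribution of each relationship type can be
estimated, compared and model-averaged.

## The model

The hazard with which a naive individual *i* acquires the behaviour at time
*t* is

```
lam_i(t) = lambda0(t) * (1 - z_i(t)) * [ sum_k s_k * sum_j a_ijk * z_j(t) * T_ij  +  A_i ]
```

* `lambda0(t)` — baseline (asocial) discovery rate, constant or a Weibull
  hazard `lambda0 * kappa * t^(kappa-1)` that rises or falls over a trial;
* `z_j(t)` — informed status of associate *j* (0 naive, 1 informed);
* `a_ijk` — association strength between *i* and *j* in network layer *k*
  (the simple ratio index, SRI, estimated from co-occurrence at feeders);
* `s_k` — social transmission rate per unit of connection in layer *k*,
  relative to the baseline rate;
* `T_ij` — tie mask: pairs arriving within a 10-min window are treated as
  co-discoveries and excluded from the social term;
* `A_i = exp(sum_v beta_v V_vi)` — individual covariates (species, site,
  residency), entering the asocial term only (*additive* models, shown
  above) or scaling the whole rate (*multiplicative* models).

The total log-likelihood sums independent diffusion trials, with per-trial
networks and right-censoring at each trial horizon. Candidate models —
different rates per layer, equal rates, single-layer-only, homogeneous
mixing, purely asocial; each additive or multiplicative, constant or
Weibull baseline — are compared by AICc, Akaike weights and summed
hypothesis support, with profile-likelihood confidence intervals (including
for the *difference* of two transmission rates). A per-event decomposition
estimates the share of discoveries attributable to each layer versus
asocial learning. An exact event-driven simulator generates diffusions from
the same hazard for validation.

## Worked example

Simulate eight diffusions on a 30-bird, two-species population (two network
layers, 3-day trials), then refit the generative model:

```console
$ multinbda simulate --config sim.yaml --seed 7 --out-dir data
simulated 8 diffusions (174 acquisitions) in data

$ multinbda fit --config fit.yaml \
    --networks data/networks_manifest.csv \
    --diffusions data/diffusions.csv --trials data/trials.csv \
    --covariates data/covariates.csv --seed 1 --out results.json
loglik=-2178.8939 aicc=4363.9289 -> results.json

$ multinbda profile-ci --config fit.yaml \
    --networks data/networks_manifest.csv \
    --diffusions data/diffusions.csv --trials data/trials.csv \
    --param s_intra --seed 1
s_intra: mle=29.2157 95% CI [16.0941, 58.345]
```

with `sim.yaml` declaring the generative truth (`s: {intra: 22.2, inter:
12.5}`, `lambda0: 4.5e-7`) and `fit.yaml` selecting the two-rate model
(`layer_constraint: free`). The fit recovers `s_intra = 29.2` and `s_inter
= 13.8` from 174 acquisition events — transmission per unit of conspecific
connection runs ~29x the baseline discovery rate, and the generative values
lie inside the profile intervals. `results.json` also reports the event
decomposition: here 90% of discoveries were social (67 points via the
conspecific layer, 22 via the heterospecific layer). Estimates this far
from truth on a single replicate are expected at this sample size; the
sampling distribution tightens with more trials.

The same subcommands operate on field data: `build-network` turns a visit
log (`id,location,time_block` or ISO timestamps) into an SRI adjacency
matrix, `split-network` separates it into within- and between-category
layers, `netstats` reports weighted degree, density, degree assortativity
and eigenvector centrality, and `model-select` fits the whole candidate
grid and writes AICc and hypothesis-support tables.

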