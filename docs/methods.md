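# Methods

## Model

A food web is a directed, binary, loop-free graph on `n` species; an arc
`i -> j` means prey `i` is eaten by predator `j` (the arrow follows energy
transfer).  The package models the whole web with an exponential random
graph model (ERGM)

    P(G) = exp( sum_s theta_s * z_s(G) ) / c ,

where each sufficient statistic `z_s` counts (or geometrically weights) one
configuration — a small subgraph pattern read as the footprint of a
micro-level trophic process — and `c` is a normalising constant over all
2^(n(n-1)) digraphs that is never computed.  The modelled catalogue uses the
"alternating" (geometrically weighted) forms built from

    g_lambda(d) = lambda * (1 - (1 - 1/lambda)^d) ,

which is increasing and concave in the count `d`: additional prey, predators
or shared partners matter less the more a species already has.  This damping
is what keeps star- and triangle-driven ERGMs away from the degenerate
regime in which probability mass collapses onto near-empty or near-complete
graphs.

Catalogue (directions under prey -> predator orientation):

| statistic | pattern | trophic reading |
|---|---|---|
| `arc` | single arc | baseline tie propensity (density control) |
| `reciprocity` | mutual dyad | mutual predation |
| `generalist` | alternating in-star | predators with many prey |
| `highly_predated` | alternating out-star | prey with many predators |
| `keystone` | mixed alternating star, `sum_v g(d_in) g(d_out)` | species with many prey **and** many predators |
| `tri_trophic` | alternating two-path (ordered pairs) | food chains of length two |
| `apparent_competition` | alternating common-sink (unordered pairs) | two prey sharing a predator |
| `exploitative_competition` | alternating common-source (unordered pairs) | two predators sharing a prey |
| `omnivory` | alternating transitive triangle | chain plus the direct shortcut |
| `cyclic_triangle` | alternating cyclic triangle | three-species feeding loop |

Raw counterparts (k-in/out-stars for k = 2, 3, two-paths, transitive and
cyclic triangles), the 13 connected triad classes, and the in-/out-degree
standard deviations are registered as descriptive statistics for goodness of
fit only.

Mixed two-paths are summed over **ordered** pairs (chain direction matters);
common-sink/common-source statistics over **unordered** pairs (competition
is symmetric).  The `keystone` statistic is formalised as the product-form
mixed star above; the catalogue is a registry, so an alternative
operationalisation can be added without touching the estimator.

### lambda

`lambda` defaults to 2.0 for every alternating statistic — the conventional
default in the ERGM literature — and is a configuration setting, not an
estimated (curved-ERGM) parameter.  As `lambda -> infinity` each alternating
star converges to the corresponding raw 2-star count (verified numerically
in the tests).

## Change statistics and sampling

Everything rests on the change statistic
`delta_s(G, i, j) = z_s(G + ij) - z_s(G - ij)`.  Closed-form local
expressions are implemented for all modelled statistics (numpy reference in
`config_statistics`, compiled duplicate in `_kernels`); the compiled chain
additionally maintains the two-path, common-sink and common-source pair
matrices incrementally so a proposal costs O(n).  Both routes are tested
against brute-force recomputation of both graph variants, exactly.

Simulation is single-arc-toggle Metropolis-Hastings: a uniform ordered dyad
is proposed and toggled with probability `min(1, exp(+/- theta . delta))`.
Burn-in and thinning default to 50 n^2 and 10 n^2 proposals.  Detailed
balance is verified on n = 3 by comparing a long chain against the exactly
enumerated distribution (total variation < 0.02).  A chain pinned at density
0 or 1 for more than 90% of retained samples raises a degeneracy warning,
not an error, so the estimator can observe and react.

**Mixing caveat.** Statistics combinations that are nearly collinear (the
alternating stars track the arc count closely) relax over ~10^5-10^6
proposals at n = 30 — far slower than the raw statistics' integrated
autocorrelation (~1.4 x 10^3 proposals).  Ensemble means therefore carry a
slowly-decaying noise component; all precision-critical defaults below are
sized against that slow mode, not the fast one.

## Estimation

`fit_ergm` solves the moment equation `E_theta[z] = z(G_obs)` (the MLE
condition of an exponential family) by stochastic approximation:

1. **Phase 1** simulates at the starting value (arc at logit(density),
   everything else 0 — exact for the Bernoulli sub-model) and estimates the
   statistic covariance, the Fisher information.  The scaling matrix is
   regularised as `0.9 cov + 0.1 diag(cov)`; a purely diagonal scaling
   conditions the updates badly here because the alternating statistics are
   strongly correlated with the arc count, and in testing left moment
   residuals of 0.5-1.5 sd.
2. **Phase 2** runs Robbins-Monro subphases of lengths (2, 4, 8, 16) x p
   with gain halving from 0.1, replacing theta by its subphase average
   (Polyak averaging) at each subphase end.  The chain advances 2 n^2
   proposals between updates and is never restarted.
3. **Newton polish**: a fixed number (default 2) of Newton steps on the
   moment equation, each using a fresh phase-3-style ensemble of growing
   size.  The fixed count matters: stopping as soon as the *measured*
   max |t| drops below threshold is optimistically biased — it halts on
   downward noise fluctuations and leaves true residuals well above the
   threshold, which surfaced as systematic goodness-of-fit failures.
4. **Phase 3** draws the final ensemble (default 1000 networks, thinning
   5 n^2) and reports convergence t-ratios
   `t_s = (mean z_s - z_obs,s) / sd z_s`, standard errors from the inverse
   statistic covariance, and the convergence flag `max |t| <= 0.1` (the
   PNet-family convention).  Up to 3 further Newton restarts run only on
   non-convergence.

A parameter is flagged significant when `|estimate| >= 2 SE`, matching the
estimate-versus-standard-error presentation convention.  Pseudo-likelihood
is not used anywhere, not even as a warm start.

On webs of at most 4 species `exact_fit_small` maximises the exactly
enumerated likelihood (BFGS with analytic gradient, gradient norm <= 1e-9 at
the optimum).  Observed statistics on the boundary of the attainable range
make the MLE diverge; the estimate is then capped at +/-20 with a warning.
The stochastic fit is required (and tested) to match the exact MLE within
0.05 per parameter on interior n = 3 webs; note that on 3 nodes most
{arc, reciprocity} statistic pairs are extreme points of the attainable
set — (L, R) = (3, 1) is the interior case used.

## Goodness of fit

`goodness_of_fit` simulates an ensemble at the fitted theta, evaluates a
32-statistic suite on every sampled network and on the observed web, and
reports the heuristic t-ratio per statistic.  The fit passes when every
modelled statistic has |t| <= 0.1 and every non-modelled statistic with a
defined t has |t| < 2.  The suite size is fixed at 32; the shipped
membership is 10 modelled-catalogue statistics + 7 raw counts + 13 connected
triad classes + 2 degree-spread statistics, and callers can substitute their
own list wholesale.

**Calibration caveat.** The pass rule is a multiple-comparisons screen over
~30 statistics, several of which (rare triad classes) are small discrete
counts with heavy-tailed t-ratios.  Measured on webs simulated *from the
fitted model itself* at n = 30, the per-web pass probability is about
0.7-0.8, not 1: roughly one correct-model web in five shows some rare-triad
|t| >= 2, and modelled statistics re-measured on an independent ensemble
occasionally exceed 0.1 by Monte-Carlo noise.  Users should read a single
failure of a rare-count statistic as a prompt to look at that statistic, not
as refutation of the model.

## Regime comparison

`compare_fits` reports, per shared configuration,
`100 * (theta_after - theta_before) / |theta_before|` — the signed change
relative to the magnitude of the earlier estimate (undefined at
theta_before = 0, flagged).  Swapping the fits changes the baseline, so the
percentage is *not* antisymmetric (a -0.5 -> -0.4 move is +20%; the reverse
is -25%).  Configurations present in only one fit are listed separately.
Fits whose metadata carry different `region` values are refused by default:
parameter magnitudes are only comparable within one system.

## Synthetic data

`niche_model_web` implements the classic niche model: species get niche
values in [0, 1]; species `i` consumes every species whose value falls in an
interval of width `x * n_i`, `x ~ Beta(1, 1/(2C) - 1)` (mean 2C), centred
below `n_i`.  This produces the triangular trophic structure of real webs
(many basal species, few top consumers) at expected connectance `C = L/n^2`;
the default C = 0.2 at n = 30 matches the scale of a ~30-species
brackish-sea web.  Cannibalistic self-links are deleted, not redrawn.  Niche
webs have strongly nested diets and are deliberately *not* ERGM draws — they
serve as structured, misspecified targets.  The frozen fixture
`baltic_like_30` (30 species, 180 arcs) is one committed niche-model draw,
so numbers attached to it are stable; it is synthetic, not a transcription
of any empirical web.

`simulate_study` draws replicate webs from a known (theta, spec) with
independent sub-seeds.  Study webs are equilibrated for 600 n^2 proposals —
an order of magnitude past the slow statistic mode — so replicates are
genuine equilibrium draws.

What passing the synthetic suites does and does not show: recovery and
self-consistency results demonstrate internal statistical correctness of the
estimator and GoF machinery under the model's own data-generating process at
the study scale (n = 30, connectance ~0.1-0.2).  They say nothing about
empirical adequacy of any particular configuration set for a real web, about
webs an order of magnitude larger, or about data with observation error in
the links (not modelled here).

## Problem sizes and reproducibility

All randomness flows from integer seeds through `numpy.random.SeedSequence`
(the pipeline derives per-stage sub-seeds as
`SeedSequence([seed, stage, index])`); fits, ensembles and reports are
deterministic given settings and seed.  The shipped experiment sizes — 50
replicate fits for recovery calibration and 20 (tests) / 12 (acceptance
script) self-consistency runs, phase-3 ensembles of 600-20000 networks —
were chosen so each suite completes in minutes on one core while keeping
Monte-Carlo noise on every asserted quantity several times smaller than its
tolerance, except where the calibration caveat above applies.

## Known limitations

- Binary, static webs only: no link weights, ontogenetic stages, node
  covariates, or dynamics; no curved-ERGM estimation of lambda.
- Single-toggle MH only (no tie/no-tie or tempered samplers); near-collinear
  statistic combinations mix slowly, which sets the practical precision of
  convergence t-ratios.
- The GoF pass rule is a screen, not a calibrated test (see above).
- `exact_fit_small` enumerates 2^(n(n-1)) graphs and is limited to n <= 4.
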