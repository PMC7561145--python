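# Methods

This note documents the statistical models implemented in `gulldiet`, the
defaults and why, the synthetic-data model and its limits, and the numerical
choices a maintainer would want to know.

## Diet bookkeeping

A pellet is a vector of six fractions (fixed order: fish, plant,
invertebrate, mammal, bird, garbage) plus an optional *unidentifiable*
residual. The residual is kept separate and **not** redistributed over the
categories: fractions + residual = 1, and per-pair category counts are sums
of the raw fractions. This preserves per-pellet proportion bookkeeping and
means a pair's total count N can be slightly below its pellet count.
"A pellet contains category *j*" means fraction<sub>j</sub> > 0 with no
minimum-fraction cutoff; niche width counts categories with any use, so it
is monotone as pellets accumulate.

Seasonal exploitation curves are computed per search occasion over the
pairs actually searched on that date (not all study pairs), with optional
calendar binning for simulated data.

## Energy rescaling

Counts are converted to energy-equivalent meal counts in two steps, in this
order: (1) the bird category is divided by `bird_correction` (default 1.7)
to undo the over-representation of feather and bone in pellets, rendering
each pellet one meal; (2) each category is multiplied by
s_j = e_j·m / mean_k(e_k·m). The scale factors average exactly 1 by
construction, so rescaling redistributes weight without inflating totals;
with equal energies and unit correction it is the identity (tested
bit-for-bit).

Energy densities `e_j` and meal size `m` are required configuration with
shipped defaults (`examples/energy_config.yaml`): wet-mass densities of
6.5 (fish), 2.0 (plant), 3.5 (invertebrate), 7.0 (mammal), 6.8 (bird),
5.0 (garbage) kJ/g and a 100 g meal. These are literature-plausible values
for a temperate gull colony chosen once as defaults; any real analysis
should substitute measured values. The per-carcass energy model
(400 g × 10.9 kJ/g × 65% digestible = 2834 kJ) and the pair demand
(1460 kJ/d) give the sufficiency threshold 1460/2834 = 0.515 ≈ 0.5
carcasses/day.

## The niche-overlap test

For counts n (total N, proportions p = n/N) against the pooled population
diet q, lambda = Π_{j:n_j>0} (q_j/p_j)^{n_j} is the ratio of the multinomial
likelihood of the data under q to its likelihood under the saturated p, and
W = lambda^{1/N} standardizes it per observation. Note the standardization
direction: **W is invariant** to scaling all counts by a common factor,
while log lambda scales linearly with the factor — W is therefore the
comparable measure across pairs with different sample sizes, and both are
reported.

Implementation choices:

* All accumulation is in log space; observed counts may be non-integer
  (energy-rescaled), handled via continuous exponents. A category used by
  the pair but absent from q gives lambda = W = 0 and a degeneracy flag.
* The null draws R multinomial(round(N), q) diets; rounding only affects
  the null's granularity. P uses the add-one estimator
  (1 + #{λ_null ≤ λ_obs})/(R+1), never exactly 0; the tie comparison uses a
  1e-9 slack on the log scale, identically in the Monte-Carlo and
  enumeration paths.
* Default R = 9999, seedable; the focal pair is included in the pooled q
  (leave-one-out pooling is a switch); P-values are reported raw, with an
  optional Benjamini–Hochberg correction off by default. These three
  conventions are surfaced as configuration because the procedure is
  under-determined in the field literature.
* `exact_overlap_p` enumerates all multinomial outcomes (feasible for
  N ≲ 10, J ≤ 3) and is the oracle for the Monte-Carlo estimator in tests.

Under the null (diets multinomial in q, N = 30, six categories) the
empirical rejection rate at α = 0.05 sits in [0.03, 0.07] (tested at 1,000
pairs, R = 999).

## Carcass-based rates

Per-visit kill rate = carcasses / days since last search. The first
(baseline) visit destroys old remains: it starts the clock and is excluded
from every rate. Season rates are the *unweighted mean of per-visit rates*
(each visit's daily consumption averaged across the season); the
total-carcasses/total-days alternative is a switch. Pairs with fewer than 4
rated searches are flagged as insufficient. Daily predatory impact is the
mean over pairs of total carcasses / total monitored days. Colony
extrapolation divides observed kills by the studied fraction of pairs,
rounding kills to the nearest 100 and nest percentages to integers,
matching conventional reporting precision (rates to 2 decimals).

## Behavior

Attack vs. aggression is a strict disjunction of four criteria; a kill with
all criteria false is internally inconsistent and is classified attack with
a warning. Timing bins are {0}, (0,1], (1,5], (5,∞) minutes since the
initial attack — upper-inclusive edges so "1–5" means 1 < t ≤ 5; 0 is its
own "immediate" bin. Published "mean ± spread" duration figures are
ambiguous between SD and SE, so both are emitted. Success rates carry
Clopper–Pearson intervals.

## Covariate model selection

Responses are per-territory (successes, trials): pellets containing bird /
pellets, or visits yielding a carcass / visits. Candidates are all 2^p
main-effect subsets (including the null) of {shoreline access, size class,
nearest-neighbor distance, treatment, hatch date}, fitted as logit-link
binomial GLMs via statsmodels. Territory size is dichotomized at the sample
mean area by default (overridable, e.g. to a published cut); area is the
product of the two summed axis extents measured from the nest.

ĉ = Pearson χ²/df on the global model (deviance/df available), floored at
1; when ĉ > 1 is used, K includes one extra parameter for it. The n in the
small-sample correction is the number of territories. Fits with |linear
predictor| > 30 are treated as separated and excluded with a warning.
Akaike weights are computed over the full candidate set; relative
importance is the summed weight of Δ ≤ 2 models containing the predictor,
renormalized by the confidence set's weight. The unrenormalized full-set
convention is a switch — published importance values rarely state which
convention was used, so both are labelled. Top-rank ties are broken toward
fewer parameters.

## Synthetic colony model

The generator emulates the statistical structure the analysis assumes, with
one integer seed driving five independent sub-streams (covariates, diets,
pellets, carcasses, behavior), so output CSVs are byte-reproducible.

* **Diets.** p_i ~ Dirichlet(c·q); c = 20 by default (broadly similar
  diets), c → ∞ collapses to q (the null), small c produces specialists.
  Pellets are single-category draws by default (a Dirichlet mixing option
  yields fractional pellets); per-visit pellet counts are Poisson.
* **Season.** Piecewise-constant bird-availability multipliers over
  hatching (Julian 148–170, ×1.0) and fledging (180–196, ×1.6) windows,
  ×0.6 outside; the multiplier reweights the bird share of each pair's
  diet and the carcass rate.
* **Calibration.** Where a regime targets an expected bird-pellet share,
  the population bird proportion is solved by Gauss–Jacobi quadrature over
  the Dirichlet marginal (root-finding, no simulation); where it targets an
  expected daily impact, the carcass-rate intercept is normalized against
  the realized covariate effects and the time-weighted season multiplier so
  the population mean is exact by construction. Covariate and treatment
  effects then act multiplicatively around that mean.
* **Study regimes.** `gull_island_2009`: 21 pairs, nine searches late May
  to mid-July, expected impact 0.41 kills/pair/day, expected bird share
  0.33 (~265 pellets in expectation). `gull_island_2015`: 27 pairs (17
  near the prey colony, 10 away), six searches, impact 0.10, bird-pellet
  share ~0.67 near vs ~0.51 away, attack rates 0.24 vs 0.08 /h (aggression
  0.31 vs 0.07), kill probability 0.36, lognormal attack durations with
  mean 3.9 and SD 3.3 min.
* **Not emulated:** within-pellet mixing structure of real pellets (both
  generator modes are provided because the truth is unobserved), spatial
  territory geometry, observer error in carcass detection, between-year
  carryover, and species misidentification. Passing tests therefore
  demonstrate correctness of the estimators under the assumed generating
  model, not robustness to these field realities.

## Problem sizes and tolerances in the test suite

Monte-Carlo agreement with enumeration is asserted within 3 MC standard
errors plus the add-one bias bound 2/(R+1). Type-I error uses 1,000 null
pairs at R = 999. Parameter recovery of the 2009 impact uses 500 simulated
seasons (2 MC SE band); selection power uses 200 replicates of 30
territories × 20 trials at a shoreline log-odds of 1.5. These sizes were
chosen so each property is decisively powered while the full suite runs in
well under a minute of simulation time.
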