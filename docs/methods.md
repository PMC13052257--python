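# Methods

This note documents the models, estimators and numerical choices behind
`swampdendro`, and what its synthetic data do and do not establish about
real tree-ring analyses.

## Chronology standardization

A measured ring-width series w_t (mm/yr) mixes an ontogenetic (age/size)
trend with the year-to-year environmental signal of interest. We remove the
trend with an **age-dependent smoothing spline**: the discrete penalized
least-squares fit

    minimize  sum_t (w_t - f_t)^2 + sum_t lambda_t (Delta^2 f)_t^2,

where Delta^2 is the second difference and the local penalty lambda_t =
(p_t / 2*pi)^4 corresponds to a cubic smoothing spline whose 50%
frequency-response cutoff is p_t = max(s0, a_t) years, with a_t the cambial
age and s0 the initial stiffness (default **20 yr**). The curve is flexible
in the fast-changing juvenile phase and stiffens as the tree ages, which is
the defining property of age-dependent standardization. The exact solver
internals of the classical dendro programs are not published; this discrete
spline is our deliberate reconstruction of that behaviour and is validated
against its contract: constants and straight lines are reproduced exactly,
and on a pure negative-exponential series (w = 3 e^(-t/40) + 0.3, n = 300)
the ring-width index deviates from 1 by < 0.05 everywhere. The fitted curve
is floored at **0.001 mm** before division so locally absent rings (width
0, kept as 0 rather than missing) give RWI 0 without dividing by ~0; any
floored years are reported.

The RWI is prewhitened with an **AR(p) model**: conditional least squares,
order selected by AIC over 0..10 on a common estimation sample, refit at
the chosen order, residuals re-centred to mean 1 (the first p years are
consumed by the lags). Note AIC deliberately trades a known ~25-30%
overfitting probability for low risk of underfitting; on pure white noise
it returns order 0 in ~72% of runs, which is the expected behaviour of the
criterion, not a defect. The per-year **Tukey biweight** robust mean
(tuning constant c = 9, MAD scale, iterated to |delta| < 1e-8, median
fallback when the MAD is 0) across series gives the chronology; the
prewhitened ("residual") flavor is the default used downstream.

Quality statistics: mean sensitivity MS = mean of |2(x_t - x_{t-1}) /
(x_t + x_{t-1})| (0..2; 0.2-0.6 is the ideal range for climate work);
series intercorrelation rbar = mean Pearson r of each series against the
biweight master of the *other* series (leave-one-out, so a series never
correlates with itself); EPS = n*rbar / (n*rbar + 1 - rbar). MS is
computed on detrended series by default (the convention of crossdating
software); pass raw widths to `mean_sensitivity` for the raw variant.

## Climate-growth correlation functions

For each monthly environment variable we form 24 monthly predictors
(previous and current January..December) plus 4 seasonal ones
(previous/current winter = Jan-Mar, summer = Jun-Sep; sums for
precipitation, means otherwise) and correlate each with the chronology.
Significance uses the **Politis-Romano stationary bootstrap**: blocks of
years with geometric lengths (mean block ceil(n^(1/3))), circular wrap,
(x, y) pairs resampled jointly to preserve their cross-correlation; the CI
is the 2.5/97.5 percentile interval of the n_boot = 1000 resampled
correlations, and a window is "significant" when the CI excludes 0. Each
predictor column's bootstrap stream is keyed by the column name, so the
table is reproducible under a seed and invariant to column order. **No
multiple-testing correction is applied** (28 windows per variable): the
table mirrors standard correlation-function practice and should be read
accordingly.

Calibration caveat: percentile bootstrap CIs for a correlation are slightly
anti-conservative at these sample sizes. Under an exact independence null
with n = 100 years we measure a rejection rate of ~0.078 rather than the
nominal 0.05 (~0.06 already for the unblocked bootstrap; blocking adds the
rest). Users needing strict type-I control should correct for this or for
multiplicity.

## Basal area increment and Age Class Isolation

BAI_t = pi(r_t^2 - r_{t-1}^2) with r_t the cumulative radius; with zero
pith offset the increments telescope exactly to pi(sum w)^2 (asserted to
1e-9 relative). Age Class Isolation assigns each tree-year to the 5-year
cambial-age class [c - 2.5, c + 2.5) for centers c = 10, 20, ..., 120 —
half-open so the windows partition ages — and regresses the per-year mean
BAI of trees occupying a class on calendar year (OLS, classical t-test p;
an n-trees weighting switch is provided but off by default, as the
plain-R^2/p reporting style suggests unweighted fits). A class needs >= 3
distinct calendar years *and* >= 2 distinct trees: a single tree walking
through a window traces its own trajectory, not a cohort comparison.

## Spatial regressions

The response is each tree's mean deviation of BAI from the **species-level
ontogenetic curve**: tree-years are pooled by cambial age, averaged, and
that mean-BAI-vs-age series is smoothed with the same age-dependent spline
(initial 20-yr kernel); a tree's residuals are its BAI minus the curve at
its ages. We use the species-level curve rather than each tree's own
spline because own-curve residuals average to ~0 for every tree by
construction, leaving nothing for a cross-tree regression to explain. The
per-tree mean residual is regressed on a distance covariate (to road, dome
center, or pineland edge) by OLS; >= 5 trees with a non-constant covariate
are required.

## Carbon isotope chain

With delta13C_wood corrected to leaf tissue by subtracting d = **2
per-mil** (wood is enriched by post-photosynthetic fractionation; d is
configurable), the simple C3 discrimination model gives

    Delta13C = (delta13Ca - delta13C_leaf) / (1 + delta13C_leaf/1000)
    Ci = Ca (Delta13C - a) / (b - a),   a = 4.4, b = 27 per-mil
    iWUE = A/gs = (Ca - Ci) / 1.6       [umol CO2 / mol H2O]

The chain is algebraically invertible; `delta13c_wood_from_iwue` is the
exact inverse and round-trips to 1e-9 across the physical domain.
Nonphysical Ci (outside [0, Ca]) is flagged but returned, preserving the
sample census for audit. Mesophyll-conductance and photorespiration terms
are out of scope. The annual atmospheric history (Ca, delta13Ca,
1700-2022) is a **synthetic compilation**: monotone PCHIP interpolation
through anchor values approximating published ice-core and flask records
(Ca ~276 -> ~419 ppm; Suess-effect delta13Ca ~-6.4 -> ~-8.7 per-mil);
substitute a measured table via the `atm_history`/`--atm` inputs for real
analyses.

Ontogeny is removed by OLS of iWUE on cambial age per species; residuals
feed the trend and covariate regressions. **Caveat**: in a decadal census
where every surviving tree is sampled up to the present, cambial age and
calendar year correlate strongly (r ~ 0.5 here), so the two-stage
estimates are mutually confounded — a planted year trend attenuates by
~25-40% after age-detrending and leaks into the age slope (it can even
flip the sign of a weak age effect). The two-stage output is what the
field procedure produces and is reported as such; for generator-recovery
verification the tests use an age-effect-only design for the age slope and
a joint OLS (age + post-1930 year + temperature) for the time-varying
effects.

## Synthetic data generator

The generator's defaults emulate the study conditions: 22/26/26 trees of
three species (pond cypress TAAS, bald cypress TADI, slash pine PIEL) with
maximum ages near 290/220/163 yr; a Big Cypress-like climatology (mean
annual ~24 C, ~1540 mm/yr; wet hot Apr-Oct ~27 C and up to ~245 mm/month,
dry cool Nov-Mar ~19 C and ~40 mm/month; monthly water depth 165-280 cm,
lowest Apr-May and deepest Sep-Oct); warming of 0.025 C/yr after 1978.
Interannual anomalies are AR(1) chains over consecutive *months* —
persistent for water depth (phi = 0.85), weakly persistent for the
atmosphere — so seasonal windows carry distinct information; a single
annual offset would make all monthly predictors collinear and window
attribution meaningless. Water depth adds a weak coupling to annual
precipitation tuned so precipitation explains only ~5-8% of annual depth
variance.

Ring widths are multiplicative: ontogeny (w0 e^(-age/decay) + asymptote)
times exp(sum_v beta_v z_v(t) + eta_t + eps_t), with z_v standardized
seasonal aggregates (cypress respond to Jun-Sep water depth, pine to
Apr-May water depth), eta a shared year effect (sigma = 0.2) and eps
lognormal tree-year noise (sigma = 0.3). The log-linear form keeps widths
positive and correlation signs unambiguous; because the response is
multiplicative, the chronology's natural ground-truth comparator is
exp(signal + eta) ("growth_factor" in the returned truth). Ontogeny
parameters are set so mean ring widths land near the reported 0.83 / 2.65
/ 3.06 mm/yr. Isotope samples follow the decadal design (2020, 2010, ...,
1880, then every 20 yr to 1800) for 16 trees per species, with birth years
calibrated deterministically so the census is exactly 167/133/116; the
prescribed iWUE(year, age, temperature) trajectory is inverted exactly
through the discrimination chain to delta13C_wood.

What the generator does **not** emulate: hurricane/fire/logging
disturbance pulses, spatial autocorrelation among neighbouring trees,
missing/false rings and crossdating error, within-ring isotopic
heterogeneity, and the nonstationarity of real hydrological management.
Passing recovery tests therefore demonstrates the estimators' correctness
under the assumed signal structure, not robustness to those field
realities.

## Numerical details and degenerate inputs

- Spline solve: sparse SPD system, direct factorization; ages must be
  strictly increasing; series shorter than 10 yr are rejected with advice
  to fall back to the series mean.
- AR selection caps the order at n//5 so short series cannot exhaust their
  sample; constant or non-finite input is rejected.
- Biweight: median fallback at MAD = 0; single value returned unchanged.
- Bootstrap: >= 20 paired years required; zero-variance columns are
  skipped with warnings; NaN years are dropped pairwise.
- Predictor columns with > 20% missing years are dropped with a warning
  (relevant when water-depth records are short).
- Tucson IO supports both end-marker dialects (999 -> 0.01 mm, -9999 ->
  0.001 mm), auto-detected per series; absent rings are width 0, not
  missing; read(write(x)) is the identity at dialect precision.
- All simulations are byte-identical under a fixed seed; per-column
  bootstrap streams are derived from (seed, column name) so results do not
  depend on iteration order.

## Problem sizes used in the shipped checks

The packaged verification suite runs entirely on synthetic data: 20-30
trees per scenario, 100 replicates for window-attribution rates, 500
replicates (n = 100 yr, 1000 resamples) for bootstrap calibration, and
isotope tables at the 167/133/116 census. These sizes match the emulated
study's scale; statistics quoted in this note (e.g. the 0.078 null
rejection rate) are computed by those checks.
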