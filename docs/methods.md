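# Methods

This note documents the model, its parameters and defaults, the synthetic
study design, and the numerical choices made where the design was open. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Hydraulics and effective river area

A drainage network is a table of reaches with static attributes (length,
slope, elevation, Strahler order, basin group, midpoint coordinates) and
twelve monthly columns for discharge, ice-free fraction, dry fraction and
air temperature. Width, depth and velocity follow downstream hydraulic
geometry — power laws of monthly mean discharge. The default coefficients
(`W = 12.88 Q^0.42` m, `D = 0.41 Q^0.29` m, `V = 0.19 Q^0.29` m/s, Q in
m³/s) are documented literature values for large-sample downstream
hydraulic geometry; they are configuration, not constants, because any
regional application should refit them. Monthly surface area is `W × R_L`,
and the *effective* (emitting) area multiplies it by `ice_free × (1 − dry)`;
ice-covered or dry channel is assumed not to emit. Both corrections are
multiplicative, the simplest contract consistent with treating them as
independent area fractions. A reach with zero discharge has zero width and
area by construction.

### Small-stream extrapolation

Channels narrower than the resolved network are added per basin group by a
Horton-style geometric progression seeded at the lowest resolved order:
each added class is `width_ratio` narrower and `length_ratio` longer (in
total channel length) than the class above, stopping before widths fall
below 0.3 m — the median width of the smallest field-surveyed channels.
When a basin group resolves two or more orders, both ratios are fitted as
geometric means of the observed order-to-order steps; otherwise configured
defaults (0.5 and 2.0 per order step) apply. Added classes inherit the
basin's first-order k600 and CH4 concentration, and — a choice the source
material leaves open — its first-order ice/dry fractions. The progression
always terminates because `width_ratio` is constrained to (0, 1).

## Gas exchange

* `k600 = S·V·2841 + 2.02` m/day (coefficients' s.d. 107 and 0.209 enter
  the Monte Carlo stage). The intercept makes k600 ≥ 2.02 for any
  non-negative slope and velocity.
* Schmidt number of CH4 in fresh water: quartic polynomial in temperature
  (coefficients pinned in `constants.py`), valid 0–40 °C; out-of-range
  temperatures raise rather than extrapolate.
* `k_CH4 = k600 (Sc/600)^(−1/2)`.
* Equilibrium CH4: zero-salinity solubility function (exponential integral
  fit in `constants.py`) applied to a 1.83 ppm atmospheric mixing ratio,
  times pressure from an isothermal barometric profile (scale height
  8,500 m). At 15 °C and sea level this gives ≈ 3.1 nmol/L
  (0.0031 mmol/m³), cross-checked in the tests against a direct evaluation
  and against Bunsen-solubility magnitudes.
* Water temperature comes from a configurable linear map of monthly air
  temperature, floored at 0 °C. The default is the identity; the floor
  means sub-zero months rely on the ice-fraction correction, not on the
  temperature mapping, to suppress fluxes.
* Fick's law fluxes keep their sign: undersaturated water yields a negative
  (invasion) flux, which is summed into totals and exempt from capping.

## Flux corrections

Upscaling `k (c_w − c_eq)` over whole reaches can produce fluxes exceeding
the dissolved stock advection delivers, most visibly in steep channels.
Three optional corrections address this, applied to the gas-specific k:

1. **cap_k** — k capped at 35 m/day (bubble-dominated exchange above).
2. **cap_flux** — rates above mean + 2 s.d. of the uncorrected population
   are set to that threshold. The population is per calendar month by
   default (configurable to pooled); the threshold is computed once, on the
   uncorrected rates; zero-spread and single-value populations pass
   through; negative rates are never modified.
3. **supply_limited** (default) — the 95% gas footprint length
   `F_L = 3V/K`, `K = k/D` per day, is the upstream distance over which the
   dissolved pool would be evaded. Where `F_L < R_L` the modelled
   concentration cannot be sustained over the reach, and k is reduced to
   `3·V·D/R_L`, making `F_L = R_L` exactly. Implemented as
   `min(k, 3·V_daily·D/R_L)`: never increases k, idempotent, and bounds
   per-reach evasion at three times the advective throughput `c·V·D·W`.
   Velocity is converted to m/day before use so the footprint algebra is
   dimensionally closed; the identity `F_L(k_corrected) = R_L` is asserted
   to 1e−9 relative error in the acceptance tests.

Days per month use the non-leap calendar; emissions convert as
mmol → g (×16.04×10⁻³) and g → Tg (×10⁻¹²). Latitudinal aggregation uses
half-open 10° bands from south to north, with +90° absorbed into the top
band so band totals always sum to the global total.

## Observation pipeline

Site categories carrying CH4 signals unexplainable by catchment predictors
(below wastewater treatment plants, fracking-affected, below dams, ditches,
glacial termini, canals, thaw slumps) are excluded before modelling; the
vocabulary is configuration and unknown labels warn but are retained.
Sites snap to the nearest reach midpoint by great-circle distance
(500 m default threshold). Aggregation to one value per reach-month is
two-stage — across years within site-month, then across sites within
reach-month — with mean/median switches at both stages (default mean/mean;
the source description is ambiguous between the two, so both paths are
tested). Monthly model windows pool the month with its two neighbours
(December–January wrap), then split 80/20 with a fixed, recorded seed.
Predictor pruning drops constant columns, removes one member of every pair
with |Pearson r| > 0.95 (an ordered keep-priority list breaks ties), and
log-transforms columns with |skewness| above 2, offsetting zeros by half
the smallest positive value.

## Concentration model

The response is ln-concentration. One regressor per month, behind a
pluggable `RegressorConfig` (random forest default, hyperparameters
mtry = 13, min_n = 8, n_trees = 1200 taken as pinned configuration; tuning
is out of scope). Test metrics (R², RMSE, log space) come from the withheld
20%; variable importance is permutation-based mean decrease in accuracy,
summarised as median ± s.d. across the twelve monthly models; partial
dependence clamps one predictor across a grid over yearly per-reach
averages and averages predictions over rows and months.

Prediction uncertainty is the bias-corrected infinitesimal jackknife for
bagged ensembles: `V(x) = Σ_i cov_b(N_bi, t_b(x))² − (n/B²) Σ_b (t_b−t̄)²`,
with in-bag counts `N_bi` re-derived from each tree's recorded random
state. If the backend's internals are unavailable the spread of
bootstrap-member predictions is used instead; the method actually used is
recorded on the results object. The back-transform to mmol/m³ is a plain
exponential by default (a lognormal bias-correction switch exists, off by
default), and the log-space s.d. maps to response units by the delta
method. Extrapolation flagging is deliberately simple: a row is flagged if
any predictor leaves the training [q01, q99] range — a per-predictor
stand-in for convex-domain screening, which over-flags nothing but cannot
detect novel predictor combinations inside marginal ranges.

## Monte Carlo and sensitivity

Per iteration: the two k600 coefficients are drawn from their published
normals once and shared across reaches (they are global model parameters);
concentrations are drawn per reach-month from N(c_hat, c_sd); a width
multiplier is drawn per reach from N(1, CV_Q), the discharge CV standing in
for the width CV since width derives from discharge. All draws are clipped
at zero (left-censoring rather than renormalised truncation — simpler, and
with the s.d. magnitudes in use the censored mass is negligible). The
active flux correction is re-applied inside every draw. Defaults: 1,000
iterations; both the 5–95 and 10–90 percentile pairs are reported, the two
conventions both being in circulation for this quantity. One-at-a-time
sensitivity shifts each of the three parameters ±1 s.d. with the others at
their means — six deterministic runs reported against the baseline.

## Ebullition

Pairs are observation rows carrying both diffusive and ebullitive flux
(same site and sampling occasion; a same-study-only pairing would need the
study key and is left switchable), filtered to both fluxes ≥ 10⁻⁴
mmol m⁻² d⁻¹ and to k600 not derived from hydraulic relationships. The fit
is OLS of ln-ebullitive on ln-diffusive (natural logs internally; slope is
base-invariant). The ebullitive total applies the regression in log space
to the diffusive total itself — the stated first-order approximation, not a
reach-by-reach map — and its uncertainty interval takes the lower 95%
prediction bound at the diffusive 2.5th Monte Carlo percentile and the
upper bound at the 97.5th, so regression scatter and Monte Carlo spread
both widen it.

## Thermal analysis

`x = 1/(k_B·288.15 K) − 1/(k_B·T)` (1/eV, zero at 15 °C, increasing in
temperature; k_B = 8.617×10⁻⁵ eV/K), so the OLS slope of ln-flux on x is
the apparent activation energy E_M in eV with the sign convention that
warming-stimulated fluxes give positive E_M. Slopes are invariant to
multiplicative flux rescaling and to the centring constant. Non-positive
fluxes cannot enter the log and are excluded with counts reported. Sites
with more than 20 usable observations get individual fits; the same set
feeds the E_M distribution (the threshold is configurable, and the
distribution can equally be built from all sites). Group comparison uses
the two-sided Wilcoxon rank-sum test plus medians, interquartile ranges and
Gaussian KDEs on a shared grid.

## Synthetic study design

The generator is the package's test-bed, not a geographic simulation. A
random recursive tree gives the topology; headwater discharge is lognormal
and accumulates downstream, with sinusoidal seasonality phased by
hemisphere; slopes decline with Strahler order on average; reach lengths
are lognormal around a 6.8 km median; ice phenology follows a latitude-
dependent air-temperature climatology (ice-free fraction ramping between
−5 and +2 °C monthly air temperature). Predictors include the true drivers
of the planted log-linear concentration model (coefficients on z-scored
predictors; defaults in `synthetic.DEFAULT_CONC_COEFFS`, log-noise s.d.
0.5), one near-duplicate pair (r > 0.95) to exercise pruning, and an inert
noise column. Observations sit on jittered reach midpoints with a visit
design mixing short records (mean 3 visits) and a 5% fraction of long time
series, so that both sparse sites and >20-observation sites exist.

Diffusive flux is Fick's law evaluated at the site's reference (annual)
state, multiplied by `exp(E_M·x)` at the planted E_M (default 0.14 eV) and
lognormal noise; computing the base flux at the reference state, rather
than per visit, makes the planted within-site thermal slope exactly E_M
(verified to machine precision in the noiseless test). The pooled slope
across sites additionally reflects covariance between site flux magnitude
and climate — a feature, since distinguishing pooled from site-level
sensitivity is the point of the analysis. Ebullition follows a planted
ln–ln relation (default slope 1.0 — the near-1:1 regime — intercept 0,
noise s.d. 1.0). "Targeted" site categories receive concentration
multipliers (e.g. ×8 below wastewater treatment plants).

What the generator does *not* emulate: spatial autocorrelation of
concentration errors, non-stationary predictor relationships, measurement-
method biases, under-ice storage and release, and realistic geography.
Passing tests therefore demonstrate the correctness of the machinery and
the recoverability of planted signal at these noise levels — not the
accuracy of any real-world emission number.

## Problem sizes and determinism

Default study sizes are 50 reaches and 500 observations (the CI-speed
fixture; property tests use up to 2,000 draws or 1,000 random reaches), and
the test suite's forest sizes are reduced from the pinned 1,200 trees to
30–300, which leaves every qualitative property intact. All randomness
flows from recorded seeds (`numpy.random.default_rng`); identical configs
reproduce identical tables, metrics and Monte Carlo draws, and each
pipeline run writes a manifest with its config hash, seeds and input
digests.

## Known limitations

* Hydraulic coefficients, the air–water temperature map and the Schmidt/
  solubility functions are pinned defaults; regional fidelity requires
  refitting them.
* The supply-limited correction treats reaches independently; it enforces
  a per-reach mass bound, not network-routed mass balance.
* The ebullition upscaling applies a site-level regression to a global
  total — a stated approximation that ignores Jensen-type aggregation
  error across reaches.
* The extrapolation flag tests marginal ranges only.
* Statistics that require the real deposited global database (retained
  counts, flux medians, pooled E_M of the global compilation) can be
  computed by these stages but not verified offline; the corresponding
  acceptance test documents this.
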