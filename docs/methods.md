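# Methods

`segmetals` implements a county-level analysis of how racial residential
segregation relates to exposure to fine-particulate trace metals, as a tested,
reusable pipeline. This note records the model, the conventions chosen where
the design was genuinely open, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproduction.

## Monitor QC and annual aggregation (`monitor_qc`)

Daily speciated PM₂.₅ records (one row per monitor-date-component; metals in
ng·m⁻³, PM₂.₅ in µg·m⁻³) pass through four rules:

1. **Validity.** Only rows flagged valid with a non-missing concentration are
   kept.
2. **Completeness.** Speciated networks sample every third day, so a full
   monitor-year expects ~121 samples. A monitor-component-year is retained iff
   `n_samples / expected_n > 0.5` with a *strict* inequality — exactly half the
   schedule is rejected. `expected_n` defaults to 121 and can be overridden
   per monitor-year (monitors active for part of a year have shorter
   schedules).
3. **Detection limits.** Values below the assay's minimum detectable limit
   (MDL) are retained by default, so annual means are not skewed upward. The
   standard censored-data substitution (replace values `< MDL` by `MDL/√2`)
   is available as a sensitivity switch. Note the substitution is not
   monotone pointwise: a draw between `MDL/√2` and `MDL` is replaced by the
   *smaller* `MDL/√2`.
4. **County aggregation.** County annual values are unweighted arithmetic
   means over the county's retained monitors (no sample-count weighting; the
   aggregation is across monitors, not across days). The PM₂.₅ mass
   proportion of a metal is the ratio of the county *annual means*
   (metal ÷ PM₂.₅), not a mean of daily ratios; the ng↔µg factor of 10³ is
   applied exactly once, here.

Urban/rural status is consumed as a boolean input column; deriving it from
census geography is out of scope.

## Dissimilarity index (`segregation`)

For a county partitioned into census tracts, with minority tract counts `x_i`
(total `X`) and reference counts `y_i` (total `Y`):

    D = ½ · Σ_i | x_i/X − y_i/Y |

`D ∈ [0, 1]`: the fraction of the minority population that would need to
relocate for every tract to mirror the county proportions. Implementation
detail: the sum is evaluated in the cross-multiplied form
`½·Σ|x_i·Y − y_i·X| / (X·Y)`, which is exact in double precision for integer
populations, so perfect evenness and complete separation return exactly 0
and 1.

Conventions:

- Counties with a single tract are *excluded by rule* (a typed signal, not an
  error); counties where `X = 0` or `Y = 0` yield a typed *undefined* record
  rather than a silent `D = 0`, which would masquerade as perfect integration.
- Racial-residential-segregation (RRS) categories use left-closed intervals
  `[0, 0.3)` well integrated, `[0.3, 0.6)` moderately segregated, `[0.6, 1]`
  highly segregated, so every DI maps to exactly one category; an empirical
  tertile scheme over a reference DI distribution is provided for
  sensitivity analyses.
- DI is computed per demographic period (e.g. an ACS 5-year window); mapping
  monitor years to periods is the caller's configuration.

## Population-weighted exposure and relative disparity (`exposure_disparity`)

Per RRS category *i*, over monitored counties *j* with population `P_j` and
exposure `x_j` (concentration or mass proportion):

    Y_i = Σ_j P_j x_j / Σ_j P_j
    RD  = √Var(Y) / µ(Y)

`P_j` is the *total* county population, not the group-specific population.
RD, the coefficient of variation of the category means, is scale-free: 0
means equal population-weighted exposure across segregation levels, and
values are comparable across components and years.

- **Variance convention.** `Var(Y)` divides by the number of categories K
  (population variance) by default; the sample-variance (K−1) convention is a
  switch. With K = 3 the two differ by the fixed factor √(3/2), so the choice
  is recorded in every output record.
- **Bootstrap.** CIs are percentile (2.5/97.5) from a stratified bootstrap:
  counties are resampled with replacement independently within each category
  at the observed per-category counts (overridable), and *both* Eq. levels —
  the category means and then RD — are recomputed per replicate. The
  resampling unit is the county, not the monitor. Deterministic given a seed.
- A percentile CI can in pathological resamples exclude the point estimate;
  this is reported, not "fixed".

The coverage verification plants category means `(1, 2, 3)` (RD\* ≈ 0.4082)
and draws county exposures with multiplicative lognormal noise (σ = 0.3,
200 counties per category). Multiplicative noise scales all category-mean
expectations equally, and RD is scale-invariant, so RD\* remains the true
value of the estimand; a literally noiseless scenario would collapse every
replicate to RD\* and make coverage trivially 100%, which is why the check
uses within-category noise.

## Log-log association (`association`)

OLS of `log(concentration)` on `log(DI)` at the county level. The slope β is
an elasticity, reported as the percent change per 10% *multiplicative*
increase in DI:

    %Δ per 10% DI = (1.1^β − 1) · 100

(The multiplicative reading follows from both variables being
log-transformed.) This map is logarithm-base invariant, and natural-log and
log₁₀ fits give identical β, SE, and p-values. CI endpoints on the percent
scale are the monotone transform of the slope CI endpoints. Counties with
zero DI or zero concentration cannot enter the fit and are excluded with a
logged count.

Extensions, each a switch: urban/rural stratification; categorical region
fixed effects (one-hot, first region alphabetically as baseline, coefficients
reported but not interpreted); percent-NHB or percent-NHW composition
covariates, log-transformed by default so their coefficients convert with the
same `(1.1^β − 1)` map (an untransformed-percent switch exists). Standard
errors are classical OLS by default with an HC1 robust switch.

## Spatial autocorrelation (`spatial_stats`)

Weights are k-nearest-neighbour (default k = 8) on great-circle (haversine)
distance, row-standardised to 1/k; KNN tolerates the irregular spacing of
monitors without islands. Distance ties (including duplicate coordinates)
break deterministically by site order. Global Moran's I uses the standard
double-sum form with null expectation −1/(n−1); local Moran's I is
`I_i = z_i·Σ_j w_ij z_j / m₂`, and for row-standardised weights
`Σ_i I_i = n·I` (verified numerically). Inference: random permutation
(global) and conditional permutation holding `z_i` fixed with neighbour
values drawn without replacement from the remaining n−1 sites (local), both
with the `(r+1)/(n_perm+1)` estimator at 999 permutations by default. Local
cluster labels HH/LL/HL/LH come from the sign pattern of `(z_i, lag_i)` at
raw p < 0.05 — descriptive use, no multiple-testing correction by default; a
Benjamini–Hochberg switch is provided. Analysis granularity is the
monitor/county-centroid coordinates present in the exposure table.

## Synthetic generator (`synthetic_data`)

The generator defines the study conditions under which the pipeline is
verified:

- **Tract mosaics.** Each county's tract allocation is a two-block
  construction driven by `mixing_theta ∈ [0, 1]`: a fraction θ of every
  minority group is packed into one dedicated tract on top of its even
  share, and the reference (NHW) population is correspondingly displaced to
  the other tracts. This yields DI = θ exactly in continuous populations
  (DI(0) = 0, DI(1) = 1, monotone in θ); integer rounding perturbs mid-range
  values by O(1/population). Group totals are rounded to multiples of the
  tract count so the endpoints are exact. County racial compositions get
  log-scale jitter (SD 0.3, renormalised) so composition covariates vary
  across counties.
- **Concentrations.** County-component annual means follow
  `log(mean) = α_m + β_m·log(DI) + region effect + N(0, σ_annual)` with
  σ_annual = 0.3. Default β_m encode gradients of 9–16% per 10% DI for the
  anthropogenic-source metals (Cu, Zn, Ni, Cr, Pb, V), 4–7% for the
  natural-source metals (Fe, Mn, Ti), and 5% for PM₂.₅; α_m are logs of
  typical annual means. Daily values are lognormal about the annual mean
  with σ_daily = 0.5 and the −σ²/2 correction so their *expectation* equals
  the planted mean (the within-year distribution is an implementation
  choice; nothing downstream depends on its shape beyond the below-MDL rate).
- **Sampling.** Days of year 1, 4, 7, … (122 scheduled days in a 365-day
  year; the QC completeness denominator stays at the conventional 121).
  Each scheduled value is dropped independently with `missing_rate`
  (default 0.10). Values below MDL are generated, never truncated.
- **Scale.** The default scenario uses 233 monitored counties — the scale of
  a national speciated-network analysis — with one monitor per county,
  20 tracts per county, and 100 000 persons per county. Regions are assigned
  from monitor coordinates by a quadrant-style split, which also makes the
  planted region effects spatially autocorrelated.
- **Seeding.** One scenario seed feeds a `SeedSequence` tree keyed by
  purpose, county, monitor, and the component's position in the canonical
  component list, so regeneration is byte-identical and adding a component
  leaves all other draws unchanged.

What the generator does **not** emulate: real station placement and spatial
clustering of monitors, covariance between metals (each component draws
independent noise), seasonality, within-county monitor heterogeneity, blank
corrections or assay uncertainty. Passing tests therefore demonstrate that
the pipeline's statistics are implemented correctly and recover planted
structure under these idealised conditions — not that real networks satisfy
those conditions.

## Verification problem sizes

The test-suite and acceptance-script checks use: 1 000 random small counties
against an exact-rational DI oracle; 500 replicates × 200 counties for
elasticity recovery (planted β = 0.904 = ln 1.09/ln 1.1, σ = 0.3); 500
replications × 2 000 bootstrap draws × 600 counties for RD coverage; 500
null simulations × 999 permutations at n = 30 for Moran p-value calibration;
and a 233-county, 10-component full pipeline run executed twice for
hash-identical determinism. These sizes give Monte-Carlo standard errors
comfortably inside the tolerance bands used by the tests.

## Known limitations

- Monitored counties are treated as representative of their whole population;
  there is no correction for unmonitored counties.
- The DI is aspatial (invariant to the arrangement of tracts) and
  scale-dependent on the tract/county choice.
- The percentile bootstrap can undercover RD slightly at the small
  per-category counts typical of sparsely monitored categories.
- Log-log fits drop zero-DI and zero-concentration counties rather than
  modelling them.
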