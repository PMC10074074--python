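# Methods

This note records the models implemented in `seepcore`, the assumptions
behind them, the defaults and why they were chosen, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## 1. CRS ²¹⁰Pb chronology

### Model

Unsupported ("excess") ²¹⁰Pb reaches the seafloor at an assumed constant
rate and decays in place (λ = ln 2 / 22.3 yr⁻¹). With m the cumulative dry
mass depth (g cm⁻²) and I(m) the excess inventory below m (Bq cm⁻²):

    t(m) = (1/λ) · ln(I₀ / I(m)),      r(m) = λ · I(m) / A_ex(m).

Assumptions: constant supply flux; no post-depositional mixing or
redistribution of ²¹⁰Pb; supported activity either assayed (²²⁶Ra-style,
per-layer `pb210_supported`) or estimable from the deep asymptote.

### Discretisation

Cores are measured as contiguous slices, so activities are treated as
slice (mass-weighted) averages and inventories are summed layerwise:
layer inventory = A_ex(Bq g⁻¹) × ρ(g cm⁻³) × thickness(cm). For the rate
identity, I within a layer is evaluated as the logarithmic mean of the
bounding boundary inventories — the layer average of a log-linearly
interpolated I(m). Two consequences:

* on a noise-free constant-rate core both ages and MAR are recovered to
  machine precision (the slice mean of an exponential is handled exactly);
* per-layer (rate × layer duration) reduces algebraically to the layer's
  own inventory, so the burial-flux conservation identity
  Σ rateᵢ·Δtᵢ = areal MP mass holds exactly, noise or no noise (when the
  error-model debiasing below is off).

### Supported activity

If supplied (argument or layer table), used as is. Otherwise the
n (default 4) deepest layers must form a plateau: the fitted log-linear
decline across the window must be either practically small (< 5% of the
mean) or statistically indistinguishable from flat (one-sided t at 0.05).
A still-decaying profile raises an error asking for an explicit value —
guessing supported activity from an unterminated profile is the classic
way to wreck a CRS chronology.

### Tail correction and equilibrium truncation

CRS is biased whenever I₀ is truncated at the core bottom. The package
fits the excess point profile A(m) = A₀e^(−βm) — as its exact slice-mean
counterpart — by weighted least squares **in linear activity space over
every layer, using the raw (possibly negative) excess values**, and adds
the analytic continuation A(m_bottom)/β below the deepest contributing
boundary. Three deliberate choices, each made because the obvious
alternative is biased:

* *linear space, all layers*: fitting in log space, or fitting only layers
  whose measured excess clears a threshold, conditions on upward noise
  fluctuations and systematically flattens β (tail overestimated several-
  fold at 20% noise);
* *fit-anchored tail*: anchoring the continuation on the deepest layer's
  own measurement inherits that layer's selection bias; the fitted profile
  value at the same depth does not;
* *fit-based equilibrium cutoff*: when per-layer activity errors are
  available, layers whose **fitted** excess falls below `sigma_cut` (2 by
  default) × their error stop contributing measured inventory (the tail
  carries everything below). The criterion depends on the smooth fit, not
  the layer's own noisy value, so it selects nothing. Boundaries below the
  cutoff are undatable and flagged.

A fixed-point loop (≤ 20 iterations, relative tolerance 10⁻⁶ via the
optimizer) reconciles slice means with the point profile; at zero noise
the fit, the cutoff (inactive) and the tail are exact.

### Measurement-error model

Activity errors, when present, are interpreted as relative dispersions of
multiplicative lognormal noise (the simulator's noise model; median-
preserving, E[ln f] = 0). Two debiasing steps follow from that model,
both inactive when no errors are supplied and both switchable off via
`error_model="gaussian"`:

* a lognormal measurement with median A and dispersion cv has mean
  A·√(1+cv²); measured totals are divided by that factor so inventory
  sums are mean-unbiased;
* per-layer MAR is proportional to 1/Δln I, convex in the layer's excess
  noise, hence biased by (1+cv²); MAR is divided by that factor, with cv
  taken from the fitted profile (again: deterministic given the fit, no
  selection). This sacrifices the exact conservation identity for
  unbiasedness; with `error_model="gaussian"` the identity is exact.

These corrections are not cosmetic: without them, simulation studies at
20% noise showed deep ages compressed by ~25% and growth-rate estimates
biased by similar amounts.

### Dating horizon and flags

²¹⁰Pb resolves roughly the last 100–150 yr; ages are capped at a
configurable 150-yr horizon and flagged `extrapolated` beyond it. Clipped
excess values (total ≤ supported; floored at 10⁻³ Bq kg⁻¹) flag their
layer's MAR `mar_unreliable`. Burial-rate reconstruction excludes
extrapolated, undatable and unreliable layers.

### ¹³⁷Cs validation and correction

The 1963 global fallout maximum provides an independent time marker. The
peak is located as the maximum-activity layer (ties broken toward the
deeper layer, since the fallout peak pre-dates coring) and refined by a
quadratic fitted to ln(activity) over the contiguous run of layers above
20% of the peak — the exact estimator for a Gaussian pulse sampled at
layer midpoints, and the natural one under multiplicative noise
(homoscedastic in log space). Validation compares the CRS age at the
refined depth with (coring year − 1963) against a tolerance (default
5 yr). In correction mode all CRS ages are rescaled by one uniform factor
so the peak dates exactly to the marker year; this is one defensible
reading of "correcting" an age series with ¹³⁷Cs, and it is flagged in
the output rather than silently applied.

## 2. Synthetic cores

The generator produces cores satisfying the CRS generating assumptions
exactly at zero noise, so the chronology can be validated against closed
forms, plus an MP deposition history with known truth.

What it emulates: exponential excess-²¹⁰Pb decay with mass depth under
constant MAR (slice averages, exactly integrated); a Gaussian ¹³⁷Cs pulse
in age centred on 1963 (reported as midpoint point-samples — the one
quantity not slice-averaged, so the peak refinement has an exact target);
MP loading of zero before 1930, a linear ramp 1930–1950 and exp(k(t−1950))
growth after 1950, scaled to a surface flux; a constant multiplicative
burial attenuation in seepage habitats; polymer composition shifting from
industrial polymers (PTFE, AC, PF) at depth to consumer polymers (PC only
post-2000) near the surface; lognormal, median-preserving measurement
noise of common cv on activities and abundances, with the generating
supported activity reported in the layer table as a direct assay.

Key defaults (all overridable): surface excess 150 Bq kg⁻¹ over supported
25 Bq kg⁻¹ (typical continental-margin values); ¹³⁷Cs peak sd 4 yr; MP
flux scale 250 mg m⁻² yr⁻¹ at the production maximum (the magnitude of
reported deep-sea "current" burial rates); number-to-mass ratio
0.5 items mg⁻¹. Two presets define the study conditions used throughout
the tests:

* `dating_scenario` — 40 × 1 cm at MAR 0.1 g cm⁻² yr⁻¹, ρ 1.0 g cm⁻³
  (≈10 yr per slice; captures > 99.99% of the excess inventory), the
  chronology benchmark;
* `deposition_scenario` — 100 × 1 cm at MAR 0.3 g cm⁻² yr⁻¹, ρ 0.30 g cm⁻³
  (fluffy surficial mud, ≈1 yr per slice, ~70 dated post-1950 layers), the
  regime in which a decade-resolved burial history is actually readable.
  Resolving ±10% growth-rate recovery at 20% noise needs this many dated
  layers; a 2-cm/10-yr core cannot support that inference, which is itself
  a useful design statement.

What it does **not** emulate — and therefore what passing tests do not
show about real cores: sediment mixing/bioturbation (none), compaction
(constant per-core density), MAR variability (constant by default; the
`varying` stress test exists in spirit via parameter overrides), bubble or
plume hydrodynamics (attenuation is one phenomenological constant), polymer-
specific degradation in place, or spatially correlated noise. Recovery
rates quoted in the tests are properties of the pipeline under these
idealised conditions, not field-accuracy claims.

`simulate_particles` draws per-particle records: Poisson counts
proportional to number abundance, sizes from a lognormal (median 120 µm,
log-sd 1.2) truncated to the 20–5000 µm detection window by inverse-CDF
sampling, configurable morphology/color probabilities, and projected areas
as π(d/2)² × shape factor.

## 3. Burial rates and trends

Burial rate = abundance × MAR, carried at the layer midpoint age with the
layer's CRS duration. Decade bins (1900–2020) plus the 2001–2020 window
report arithmetic mean ± sample sd (singleton sd 0; empty bins are
missing, never zero). Normalised histories divide by the series maximum.
`growth_fit` is OLS of ln(rate) on (year − 1950), excluding (and counting)
zero rates. `seepage_contrast` is the ratio of period means with a seeded
bootstrap percentile interval; by default each layer is weighted by its
deposition time, making the period mean the buried mass divided by the
period duration — the physical period-average flux, and by the
conservation identity insensitive to per-layer MAR noise. Equal weighting
is available where the plain mean of layer rates is wanted.

## 4. Fragmentation indicators

R_N/M = number/mass abundance (items mg⁻¹); 0/0 and n/0 are reported
missing, never zero. Size fractions use thresholds 50 and 250 µm.
"Particle" is the granule/sphere morphology class, ratioed against
fragment+film+fiber. United projected area is reported both as the mean
per-particle area (µm²) and as areal load (mm² kg⁻¹ = mean × number
abundance); records lacking a measured area are imputed as
π(d/2)² × shape factor (default 0.5, flagged and counted). The
colored/colorless profile correlation uses Pearson (or Spearman) with a
seeded permutation p-value (default 10⁴ permutations) — abundance
distributions are too irregular to trust a parametric p.

## 5. Risk indices

* **PLI.** CF = C/C₀ with C₀ the lowest positive detected abundance across
  the analysed sites (overridable). Per point PLI = √CF; regional PLI is
  the geometric mean. The source literature also circulates a literal
  PLI = CF form; it is available as `mode="literal"`.
* **PHI** = Σ Pₙ·Sₙ. Hazard scores ship as a versioned table (PU 1094,
  PA 50, PET 4, POM 871, PC 1177, PE 11, PP 1, PS 30, PBD 6552, PVC 10001,
  PSF 1, PMMA 1021, AC 10599, SI 2, FKM 2, PF 750). PTFE has no published
  score: the strict policy (default for direct `phi()` calls) raises,
  naming the polymer; `default` assigns a user score; `exclude`
  renormalises without it (the pipeline default, logged in the report
  parameters). Compositions default to number-abundance proportions; mass
  basis is configurable.
* **PRI** = Σ Pₙ·C_f·Sₙ with C_f = C/C₀ dimensionless; a literal-C form
  is selectable.
* **NPI** = √((P̄² + P²_max)/2), P = C/C_s with C_s = 373 items kg⁻¹
  (NPI-N) or 3465 mg kg⁻¹ (NPI-M).

Classification intervals are left-closed ([lower, upper)) for PLI
(10/20/30), PHI (1/10/100/1000) and PRI (150/300/600/1200). NPI's
published scheme assigns "≤ 0.7" to level I, forcing left-open/right-
closed interior bands (0.7/1.0/2.0/3.0); the asymmetry is deliberate and
boundary-tested. Cross-site summaries min-max normalise each indicator to
[0, 1]; degenerate indicators (zero range — PHI is composition-scale-
invariant, so sites differing only in amount tie) are left as missing with
a warning rather than fabricated. Reports echo C₀, C_s, the basis, the
PLI mode and a hash of the hazard table.

## 6. Degenerate inputs and tie-breaks

Non-positive excess: clipped to 10⁻³ Bq kg⁻¹, flagged. I ≤ 0: undatable.
I > I₀: hard error (inconsistent inventory). ¹³⁷Cs all zero: validation
skipped, reported. Peak below the dating horizon: skipped with warning.
Tied ¹³⁷Cs maxima: deeper layer. All-zero burial series: normalisation
refuses. Fewer than 4 usable points: growth fit refuses. Empty period:
contrast refuses. Missing particle table: fragmentation metrics reported
missing, pipeline completes.

## 7. Problem sizes used by the test battery

Replicate studies run 200 seeded replicates (40 in the faster unit-test
variants): chronology recovery at noise cv 0.02 on the dating preset;
growth and attenuation recovery at cv 0.2 on the deposition preset;
1000 random inputs for the risk-index oracle; 10⁴-draw Monte-Carlo checks
for particle sizes. The full suite runs in well under five minutes on one
CPU; the end-to-end pipeline on a default synthetic scenario completes in
seconds.

## 8. Known limitations

The CRS implementation offers no CIC/CFCS alternatives and no Bayesian
age-depth machinery; the ¹³⁷Cs correction is a uniform rescale, not a
joint model; the lognormal debiasing assumes the error column really is a
relative dispersion (set `error_model="gaussian"` for plain counting
errors); seepage attenuation is a single constant, so nothing can be
inferred about its mechanism; and the risk indices inherit the hazard
table's monomer-toxicity weighting wholesale, including its strong
sensitivity to the composition basis (number vs mass).
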