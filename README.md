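# seepcore

Sediment-core chronology and microplastic (MP) burial/risk analysis for
deep-sea cold-seep environments.

Deep-sea sediments are a long-term sink for microplastics, and methane-seep
habitats appear to bury *less* plastic than neighbouring non-seepage seafloor
while fragmenting what they do bury. Testing such claims requires three
things done carefully: dating recent sediment slices, converting per-mass MP
abundances into time-resolved burial fluxes, and scoring the resulting
contamination on standard risk scales. `seepcore` implements that pipeline
for geochemists and marine-pollution researchers, together with a forward
simulator that generates cores with known truth so every stage can be
validated quantitatively.

## What it computes

**CRS ²¹⁰Pb chronology.** Under the constant-rate-of-supply model, with
I(z) the excess-²¹⁰Pb inventory (Bq cm⁻²) below depth z and I₀ = I(0),

    t(z) = (1/λ) · ln(I₀ / I(z)),      λ = ln 2 / 22.3 yr⁻¹
    r(z) = λ · I(z) / A_ex(z)          (mass accumulation rate, g cm⁻² yr⁻¹)

with slice-resolved inventory summation, an exponential tail correction for
the unsampled inventory below the core, equilibrium-depth truncation, and
validation (optionally uniform correction) of the age scale against the
1963 ¹³⁷Cs fallout maximum.

**Burial-rate reconstruction.** Per dated layer, burial rate = abundance ×
MAR (mg or items m⁻² yr⁻¹), with decade binning, max-normalised histories,
exponential growth fits of ln(rate) against time since 1950, and
seepage/non-seepage contrasts with bootstrap intervals.

**Fragmentation indicators.** R_N/M (number-to-mass abundance ratio,
items mg⁻¹), size fractions below 50/250 µm, granule-to-other morphology
ratio, united projected area, and the colored/colorless profile correlation
with a permutation p-value.

**Risk indices.** PLI (√(C_i/C₀), geometric mean across points), PHI
(Σ Pₙ·Sₙ over polymer hazard scores, e.g. PVC 10001, PP 1), PRI
(Σ Pₙ·C_f·Sₙ) and the Nemerow index NPI = √((P̄² + P²_max)/2) with
P_i = C_i/C_s against 373 items kg⁻¹ / 3465 mg kg⁻¹ reference levels —
each with its five-level classification.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from seepcore import CRSAgeModel, simulate_core, burial_series, growth_fit, phi
from seepcore.synthetic import deposition_scenario
from seepcore.deposition import bin_by_period

params = deposition_scenario(noise_cv=0.1, seed=42)   # rapid-deposition core
core, inventory, truth = simulate_core(params)

model = CRSAgeModel().fit(core, coring_year=2021)
v = model.validate_cs137(peak_year=1963, correct=True)
series = burial_series(model, inventory)
g = growth_fit(series, start_year=1950)
b = bin_by_period(series, [2001, 2021])

print(f"total excess 210Pb inventory: {model.total_inventory_:.3f} Bq cm^-2")
print(f"137Cs peak at {model.cs_peak_.best_depth_cm:.1f} cm -> CRS age "
      f"{v.crs_age_at_peak:.1f} yr (expected {v.expected_age:.0f})")
print(f"growth since 1950: k = {g.k_hat:.4f} /yr (r^2 = {g.r_squared:.3f})")
print(f"mean burial 2001-2020: {b['mean'].iloc[0]:.1f} +/- {b['sd'].iloc[0]:.1f} mg m^-2 yr^-1")
print(f"PHI of a pure-PC sample: {phi({'PC': 1.0})[0]:.0f}")
```

prints

```
total excess 210Pb inventory: 1.153 Bq cm^-2
137Cs peak at 58.1 cm -> CRS age 59.3 yr (expected 58)
growth since 1950: k = 0.0512 /yr (r^2 = 0.979)
mean burial 2001-2020: 160.0 +/- 56.8 mg m^-2 yr^-1
PHI of a pure-PC sample: 1177
```

The simulated core deposits plastic following the global production history
(exponential at k = 0.05 yr⁻¹ since 1950), so the fitted growth rate
0.0512 yr⁻¹ recovers the generating value within 3%; the ¹³⁷Cs horizon
dates within ~1 yr of its true age; and a sample that is 100%
polycarbonate scores exactly PC's hazard value, in the highest hazard
level (V).

The same pipeline runs from the shell:

```sh
seepcore simulate --seed 42 --out sim/
seepcore report --layers sim/layers.csv --inventory sim/mp_inventory.csv \
                --particles sim/particles.csv --out report/
```

writing `agemodel.csv`, `burial.csv`, `frag.csv`, `risk.json` and a
machine-readable `summary.json` (plus the resolved configuration) under
`report/`.

## Layout

| module | contents |
| --- | --- |
| `seepcore.core` | domain types, units, validation |
| `seepcore.synthetic` | forward simulator with known truth |
| `seepcore.chronology` | CRS age-depth model, ¹³⁷Cs validation |
| `seepcore.deposition` | burial series, binning, growth, contrasts |
| `seepcore.fragmentation` | R_N/M, size/morphology/area/color metrics |
| `seepcore.risk` | PLI/PHI/PRI/NPI and classifications |
| `seepcore.io`, `seepcore.cli` | CSV/YAML I/O, configuration, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
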