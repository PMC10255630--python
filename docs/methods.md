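# Methods

This note documents the models, conventions and numerical choices
behind `bloomscan`, in the order data flows through the pipeline.

## Carbonate chemistry

In calcite-metastable surface water, pH is controlled by alkalinity,
temperature and dissolved CO₂, so CO₂ follows from the other three.
We solve the dilute-solution carbonate system with charge-balance
alkalinity restricted to carbonate species:

    Alk = [HCO₃⁻] + 2[CO₃²⁻] + [OH⁻] − [H⁺]

Given H = 10^(−pH), the closed form is

    [HCO₃⁻] = (Alk − K_w/H + H) / (1 + 2K₂/H)
    [CO₃²⁻] = K₂[HCO₃⁻]/H
    [CO₂*]  = H[HCO₃⁻]/K₁

Constants K₁, K₂ follow the Plummer & Busenberg (1982) freshwater
temperature expressions and K_w the matching ion-product fit (the same
parameterization family PHREEQC's default database uses), valid over
the lake-relevant 0–40 °C. Activity corrections are omitted: at 20–35
mS/m the ionic strength is a few mmol/L and the correction is far
below sensor precision. Organic-matter alkalinity is likewise outside
the charge balance — no site-specific DOC charge model is assumed.
Minor ion pairs modelled by full speciation codes are noted but not
included; at this ionic strength their effect on CO₂ is well below the
tolerances used here.

The inverse problem (pH from alkalinity and CO₂) reduces to the single
positive root of the cubic
`H³ + Alk·H² − (K_w + K₁·CO₂)·H − 2K₁K₂·CO₂ = 0`
(one sign change ⇒ uniqueness). The scalar solver brackets it with
Brent's method in H-space — solving in H rather than pH avoids NaNs at
the feasibility edge where [HCO₃⁻] → 0; the vectorized solver used for
long sensor series runs 70 bisection steps on the same cubic, giving
pH to ~1e-12. A (pH, Alk) pair implying negative bicarbonate raises an
explicit chemistry-infeasible error; series-level computation excludes
and reports such points rather than dropping them silently.

Weekly lab alkalinity is upgraded to sensor cadence by OLS regression
on conductivity. Each lab value pairs with the nearest-in-time
conductivity reading (ties toward the earlier one); pairs more than
`max_gap_hours` (default 6 h) apart are discarded, and at least two
surviving pairs are required. The regression orientation is
`Alk [mM] = slope · conductivity [mS/m] + intercept`. With noisy
conductivity the OLS slope is attenuated relative to the generative
line (classical errors-in-variables); the fit's residual sd is
reported so users can judge the propagated CO₂ uncertainty.

## Synthetic scenarios

Real raw-water records of this kind are utility-restricted, so the
generator is first-class, tested code. One seeded configuration fully
determines the output (NumPy `SeedSequence` children per channel).
The weekly generative chain:

1. **Temperature** (°C): seasonal sinusoid with minimum in late
   January (mean 6.0, amplitude 5.5) plus an AR(1) anomaly (φ = 0.7,
   stationary sd 0.6), clipped at 0. Defaults keep ≈99.9% of values in
   the 0–12.5 °C band typical of a deep north-temperate lake intake.
2. **Alkalinity** (mM): slow AR(1) around 1.175 (φ = 0.99, sd 0.06) —
   mixing-driven drift, no seasonality.
3. **Conductivity** (mS/m): the alkalinity line inverted,
   `(Alk − intercept)/slope`, plus N(0, 0.4) scatter; defaults
   (slope 0.05 mM per mS/m, intercept −0.2 mM) put conductivity in the
   20–35 mS/m band.
4. **Algae** (cells/L): Gaussian pulses in log cell space, centred in
   late summer (one bloom/year at week 31 by default; multiple blooms
   spread over weeks 26–34), amplitude `log(peak/baseline)` with peak
   4×10⁶ and baseline 2×10⁵ cells/L. The pulse is **gated** on
   temperature three weeks earlier exceeding 8 °C (logistic, 0.75 °C
   scale), and warm/cold springs shift the bloom centre (−1.5
   weeks/°C of spring anomaly). This is the planted, genuinely lagged
   temperature → algae dependency a 7-week window can exploit.
   Multiplicative lognormal noise (sd 0.25 in log space) on top.
5. **CO₂** (mol/L): baseline 20 µM minus photosynthetic drawdown of
   12 µM per unit peak-normalized algae, plus N(0, 0.8 µM), floored at
   2 µM. The reported CO₂ channel carries additional observation
   scatter (0.8 µM) because in the real pipeline CO₂ is a derived
   quantity that inherits alkalinity-regression error, whereas pH is
   directly sensed (0.02 pH observation noise). This asymmetry makes
   the pH-bearing closed system slightly more stable than the
   CO₂-bearing one, as expected for a derived signal.
6. **pH**: solved exactly from (alkalinity, CO₂, temperature) via the
   carbonate module — so pH ↔ CO₂ ↔ algae are mutually informative and
   {temperature, pH} / {temperature, CO₂} are the recoverable closed
   systems. Defaults keep pH within 7.2–9.3.
7. **Turbidity / DOM**: independent AR processes by default (decoy
   role); a config switch weakly couples them to algae instead.
   **Decoy channels** are pure AR(1) noise with no causal link.

Weekly lab quantities are point samples at a fixed clock time (Monday
10:00), not weekly means. Sensor channels (default 5-min cadence)
interpolate the weekly latents, add instrument noise, and re-solve pH
from the carbonate system at sensor cadence so the high-resolution
chain is self-consistent; with all noise terms silenced the CO₂
recovered by the pipeline equals the planted CO₂ exactly.

**Calendar convention.** The modelling grid is 52 weeks per calendar
year, anchored at each year's first Monday; the 53rd Monday of long
years is skipped, leaving one deliberate 14-day lattice step at that
boundary (window samples never straddle it). `to_weekly` anchors rows
on the weekly-cadence lab timestamps mapped to a 7-day lattice and
averages sensor readings within each ±3.5-day bin.

What the generator does *not* emulate: nutrient (N/P) dynamics, species
succession, hydrodynamics, meteorological forcing, sensor drift and
fouling, or irregular lab schedules. Passing tests therefore
demonstrate that the pipeline recovers planted statistical structure of
the assumed form — not that any specific lake obeys that form.

## Dataset construction

Missing weeks are linearly interpolated across at most 2 consecutive
lattice positions (policy recorded on the table; a `drop` policy is
available). Windows flatten W = 7 consecutive weeks, lag-major and
factor-minor, of (year, month, day, algae, subset…); targets are
(algae, subset…) at horizon h = 1 week. Both W and h are configurable.
Date enters as three min-max-normalized numeric fields; window counts
for n contiguous rows are n − W − h + 1, and samples crossing a lattice
gap are excluded. Normalization is min-max on the **training years
only**; validation/application values may leave [0, 1] and are never
clipped (the model must face drift, not have it hidden).

## Network and training

One tanh hidden layer, linear output, minimizing the MSE pooled over
all outputs. Training is full-batch L-BFGS (scipy) with analytic
gradients — deterministic given (replicate seed, data,
hyperparameters), which the scan's reproducibility depends on.
Weights initialize uniformly in ±0.5 from the replicate seed. Defaults:
200 iterations, gradient tolerance 1e-7, no weight decay (available
via config). Early stopping is off by default; generalization is
handled by the separate validation year, not a held-out slice.
Sample order is immaterial up to floating-point summation order.
Non-finite losses raise a training-diverged error carrying the
iteration count; the scan records such conditions and continues.

## Scanning and selection

Condition seeds derive from a SHA-256 hash of (base seed, subset,
width, replicate), so the scan is exactly reproducible and resumable
from a partial ledger. The ledger holds one row per training with
integrated R²/MSE on training and validation plus per-factor validation
metrics. Integrated pooling uses per-factor means in SST
(`1 − ΣSSE_f/ΣSST_f`); pooling around a grand mean would inflate R²
through between-factor mean spread. Zero-variance target factors are
flagged and excluded from the pool with a warning.

Per subset, the best width is the argmax of mean validation integrated
R² (ties toward the smaller width); the output-factor count is reported
alongside so the empirical "width ≈ number of outputs" pattern can be
inspected rather than assumed. Ranking uses the replicate **mean** for
robustness, while the exported deliverable model is the single best
replicate, retrained deterministically from its stored seed.

The closed-system tolerance defaults to 0.01 validation-R² units: a
member must cost > 0.01 when removed, a non-member must gain ≤ 0.01
when added, both read from the scan's own neighbouring subsets (the
empty subset's score — SP — anchors singletons). A non-finite
tolerance disables the property check entirely, collapsing selection
to the pure ranking. When no subset passes, the top-ranked subsets are
returned with their property flags set false rather than hidden. The
ranking metric is integrated R² by default (an algae-only ranking is a
one-line change on the ledger); no formal lag-regression
Granger hypothesis test is performed — the criterion is a retention
heuristic over subsets, by design.

## Evaluation

Reports carry per-factor R² and native-unit RMSE per (method, factor,
period); for min-max scaling, native RMSE = normalized RMSE × (max −
min) exactly. Cells for factors a method does not model are present
and marked not applicable. Windows are built once over the full table
and assigned to periods by their **target** week's calendar year, so an
input window may legitimately begin in the preceding period.

Cell counts convert to chlorophyll-a equivalents at 35 µg/L per 4×10⁶
cells/L (midpoint of the observed 30–40 µg/L correspondence,
overridable), banded at 10 and 50 µg/L into safe / moderate / high.
The guidance band "low, with cyanobacteria dominance" requires
taxonomic composition that is not an input here and is folded into
moderate; the upper band is closed below (50.0 → high).

## Problem sizes

The shipped study uses five scenarios of eight years of weekly data
(416 rows; ≈250 training windows), a reduced grid of widths 1–5 with 3
replicates (960 trainings per scenario, ≈25–30 s each scan on one CPU),
a one-year monitoring gap with mild drift (+0.3 °C, +0.05 pH) before
the application year, and the full 1–10 × 10-replicate grid only for
combinatorial accounting. These sizes were chosen to make the whole
study reproducible on a laptop in minutes while leaving the planted
structure comfortably recoverable.

## Known limitations

* The carbonate model is dilute-solution, carbonate-only alkalinity;
  high-DOC or high-ionic-strength waters need a full speciation code.
* OLS alkalinity–conductivity slopes attenuate under conductivity
  noise; an errors-in-variables fit is not implemented.
* Selection evidence is correlational ranking, not causal inference;
  decoys are rejected because they fail to predict, which is weaker
  than demonstrating non-causality.
* Forecast horizon is a single week; multi-horizon joint forecasting
  is out of scope.
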