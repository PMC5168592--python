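# Methods

## Headspace gas balance

A batch bioreactor (1.5 L working volume, 2.3 L vessel) ferments glucose at
80 °C while the headspace is swept with O₂-free N₂. The model treats the dry
headspace as a single well-mixed, isobaric compartment of volume
*V* = *V*<sub>HR</sub> − *V*<sub>Steam</sub> (960 − 320 = 640 mL by default).
For each gas X ∈ {N₂, CO₂, H₂},

d*p*ₓᵒᵘᵗ/d*t* = (*Q*ₓ · *p*ₓ − *Q*ᵀᵒᵘᵗ · *p*ₓᵒᵘᵗ) / *V*,

with source purities *p*ₓ = 100 % (the carrier is pure N₂; the biological
gases enter as pure streams from the liquid), total outflow
*Q*ᵀᵒᵘᵗ = *Q*<sub>N₂</sub> + *Q*<sub>CO₂</sub> + *Q*<sub>H₂</sub>, and the
closure constraint that outlet fractions sum to 100 %. Assumptions: ideal
gas, isobaric at 1 bar, no pressure dynamics, instantaneous transfer of
produced gas to the headspace, and reactor feeding/emptying treated only as
run boundaries.

**Units and conversions.** Time is hours at the interfaces and minutes
internally; all flows are mL min⁻¹ at the headspace temperature (69 °C, the
median during a run). The carrier mass-flow meter reads at 20 °C, so its
record is expanded by (273 + 69)/(273 + 20) ≈ 1.167. Volumetric flows
convert to molar rates by the ideal gas law at 69 °C and 1 bar
(0.03515 mmol mL⁻¹); cumulative production is stated per litre of the 1.5 L
working volume.

**Water-vapour volume.** The pipeline carries a fixed
*V*<sub>Steam</sub> = 320 mL. `steam_volume_antoine` evaluates the standard
water Antoine parameterisation (8.07131, 1730.63, 233.426; mmHg/°C) as a
diagnostic; it yields ≈ 286 mL at 69 °C, somewhat below the fixed value.
The fixed constant is retained as the default because the derived quantities
depend on *V* only through the transient term, and the discrepancy is within
the uncertainty of the effective condenser-side volume; the function exists
so users can quantify the difference.

**Forward integration.** `simulate_headspace` integrates the three linear
ODEs with LSODA at rtol 10⁻⁸ (atol 10⁻¹⁰), with production flows held
zero-order between samples and a step cap at the sampling interval so
piecewise-constant inputs are resolved. The production grid must be finer
than the residence time *V*/*Q*ᵀ (≈ 10 min at typical flows).

**Setpoint controller.** The study's process regulated the carrier flow to
hold the outlet H₂ fraction at 5 % (35 mbar, below the growth-inhibitory
partial pressure of ~200 mbar). The control law here is the algebraic
steady-state feedforward *Q*<sub>N₂</sub> = *Q*<sub>H₂</sub>(100 − s)/s −
*Q*<sub>CO₂</sub> floored at the initial carrier flow (10 mL min⁻¹), passed
through a first-order filter with a 5 min time constant to mimic regulation
sluggishness. This reproduces the setpoint behaviour without inventing
feedback gains; under slowly varying production the simulated outlet H₂
stays within ±0.5 % absolute of the setpoint. A commanded flow below
15 mL min⁻¹ raises the emptying-trigger flag that ends a fermentation cycle.

**Inverse reconstruction.** With the temperature-corrected carrier flow
known, the N₂ balance gives *Q*ᵀ = (100·*Q*<sub>N₂</sub> − *V*·d*p*<sub>N₂</sub>/d*t*)/*p*<sub>N₂</sub>ᵒᵘᵗ,
and each product balance then yields
*Q*ₓ = (*V*·d*p*ₓ/d*t* + *Q*ᵀ·*p*ₓᵒᵘᵗ)/100. Derivatives are central finite
differences on the sample grid. When the accumulation term is negligible —
|d*p*/d*t*|·*V*/*Q*ᵀ below a tolerance — the quasi-steady-state solution
(derivative dropped) is used instead. The default tolerance is 0.005 % of
total pressure: the dropped term is bounded by tolerance·*Q*ᵀ/100 in flow
units, and this default keeps the switchover bias below 1 % of production
flows down to ~0.5 mL min⁻¹. For noisy records sampled every ~2 min a larger
tolerance (0.1) buys smoothness at the cost of transient fidelity; the
parameter is exposed. Negative reconstructed flows (noise) are clipped to
zero before integration, with the raw values retained for diagnostics.
Reconstruction is singular wherever the outlet N₂ fraction is zero.

**Dissolved CO₂.** At pH 7 a substantial CO₂ inventory stays in the liquid.
`total_dissolved_co2_correction` closes the budget with the carbonate
equilibria ([CO₂]aq = K₀·*p*CO₂; [HCO₃⁻] = K₁[CO₂]aq/[H⁺];
[CO₃²⁻] = K₂[HCO₃⁻]/[H⁺]; [H⁺] = 10^−pH) using K₀ = 0.0127 mol L⁻¹ bar⁻¹,
K₁ = 4.93·10⁻⁷, K₂ = 8.18·10⁻¹¹ at 80 °C. By default the correction is
applied once, as the inventory at run end; evaluating it along the pH/pCO₂
record for a continuous correction is equally possible and both modes are
reachable from the CLI. No activity corrections are made for the 20 g L⁻¹
NaCl medium, and no temperature interpolation of the constants is attempted.

## Fermentation accounting

Glucose dark fermentation by *T. maritima* produces acetate, H₂ and CO₂
(ideally 1:2:1 per the acetate pathway, up to the Thauer limit of
4 H₂/glucose), with lactate, L-alanine and extracellular polysaccharides
(EPS, assayed in glucose equivalents) as side products. Cell dry weight is
obtained from OD₆₀₀ at 330 mg L⁻¹ per unit and carries 50 % carbon (w/w);
the biomass elemental composition C₁H₁.₆O₀.₆N₀.₂S₀.₀₀₅ gives a formula-unit
mass of 26.18 g per C-mol from standard atomic masses.

**Carbon recovery.** Over a window, C¹ = 100 × [0.5·ΔX/12.011 + 3·Δlac +
2·Δacet + ΔCO₂]/(6·Δglu) with ΔX the produced dry weight in mg L⁻¹; C²
additionally counts 3·Δala + 6·ΔEPS. For serum-bottle cultures without an
off-gas train, CO₂ is taken as one per acetate (`co2_mode =
"acetate_stoichiometric"`); bioreactor runs use the measured (reconstructed
plus dissolved) CO₂.

**Windows.** Serum-bottle summaries run from inoculation to a sampling time
(t₀ → t); bioreactor growth-phase summaries run from growth onset to growth
end (t₁ → t₂). Both are explicit parameters. One subtlety found while
validating against the reference tables: the published cell-yield column
(cells/glucose, g mol⁻¹) is computed over the growth phase while the other
molar yields are cumulative from t₀; `molar_yields` therefore accepts a
separate `cells_window`.

**Specific rates.** q = (volumetric rate)/(X_lm/1000) with the logarithmic
mean X_lm = (X₂ − X₁)/ln(X₂/X₁) of the window-end biomasses. This averaging
is exact for exponential growth at constant specific rate — for
X = X₀e^{μt} and production rate qX, ΔP·μ/ΔX ≡ q — and it reproduces the
published specific rates (13.4, 18.5, 40.4 mmol g⁻¹ h⁻¹ …) where an
arithmetic mean does not. That agreement is what fixed the averaging choice.

**Cell yield on thiosulfate.** Below ~0.06 mmol L⁻¹ initial thiosulfate the
maximum cell density rises linearly with thiosulfate: growth is
sulfur-limited. `yield_on_thiosulfate` fits OLS (statsmodels) of maximum
cells on initial thiosulfate restricted to that range; the slope is
*Y*<sub>X/Thio</sub> in mg cells per mmol. On the four packaged means the
slope is 3732 mg mmol⁻¹, inside the published 3617 ± 176 band (the original
fit used replicate-level data that are not tabulated). The x-axis intercept
of the fit, ≈ −0.037 mmol L⁻¹, measures the thiosulfate-equivalent of the
sulfur nutrients contributed by 1 g L⁻¹ yeast extract (~0.03 mmol L⁻¹).

**Sulfur budget and detoxification.** Medium sulfur = 0.07 mmol organic S
per g yeast extract + 2 S per thiosulfate; cell sulfur = 0.005 S per C-mol
of biomass. The incorporation ratio S-cells/S-(YE + thio) comes out at ~35 %
for both reference conditions. Independently, reducing one thiosulfate to
sulfide consumes 4 H₂, so `thiosulfate_detox_capacity` bounds the H₂ a given
thiosulfate dose could sink — at 0.15 mmol L⁻¹ that is 0.6 mmol L⁻¹ H₂,
negligible against ~47 mmol L⁻¹ produced, which is the quantitative argument
that thiosulfate at low doses acts as a sulfur nutrient, not a detoxifier.

## Synthetic runs

The generator produces batch runs with the statistical and stoichiometric
structure the analysis assumes, not a mechanistic kinetic model:

* **Growth** is logistic, dX/dt = μ_max·X·(1 − X/K), toward a ceiling set by
  the sulfur inventory, K = X₀ + Y_X/Thio·(thio₀ + 0.03·YE). Defaults:
  μ_max = 0.25 h⁻¹ (growth-phase log-slopes of the reference runs span
  ~0.15–0.25 h⁻¹), Y_X/Thio = 3617 mg mmol⁻¹, X₀ = 25 mg L⁻¹, 60 mM glucose,
  1 g L⁻¹ yeast extract, 40 h horizon sampled every 0.25 h.
* **Glucose** consumption is growth-associated (cell carbon divided by its
  carbon fraction of the split) plus maintenance (0.3 mmol g⁻¹ h⁻¹). The
  carbon split over products is exhaustive — acetate-pathway (acetate + CO₂
  + 2 H₂ per acetate), lactate, alanine, EPS fractions with cell carbon as
  the remainder — so noiseless runs close the C² balance exactly, and with
  the alanine/EPS branches off the C¹ balance closes at 100 % with
  H₂/acetate = 2. Default fractions (0.58/0.25/0.05/0.06) land the yields in
  the observed ranges (acetate/glu ≈ 1, H₂/glu ≈ 2, cells/glu ≈ 9 g mol⁻¹).
* **Sulfur stress** shifts carbon from acetate to EPS linearly as thio₀
  falls below 0.06 mmol L⁻¹ (up to +0.20 of glucose carbon), mirroring the
  EPS up-shift of starved cultures.
* **Gas** rates are converted to volumetric flows and pushed through the
  headspace model under the closed-loop controller, producing an off-gas
  record for the inverse problem. If glucose runs out the fermentation stops
  and the run is flagged.
* **Noise** is multiplicative Gaussian (CV 0.05 by default, matching the
  published error bars), truncated at zero, applied to all measured channels
  (noisy cumulative glucose is re-monotonised; noisy gas fractions are
  renormalised to 100 %). The noiseless truth channels are always retained.
  A fixed seed makes output bit-reproducible.

What the generator does *not* emulate: dual-substrate Monod kinetics, pH/
NaOH titration dynamics, H₂ growth inhibition (beyond what the setpoint
controller prevents), autocorrelated sensor drift, or irregular sampling.
Passing tests on synthetic data therefore demonstrate correctness of the
accounting and inversion algebra under the stated stoichiometric structure,
not robustness to every artefact of real chromatography records.

The maximum-cell-density estimator used in parameter-recovery experiments
reads the measured value at the growth-end marker rather than the running
maximum of all samples; the running maximum of a noisy plateau is biased
high (by ~2 standard deviations over ~100 samples), while the marker read is
unbiased.

## Numerical choices and edge cases

* ODE integration: LSODA, rtol 10⁻⁸, atol 10⁻¹⁰, max step = sampling
  interval. Everything outside the noise model is deterministic.
* Outlet series validate the sum-to-100 closure (tolerance 2 % for measured
  records, 0.01 % for simulated ones) and reject fractions outside [0, 100].
* Window quantities interpolate linearly between samples; windows of zero
  duration, zero glucose consumption, zero biomass at a window end, or an
  all-NaN column are signalled as errors rather than returning NaN.
* The log mean falls back to X₁ when X₂ = X₁.
* OLS with fewer than two in-range points or zero predictor variance is
  rejected; the slope standard error is NaN for exactly two points.
* Reference-table regression tests compare at one unit in the last printed
  digit, slightly widened where recomputation from rounded raw cells cannot
  land closer (documented per test).

## Known limitations

* The published ± uncertainties are not propagated; only means are carried.
* Carbonate constants are fixed-temperature; no interpolation.
* The controller is feedforward from known production rates; reconstructing
  controller behaviour from a measured record is not modelled.
* Sulfide chemistry (H₂S stripping, detection) is out of scope; the detox
  capacity is a stoichiometric bound only.
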