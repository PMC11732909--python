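# Methods

## Clumped-isotope thermometry

Temperature inverts Δ47 = a/T² + b with a = 0.0391×10⁶ ‰·K² and
b = 0.154 ‰ (the unified carbonate calibration on the I-CDES scale,
statistically indistinguishable from bioapatite-specific calibrations);
both constants are configurable so alternative calibrations can be
swapped in. The inversion is undefined at Δ47 ≤ b and raises rather than
returning an imaginary temperature.

**Uncertainty.** Temperature SE uses first-order (delta-method)
propagation, |dT/dΔ47|·SE(Δ47) with dT/dΔ47 = −½√a·(Δ47−b)^(−3/2); a
central finite-difference half-range mode is provided as a cross-check
and agrees within 5% for SE ≤ 0.01 ‰. Published per-sample temperature
SEs in this literature are sometimes smaller than delta-method
propagation of the printed Δ47 SE (the propagation convention is rarely
stated); we therefore treat reported SEs as indicative, not as exact
targets.

**Standards correction.** Replicates are corrected with a single affine
measured→accepted OLS fit over a moving window of up to 10 standards on
either side of the sample in the analytical sequence. This is a
one-stage analogue of the two-stage nonlinearity + scale-transfer
reduction used by dedicated reduction software; when standards span the
sample range, the fitted slope/intercept carry equivalent diagnostic
content and an affine instrument distortion is inverted exactly.

**Coverage and small n.** With n = 4 replicates, an SE estimated from
the sample SD makes (mean − truth)/SE t(3)-distributed, and nominal
2-sigma intervals cover only ~86% of the time — a small-sample property
of the SE estimate, not a defect of the calibration. Calibration
coverage checks in the test suite therefore evaluate intervals at the
known simulation noise level (sd/√n), where 2-sigma coverage is the
normal ~95%. Users quoting mean ± 2·SE from 3–5 replicates should apply
a t-multiplier instead.

**Water δ18O.** Formation-water δ18O uses the carbonate–water
fractionation 1000·ln α = 18.03·(10³/T_K) − 32.42 applied to carbonate
δ18O converted to V-SMOW (δ_SMOW = 1.03091·δ_PDB + 30.91). A
phosphate-thermometry strategy (T = 117.4 − 4.50·(δp − δw), inverted) is
selectable for phosphate-moiety inputs. The carbonate expression is the
default because it reproduces fossil-tooth water values within their
reported SDs; water δ18O should nevertheless be treated as approximate —
candidate fractionation expressions differ at the few-tenths-per-mil
level.

**Δ48 screen.** Mean Δ48 strictly above a configurable threshold
(default 1.0 ‰) flags isobaric contamination (typically residual
organics); such samples can carry implausible Δ47 temperatures even when
trace-element screens are clean.

## Diagenesis screening

The REE index is Σ PAAS-normalized lanthanide concentrations in
orthodentine divided by the same sum in cortical bone. Normalization
uses the Taylor & McLennan (1985) PAAS table shipped as a versioned
fixture (users may supply their own reference); because the index is a
ratio of normalized sums, small differences between PAAS compilations
cancel almost entirely. Elements measured in only one tissue are dropped
from both sums (pairwise, with a logged count); non-REE analytes
(Ca, Sc, Sr, Y, Ba, Pb, U, In) are parsed but excluded.

Classification: ratio < 0.35 minimal; 0.35–0.5 low; 0.5–1.0
mild-to-moderate (1.0 inclusive); > 1.0 significant alteration. The
boundary placement follows the usage of the index in the fossil-tooth
literature, where values like 0.42 and 0.86 are altered-but-acceptable
and values near 0.02 are effectively pristine. The carbonate–phosphate
δ18O offset screen uses a closed interval, default 7–10 ‰; the
extant-vertebrate band is dataset-dependent and must remain
configuration.

## Metabolic scaling

* Xenarthran law: BMR = 3.14 M^0.69, M in grams, ml O₂ h⁻¹, converted
  to watts with a 20.0 J ml⁻¹ oxyjoule equivalent (standard mixed-fuel
  value; configurable). This reproduces the 4,490 kg daily lower bound
  of 58,646 kJ day⁻¹ to 0.01%.
* Placental (Kleiber-form) law: BMR = 3.3 M^0.76, M in kg, output taken
  directly in watts (as presented in the comparative literature; no
  respiratory-quotient adjustment).
* FMR = activity multiplier × BMR, default multiplier 2.
* Daily comfort bounds: BMR and FMR in kJ h⁻¹ × 24 (lower = BMR·86.4
  kJ day⁻¹ per W).

For the three larger genera, published daily-bound figures are ≈1.1%
above what the stated masses and law produce; the masses actually used
in those original simulations evidently differed slightly. We compute
from the stated masses and do not reconcile.

## Heat-balance model

**Geometry.** Prolate spheroid of body density 1,000 kg m⁻³ and
length:diameter ratio 2 (both configurable); volume is exactly
mass/density, surface area by the closed form, characteristic dimension
= trunk diameter. This replaces sculpted 3-D meshes with an analytic,
mass-consistent shape; absolute areas are a little lower than a real
sloth's (limbs and head omitted), which shifts critical temperatures by
a few degrees but preserves all orderings.

**Fur.** Coat conductivity k_eff = k_air + (k_hair − k_air)·f with
fiber volume fraction f from hair density and diameter (defaults:
100 µm hairs, k_hair = 0.209, k_air = 0.0257 W m⁻¹ K⁻¹); radiative
transport within the coat is folded into k_eff rather than modelled
separately (defensible for ≤ 50 mm coats much thinner than the trunk
radius). Only the immobilized fraction of the coat insulates: the
fraction is min(1, L/s) with s = density^(−1/2) the mean inter-hair
spacing and L = 0.2 mm the spacing at which inter-hair air is fully
still. Dense coats (1,300–2,000 cm⁻²) insulate ~70–90% of their depth;
sparse coats (0.07–8.5 cm⁻²) a few percent, making them nearly bare
skin — without this, a sparse coat would absurdly insulate like a slab
of pure still air. The conduction slab uses the spheroid area at coat
mid-depth.

**Surface exchange.** Convection: cylinder-in-crossflow
Nu = 0.35 + 0.56·Re^0.52 with dry-air k and ν at film temperature
(linear fits to standard tables), floored at the conduction limit
Nu = 2. Thermal IR: ε = 0.95 against the environment's radiant
temperature. Solar: absorptivity 0.8 × silhouette interception 0.25 ×
(1 − shade). Skin is taken at core temperature (well-perfused);
evaporation is a fixed fraction (default 0.05) of heat production —
active panting/sweating is not modelled, so upper critical temperatures
follow purely from the ≤ 0.95·BMR criterion.

**Solution.** The fur-surface temperature solves the surface balance by
Brent root-finding (strictly monotone residual; bracket expanded to
±200 K before failing with a flux dump); closure residual is well below
0.1 W. Negative required production is returned flagged infeasible: the
animal would need heat-loss mechanisms beyond this model. A
heterothermic mode relaxes the core set point within a tolerated range,
picking the value that brings production closest to basal.

**Thermoneutral zone.** The chamber protocol holds wall temperature
equal to air, wind 0.1 m s⁻¹, no sun. The gridded sweep (default 0.5 °C
over −60…50 °C) reports the contiguous band where
|M_req − BMR| ≤ 0.05·BMR; a continuous variant root-finds the two band
crossings directly and is preferred for ordering comparisons, since
grid quantization can tie configurations that differ by less than a
step. Absolute critical temperatures from any such model depend
strongly on the exchange coefficients; published values for these taxa
are treated as directional anchors (orderings, signs), not exact
targets.

## Microclimate and daily budgets

One representative day (the 15th) per month, same weather every day of
the month. Air temperature: two half-cosine segments anchored at the
sunrise hour (minimum, from latitude and solar declination) and 14:00
(maximum), so both extremes are attained exactly; paleoclimate enters
as an additive monthly offset. Solar: S₀·0.7^airmass·cos z·(1 −
0.75·cloud) with airmass capped at 38. Sky: Idso–Jackson clear-sky
emissivity ε = 1 − 0.261·exp(−7.77×10⁻⁴(273 − T_K)²), cloud filling the
emissivity gap linearly. The radiant environment mixes sky (view factor
0.5) with ground at air temperature; shade swaps sky view for canopy at
air temperature and scales direct solar.

Each hour the animal chooses between the locality's minimum-shade and
maximum-shade microhabitats, keeping the option with production closest
to basal. Hours requiring negative production integrate as zero and are
counted as heat-load hours. Daily energy is the trapezoidal integral of
the periodic 24-h trace; classification: above the FMR bound = cold
stress, below the BMR bound = heat stress, else comfort. Active hours
count the hours whose *minimum-shade* requirement is ≥ 0.95·BMR, i.e.
hours the animal can hold basal output in full sun without suppression;
the 0.95 threshold mirrors the chamber's lower band edge (the
literature states no explicit threshold). Annual summaries select, per
locality, the fur configuration with fewest stressed months, breaking
ties toward the thinner then sparser coat.

The below-ground substrate balance of full microclimate models (soil
heat diffusion, burrows, snow) is out of scope; air-level drivers are
generated directly.

## Foraging

Wet intake = daily kJ / (gross energy × digestibility) /
dry-matter fraction. Default leaf diet: 18 MJ kg⁻¹ DM gross energy,
digestibility 0.45, dry-matter fraction 0.30 — typical browse values,
editable; absolute intake magnitudes depend entirely on these feed
parameters and are not treated as targets. Monthly series are fitted
with OLS quadratics; R² is defined as 0 for constant data.

## Synthetic data

Generators emulate the real inputs with known truth: Δ47 replicates are
normal around the calibration's forward value (normality is an
assumption; the source data state only SDs), concentrations are
lognormal (non-negative support), REE tables are constructed to hit a
requested dentine:bone index exactly, standards runs apply a known
affine distortion recoverable to numerical precision, and climate
regimes (tropical/temperate/cold) produce 12-month series with
latitude-scaled seasonality inside realistic envelopes (tropical months
stay within ~2–30 °C for tropical latitudes, |lat| ≤ 30). All
randomness flows through explicit integer seeds; outputs are
bit-reproducible per seed.

What passing synthetic tests does *not* show: real replicate noise can
be non-normal and autocorrelated within a run; real climates have
day-to-day weather variance, which monthly-sinusoid forcing smooths
away (narrowing the simulated stress extremes); and the heat-balance
exchange coefficients are literature defaults, not fitted to any
captive-animal measurement.

## Problem sizes

Default problem sizes keep everything desk-scale: 1,000-draw closure
and coverage checks, 221-point chamber sweeps, and the full factorial
of 4 taxa × 6 fur configurations × 3 localities × 12 months (864
simulated days, ~41k heat-balance solves), which completes in a few
seconds on one core.

## Known limitations

* Steady-state only; no thermal inertia, regional heterothermy, or
  respiratory water budget.
* No evaporative escalation, so heat-stress classifications are
  conservative (an animal that could sweat would tolerate more).
* Analytic geometry underestimates surface area relative to full-body
  meshes; critical temperatures shift accordingly.
* The fur immobilization length (0.2 mm) is an order-of-magnitude
  physical choice, not a fitted parameter; it controls how sharply
  insulation collapses with coat sparseness.
* Water-δ18O estimates inherit the fractionation-equation ambiguity
  noted above.
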