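# Methods

This note documents the model behind `bsfplant`, its assumptions, the
parameters that matter, and the choices made where the design was open.

## Scope and modelling philosophy

The package simulates one plant: a batch facility converting black soldier
fly larvae into four fatty-acid products, a dried protein by-product, and
ash/cellulose wastes, then assessing its 20-year economics.  All unit
operations are *split-factor* models — each outlet receives a fixed,
parameterized fraction of each inlet component.  This is deliberate: the
quantities the model is asked to reproduce (bulk material balances, batch
counts, waste/product splits) are linear in the feed, and split factors make
mass conservation provable to machine precision rather than a convergence
outcome.  Nothing in the package performs vapor–liquid equilibrium,
reaction kinetics, or equipment sizing beyond membrane area.

## Composition model

A feed scenario is a proximate row: dry matter (% of wet mass) plus ash,
crude protein, NDF, ADF, ether extract and organic matter (% of dry
matter), each with an SD.  Because the analytes overlap (organic matter
subsumes protein/fiber/fat; ADF ⊂ NDF), only {ash, crude protein, NDF,
ether extract} become simulation components, renormalized over their own
sum S to fill the dry matter exactly; NDF stands in for cellulose, ether
extract for crude fat.  ADF and organic matter are carried for reporting
only.  The renormalization is robust to rows whose analytes sum slightly
past 100 (independent assays routinely do; the spent-grain row reaches
112.5, and the validation bound is set at 120 to accept real rows while
still catching corrupt input).  The chicken-manure row's organic matter
(59.8 vs 84–90 elsewhere) is internally inconsistent with its other
analytes; it is carried as-is since organic matter does not enter the
simulation components.

Crude fat is split over lauric/myristic/palmitic/stearic acid by a
configurable profile.  Measured profiles per rearing substrate are not
available as numbers, so the default is lauric-dominant
(0.50/0.20/0.20/0.10) — lauric acid is the plant's lead product (the first
and most heavily refluxed tower is the lauric tower) and black soldier fly
lipid is characteristically lauric-rich.  The profile is a per-scenario
config knob, not a claim.

## Unit operations

| Unit | Model | Key parameters (defaults) |
|---|---|---|
| WSH-101 washer | fixed removal fractions; all wash water exits with the waste | 66% ash, 38% cellulose removal; 20,000 kg wash water/batch |
| GR-101 grinder | composition-preserving; duration = mass/throughput | 9,174 kg/h |
| BR-101 reactor | adds enzyme + dilution water; relabels a conversion fraction of protein as hydrolyzed (same mass) | 100 kg alcalase, 15,000 kg water, conversion 0.9, 60 °C |
| MF-101/102, UF-101 membranes | rejection fraction of one target solid to the retentate; 5% of crossing protein relabelled denatured; area = volumetric flow / flux | rejection 0.999, flux 20 L/m²·h, max density 1100/1200 g/L |
| DC-101 centrifuge | component → {light, heavy, aqueous} routing; water split fractions; optional fat carryover to the cake | water: 0.2% to oil, 8% to cake; carryover 0 |
| C-101/102/103 towers | sharp split at a cut temperature between adjacent boiling points; duty = (R+1)·D·λ | cuts 310/335/352 °C; reflux 14.404/1.186/0.984 |
| HX condensers | total condensation + sensible cooling to 80 °C | λ, Cp from the component registry |
| GAC-101 adsorber | all water (plus backwash) leaves as reusable water | backwash ≈ 1,058 kg/batch |
| FDR-101 freeze dryer | dries the cake to a target moisture; duration = tray depth / sublimation rate | 5% moisture, 10 mm/h, 10 mm tray |
| P-11 transport | pass-through; counts 20 t shipments | — |

Design choices worth recording:

- **Retained water in membrane retentates.** The sources give a maximum
  retentate density but no water split, so the default retains the
  *minimum* water that keeps the rejected solids at or below that density
  (solving solids/(V_water + V_solids) = c_max with component densities:
  water 1,000, oils 900, solids 1,500 kg/m³).  An explicit
  `retained_water` override is checked against the density limit and logs
  an infeasibility warning rather than failing.
- **Centrifuge water splits.** The expected stream contents place water in
  both the wet protein cake and the oil phase, but a pure component→outlet
  map cannot do that, so the unit takes two water split fractions.  The
  defaults (0.2% to oil, 8% to cake) make the downstream adsorber and
  freeze dryer do real work while keeping the aqueous stream dominant.
- **Stearic bottoms as vapor.** In a sharp split the bottoms are liquid,
  but the plant's stream table carries stearic acid to its condenser as a
  vapor; the last tower therefore sets `bottoms_phase="vapor"` (its
  reboiler fully vaporizes the single-component bottoms), and the strict
  vapor-only contract of the condenser is preserved everywhere.
- **Unit order.** Wash → grind → react was chosen over the alternative
  grind-after-incubation reading of the stream table, matching the
  process-section narrative (mechanical pre-treatment, then reaction, then
  separation); and condense-then-adsorb was chosen for the lauric cut.
- **Temperatures and pressures** are stream metadata only; they never
  alter a mass split (no VLE).  Tower temperatures near the products'
  boiling points are carried for reporting.
- **Energy.**  Latent heats (water 2,257; fatty acids 200 kJ/kg) and heat
  capacities (2.1 kJ/kg·K for organics) are handbook-order defaults in a
  configurable registry.  Duties exist to drive consumable costs; they are
  config-dependent estimates and are not treated as reproducible outputs.

## Scheduling

`n_batches(T, t_b, t_c) = floor((T − t_b)/t_c) + 1`: the first batch
occupies its full batch time, each further batch adds one cycle time.  With
the defaults (T = 7919 h — 330 days, leaving maintenance downtime;
t_b = 7.25 h; t_c = 2.75 h) this gives 2,878 batches/yr.  An annual window
of 7920 h gives the same count; 7919 h is kept as the canonical default.
The default recipe assigns the main stages one hour each in sequence with
sub-hour transfer steps downstream; only the 7.25 h batch time and 2.75 h
cycle time are schedule-defining — the individual offsets are a fixture.
The Gantt builder proves conflict-freedom: intervals on one unit across
staggered batches cannot overlap iff every operation's duration is at most
the cycle time, and the builder checks both the condition and (in tests)
the expanded intervals.

The per-batch water row of the bulk balance (36,058.03 kg) is the sum of
the wash, dilution and backwash inputs; the three-way split (20,000 /
15,000 / ~1,058 kg) is a configuration choice — only the sum is
balance-defining, corresponding to an annual water demand of 103,775,015 kg
over the 2,878-batch campaign.

## Economics

Gross profit = product revenue − (enzyme + waste fees + steam + cooling
water + electricity + membrane replacement).  Consumables are derived from
the simulation: steam covers reboiler duties at 2,100 kJ/kg; cooling water
absorbs condenser duties over a 10 K rise; electricity covers grinding
(0.02 kWh/kg) and freeze-drying (1 kWh/kg water sublimed); membrane area is
amortized over a 100-batch life.  The cash-flow series is −capital in year
0 and the constant (optionally taxed) profit for 20 years; the 6% flat tax
applies to positive gross profit only — no depreciation shield, no loss
credits, matching the flat-tax description.  NPV is the discounted sum;
IRR is found by a deterministic scan-and-bisect root search of NPV on
(−0.999, 10], refined to interval convergence, returning None (reported as
−100%) when NPV never changes sign.

Product prices, fees, tariffs and the capital cost are **not** published
quantities; the shipped defaults (fatty acids 1.8–2.4 /kg, protein meal
0.8 /kg, alcalase 6 /kg, waste fee 0.05 /kg, capital 60 M) are plausible
market-order values and every economic output is conditional on them.
Absolute IRR/NPV values are therefore not reproducible figures; what the
model does reproduce robustly is the *ordering* (fat-rich kitchen-waste
larvae profitable, the low-fat control plant unprofitable with a −100%
IRR) and the structural properties (NPV strictly decreasing in rate,
NPV(IRR) = 0, after-tax IRR ≤ before-tax IRR).  One caveat: the
kitchen-waste > control profit ordering holds across market-range product
prices with realistic waste fees, but is not a theorem for *arbitrary*
non-negative price sets — with all product prices at zero and a positive
waste fee the fat-rich plant pays more disposal and loses the comparison.

## Synthetic scenarios

The sampler draws each proximate analyte independently from a normal with
the row's mean and SD, truncated to [0, 100]; rows failing composition
validation are redrawn (deterministically under the generator state).  The
± values are treated as SDs.  No covariance between analytes is published,
so draws are independent — real proximate analytes are negatively
correlated (they compete for the same dry matter), which the sampler does
not emulate; sampled rows are therefore somewhat over-dispersed in their
sums.  Prices are perturbed log-normally with σ² = ln(1 + CV²) and mean
correction, keeping them positive and unbiased.  Passing tests on these
synthetics demonstrate the pipeline's arithmetic, determinism and
monotonicity; they do not validate the biology of substrate → composition
(out of scope) nor market price dynamics.

## Numerical choices and problem sizes

- Mass-closure tolerance 1e-9 relative per unit and plant-wide; split-factor
  arithmetic typically achieves ~1e-16.
- Fraction-sum tolerances 1e-9; renormalization round-off is absorbed into
  the water fraction so sums are exact.
- Sharp-split cut temperatures must lie strictly between boiling points;
  a cut hitting a boiling point is an error, an empty distillate or bottoms
  a recorded warning (and an all-empty unit input is passed through as
  empty outputs, so an empty plant feed propagates without error).
- IRR: 200-point bracket scan, ≤200 bisections, no derivatives.
- Report CSVs fix masses to two decimals (with thousands separators for
  annual totals); the in-memory report stores the same rounded values so a
  write/read round trip is bit-exact.
- Test/verification problem sizes: 1,000 random feeds for closure, 1,000
  random cash-flow series for NPV(IRR)=0, 10,000 draws for sampler
  calibration (3-SE band), 200 sampled scenarios for the fat-in/fat-out
  regression, the full 2,878-batch campaign for Gantt conflict-freedom.
  All complete in seconds.

## Known limitations

- Sharp splits ignore azeotropes, relative-volatility limits and tray
  efficiency; the separation is idealized.
- Hydrolysis is bookkeeping (relabelled mass), not kinetics; conversion is
  an input.
- Consumable demands are linear surrogates, not rigorous utility balances.
- Economics are conditional on the configured price set; no working
  capital, depreciation or salvage value.
- The composition sampler ignores analyte covariance (see above).
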