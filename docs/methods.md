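# Methods

## Model

The package computes annual farm-scale nutrient balances by mass
conservation: every budget is an ordered ledger of named input and output
terms in kg of nutrient (N or P) per year, and the balance is the input
total minus the output total. Three system boundaries are implemented.

**Current gross nutrient balance (GNB).** The boundary is the extended
soil surface including the barn and manure management system. Inputs:
chemical fertilizer, raw livestock manure, net manure import/export,
organic fertilizer, biological N fixation (N only), atmospheric
deposition, planting materials. Outputs: crop harvest, fodder production,
crop residues. Raw manure nutrient input is herd size × per-head daily
excretion × 365 × manure nutrient content, plus the bulking agent's
contribution.

**Ideal GNB.** As above, plus crop residues on the input side and soil
nutrient stock changes on the output side. For nitrogen the gross surplus
is decomposed: the loss before soil application is
`N_NLB = N_man − N_com` (what disappears during solid–liquid separation
and composting), the loss after application is
`N_NLA = N_vol + N_den`, and the hydrologic surplus is the gross surplus
minus the atmospheric one.

**Soil system budget (SSB).** The boundary is the soil. The manure input
is replaced by the two compost streams actually applied — for each phase
(liquid, solid), `production × content/1000 × LC`, where `LC` is the
loading flux, the fraction of the stream's nutrient content that survives
the treatment method and reaches the soil — and mineralization is
carried as a component. Outputs add the loss pathways from soil: NH₃
volatilization and denitrification (N only; fractions of fertilizer and
compost inputs plus an area-proportional arable term), and leaching and
runoff as fractions of the same-nutrient total SSB input, plus
immobilization.

Components excluded for lack of data on the case-study farms (crop
residues, mineralization, fodder production, immobilization, manure
trade, organic fertilizer) are carried as explicit zero-valued ledger
terms, so every budget is structurally complete and the component lists
of the three approaches remain comparable.

### aGNS conventions

The decomposition formula states aGNS = N_NLB + N_NLA, but the published
budget sheets this package reproduces tabulate aGNS as N_NLB alone, with
hGNS following from it. Both conventions are implemented;
`table_consistent` (N_NLB only) is the default, and
`with_post_application` applies the formula literally. The two coincide
whenever there are no post-application atmospheric losses.

## Parameters and units

All masses kg, areas ha, contents g/kg (divided by 1000 before
multiplying kg masses — the only convention consistent with the
case-study sheets), fractions dimensionless in [0, 1]. A year is 365
days. Key coefficients in the bundled case-study flux table:

| coefficient | value | unit |
|---|---|---|
| seed input, sesame / corn (N) | 0.4 / 4.4 | kg/ha/yr |
| seed input, sesame / corn (P) | 0.7 / 1.1 | kg/ha/yr |
| biological N fixation | 15.0 | kg/ha/yr |
| atmospheric deposition N / P | 24.1 / 0.59 | kg/ha/yr |
| volatilization: fertilizer / compost | 14 / 23 | % |
| denitrification: fertilizer / compost / arable | 15 % / 13 % / 3.0 kg/ha/yr | |
| leaching N / P | 26.5 / 35.3 | % of total input |
| runoff N / P | 15.0 / 7.4 | % of total input |
| manure content N / P | 8.5 / 1.5 | g/kg |
| liquid compost content N / P | 8.0 / 0.4 | g/kg |
| solid compost content N / P | 9.6 / 3.6 | g/kg |
| liquid loading N: storage / IA / CA | 0.67 / 0.52 / 0.26 | – |
| liquid loading P: storage / IA / CA | 0.91 / 0.15 / 0.08 | – |
| solid loading N: T / TA | 0.69 / 0.48 | – |
| solid loading P: T / TA | 0.94 / 0.96 | – |

Provenance caveats, recorded in `farmbudget.datasets`: the manure
contents and the storage-only loading fluxes are back-derived from the
published sheets (each value reproduces every relevant printed row at one
decimal); the solid-compost P loadings are assigned the way the sheets
and the stated 2.1 % efficiency difference require. Crop harvest
exports, soil stock changes, and fertilizer nutrient inputs are stored as
resolved per-farm constants because the underlying per-crop contents are
not published; rate-based computation paths exist and take over whenever
contents are supplied.

Two further readings were fixed where sources disagree internally: farm
3's liquid compost production uses the management-table value
(2,668.9 × 10³ kg/yr) rather than the narrative's 2,668.7 × 10³, and the
bulking-agent term in the compost equations is interpreted as
mass × content/1000 (content defaulting to 0) rather than a bare mass
addend, which would be dimensionally inconsistent and contradicts the
published solid-compost rows.

## Synthetic data generator

`farmbudget.synthetic` draws farms with the same multiplicative
structure the budgets assume. Defaults mirror the case-study conditions:
herds uniform on 700–1,800 head, excretion fixed at the national
coefficient 5.1 kg/head/d, 1–3 plots of 0.66–1.65 ha of sesame or corn,
liquid and solid compost masses sampled as 0.85–0.95 and 0.05–0.12 of
manure mass (independently — their sum may exceed 1, as it does on real
farms, via bulking agent and moisture change). Every flux-table
coefficient is sampled per farm from intervals centred on the case-study
values, and everything sampled is stored in a truth record together with
plain-arithmetic soil-system terms for oracle comparisons.

Randomness is a numpy `default_rng` seeded with the pair
`(seed, farm index)`, so each farm is a counter-based substream and
cohorts are reproducible regardless of generation order.

What the generator does *not* emulate: correlations between herd size
and arable area, seasonality, measurement error in the census data, and
any feedback of soil state on losses. Passing tests on synthetic cohorts
therefore demonstrate the accounting structure (identities, linearity,
coefficient recovery), not predictive validity for real farm
populations.

## Numerical choices

* All ledger sums use `math.fsum` (correctly rounded), so totals are
  independent of term order and oracle re-summations match bit-for-bit;
  `surplus` is defined as `inputs.total − outputs.total` and is exact by
  construction, while the rearranged identity `hGNS + aGNS = GNS` holds
  to one unit in the last place of double rounding.
* Comparisons against printed sheet values use 0.5 % relative tolerance
  with a floor of half a unit of the last printed digit, because the
  sheets round every intermediate to one decimal before summing; the
  engine itself always carries full precision. The published
  suggested-scenario sheets were evidently computed from unrounded
  intermediates and are reproduced to the same 0.5 %; their printed
  N-surplus reductions are internally inconsistent with the baseline
  sheets by up to ~1 percentage point, so those are matched at ±1.5
  points (P reductions at ±0.5).
* Display rounding in reports is half-up to one decimal (sheet style) in
  a companion column; machine-readable values are full precision and
  never carry thousands separators.
* Degenerate inputs: a farm with no solid facility contributes an exact
  zero solid-compost term; zero compost production short-circuits before
  coefficient lookup, so flux tables only need coefficients for
  (phase, method) pairs a farm actually uses — validation checks exactly
  that coverage.

## Design choices

* Budgeting is plain deterministic accounting, so the API is functions
  over frozen dataclasses (`compute_budget`, `compare_scenarios`, …)
  rather than stateful estimator objects; the CLI is a thin click layer
  over the same functions.
* P leaching/runoff fractions are applied to the P input total (the
  loss-equation notation is ambiguous on this; the sheets are not).
* The GNB-vs-SSB surplus ratio pools the two GNB approaches by default;
  per-approach ratios are available separately.
* Scenario analysis replaces treatment methods while holding production
  amounts fixed — it reroutes the same streams, it does not re-model the
  composting mass balance.

## Problem sizes

The bundled analyses are desk-scale: three farms × two nutrients × three
approaches. The test suite exercises synthetic cohorts of 50–1,000 farms
(identities, recovery, oracle equivalence); the full suite runs in a few
seconds on one CPU.

## Limitations

No process-based emission modelling (losses are fixed fractions), no
moisture/mass balance of the composting process itself, no struvite
chemistry, no correction of atmospheric losses for odor-capture
facilities, and no economics of treatment choice. Flux coefficients are
taken as given from the literature table; their uncertainty is not
propagated.
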