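# farmbudget

Farm-gate nitrogen and phosphorus budgeting for mixed crop-swine farms,
with explicit handling of on-farm manure treatment (solid–liquid
separation followed by solid and liquid composting, as practised in
Korea).

Nutrient budgets rest on conservation of mass: for a chosen system
boundary, the balance is

```
SP = Σ inputs − Σ outputs        [kg nutrient / yr]
```

with a positive balance (surplus) indicating potential loss to the
environment. The package implements three boundaries side by side:

* **current GNB** — the OECD gross nutrient balance. Raw livestock manure
  (`N_man = AH·D·C_man + BA·C_bed`) counts as an input; crop harvest is
  the only output.
* **ideal GNB** — adds soil nutrient stock changes
  (`ΔN_soil = (N_2017 − N_2016)·A`) on the output side and, for N,
  decomposes the gross nitrogen surplus into an atmospheric part
  (aGNS, dominated by `N_NLB = N_man − N_com`, the loss during
  composting) and a hydrologic part (`hGNS = GNS − aGNS`).
* **SSB** — the soil system budget. Only what actually reaches the soil
  enters: solid and liquid compost
  (`N_c = production · C · LC`, with `LC` the phase- and
  treatment-specific loading flux), and the outputs include NH₃
  volatilization, denitrification (N), leaching and runoff
  (`N_leach = N_input · L`, etc.).

Shared input terms are seed/planting material (`Seed·A`), chemical
fertilizer, atmospheric deposition (`AD·A`) and, for N, biological
fixation (`BNF·A`). A scenario comparator recomputes SSB budgets under
alternative treatment methods (e.g. switching liquid composting from
intermittent to continuous aeration) and reports surplus reductions.

The package ships the three-farm Korean case-study dataset (herds of
700–1,800 head on 0.66–3.3 ha of arable land) and a synthetic-farm
generator with the same multiplicative structure for property testing.

## Worked example

```python
from farmbudget import (case_study, compute_budget, compare_scenarios,
                        Approach, Nutrient)

farms, fluxes = case_study()
farm1 = farms[0]

budget = compute_budget(farm1, fluxes, Nutrient.N, Approach.SSB)
print(f"total N inputs : {budget.inputs.total:9.1f} kg/yr")
print(f"total N outputs: {budget.outputs.total:9.1f} kg/yr")
print(f"N surplus      : {budget.surplus:9.1f} kg/yr")

cmp = compare_scenarios(farm1, fluxes, liquid_method="continuous_aeration")
print(f"P surplus reduction under continuous aeration: "
      f"{cmp.reduction_pct[Nutrient.P]:.1f} %")
```

prints

```
total N inputs :    5065.2 kg/yr
total N outputs:    3943.9 kg/yr
N surplus      :    1121.2 kg/yr
P surplus reduction under continuous aeration: 47.6 %
```

That is: of the ~5.1 t of N reaching farm 1's soil each year (mostly
liquid compost), ~3.9 t leaves again through leaching, volatilization,
runoff, denitrification and harvest, leaving a 1.1 t/yr soil-system N
surplus; switching the liquid composting aeration regime from
intermittent to continuous would cut the P surplus by about half.

The same computations are available from a shell:

```sh
farmbudget fixture --out configs/
farmbudget compute --farm configs/farm1.yaml --fluxes configs/fluxes.yaml \
    --approach all --nutrient both --out farm1_budget.csv
farmbudget scenario --farm configs/farm1.yaml --fluxes configs/fluxes.yaml \
    --liquid ca --out farm1_scenario.csv
farmbudget loading-table --farm configs/farm2.yaml --fluxes configs/fluxes.yaml
```

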