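"""Manure-treatment scenario analysis.

Quantifies the nutrient loading each available treatment method would put
on the soil given the farm's actual compost production, and recomputes the
soil-system budgets under alternative treatment combinations (e.g. the
suggested continuous aeration for liquid composting and turning+aeration
for solid composting) with percent-change metrics on the surplus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import (
    Approach,
    ConfigurationError,
    FarmRecord,
    FluxTable,
    LiquidMethod,
    Nutrient,
    Phase,
    ScenarioComparison,
    SolidMethod,
    UndefinedRatioError,
)
from .engine import compute_budget
from .inputs import compost_input

__all__ = [
    "LoadingTableRow",
    "loading_table",
    "percent_change",
    "apply_scenario",
    "compare_scenarios",
]


@dataclass(frozen=True)
class LoadingTableRow:
    """Nutrient loading one treatment method would deliver to the soil,
    at the farm's actual compost production."""

    farm_id: str
    phase: Phase
    method: str
    loading_n: float  # kg N/yr
    loading_p: float  # kg P/yr
    is_current: bool


def loading_table(farm: FarmRecord, fluxes: FluxTable) -> list[LoadingTableRow]:
    """One row per (phase, method) the farm could operate.

    Liquid rows appear when the farm produces liquid compost; solid rows
    when it has a solid facility.  The row for the farm's current method is
    flagged.  Loadings use the compost computation with the method
    overridden, so current-method rows equal the compost terms of the
    farm's SSB input ledger.
    """
    rows: list[LoadingTableRow] = []
    if farm.solid_compost_production > 0:
        for method in (SolidMethod.TURNING_AERATION, SolidMethod.TURNING):
            rows.append(
                LoadingTableRow(
                    farm_id=farm.farm_id,
                    phase=Phase.SOLID,
                    method=method.value,
                    loading_n=compost_input(
                        farm, fluxes, Nutrient.N, Phase.SOLID, method=method.value
                    ),
                    loading_p=compost_input(
                        farm, fluxes, Nutrient.P, Phase.SOLID, method=method.value
                    ),
                    is_current=farm.solid_treatment is method,
                )
            )
    if farm.liquid_compost_production > 0:
        for method in (
            LiquidMethod.INTERMITTENT_AERATION,
            LiquidMethod.CONTINUOUS_AERATION,
            LiquidMethod.STORAGE_ONLY,
        ):
            rows.append(
                LoadingTableRow(
                    farm_id=farm.farm_id,
                    phase=Phase.LIQUID,
                    method=method.value,
                    loading_n=compost_input(
                        farm, fluxes, Nutrient.N, Phase.LIQUID, method=method.value
                    ),
                    loading_p=compost_input(
                        farm, fluxes, Nutrient.P, Phase.LIQUID, method=method.value
                    ),
                    is_current=farm.liquid_treatment is method,
                )
            )
    return rows


def percent_change(reference: float, alternative: float) -> float:
    """Percent change relative to ``reference``; positive = reduction."""
    if reference == 0:
        raise UndefinedRatioError("percent change with a zero reference value")
    return 100.0 * (reference - alternative) / reference


def apply_scenario(
    farm: FarmRecord,
    liquid_method: Optional[str] = None,
    solid_method: Optional[str] = None,
) -> FarmRecord:
    """Copy of ``farm`` with treatment methods replaced.

    Production amounts are unchanged — the scenario reroutes the same
    compost streams through different treatments.  A solid method is
    ignored when the farm has no solid facility.
    """
    liquid = None
    solid = None
    if liquid_method is not None:
        try:
            liquid = LiquidMethod(liquid_method)
        except ValueError:
            raise ConfigurationError(
                f"unknown liquid treatment method {liquid_method!r}"
            ) from None
    if solid_method is not None:
        try:
            solid = SolidMethod(solid_method)
        except ValueError:
            raise ConfigurationError(
                f"unknown solid treatment method {solid_method!r}"
            ) from None
        if farm.solid_treatment is SolidMethod.NONE:
            solid = None  # no facility to change
    return farm.with_treatments(liquid=liquid, solid=solid)


def compare_scenarios(
    farm: FarmRecord,
    fluxes: FluxTable,
    liquid_method: Optional[str] = None,
    solid_method: Optional[str] = None,
) -> ScenarioComparison:
    """Soil-system budgets (both nutrients) for the farm's current
    treatments versus an alternative combination, with surplus percent
    reductions."""
    scenario_farm = apply_scenario(farm, liquid_method, solid_method)
    baseline = {
        nutrient: compute_budget(farm, fluxes, nutrient, Approach.SSB)
        for nutrient in Nutrient
    }
    alternative = {
        nutrient: compute_budget(scenario_farm, fluxes, nutrient, Approach.SSB)
        for nutrient in Nutrient
    }
    reduction = {
        nutrient: percent_change(
            baseline[nutrient].surplus, alternative[nutrient].surplus
        )
        for nutrient in Nutrient
    }
    return ScenarioComparison(
        baseline=baseline, alternative=alternative, reduction_pct=reduction
    )
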