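"""Budget assembly: surplus and its atmospheric/hydrologic decomposition.

The gross nitrogen surplus (GNS) of the ideal GNB splits into an
atmospheric part (aGNS) and a hydrologic part (hGNS = GNS - aGNS).  Two
aGNS conventions are supported:

``table_consistent`` (default)
    aGNS = N_NLB, the nitrogen lost before soil application, i.e. manure
    N input minus total compost N input.  This is the convention the
    published budget sheets follow.
``with_post_application``
    aGNS = N_NLB + N_NLA, additionally counting the post-application
    atmospheric losses (volatilization + denitrification) as the
    decomposition formula states literally.
"""

from __future__ import annotations

import statistics
from typing import Iterable, Sequence

from .core import (
    Approach,
    BudgetResult,
    FarmRecord,
    FluxTable,
    Nutrient,
    UndefinedRatioError,
)
from .inputs import (
    assemble_input_ledger,
    fertilizer_input,
    manure_input,
    total_compost_input,
)
from .outputs import (
    assemble_output_ledger,
    denitrification_output,
    volatilization_output,
)

__all__ = [
    "compute_budget",
    "compute_all_budgets",
    "nitrogen_loss_before_application",
    "nitrogen_loss_after_application",
    "agns",
    "hgns",
    "surplus_ratio",
    "surplus_ratio_by_approach",
    "AGNS_MODES",
]

AGNS_MODES = ("table_consistent", "with_post_application")


def nitrogen_loss_before_application(farm: FarmRecord, fluxes: FluxTable) -> float:
    """N lost during manure treatment/composting, before soil application:
    raw-manure N input minus total compost N input (kg N/yr)."""
    return manure_input(farm, fluxes, Nutrient.N) - total_compost_input(
        farm, fluxes, Nutrient.N
    )


def nitrogen_loss_after_application(farm: FarmRecord, fluxes: FluxTable) -> float:
    """N lost from the soil after application: volatilization plus
    denitrification under the SSB input terms (kg N/yr)."""
    fert = fertilizer_input(farm, fluxes, Nutrient.N)
    compost = total_compost_input(farm, fluxes, Nutrient.N)
    vol = sum(volatilization_output(fert, compost, fluxes))
    den = sum(denitrification_output(fert, compost, farm.total_arable_area, fluxes))
    return vol + den


def agns(farm: FarmRecord, fluxes: FluxTable, mode: str = "table_consistent") -> float:
    """Atmospheric gross nitrogen surplus (kg N/yr); see module docstring
    for the two conventions."""
    if mode not in AGNS_MODES:
        raise ValueError(f"unknown aGNS mode {mode!r}; expected one of {AGNS_MODES}")
    nlb = nitrogen_loss_before_application(farm, fluxes)
    if mode == "table_consistent":
        return nlb
    return nlb + nitrogen_loss_after_application(farm, fluxes)


def hgns(gns: float, agns_value: float) -> float:
    """Hydrologic gross nitrogen surplus: GNS minus aGNS (kg N/yr)."""
    return gns - agns_value


def compute_budget(
    farm: FarmRecord,
    fluxes: FluxTable,
    nutrient: Nutrient,
    approach: Approach,
    agns_mode: str = "table_consistent",
) -> BudgetResult:
    """Full budget for one (farm, nutrient, approach).

    ``surplus = inputs.total - outputs.total`` (positive = surplus).  For
    the ideal GNB nitrogen budget, the surplus decomposition fields
    (``nlb``, ``nla``, ``agns``, ``hgns``) are also populated.
    """
    nutrient = Nutrient(nutrient)
    approach = Approach(approach)
    inputs = assemble_input_ledger(farm, fluxes, nutrient, approach)
    outputs = assemble_output_ledger(farm, fluxes, nutrient, approach, inputs)
    surplus = inputs.total - outputs.total
    nlb = nla = agns_value = hgns_value = None
    if approach is Approach.IDEAL_GNB and nutrient is Nutrient.N:
        nlb = nitrogen_loss_before_application(farm, fluxes)
        nla = nitrogen_loss_after_application(farm, fluxes)
        agns_value = agns(farm, fluxes, mode=agns_mode)
        hgns_value = hgns(surplus, agns_value)
    return BudgetResult(
        farm_id=farm.farm_id,
        approach=approach,
        nutrient=nutrient,
        inputs=inputs,
        outputs=outputs,
        surplus=surplus,
        nlb=nlb,
        nla=nla,
        agns=agns_value,
        hgns=hgns_value,
    )


def compute_all_budgets(
    farm: FarmRecord,
    fluxes: FluxTable,
    nutrients: Sequence[Nutrient] = tuple(Nutrient),
    approaches: Sequence[Approach] = tuple(Approach),
) -> list[BudgetResult]:
    """Budgets for every requested (nutrient, approach) combination."""
    return [
        compute_budget(farm, fluxes, nutrient, approach)
        for nutrient in nutrients
        for approach in approaches
    ]


def surplus_ratio(
    farms: Iterable[FarmRecord], fluxes: FluxTable, nutrient: Nutrient
) -> float:
    """Mean GNB surplus (both GNB approaches pooled, across farms) divided
    by the mean SSB surplus.

    Summarises how strongly the wider GNB boundary inflates the apparent
    surplus relative to what actually reaches and leaves the soil.
    """
    farms = list(farms)
    if not farms:
        raise ValueError("surplus_ratio needs at least one farm")
    gnb = [
        compute_budget(f, fluxes, nutrient, approach).surplus
        for f in farms
        for approach in (Approach.CURRENT_GNB, Approach.IDEAL_GNB)
    ]
    ssb = [compute_budget(f, fluxes, nutrient, Approach.SSB).surplus for f in farms]
    mean_ssb = statistics.fmean(ssb)
    if mean_ssb == 0:
        raise UndefinedRatioError("mean SSB surplus is zero")
    return statistics.fmean(gnb) / mean_ssb


def surplus_ratio_by_approach(
    farms: Iterable[FarmRecord], fluxes: FluxTable, nutrient: Nutrient
) -> dict:
    """Per-approach GNB/SSB surplus ratios plus the pooled ratio."""
    farms = list(farms)
    ssb = [compute_budget(f, fluxes, nutrient, Approach.SSB).surplus for f in farms]
    mean_ssb = statistics.fmean(ssb)
    if mean_ssb == 0:
        raise UndefinedRatioError("mean SSB surplus is zero")
    out = {}
    for approach in (Approach.CURRENT_GNB, Approach.IDEAL_GNB):
        vals = [compute_budget(f, fluxes, nutrient, approach).surplus for f in farms]
        out[approach.value] = statistics.fmean(vals) / mean_ssb
    out["gnb_pooled"] = surplus_ratio(farms, fluxes, nutrient)
    return out
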