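"""Nutrient output terms of the farm budgets.

The current GNB counts only crop harvest; the ideal GNB adds soil stock
changes; the soil system budget counts harvest plus the loss pathways from
soil — volatilization and denitrification (N only), leaching and runoff
(both nutrients), the hydrologic terms being fractions of the same-nutrient
total SSB input.
"""

from __future__ import annotations

import math

from .core import (
    Approach,
    FarmRecord,
    FluxTable,
    Ledger,
    Nutrient,
    Side,
    UnresolvableTermError,
)
from .inputs import fertilizer_input, total_compost_input

__all__ = [
    "crop_harvest_output",
    "soil_stock_change",
    "volatilization_output",
    "denitrification_output",
    "leaching_output",
    "runoff_output",
    "assemble_output_ledger",
    "OUTPUT_COMPONENTS",
]


def crop_harvest_output(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Nutrient exported in harvested crops (kg/yr).

    A farm-level resolved export wins; otherwise each plot contributes its
    own resolved value or production x crop nutrient content x area.
    """
    nutrient = Nutrient(nutrient)
    resolved = farm.resolved_harvest(nutrient)
    if resolved is not None:
        return resolved
    terms = []
    for plot in farm.plots:
        plot_resolved = plot.resolved_harvest(nutrient)
        if plot_resolved is not None:
            terms.append(plot_resolved)
            continue
        content = plot.crop_content(nutrient)
        if content is None:
            raise UnresolvableTermError(
                f"crop harvest {nutrient.value}: plot {plot.crop_name!r} has "
                "neither a resolved export nor a crop nutrient content"
            )
        terms.append(plot.production_rate * content * plot.area)
    return math.fsum(terms)


def soil_stock_change(farm: FarmRecord, nutrient: Nutrient) -> float:
    """Annual change in the soil nutrient stock (kg/yr; negative values
    are stock depletion)."""
    nutrient = Nutrient(nutrient)
    if nutrient is Nutrient.N:
        resolved, start, end = (
            farm.soil_stock_change_n,
            farm.soil_n_per_ha_start,
            farm.soil_n_per_ha_end,
        )
    else:
        resolved, start, end = (
            farm.soil_stock_change_p,
            farm.soil_p_per_ha_start,
            farm.soil_p_per_ha_end,
        )
    if resolved is not None:
        return resolved
    if start is not None and end is not None:
        return (end - start) * farm.total_arable_area
    raise UnresolvableTermError(
        f"soil {nutrient.value} stock change: neither a resolved value nor a "
        "per-ha year pair is available"
    )


def volatilization_output(
    fert_input: float, compost_input: float, fluxes: FluxTable
) -> tuple[float, float]:
    """Ammonia volatilization from applied fertilizer and compost (kg N/yr),
    reported as the two sub-terms (fertilizer, compost)."""
    return (
        fert_input * fluxes.volatilization_fert,
        compost_input * fluxes.volatilization_compost,
    )


def denitrification_output(
    fert_input: float, compost_input: float, arable_area: float, fluxes: FluxTable
) -> tuple[float, float, float]:
    """Denitrification losses (kg N/yr) as three sub-terms:
    (fertilizer, compost, arable land area x unit flux)."""
    return (
        fert_input * fluxes.denit_fert,
        compost_input * fluxes.denit_compost,
        arable_area * fluxes.denit_arable,
    )


def leaching_output(total_input: float, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Leaching loss (kg/yr) as the leaching fraction of the same-nutrient
    total SSB input."""
    return total_input * fluxes.leach[Nutrient(nutrient)]


def runoff_output(total_input: float, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Runoff loss (kg/yr) as the runoff fraction of the same-nutrient
    total SSB input."""
    return total_input * fluxes.runoff[Nutrient(nutrient)]


OUTPUT_COMPONENTS = {
    Approach.CURRENT_GNB: (
        "crop_harvesting",
        "fodder_production",
        "crop_residues",
    ),
    Approach.IDEAL_GNB: (
        "crop_harvesting",
        "fodder_production",
        "crop_residues",
        "soil_stock_change",
    ),
    Approach.SSB: (
        "crop_harvesting",
        "volatilization_fertilizer",
        "volatilization_compost",
        "denitrification_fertilizer",
        "denitrification_compost",
        "denitrification_arable_land",
        "leaching",
        "runoff",
        "immobilization",
    ),
}


def assemble_output_ledger(
    farm: FarmRecord,
    fluxes: FluxTable,
    nutrient: Nutrient,
    approach: Approach,
    input_ledger: Ledger,
) -> Ledger:
    """Build the output-side ledger for one approach and nutrient.

    ``input_ledger`` must be the matching input ledger for the same
    approach/nutrient: the SSB hydrologic terms are fractions of its total.
    Components excluded for lack of data (fodder, crop residues,
    immobilization) are explicit zero terms.
    """
    nutrient = Nutrient(nutrient)
    approach = Approach(approach)
    terms: list[tuple[str, float]] = []
    total_input = input_ledger.total
    for component in OUTPUT_COMPONENTS[approach]:
        if component == "crop_harvesting":
            value = crop_harvest_output(farm, fluxes, nutrient)
        elif component == "soil_stock_change":
            value = soil_stock_change(farm, nutrient)
        elif component in (
            "volatilization_fertilizer",
            "volatilization_compost",
            "denitrification_fertilizer",
            "denitrification_compost",
            "denitrification_arable_land",
        ):
            if nutrient is not Nutrient.N:
                continue  # atmospheric loss pathways exist for N only
            fert = fertilizer_input(farm, fluxes, nutrient)
            compost = total_compost_input(farm, fluxes, nutrient)
            vol_f, vol_c = volatilization_output(fert, compost, fluxes)
            den_f, den_c, den_a = denitrification_output(
                fert, compost, farm.total_arable_area, fluxes
            )
            value = {
                "volatilization_fertilizer": vol_f,
                "volatilization_compost": vol_c,
                "denitrification_fertilizer": den_f,
                "denitrification_compost": den_c,
                "denitrification_arable_land": den_a,
            }[component]
        elif component == "leaching":
            value = leaching_output(total_input, fluxes, nutrient)
        elif component == "runoff":
            value = runoff_output(total_input, fluxes, nutrient)
        else:  # zero-default components (fodder, residues, immobilization)
            value = 0.0
        terms.append((component, value))
    return Ledger.build(Side.OUTPUT, terms)
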