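"""Nutrient input terms of the farm budgets.

Every function returns kg of nutrient per year for one farm.  The soil
system budget (SSB) counts compost terms (what actually reaches the soil)
while both gross-nutrient-balance (GNB) approaches count raw livestock
manure; all other input components are shared.
"""

from __future__ import annotations

import math
from typing import Optional

from .core import (
    Approach,
    CoefficientMissingError,
    FarmRecord,
    FluxTable,
    Ledger,
    NotApplicableError,
    Nutrient,
    Phase,
    Side,
    SolidMethod,
    UnresolvableTermError,
    DAYS_PER_YEAR,
)

__all__ = [
    "annual_manure_production",
    "seed_input",
    "fertilizer_input",
    "manure_input",
    "compost_input",
    "total_compost_input",
    "deposition_input",
    "bnf_input",
    "assemble_input_ledger",
    "INPUT_COMPONENTS",
]


def annual_manure_production(farm: FarmRecord) -> float:
    """Total manure excreted per year (kg/yr): heads x per-head daily
    excretion x 365."""
    return farm.head_count * farm.excretion_rate * DAYS_PER_YEAR


def seed_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Nutrient brought in with seed and planting material (kg/yr),
    summed as per-crop seed flux x plot area."""
    nutrient = Nutrient(nutrient)
    terms = []
    for plot in farm.plots:
        try:
            flux = fluxes.seed_flux[plot.crop_name][nutrient]
        except KeyError:
            raise CoefficientMissingError(
                f"no {nutrient.value} seed flux for crop {plot.crop_name!r}"
            ) from None
        terms.append(flux * plot.area)
    return math.fsum(terms)


def fertilizer_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Nutrient applied as chemical fertilizer (kg/yr).

    Uses the farm's resolved constant when present; otherwise computes
    sum over plots of application rate x fertilizer nutrient content x area.
    Farms that apply no fertilizer return 0.
    """
    nutrient = Nutrient(nutrient)
    resolved = farm.resolved_fertilizer(nutrient)
    if resolved is not None:
        return resolved
    total_rate = math.fsum(p.fertilizer_rate * p.area for p in farm.plots)
    if total_rate == 0:
        return 0.0
    content = (fluxes.fertilizer_content or {}).get(nutrient)
    if content is None:
        raise UnresolvableTermError(
            f"fertilizer {nutrient.value} input: no resolved value and no "
            "fertilizer nutrient content in the flux table"
        )
    return math.fsum(p.fertilizer_rate * content * p.area for p in farm.plots)


def manure_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Nutrient in raw livestock manure plus bulking agent (kg/yr)."""
    nutrient = Nutrient(nutrient)
    try:
        content = fluxes.manure_content[nutrient]
    except KeyError:
        raise CoefficientMissingError(
            f"no manure {nutrient.value} content defined"
        ) from None
    manure = annual_manure_production(farm) * content / 1000.0
    bedding = farm.bulking_agent_mass * farm.bulking_agent_content(nutrient) / 1000.0
    return manure + bedding


def compost_input(
    farm: FarmRecord,
    fluxes: FluxTable,
    nutrient: Nutrient,
    phase: Phase,
    method: Optional[str] = None,
) -> float:
    """Nutrient reaching the soil from one compost stream (kg/yr).

    production x content/1000 x loading flux for the (phase, method) pair,
    plus the bulking-agent contribution (content defaults to 0, so normally
    nothing).  ``method`` overrides the farm's current treatment, which is
    how treatment scenarios are priced.  A farm without a solid facility
    contributes 0 for the solid phase.
    """
    nutrient = Nutrient(nutrient)
    phase = Phase(phase)
    if phase is Phase.SOLID and farm.solid_treatment is SolidMethod.NONE and method is None:
        return 0.0
    production = farm.compost_production(phase)
    if production == 0:
        return 0.0
    if method is None:
        method = farm.treatment(phase)
    content = fluxes.compost_content(phase, nutrient)
    loading = fluxes.loading_flux(phase, method, nutrient)
    base = production * content / 1000.0 * loading
    if phase is Phase.SOLID:
        base += farm.bulking_agent_mass * farm.bulking_agent_content(nutrient) / 1000.0
    return base


def total_compost_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Total compost nutrient input: solid + liquid streams (kg/yr)."""
    return compost_input(farm, fluxes, nutrient, Phase.LIQUID) + compost_input(
        farm, fluxes, nutrient, Phase.SOLID
    )


def deposition_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient) -> float:
    """Atmospheric deposition onto the farm's arable land (kg/yr)."""
    nutrient = Nutrient(nutrient)
    try:
        flux = fluxes.deposition[nutrient]
    except KeyError:
        raise CoefficientMissingError(
            f"no atmospheric deposition flux for {nutrient.value}"
        ) from None
    return flux * farm.total_arable_area


def bnf_input(farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient = Nutrient.N) -> float:
    """Biological nitrogen fixation on arable land (kg N/yr); N only."""
    if Nutrient(nutrient) is not Nutrient.N:
        raise NotApplicableError("biological fixation is a nitrogen-only input")
    return fluxes.bnf_flux * farm.total_arable_area


#: Component order of the input ledgers, mirroring the budget sheets.
#: Optional components the study farms do not use appear as zero-valued
#: ledger terms so every budget is structurally complete.
INPUT_COMPONENTS = {
    Approach.CURRENT_GNB: (
        "chemical_fertilizer",
        "livestock_manure",
        "net_manure_import_export",
        "organic_fertilizer",
        "biological_n_fixation",
        "atmospheric_deposition",
        "planting_materials",
    ),
    Approach.IDEAL_GNB: (
        "chemical_fertilizer",
        "livestock_manure",
        "net_manure_import_export",
        "organic_fertilizer",
        "biological_n_fixation",
        "atmospheric_deposition",
        "planting_materials",
        "crop_residues",
    ),
    Approach.SSB: (
        "chemical_fertilizer",
        "liquid_compost",
        "solid_compost",
        "organic_fertilizer",
        "biological_n_fixation",
        "atmospheric_deposition",
        "mineralization",
        "planting_materials",
    ),
}


def assemble_input_ledger(
    farm: FarmRecord, fluxes: FluxTable, nutrient: Nutrient, approach: Approach
) -> Ledger:
    """Build the full input-side ledger for one approach and nutrient.

    The GNB approaches share one component set (raw manure as input); the
    SSB replaces the manure term with the two compost streams.  Components
    not used on these farms (manure trade, organic fertilizer) and those
    excluded for lack of data (mineralization, crop residues) are carried
    as explicit zero terms.
    """
    nutrient = Nutrient(nutrient)
    approach = Approach(approach)
    terms: list[tuple[str, float]] = []
    for component in INPUT_COMPONENTS[approach]:
        if component == "chemical_fertilizer":
            value = fertilizer_input(farm, fluxes, nutrient)
        elif component == "livestock_manure":
            value = manure_input(farm, fluxes, nutrient)
        elif component == "liquid_compost":
            value = compost_input(farm, fluxes, nutrient, Phase.LIQUID)
        elif component == "solid_compost":
            value = compost_input(farm, fluxes, nutrient, Phase.SOLID)
        elif component == "biological_n_fixation":
            if nutrient is not Nutrient.N:
                continue  # the P budget has no fixation component
            value = bnf_input(farm, fluxes)
        elif component == "atmospheric_deposition":
            value = deposition_input(farm, fluxes, nutrient)
        elif component == "planting_materials":
            value = seed_input(farm, fluxes, nutrient)
        else:  # optional zero-default components
            value = 0.0
        terms.append((component, value))
    return Ledger.build(Side.INPUT, terms)
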