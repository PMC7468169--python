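"""Domain types, unit conventions, and validation for farm nutrient budgets.

Unit conventions used throughout the package
--------------------------------------------
* masses: kg, annual flows: kg/yr
* nutrient contents: g nutrient per kg material; combined with kg masses as
  ``mass * content / 1000`` to give kg of nutrient
* areas: ha; area-based fluxes: kg/ha/yr
* loss coefficients (volatilization, denitrification, leaching, runoff) and
  loading fluxes: dimensionless fractions in [0, 1]
* a year is 365 days

All ledger values are kg of nutrient per year.  Positive budget balances are
surpluses (potential loss to the environment), negative balances deficits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

DAYS_PER_YEAR = 365.0

__all__ = [
    "DAYS_PER_YEAR",
    "Nutrient",
    "Approach",
    "Phase",
    "LiquidMethod",
    "SolidMethod",
    "Side",
    "CropPlot",
    "FarmRecord",
    "FluxTable",
    "Ledger",
    "BudgetResult",
    "ScenarioComparison",
    "ValidationIssue",
    "BudgetError",
    "CoefficientMissingError",
    "UnresolvableTermError",
    "NotApplicableError",
    "UndefinedRatioError",
    "ConfigurationError",
    "validate_farm",
]


class Nutrient(str, Enum):
    """Nutrient species tracked by the budgets."""

    N = "N"
    P = "P"


class Approach(str, Enum):
    """Budgeting approach.

    ``current_gnb``
        OECD gross nutrient balance: raw livestock manure counts as input and
        crop harvest is the only output.
    ``ideal_gnb``
        As above plus soil nutrient stock changes on the output side, and (for
        N) decomposition of the surplus into atmospheric and hydrologic parts.
    ``ssb``
        Soil system budget: only nutrients actually reaching the soil (solid
        and liquid compost, not raw manure) count as inputs, and atmospheric
        (N) and hydrologic losses from the soil count as outputs.
    """

    CURRENT_GNB = "current_gnb"
    IDEAL_GNB = "ideal_gnb"
    SSB = "ssb"


class Phase(str, Enum):
    """Physical phase of a separated swine-manure compost stream."""

    LIQUID = "liquid"
    SOLID = "solid"


class LiquidMethod(str, Enum):
    """Liquid composting method for the separated slurry fraction."""

    STORAGE_ONLY = "storage_only"
    INTERMITTENT_AERATION = "intermittent_aeration"
    CONTINUOUS_AERATION = "continuous_aeration"


class SolidMethod(str, Enum):
    """Solid composting method; ``NONE`` means no solid processing facility."""

    NONE = "none"
    TURNING = "turning"
    TURNING_AERATION = "turning_aeration"


class Side(str, Enum):
    INPUT = "input"
    OUTPUT = "output"


class BudgetError(Exception):
    """Base class for budget computation errors."""


class CoefficientMissingError(BudgetError, KeyError):
    """A required flux/coefficient is not defined in the flux table."""


class UnresolvableTermError(BudgetError):
    """A budget term can be computed neither from resolved constants nor
    from rates and contents."""


class NotApplicableError(BudgetError):
    """Operation requested for a nutrient it is not defined for."""


class UndefinedRatioError(BudgetError, ZeroDivisionError):
    """A ratio or percent change with a zero reference value."""


class ConfigurationError(BudgetError, ValueError):
    """Invalid configuration value (bad enum name, malformed config file)."""


@dataclass(frozen=True)
class CropPlot:
    """One cultivated plot of a single crop.

    ``crop_n_content`` / ``crop_p_content`` are mass fractions of the
    harvested product (e.g. 0.02 for 2 %), used when no resolved harvest
    export is supplied.
    """

    crop_name: str
    area: float  # ha
    fertilizer_rate: float = 0.0  # kg fertilizer/ha/yr
    production_rate: float = 0.0  # kg crop/ha/yr
    crop_n_content: Optional[float] = None  # mass fraction
    crop_p_content: Optional[float] = None
    resolved_harvest_n: Optional[float] = None  # kg N/yr override
    resolved_harvest_p: Optional[float] = None  # kg P/yr override

    def crop_content(self, nutrient: Nutrient) -> Optional[float]:
        return self.crop_n_content if nutrient is Nutrient.N else self.crop_p_content

    def resolved_harvest(self, nutrient: Nutrient) -> Optional[float]:
        if nutrient is Nutrient.N:
            return self.resolved_harvest_n
        return self.resolved_harvest_p


@dataclass(frozen=True)
class FarmRecord:
    """Everything known about one mixed crop-swine farm.

    ``soil_stock_change_*`` are resolved annual changes in the soil nutrient
    stock (kg/yr, may be negative).  Alternatively, per-ha soil contents for
    two consecutive years (``soil_*_per_ha_start/end``, kg/ha) may be given
    and the change is ``(end - start) * total area``.

    ``resolved_fertilizer_*`` and ``resolved_harvest_*`` short-circuit the
    rate-based computations when farm-level constants are known.
    """

    farm_id: str
    head_count: float  # head
    excretion_rate: float  # kg manure/head/day
    plots: tuple[CropPlot, ...] = ()
    bulking_agent_mass: float = 0.0  # kg/yr
    bulking_agent_n_content: float = 0.0  # g/kg
    bulking_agent_p_content: float = 0.0  # g/kg
    liquid_treatment: LiquidMethod = LiquidMethod.STORAGE_ONLY
    solid_treatment: SolidMethod = SolidMethod.NONE
    liquid_compost_production: float = 0.0  # kg/yr
    solid_compost_production: float = 0.0  # kg/yr
    soil_stock_change_n: Optional[float] = None  # kg/yr
    soil_stock_change_p: Optional[float] = None
    soil_n_per_ha_start: Optional[float] = None  # kg/ha
    soil_n_per_ha_end: Optional[float] = None
    soil_p_per_ha_start: Optional[float] = None
    soil_p_per_ha_end: Optional[float] = None
    resolved_fertilizer_n: Optional[float] = None  # kg N/yr
    resolved_fertilizer_p: Optional[float] = None
    resolved_harvest_n: Optional[float] = None  # kg N/yr
    resolved_harvest_p: Optional[float] = None

    @property
    def total_arable_area(self) -> float:
        """Total arable land area (ha), summed over plots."""
        return math.fsum(p.area for p in self.plots)

    def bulking_agent_content(self, nutrient: Nutrient) -> float:
        if nutrient is Nutrient.N:
            return self.bulking_agent_n_content
        return self.bulking_agent_p_content

    def resolved_fertilizer(self, nutrient: Nutrient) -> Optional[float]:
        if nutrient is Nutrient.N:
            return self.resolved_fertilizer_n
        return self.resolved_fertilizer_p

    def resolved_harvest(self, nutrient: Nutrient) -> Optional[float]:
        if nutrient is Nutrient.N:
            return self.resolved_harvest_n
        return self.resolved_harvest_p

    def treatment(self, phase: Phase) -> str:
        m = self.liquid_treatment if phase is Phase.LIQUID else self.solid_treatment
        return m.value

    def compost_production(self, phase: Phase) -> float:
        if phase is Phase.LIQUID:
            return self.liquid_compost_production
        return self.solid_compost_production

    def with_treatments(
        self,
        liquid: Optional[LiquidMethod] = None,
        solid: Optional[SolidMethod] = None,
    ) -> "FarmRecord":
        """Copy of this farm with treatment methods replaced (production
        amounts unchanged)."""
        changes = {}
        if liquid is not None:
            changes["liquid_treatment"] = LiquidMethod(liquid)
        if solid is not None:
            changes["solid_treatment"] = SolidMethod(solid)
        return replace(self, **changes)


@dataclass(frozen=True)
class FluxTable:
    """All coefficients needed to turn farm records into nutrient flows.

    * ``seed_flux[crop][nutrient]``: kg/ha/yr brought in with seed/planting
      material for each crop.
    * ``loading[phase][method][nutrient]``: loading flux, the fraction of a
      compost stream's nutrient content that reaches the soil, specific to
      the phase (solid/liquid) and treatment method.
    * contents are g nutrient per kg material.
    """

    seed_flux: dict  # {crop: {Nutrient: kg/ha/yr}}
    bnf_flux: float  # kg N/ha/yr
    deposition: dict  # {Nutrient: kg/ha/yr}
    volatilization_fert: float  # fraction
    volatilization_compost: float
    denit_fert: float  # fraction
    denit_compost: float
    denit_arable: float  # kg N/ha/yr
    leach: dict  # {Nutrient: fraction}
    runoff: dict  # {Nutrient: fraction}
    manure_content: dict  # {Nutrient: g/kg}
    liquid_compost_content: dict  # {Nutrient: g/kg}
    solid_compost_content: dict  # {Nutrient: g/kg}
    loading: dict  # {phase: {method: {Nutrient: fraction}}}
    fertilizer_content: Optional[dict] = None  # {Nutrient: mass fraction}

    def compost_content(self, phase: Phase, nutrient: Nutrient) -> float:
        table = (
            self.liquid_compost_content
            if phase is Phase.LIQUID
            else self.solid_compost_content
        )
        try:
            return table[nutrient]
        except KeyError:
            raise CoefficientMissingError(
                f"no {phase.value}-compost {nutrient.value} content defined"
            ) from None

    def loading_flux(self, phase: Phase, method: str, nutrient: Nutrient) -> float:
        method = str(getattr(method, "value", method))
        try:
            return self.loading[phase.value][method][nutrient]
        except KeyError:
            raise CoefficientMissingError(
                f"no {nutrient.value} loading flux for {phase.value}/{method}"
            ) from None

    def has_loading(self, phase: Phase, method: str, nutrient: Nutrient) -> bool:
        method = str(getattr(method, "value", method))
        return nutrient in self.loading.get(phase.value, {}).get(method, {})


@dataclass(frozen=True)
class Ledger:
    """Ordered list of named kg/yr terms for one side of a budget.

    Input terms are non-negative; the only output terms allowed to be
    negative are soil stock changes (stock depletion).
    """

    side: Side
    terms: tuple[tuple[str, float], ...]

    @property
    def total(self) -> float:
        return math.fsum(v for _, v in self.terms)

    def __getitem__(self, label: str) -> float:
        for name, value in self.terms:
            if name == label:
                return value
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [name for name, _ in self.terms]

    @staticmethod
    def build(side: Side, terms: Iterable[tuple[str, float]]) -> "Ledger":
        return Ledger(side=Side(side), terms=tuple((str(k), float(v)) for k, v in terms))


@dataclass(frozen=True)
class BudgetResult:
    """Full budget for one (farm, approach, nutrient).

    ``surplus = inputs.total - outputs.total``; for the ideal GNB nitrogen
    budget the surplus is additionally decomposed into atmospheric (``agns``)
    and hydrologic (``hgns``) parts, with ``nlb``/``nla`` the nitrogen lost
    before/after soil application.
    """

    farm_id: str
    approach: Approach
    nutrient: Nutrient
    inputs: Ledger
    outputs: Ledger
    surplus: float
    nlb: Optional[float] = None
    nla: Optional[float] = None
    agns: Optional[float] = None
    hgns: Optional[float] = None


@dataclass(frozen=True)
class ScenarioComparison:
    """Baseline vs alternative-treatment soil-system budgets.

    ``reduction_pct[nutrient]`` is ``100 * (baseline - alternative) /
    baseline`` on the surplus: positive values are reductions.
    """

    baseline: dict  # {Nutrient: BudgetResult} (SSB)
    alternative: dict
    reduction_pct: dict  # {Nutrient: float}


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.field}: {self.message}"


def _check(issues: list, cond: bool, field_name: str, message: str, severity: str = "error"):
    if not cond:
        issues.append(ValidationIssue(field_name, message, severity))


def validate_farm(farm: FarmRecord, fluxes: FluxTable) -> list[ValidationIssue]:
    """Check a farm record against its invariants and coefficient coverage.

    Returns an empty list iff every invariant holds and every
    (phase, treatment) combination the farm uses has loading fluxes and
    contents defined in ``fluxes``.  Reporting only; never raises.
    """
    issues: list[ValidationIssue] = []
    _check(issues, farm.head_count >= 0, "head_count", "must be >= 0")
    _check(issues, farm.excretion_rate >= 0, "excretion_rate", "must be >= 0")
    _check(issues, farm.bulking_agent_mass >= 0, "bulking_agent_mass", "must be >= 0")
    _check(
        issues,
        farm.liquid_compost_production >= 0,
        "liquid_compost_production",
        "must be >= 0",
    )
    _check(
        issues,
        farm.solid_compost_production >= 0,
        "solid_compost_production",
        "must be >= 0",
    )
    if farm.solid_treatment is SolidMethod.NONE:
        _check(
            issues,
            farm.solid_compost_production == 0,
            "solid_compost_production",
            "must be 0 when there is no solid composting facility",
        )
    _check(issues, len(farm.plots) > 0, "plots", "farm must have at least one plot")
    for i, plot in enumerate(farm.plots):
        _check(issues, plot.area > 0, f"plots[{i}].area", "must be > 0")
        _check(issues, plot.fertilizer_rate >= 0, f"plots[{i}].fertilizer_rate", "must be >= 0")
        _check(issues, plot.production_rate >= 0, f"plots[{i}].production_rate", "must be >= 0")
        for attr in ("crop_n_content", "crop_p_content"):
            val = getattr(plot, attr)
            if val is not None:
                _check(issues, 0 <= val <= 1, f"plots[{i}].{attr}", "fraction must be in [0, 1]")
    if farm.plots:
        _check(issues, farm.total_arable_area > 0, "plots", "total arable area must be > 0")

    # coefficient coverage for the treatments the farm actually uses
    for nutrient in Nutrient:
        if not fluxes.has_loading(Phase.LIQUID, farm.liquid_treatment, nutrient):
            issues.append(
                ValidationIssue(
                    "fluxes.loading",
                    f"missing {nutrient.value} loading flux for "
                    f"liquid/{farm.liquid_treatment.value}",
                )
            )
        if nutrient not in fluxes.liquid_compost_content:
            issues.append(
                ValidationIssue(
                    "fluxes.liquid_compost_content",
                    f"missing liquid compost {nutrient.value} content",
                )
            )
        if farm.solid_treatment is not SolidMethod.NONE:
            if not fluxes.has_loading(Phase.SOLID, farm.solid_treatment, nutrient):
                issues.append(
                    ValidationIssue(
                        "fluxes.loading",
                        f"missing {nutrient.value} loading flux for "
                        f"solid/{farm.solid_treatment.value}",
                    )
                )
            if nutrient not in fluxes.solid_compost_content:
                issues.append(
                    ValidationIssue(
                        "fluxes.solid_compost_content",
                        f"missing solid compost {nutrient.value} content",
                    )
                )
        if nutrient not in fluxes.manure_content:
            issues.append(
                ValidationIssue(
                    "fluxes.manure_content", f"missing manure {nutrient.value} content"
                )
            )
    return issues
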