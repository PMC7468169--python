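"""Synthetic farm generator.

Generates random mixed crop-swine farms with the multiplicative structure
the budgets assume — every input term is mass x content x loading flux and
every soil-loss output is fraction x total input — so that ledger assembly,
surplus identities and coefficient recovery can be exercised on arbitrarily
many farms without external data.

Each farm is drawn from its own counter-based substream: ``(seed, index)``
fully determines the farm regardless of generation order.  Every sampled
coefficient is recorded in a truth record, alongside independently computed
(plain-arithmetic) soil-system input and output terms, so downstream tests
can compare the engine's ledgers against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CropPlot,
    FarmRecord,
    FluxTable,
    LiquidMethod,
    Nutrient,
    SolidMethod,
    UndefinedRatioError,
    DAYS_PER_YEAR,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticFarm",
    "generate_farm",
    "generate_farms",
    "recover_loading_flux",
    "DEFAULT_CROP_POOL",
    "DEFAULT_FLUX_RANGES",
]

N = Nutrient.N
P = Nutrient.P

#: Crops available to the generator: seed nutrient fluxes (kg/ha/yr) and
#: harvest nutrient content ranges (mass fraction) per crop.
DEFAULT_CROP_POOL = {
    "sesame": {"seed": {N: 0.4, P: 0.7}, "n_content": (0.02, 0.04), "p_content": (0.004, 0.008)},
    "corn": {"seed": {N: 4.4, P: 1.1}, "n_content": (0.010, 0.016), "p_content": (0.002, 0.004)},
}

#: Sampling intervals for every coefficient of the flux table.  Centred on
#: the Korean case-study values so synthetic cohorts behave like plausible
#: mixed crop-swine farms.
DEFAULT_FLUX_RANGES = {
    "manure_content_n": (7.0, 10.0),  # g/kg
    "manure_content_p": (1.0, 2.0),
    "liquid_content_n": (6.0, 10.0),
    "liquid_content_p": (0.3, 0.5),
    "solid_content_n": (8.0, 11.0),
    "solid_content_p": (3.0, 4.0),
    "loading": (0.05, 0.95),  # any (phase, method, nutrient)
    "bnf_flux": (10.0, 20.0),  # kg N/ha/yr
    "deposition_n": (20.0, 28.0),
    "deposition_p": (0.4, 0.8),
    "volatilization_fert": (0.10, 0.18),
    "volatilization_compost": (0.18, 0.28),
    "denit_fert": (0.10, 0.20),
    "denit_compost": (0.08, 0.16),
    "denit_arable": (2.0, 4.0),  # kg N/ha/yr
    "leach_n": (0.20, 0.32),
    "leach_p": (0.30, 0.40),
    "runoff_n": (0.10, 0.20),
    "runoff_p": (0.05, 0.10),
    "fertilizer_content_n": (0.10, 0.20),  # mass fraction
    "fertilizer_content_p": (0.05, 0.10),
    "fertilizer_rate": (0.0, 150.0),  # kg/ha/yr
    "production_rate": (400.0, 5500.0),  # kg/ha/yr
    "soil_stock_change": (-250.0, 250.0),  # kg/yr
    "bulking_agent_mass": (0.0, 20000.0),  # kg/yr
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling ranges for synthetic farms.

    Defaults are anchored to the case-study farms: herds of 700-1,800 head,
    per-plot areas of 0.66-1.65 ha (farm totals 0.66-3.3 ha over 1-3
    plots), excretion fixed at the national per-head coefficient of
    5.1 kg/head/d, and compost mass fractions of 0.85-0.95 (liquid) and
    0.05-0.12 (solid) of manure mass.  The fractions are sampled
    independently and may sum above 1, as they do on real farms (bulking
    agent and moisture changes).
    """

    seed: int = 0
    n_farms: int = 10
    head_range: tuple = (700, 1800)
    excretion_range: tuple = (5.1, 5.1)
    plots_per_farm: tuple = (1, 3)
    area_range: tuple = (0.66, 1.65)  # ha per plot
    crop_pool: dict = field(default_factory=lambda: dict(DEFAULT_CROP_POOL))
    liquid_fraction_range: tuple = (0.85, 0.95)
    solid_fraction_range: tuple = (0.05, 0.12)
    method_probabilities: dict = field(
        default_factory=lambda: {
            "liquid": {
                "storage_only": 1 / 3,
                "intermittent_aeration": 1 / 3,
                "continuous_aeration": 1 / 3,
            },
            "solid": {"none": 0.25, "turning": 0.375, "turning_aeration": 0.375},
        }
    )
    flux_ranges: dict = field(default_factory=lambda: dict(DEFAULT_FLUX_RANGES))

    def __post_init__(self):
        for name in ("head_range", "excretion_range", "plots_per_farm", "area_range",
                     "liquid_fraction_range", "solid_fraction_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: empty interval ({lo}, {hi})")
        for phase, probs in self.method_probabilities.items():
            total = math.fsum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"method probabilities for {phase!r} sum to {total}, not 1")


@dataclass(frozen=True)
class SyntheticFarm:
    """A generated farm, its own sampled flux table, and the ground truth.

    ``truth`` holds every sampled coefficient plus independently computed
    soil-system input/output terms (``ssb_inputs`` / ``ssb_outputs``,
    plain-arithmetic dicts) for oracle comparisons.
    """

    farm: FarmRecord
    fluxes: FluxTable
    truth: dict


def _uniform(rng: np.random.Generator, interval) -> float:
    lo, hi = interval
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _choice(rng: np.random.Generator, probs: dict) -> str:
    names = sorted(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    return str(names[rng.choice(len(names), p=p / p.sum())])


def generate_farm(config: GeneratorConfig, index: int) -> SyntheticFarm:
    """Draw one synthetic farm; deterministic given ``(config.seed, index)``."""
    rng = np.random.default_rng([config.seed, index])
    r = config.flux_ranges

    head_count = int(rng.integers(config.head_range[0], config.head_range[1] + 1))
    excretion = _uniform(rng, config.excretion_range)
    manure = head_count * excretion * DAYS_PER_YEAR

    n_plots = int(rng.integers(config.plots_per_farm[0], config.plots_per_farm[1] + 1))
    crop_names = sorted(config.crop_pool)
    plots = []
    crop_contents = {}
    for _ in range(n_plots):
        crop = str(crop_names[rng.integers(len(crop_names))])
        spec = config.crop_pool[crop]
        if crop not in crop_contents:
            crop_contents[crop] = {
                N: _uniform(rng, spec["n_content"]),
                P: _uniform(rng, spec["p_content"]),
            }
        plots.append(
            CropPlot(
                crop_name=crop,
                area=_uniform(rng, config.area_range),
                fertilizer_rate=_uniform(rng, r["fertilizer_rate"]),
                production_rate=_uniform(rng, r["production_rate"]),
                crop_n_content=crop_contents[crop][N],
                crop_p_content=crop_contents[crop][P],
            )
        )

    liquid_method = _choice(rng, config.method_probabilities["liquid"])
    solid_method = _choice(rng, config.method_probabilities["solid"])
    liquid_fraction = _uniform(rng, config.liquid_fraction_range)
    solid_fraction = _uniform(rng, config.solid_fraction_range)
    liquid_production = manure * liquid_fraction
    solid_production = 0.0 if solid_method == "none" else manure * solid_fraction

    loading = {
        "liquid": {
            m.value: {N: _uniform(rng, r["loading"]), P: _uniform(rng, r["loading"])}
            for m in LiquidMethod
        },
        "solid": {
            m.value: {N: _uniform(rng, r["loading"]), P: _uniform(rng, r["loading"])}
            for m in SolidMethod
            if m is not SolidMethod.NONE
        },
    }
    fluxes = FluxTable(
        seed_flux={c: dict(config.crop_pool[c]["seed"]) for c in crop_names},
        bnf_flux=_uniform(rng, r["bnf_flux"]),
        deposition={N: _uniform(rng, r["deposition_n"]), P: _uniform(rng, r["deposition_p"])},
        volatilization_fert=_uniform(rng, r["volatilization_fert"]),
        volatilization_compost=_uniform(rng, r["volatilization_compost"]),
        denit_fert=_uniform(rng, r["denit_fert"]),
        denit_compost=_uniform(rng, r["denit_compost"]),
        denit_arable=_uniform(rng, r["denit_arable"]),
        leach={N: _uniform(rng, r["leach_n"]), P: _uniform(rng, r["leach_p"])},
        runoff={N: _uniform(rng, r["runoff_n"]), P: _uniform(rng, r["runoff_p"])},
        manure_content={N: _uniform(rng, r["manure_content_n"]), P: _uniform(rng, r["manure_content_p"])},
        liquid_compost_content={N: _uniform(rng, r["liquid_content_n"]), P: _uniform(rng, r["liquid_content_p"])},
        solid_compost_content={N: _uniform(rng, r["solid_content_n"]), P: _uniform(rng, r["solid_content_p"])},
        loading=loading,
        fertilizer_content={
            N: _uniform(rng, r["fertilizer_content_n"]),
            P: _uniform(rng, r["fertilizer_content_p"]),
        },
    )

    farm = FarmRecord(
        farm_id=f"synthetic-{config.seed}-{index}",
        head_count=head_count,
        excretion_rate=excretion,
        plots=tuple(plots),
        bulking_agent_mass=_uniform(rng, r["bulking_agent_mass"]),
        liquid_treatment=LiquidMethod(liquid_method),
        solid_treatment=SolidMethod(solid_method),
        liquid_compost_production=liquid_production,
        solid_compost_production=solid_production,
        soil_stock_change_n=_uniform(rng, r["soil_stock_change"]),
        soil_stock_change_p=_uniform(rng, r["soil_stock_change"]),
    )

    # ground-truth soil-system terms, plain arithmetic independent of the
    # ledger-assembly code paths
    truth: dict = {
        "manure_production": manure,
        "liquid_fraction": liquid_fraction,
        "solid_fraction": solid_fraction,
        "liquid_method": liquid_method,
        "solid_method": solid_method,
        "crop_contents": crop_contents,
        "loading": loading,
    }
    for nutrient in (N, P):
        fert = math.fsum(
            p.fertilizer_rate * fluxes.fertilizer_content[nutrient] * p.area for p in plots
        )
        liq = (
            liquid_production
            * fluxes.liquid_compost_content[nutrient]
            / 1000.0
            * loading["liquid"][liquid_method][nutrient]
        )
        sol = 0.0
        if solid_method != "none":
            sol = (
                solid_production
                * fluxes.solid_compost_content[nutrient]
                / 1000.0
                * loading["solid"][solid_method][nutrient]
            )
        area = math.fsum(p.area for p in plots)
        seed_term = math.fsum(fluxes.seed_flux[p.crop_name][nutrient] * p.area for p in plots)
        inputs = {
            "chemical_fertilizer": fert,
            "liquid_compost": liq,
            "solid_compost": sol,
            "atmospheric_deposition": fluxes.deposition[nutrient] * area,
            "planting_materials": seed_term,
        }
        if nutrient is N:
            inputs["biological_n_fixation"] = fluxes.bnf_flux * area
        total_in = math.fsum(inputs.values())
        harvest = math.fsum(
            p.production_rate * crop_contents[p.crop_name][nutrient] * p.area for p in plots
        )
        outputs = {
            "crop_harvesting": harvest,
            "leaching": total_in * fluxes.leach[nutrient],
            "runoff": total_in * fluxes.runoff[nutrient],
        }
        if nutrient is N:
            compost = liq + sol
            outputs["volatilization_fertilizer"] = fert * fluxes.volatilization_fert
            outputs["volatilization_compost"] = compost * fluxes.volatilization_compost
            outputs["denitrification_fertilizer"] = fert * fluxes.denit_fert
            outputs["denitrification_compost"] = compost * fluxes.denit_compost
            outputs["denitrification_arable_land"] = area * fluxes.denit_arable
        truth[f"ssb_inputs_{nutrient.value}"] = inputs
        truth[f"ssb_outputs_{nutrient.value}"] = outputs
    return SyntheticFarm(farm=farm, fluxes=fluxes, truth=truth)


def generate_farms(config: GeneratorConfig) -> list[SyntheticFarm]:
    """Generate ``config.n_farms`` farms from independent substreams."""
    return [generate_farm(config, i) for i in range(config.n_farms)]


def recover_loading_flux(nutrient_input: float, production: float, content: float) -> float:
    """Invert the compost-input relation: loading = input / (production x
    content/1000).  ``content`` in g/kg, masses in kg."""
    denom = production * content / 1000.0
    if denom == 0:
        raise UndefinedRatioError("cannot recover a loading flux from zero production x content")
    return nutrient_input / denom
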