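"""Configuration reading/writing and report generation.

Farm and flux configurations are structured key-value documents (JSON or
YAML; YAML is a superset so both parse the same way) with explicit
unit-bearing field names, e.g. ``excretion_rate_kg_per_head_day``.
Unknown keys are logged as warnings; missing required keys raise
:class:`~farmbudget.core.ConfigurationError` naming the field.

Budget reports are long-format tables (CSV or JSON) with one row per
ledger term plus summary rows; values are serialized at full precision
with a display-rounded companion column (half-up to one decimal, the
style of printed budget sheets).  Thousands separators never appear in
machine-readable output.
"""

from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from .core import (
    BudgetResult,
    ConfigurationError,
    CropPlot,
    FarmRecord,
    FluxTable,
    LiquidMethod,
    Nutrient,
    ScenarioComparison,
    SolidMethod,
)

logger = logging.getLogger("farmbudget")

__all__ = [
    "read_farm_config",
    "write_farm_config",
    "read_flux_config",
    "write_flux_config",
    "write_budget_report",
    "write_scenario_report",
    "budget_report_frame",
    "display_round",
]

# (config key, FarmRecord attribute, required, default)
_FARM_FIELDS = [
    ("farm_id", "farm_id", True, None),
    ("head_count", "head_count", True, None),
    ("excretion_rate_kg_per_head_day", "excretion_rate", True, None),
    ("bulking_agent_mass_kg_per_yr", "bulking_agent_mass", False, 0.0),
    ("bulking_agent_n_content_g_per_kg", "bulking_agent_n_content", False, 0.0),
    ("bulking_agent_p_content_g_per_kg", "bulking_agent_p_content", False, 0.0),
    ("liquid_treatment", "liquid_treatment", False, "storage_only"),
    ("solid_treatment", "solid_treatment", False, "none"),
    ("liquid_compost_production_kg_per_yr", "liquid_compost_production", False, 0.0),
    ("solid_compost_production_kg_per_yr", "solid_compost_production", False, 0.0),
    ("soil_stock_change_n_kg_per_yr", "soil_stock_change_n", False, None),
    ("soil_stock_change_p_kg_per_yr", "soil_stock_change_p", False, None),
    ("soil_n_per_ha_start_kg", "soil_n_per_ha_start", False, None),
    ("soil_n_per_ha_end_kg", "soil_n_per_ha_end", False, None),
    ("soil_p_per_ha_start_kg", "soil_p_per_ha_start", False, None),
    ("soil_p_per_ha_end_kg", "soil_p_per_ha_end", False, None),
    ("resolved_fertilizer_n_kg_per_yr", "resolved_fertilizer_n", False, None),
    ("resolved_fertilizer_p_kg_per_yr", "resolved_fertilizer_p", False, None),
    ("resolved_harvest_n_kg_per_yr", "resolved_harvest_n", False, None),
    ("resolved_harvest_p_kg_per_yr", "resolved_harvest_p", False, None),
]

_PLOT_FIELDS = [
    ("crop_name", "crop_name", True, None),
    ("area_ha", "area", True, None),
    ("fertilizer_rate_kg_per_ha_yr", "fertilizer_rate", False, 0.0),
    ("production_rate_kg_per_ha_yr", "production_rate", False, 0.0),
    ("crop_n_content_fraction", "crop_n_content", False, None),
    ("crop_p_content_fraction", "crop_p_content", False, None),
    ("resolved_harvest_n_kg_per_yr", "resolved_harvest_n", False, None),
    ("resolved_harvest_p_kg_per_yr", "resolved_harvest_p", False, None),
]


def _load_document(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping at the top level")
    return data


def _extract(data: dict, fields, context: str) -> dict:
    known = {key for key, *_ in fields} | {"plots"}
    for key in data:
        if key not in known:
            logger.warning("%s: unknown key %r ignored", context, key)
    out = {}
    for key, attr, required, default in fields:
        if key in data and data[key] is not None:
            out[attr] = data[key]
        elif required:
            raise ConfigurationError(f"{context}: missing required key {key!r}")
        else:
            out[attr] = default
    return out


def read_farm_config(path: Union[str, Path]) -> FarmRecord:
    """Read a farm record from a JSON/YAML configuration file."""
    data = _load_document(path)
    kwargs = _extract(data, _FARM_FIELDS, f"farm config {path}")
    plots_data = data.get("plots")
    if not plots_data:
        raise ConfigurationError(f"farm config {path}: missing required key 'plots'")
    plots = []
    for i, plot_data in enumerate(plots_data):
        plot_kwargs = _extract(plot_data, _PLOT_FIELDS, f"farm config {path} plots[{i}]")
        plots.append(CropPlot(**plot_kwargs))
    try:
        kwargs["liquid_treatment"] = LiquidMethod(kwargs["liquid_treatment"])
        kwargs["solid_treatment"] = SolidMethod(kwargs["solid_treatment"])
    except ValueError as exc:
        raise ConfigurationError(f"farm config {path}: {exc}") from None
    return FarmRecord(plots=tuple(plots), **kwargs)


def write_farm_config(farm: FarmRecord, path: Union[str, Path]) -> Path:
    """Serialize a farm record; format chosen by extension (.json else YAML)."""
    doc: dict = {}
    for key, attr, _required, default in _FARM_FIELDS:
        value = getattr(farm, attr)
        if isinstance(value, (LiquidMethod, SolidMethod)):
            value = value.value
        if value is None and default is None:
            continue
        doc[key] = value
    doc["plots"] = []
    for plot in farm.plots:
        plot_doc = {}
        for key, attr, _required, default in _PLOT_FIELDS:
            value = getattr(plot, attr)
            if value is None and default is None:
                continue
            plot_doc[key] = value
        doc["plots"].append(plot_doc)
    return _dump_document(doc, path)


def _nutrient_map(d: dict, context: str) -> dict:
    try:
        return {Nutrient.N: float(d["n"]), Nutrient.P: float(d["p"])}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"{context}: expected mapping with keys 'n' and 'p'") from exc


def read_flux_config(path: Union[str, Path]) -> FluxTable:
    """Read a flux/coefficient table from a JSON/YAML configuration file."""
    data = _load_document(path)
    ctx = f"flux config {path}"
    required = [
        "seed_flux_kg_per_ha_yr",
        "bnf_flux_kg_n_per_ha_yr",
        "deposition_kg_per_ha_yr",
        "volatilization_fraction",
        "denitrification",
        "leaching_fraction",
        "runoff_fraction",
        "manure_content_g_per_kg",
        "liquid_compost_content_g_per_kg",
        "solid_compost_content_g_per_kg",
        "loading_fraction",
    ]
    for key in required:
        if key not in data:
            raise ConfigurationError(f"{ctx}: missing required key {key!r}")
    seed = {
        crop: _nutrient_map(vals, f"{ctx}: seed flux for {crop!r}")
        for crop, vals in data["seed_flux_kg_per_ha_yr"].items()
    }
    vol = data["volatilization_fraction"]
    den = data["denitrification"]
    loading = {
        phase: {
            method: _nutrient_map(vals, f"{ctx}: loading {phase}/{method}")
            for method, vals in methods.items()
        }
        for phase, methods in data["loading_fraction"].items()
    }
    fert_content = data.get("fertilizer_content_fraction")
    return FluxTable(
        seed_flux=seed,
        bnf_flux=float(data["bnf_flux_kg_n_per_ha_yr"]),
        deposition=_nutrient_map(data["deposition_kg_per_ha_yr"], ctx),
        volatilization_fert=float(vol["chemical_fertilizer"]),
        volatilization_compost=float(vol["compost"]),
        denit_fert=float(den["chemical_fertilizer_fraction"]),
        denit_compost=float(den["compost_fraction"]),
        denit_arable=float(den["arable_land_kg_per_ha_yr"]),
        leach=_nutrient_map(data["leaching_fraction"], ctx),
        runoff=_nutrient_map(data["runoff_fraction"], ctx),
        manure_content=_nutrient_map(data["manure_content_g_per_kg"], ctx),
        liquid_compost_content=_nutrient_map(data["liquid_compost_content_g_per_kg"], ctx),
        solid_compost_content=_nutrient_map(data["solid_compost_content_g_per_kg"], ctx),
        loading=loading,
        fertilizer_content=_nutrient_map(fert_content, ctx) if fert_content else None,
    )


def write_flux_config(fluxes: FluxTable, path: Union[str, Path]) -> Path:
    """Serialize a flux table; format chosen by extension (.json else YAML)."""

    def nmap(d: dict) -> dict:
        return {"n": d[Nutrient.N], "p": d[Nutrient.P]}

    doc = {
        "seed_flux_kg_per_ha_yr": {crop: nmap(v) for crop, v in fluxes.seed_flux.items()},
        "bnf_flux_kg_n_per_ha_yr": fluxes.bnf_flux,
        "deposition_kg_per_ha_yr": nmap(fluxes.deposition),
        "volatilization_fraction": {
            "chemical_fertilizer": fluxes.volatilization_fert,
            "compost": fluxes.volatilization_compost,
        },
        "denitrification": {
            "chemical_fertilizer_fraction": fluxes.denit_fert,
            "compost_fraction": fluxes.denit_compost,
            "arable_land_kg_per_ha_yr": fluxes.denit_arable,
        },
        "leaching_fraction": nmap(fluxes.leach),
        "runoff_fraction": nmap(fluxes.runoff),
        "manure_content_g_per_kg": nmap(fluxes.manure_content),
        "liquid_compost_content_g_per_kg": nmap(fluxes.liquid_compost_content),
        "solid_compost_content_g_per_kg": nmap(fluxes.solid_compost_content),
        "loading_fraction": {
            phase: {method: nmap(v) for method, v in methods.items()}
            for phase, methods in fluxes.loading.items()
        },
    }
    if fluxes.fertilizer_content:
        doc["fertilizer_content_fraction"] = nmap(fluxes.fertilizer_content)
    return _dump_document(doc, path)


def _dump_document(doc: dict, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def display_round(value: float, decimals: int = 1) -> float:
    """Half-up rounding for display columns (printed budget-sheet style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def budget_report_frame(results: Sequence[BudgetResult]) -> pd.DataFrame:
    """Long-format report: one row per ledger term, plus summary rows
    (totals, surplus, and the N-surplus decomposition where present)."""
    if not results:
        raise ValueError("budget report needs at least one result")
    rows = []
    for res in results:
        base = {
            "farm_id": res.farm_id,
            "nutrient": res.nutrient.value,
            "approach": res.approach.value,
        }
        for ledger in (res.inputs, res.outputs):
            for term, value in ledger.terms:
                rows.append({**base, "side": ledger.side.value, "term": term,
                             "value_kg_per_yr": value})
        summary = [
            ("total_inputs", res.inputs.total),
            ("total_outputs", res.outputs.total),
            ("surplus", res.surplus),
        ]
        for name, value in (
            ("n_loss_before_application", res.nlb),
            ("n_loss_after_application", res.nla),
            ("atmospheric_gns", res.agns),
            ("hydrologic_gns", res.hgns),
        ):
            if value is not None:
                summary.append((name, value))
        for term, value in summary:
            rows.append({**base, "side": "summary", "term": term, "value_kg_per_yr": value})
    frame = pd.DataFrame(rows)
    frame["value_display"] = frame["value_kg_per_yr"].map(display_round)
    return frame


def _write_frame(frame: pd.DataFrame, path: Union[str, Path], fmt: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ConfigurationError(f"unknown report format {fmt!r}; use 'csv' or 'json'")
    return path


def write_budget_report(
    results: Sequence[BudgetResult], path: Union[str, Path], format: str = "csv"
) -> Path:
    """Write budget results to ``path`` as CSV or JSON (identical values)."""
    return _write_frame(budget_report_frame(results), path, format)


def write_scenario_report(
    comparison: ScenarioComparison, path: Union[str, Path], format: str = "csv"
) -> Path:
    """Write a scenario comparison: baseline and alternative SSB budgets
    plus surplus percent-reduction summary rows."""
    frames = []
    for label, budgets in (("baseline", comparison.baseline),
                           ("alternative", comparison.alternative)):
        frame = budget_report_frame(list(budgets.values()))
        frame.insert(0, "scenario", label)
        frames.append(frame)
    frame = pd.concat(frames, ignore_index=True)
    reduction_rows = []
    for nutrient, pct in comparison.reduction_pct.items():
        reduction_rows.append(
            {
                "scenario": "comparison",
                "farm_id": comparison.baseline[nutrient].farm_id,
                "nutrient": nutrient.value,
                "approach": "ssb",
                "side": "summary",
                "term": "surplus_reduction_pct",
                "value_kg_per_yr": pct,  # percent, not kg; column kept uniform
                "value_display": display_round(pct),
            }
        )
    frame = pd.concat([frame, pd.DataFrame(reduction_rows)], ignore_index=True)
    return _write_frame(frame, path, format)
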