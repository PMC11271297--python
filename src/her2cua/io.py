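"""Reading and writing model configurations.

The canonical on-disk form is a JSON or YAML document holding the flat
parameter values, the sampling-distribution specs and the run settings. Long
tables — the life table and per-strategy cost schedules — may instead be
referenced as CSV files whose rows are mapped back onto the canonical
parameter names; mismatched band or piece boundaries are a validation error
naming the offending row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .distributions import DistributionSpec
from .parameters import (
    ParameterSet,
    ParameterValidationError,
    build_parameter_set,
    builtin_base_case,
)
from .states import EfficacyMode

__all__ = [
    "parameter_set_to_dict",
    "parameter_set_from_dict",
    "load_parameter_set",
    "save_parameter_set",
    "packaged_base_case_path",
    "parameter_hash",
]

SCHEMA = "her2cua-model/1"

_SETTINGS_FIELDS = (
    "start_age_years",
    "horizon_age_years",
    "discount_rate_costs",
    "discount_rate_outcomes",
    "wtp_lkr",
    "lkr_per_usd",
)


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Serializable canonical form of a parameter set."""
    return {
        "schema": SCHEMA,
        "settings": {name: getattr(ps, name) for name in _SETTINGS_FIELDS},
        "efficacy_mode": ps.efficacy_mode.value,
        "values": dict(sorted(ps.values.items())),
        "distributions": {
            name: spec.to_dict() for name, spec in sorted(ps.distribution_specs.items())
        },
    }


def parameter_set_from_dict(doc: dict, base_dir: Path | None = None) -> ParameterSet:
    """Rebuild a parameter set from its canonical form.

    ``base_dir`` resolves relative CSV references (``life_table_csv``,
    ``cost_schedules_csv``).
    """
    if doc.get("schema") not in (None, SCHEMA):
        raise ParameterValidationError(f"unsupported schema {doc.get('schema')!r}")
    values = {str(k): float(v) for k, v in doc.get("values", {}).items()}
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    if "life_table_csv" in doc:
        values.update(_life_table_values(base_dir / doc["life_table_csv"]))
    for sid, rel in doc.get("cost_schedules_csv", {}).items():
        values.update(_cost_schedule_values(base_dir / rel, sid))
    specs = {
        str(name): DistributionSpec.from_dict(d)
        for name, d in doc.get("distributions", {}).items()
    }
    if not specs:
        specs = None
    settings = doc.get("settings", {})
    unknown = set(settings) - set(_SETTINGS_FIELDS)
    if unknown:
        raise ParameterValidationError(f"unknown settings: {sorted(unknown)}")
    return build_parameter_set(
        values,
        distribution_specs=specs,
        efficacy_mode=EfficacyMode(doc.get("efficacy_mode", EfficacyMode.HR_ON_BASELINE)),
        **{k: float(v) for k, v in settings.items()},
    )


def _life_table_values(path: Path) -> dict[str, float]:
    from .parameters import _MORT_BANDS  # canonical band boundaries

    table = pd.read_csv(path)
    required = {"age_low_years", "age_high_years", "monthly_death_probability"}
    if not required.issubset(table.columns):
        raise ParameterValidationError(
            f"{path.name}: life table CSV needs columns {sorted(required)}"
        )
    if len(table) != len(_MORT_BANDS):
        raise ParameterValidationError(
            f"{path.name}: expected {len(_MORT_BANDS)} life-table bands, got {len(table)}"
        )
    values = {}
    for i, (name, lo, hi) in enumerate(_MORT_BANDS):
        row = table.iloc[i]
        hi_csv = row["age_high_years"]
        open_ended = pd.isna(hi_csv)
        if row["age_low_years"] != lo or (open_ended != (hi is None)) or (
            hi is not None and not open_ended and hi_csv != hi
        ):
            raise ParameterValidationError(
                f"{path.name} row {i}: band [{row['age_low_years']}, {hi_csv}) "
                f"does not match the canonical band [{lo}, {hi})"
            )
        values[name] = float(row["monthly_death_probability"])
    return values


# canonical cost pieces: (state, clock, start, end, dmc name or None, dnmc name)
def _cost_piece_names(strategy_id: str):
    sl = strategy_id.lower()
    return (
        ("EVENT_FREE", "model_time", 0, 12, f"cost.ef_dmc_y1.{sl}", "cost.ef_dnmc_y1"),
        ("EVENT_FREE", "model_time", 12, 60, "cost.ef_dmc_y2_5", "cost.ef_dnmc_later"),
        ("EVENT_FREE", "model_time", 60, 120, "cost.ef_dmc_y6_10", "cost.ef_dnmc_later"),
        ("EVENT_FREE", "model_time", 120, None, "cost.ef_dmc_gt10", "cost.ef_dnmc_later"),
        ("LOCOREGIONAL", "time_in_state", 0, 12, "cost.lrr_dmc_y1", "cost.lrr_dnmc"),
        ("LOCOREGIONAL", "time_in_state", 12, None, "cost.lrr_dmc_later", "cost.lrr_dnmc"),
        ("REMISSION", "time_in_state", 0, 12, "cost.rem_dmc_y1", "cost.rem_dnmc_y1"),
        ("REMISSION", "time_in_state", 12, 60, "cost.rem_dmc_y2_5", "cost.rem_dnmc_later"),
        ("REMISSION", "time_in_state", 60, 120, "cost.rem_dmc_y6_10", "cost.rem_dnmc_later"),
        ("REMISSION", "time_in_state", 120, None, "cost.rem_dmc_gt10", "cost.rem_dnmc_later"),
        ("METASTASIS", "model_time", 0, None, "cost.met_dmc", "cost.met_dnmc"),
    )


def _cost_schedule_values(path: Path, strategy_id: str) -> dict[str, float]:
    table = pd.read_csv(path)
    required = {
        "state",
        "clock",
        "start_month",
        "end_month",
        "monthly_dmc_lkr",
        "monthly_dnmc_lkr",
    }
    if not required.issubset(table.columns):
        raise ParameterValidationError(
            f"{path.name}: cost schedule CSV needs columns {sorted(required)}"
        )
    canonical = _cost_piece_names(strategy_id)
    values: dict[str, float] = {}
    for i, row in table.iterrows():
        if row["state"] == "DEAD":
            continue
        end = None if pd.isna(row["end_month"]) else int(row["end_month"])
        key = (row["state"], row["clock"], int(row["start_month"]), end)
        for state, clock, start, stop, dmc_name, dnmc_name in canonical:
            if key == (state, clock, start, stop):
                _assign(values, dmc_name, float(row["monthly_dmc_lkr"]), path, i)
                _assign(values, dnmc_name, float(row["monthly_dnmc_lkr"]), path, i)
                break
        else:
            raise ParameterValidationError(
                f"{path.name} row {i}: piece {key} does not match a canonical "
                f"cost piece for strategy {strategy_id}"
            )
    return values


def _assign(values: dict, name: str, value: float, path: Path, row: int) -> None:
    if name in values and values[name] != value:
        raise ParameterValidationError(
            f"{path.name} row {row}: conflicting values for {name} "
            f"({values[name]} vs {value})"
        )
    values[name] = value


def save_parameter_set(ps: ParameterSet, path: str | Path) -> Path:
    """Write a parameter set as JSON (default) or YAML, by file suffix."""
    path = Path(path)
    doc = parameter_set_to_dict(ps)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a model configuration (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ParameterValidationError(f"{path.name}: expected a mapping document")
    return parameter_set_from_dict(doc, base_dir=path.parent)


def packaged_base_case_path() -> Path:
    """Location of the installed base-case fixture."""
    return Path(__file__).parent / "data" / "base_case.json"


def parameter_hash(ps: ParameterSet) -> str:
    """SHA-256 over the canonical serialized form, for report provenance."""
    doc = json.dumps(parameter_set_to_dict(ps), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def regenerate_packaged_base_case() -> Path:  # pragma: no cover - maintenance helper
    """Rewrite the installed base-case fixture from the in-code registry."""
    return save_parameter_set(builtin_base_case(), packaged_base_case_path())
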