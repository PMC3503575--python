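"""File formats: CSV measurement tables, YAML config, JSON reports.

Run files are delimited CSV with header ``name,role,value,std_uncertainty,
units``; the ``role`` column binds each measured row to a symbol of the
corresponding yield formula (e.g. ``f_IS_final``, ``C_X``).  Reports are
JSON with a provenance block (seed, config hash, package version) so any
result can be re-run bit-identically.

Percent convention: values cross this boundary on the scale people report
(yields in percent); all internal math uses fractions.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from .montecarlo import MCInputSpec
from .surrogate import CompositionProfile, EconConfig
from .uncertainty import Measurement, UncertaintyBudget
from .yields import (
    EnzymaticHydrolysisRun,
    FermentationRun,
    PretreatmentRun,
    YieldError,
)

__all__ = [
    "SchemaError",
    "read_measurements",
    "read_run",
    "write_run_csv",
    "read_mc_specs",
    "write_report",
    "read_report",
    "load_config",
]

_COLUMNS = ["name", "role", "value", "std_uncertainty", "units"]

_PT_BATCH = {"m_f", "m_i", "f_IS", "rho_L", "C_X", "x_X"}
_PT_CONT_DERIVED = {"feed_dry_flow", "feed_moisture", "water_flow",
                    "acid_flow", "f_IS", "rho_L", "C_X", "x_X"}
_PT_CONT_MEASURED = {"feed_dry_flow", "slurry_flow", "f_IS", "rho_L", "C_X",
                     "x_X"}
_EH = {"m_slurry_0", "f_IS_0", "x_C", "m_slurry_f", "f_IS_f", "rho_L", "C_G"}
_FERM = {"m_slurry_0", "f_IS_0", "m_slurry_f", "f_IS_f", "rho_L",
         "c_glc_0", "c_glc_f", "c_fru_0", "c_fru_f", "c_xyl_0", "c_xyl_f",
         "c_etoh_0", "c_etoh_f"}
_CONSTANT_ROLES = {"flash_loss", "assumed_hexose_yield"}


class SchemaError(ValueError):
    pass


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"run file missing columns: {missing}")
    dup = df["role"][df["role"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate role rows: {sorted(set(dup))}")
    if (df["std_uncertainty"] < 0).any():
        bad = df.loc[df["std_uncertainty"] < 0, "role"].tolist()
        raise SchemaError(f"negative std_uncertainty for roles: {bad}")
    return df


def read_measurements(path) -> dict[str, Measurement]:
    """Read a measurement table as a role -> Measurement mapping."""
    df = _read_table(path)
    return {
        str(rec["role"]): Measurement(
            str(rec["name"]), float(rec["value"]),
            float(rec["std_uncertainty"]), str(rec["units"]),
        )
        for rec in df.to_dict("records")
    }


def _require_roles(roles: Mapping[str, Measurement], needed: set,
                   unit: str) -> None:
    missing = sorted(needed - set(roles))
    if missing:
        raise SchemaError(f"{unit} run is missing roles: {missing}")


def read_run(path, unit: str):
    """Read a run CSV into the typed run object for ``unit``.

    ``unit`` is one of ``pretreatment``, ``eh`` (enzymatic hydrolysis) or
    ``fermentation``.  The pretreatment variant (batch, continuous with a
    measured slurry flow, continuous with a derived slurry flow) is inferred
    from the roles present.
    """
    roles = read_measurements(path)
    constants = {r: roles.pop(r).value for r in list(roles)
                 if r in _CONSTANT_ROLES}
    if unit == "pretreatment":
        if "m_f" in roles:
            _require_roles(roles, _PT_BATCH, unit)
            return PretreatmentRun(
                mode="batch",
                m_f=roles["m_f"], m_i=roles["m_i"], f_IS=roles["f_IS"],
                rho_L=roles["rho_L"], C_X=roles["C_X"], x_X=roles["x_X"],
            )
        if "slurry_flow" in roles:
            _require_roles(roles, _PT_CONT_MEASURED, unit)
            return PretreatmentRun(
                mode="continuous",
                feed_dry_flow=roles["feed_dry_flow"],
                slurry_flow=roles["slurry_flow"], f_IS=roles["f_IS"],
                rho_L=roles["rho_L"], C_X=roles["C_X"], x_X=roles["x_X"],
            )
        _require_roles(roles, _PT_CONT_DERIVED, unit)
        return PretreatmentRun(
            mode="continuous",
            feed_dry_flow=roles["feed_dry_flow"],
            feed_moisture=roles["feed_moisture"],
            water_flow=roles["water_flow"], acid_flow=roles["acid_flow"],
            flash_loss=constants.get("flash_loss", 0.0),
            f_IS=roles["f_IS"], rho_L=roles["rho_L"], C_X=roles["C_X"],
            x_X=roles["x_X"],
        )
    if unit == "eh":
        _require_roles(roles, _EH, "enzymatic hydrolysis")
        return EnzymaticHydrolysisRun(**{r: roles[r] for r in _EH})
    if unit == "fermentation":
        _require_roles(roles, _FERM, unit)
        return FermentationRun(
            **{r: roles[r] for r in _FERM},
            assumed_hexose_yield=constants.get("assumed_hexose_yield", 0.95),
        )
    raise SchemaError(f"unknown unit {unit!r}")


def write_run_csv(run, path) -> None:
    """Write a typed run back to the CSV run-file dialect."""
    rows = []

    def add(role: str, m: Optional[Measurement]):
        if m is not None:
            rows.append((m.name, role, m.value, m.std_uncertainty, m.units))

    def add_const(role: str, value: float):
        rows.append((role, role, value, 0.0, "constant"))

    if isinstance(run, PretreatmentRun):
        for role in ("m_f", "m_i", "feed_dry_flow", "feed_moisture",
                     "water_flow", "acid_flow", "slurry_flow", "f_IS",
                     "rho_L", "C_X", "x_X"):
            add(role, getattr(run, role))
        if run.mode == "continuous" and run.slurry_flow is None:
            add_const("flash_loss", run.flash_loss)
    elif isinstance(run, EnzymaticHydrolysisRun):
        for role in sorted(_EH):
            add(role, getattr(run, role))
    elif isinstance(run, FermentationRun):
        for role in sorted(_FERM):
            add(role, getattr(run, role))
        add_const("assumed_hexose_yield", run.assumed_hexose_yield)
    else:
        raise SchemaError(f"cannot serialize {type(run).__name__}")
    # %.17g keeps every float bit so read -> compute round-trips exactly
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False,
                                                float_format="%.17g")


def read_mc_specs(path) -> list[MCInputSpec]:
    """Monte Carlo input specs from CSV (name, base, max, uncertainty, group)."""
    df = pd.read_csv(path)
    needed = {"name", "base", "max", "uncertainty", "group"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"spec file missing columns: {sorted(missing)}")
    specs = []
    for rec in df.to_dict("records"):
        mx = None if pd.isna(rec["max"]) else float(rec["max"])
        specs.append(MCInputSpec(str(rec["name"]), float(rec["base"]),
                                 float(rec["uncertainty"]), str(rec["group"]),
                                 mx))
    return specs


def _sig12(x: float) -> float:
    return float(f"{x:.12g}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, UncertaintyBudget):
        return obj.to_dict()
    if hasattr(obj, "summary_dict"):
        return {k: _jsonable(v) for k, v in obj.summary_dict().items()}
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float):
        return _sig12(obj)
    return obj


def _config_hash(config: Any) -> str:
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results: Any, path, seed: Optional[int] = None,
                 config: Any = None) -> dict:
    """Write a JSON report with a provenance block; returns the payload.

    Budgets keep full float precision (so report -> parse -> report round
    trips losslessly); Monte Carlo summaries and other floats carry 12
    significant digits.
    """
    from . import __version__

    if isinstance(results, UncertaintyBudget):
        body = results.to_dict()          # full precision for round-trip
    else:
        body = _jsonable(results)
    payload = {
        "provenance": {
            "package": "biorefuq",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config) if config is not None else None,
        },
        "results": body,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Load a YAML/TOML plant configuration.

    Recognized keys: ``composition`` (component -> dry-basis fraction),
    ``econ`` (EconConfig fields), ``yields`` (reaction name -> fraction),
    ``feed_rate`` (kg dry/h), ``target_mesp`` ($/gal).
    """
    p = Path(path)
    if p.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(p.read_text())
    else:
        raw = yaml.safe_load(p.read_text()) or {}
    out: dict[str, Any] = {}
    if "composition" in raw:
        out["composition"] = CompositionProfile(**raw["composition"])
    if "econ" in raw:
        out["econ"] = EconConfig(**raw["econ"])
    out["yields"] = dict(raw.get("yields", {}))
    out["feed_rate"] = float(raw.get("feed_rate", 83_333.0))
    out["target_mesp"] = float(raw.get("target_mesp", 2.15))
    return out
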