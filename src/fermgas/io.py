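"""CSV/YAML/JSON input-output for runs, off-gas records and reports.

Run time series travel as CSV with a leading ``# key: value`` metadata block
(thiosulfate, yeast extract, phase markers, CO2 convention) followed by a
header row; off-gas records are plain CSV.  Machine-readable summaries are
JSON with a versioned schema and stable key order; configuration files are
flat YAML mappings of :class:`~fermgas.gas_balance.HeadspaceConfig` fields
(unknown keys rejected).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .accounting import FermentationRun, PhaseMarkers, SulfurBudget, YieldReport
from .exceptions import SchemaError
from .gas_balance import HeadspaceConfig, OutletGasSeries, ProductionSeries

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "load_run",
    "write_run",
    "load_gas",
    "write_gas",
    "write_production",
    "load_headspace_config",
    "report",
    "write_report",
]

REPORT_SCHEMA_VERSION = "1"

RUN_COLUMNS = {
    "time_h": "time_h",
    "cells_mg_L": "cells",
    "glucose_consumed_mM": "glucose_consumed",
    "lactate_mM": "lactate",
    "acetate_mM": "acetate",
    "alanine_mM": "alanine",
    "eps_glcEq_mM": "eps_glucose_equiv",
    "H2_mM": "h2",
    "CO2_mM": "co2",
}
_REQUIRED_RUN_COLUMNS = ("time_h", "cells_mg_L", "glucose_consumed_mM",
                         "lactate_mM", "acetate_mM", "H2_mM")

GAS_COLUMNS = ("time_h", "pN2_pct", "pH2_pct", "pCO2_pct", "qN2_ref_mL_min", "pH")


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def load_run(path: str | Path) -> FermentationRun:
    """Read a fermentation-run CSV, validating schema and invariants.

    Violations are reported with a row index (0-based data row) and column
    name where applicable.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    meta = _read_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if df.empty:
        raise SchemaError(f"{path} has no data rows")
    missing = [c for c in _REQUIRED_RUN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} missing required columns {missing}")
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError("time_h not strictly increasing", row=int(bad[0]) + 1,
                          column="time_h")
    for csv_name, attr in RUN_COLUMNS.items():
        if csv_name == "time_h" or csv_name not in df.columns:
            continue
        col = df[csv_name].to_numpy(dtype=float)
        neg = np.nonzero(col[np.isfinite(col)] < 0)[0]
        if np.any(np.isfinite(col) & (col < 0)):
            row = int(np.nonzero(np.isfinite(col) & (col < 0))[0][0])
            raise SchemaError("negative concentration", row=row, column=csv_name)

    def opt(name):
        if name not in df.columns:
            return None
        col = df[name].to_numpy(dtype=float)
        return col if np.isfinite(col).any() else None

    phases = None
    if all(f"t{i}_h" in meta for i in range(4)):
        phases = PhaseMarkers(*(float(meta[f"t{i}_h"]) for i in range(4)))
    return FermentationRun(
        time_h=t,
        cells=df["cells_mg_L"].to_numpy(dtype=float),
        glucose_consumed=df["glucose_consumed_mM"].to_numpy(dtype=float),
        lactate=df["lactate_mM"].to_numpy(dtype=float),
        acetate=df["acetate_mM"].to_numpy(dtype=float),
        h2=df["H2_mM"].to_numpy(dtype=float),
        co2=opt("CO2_mM"),
        alanine=opt("alanine_mM"),
        eps_glucose_equiv=opt("eps_glcEq_mM"),
        thiosulfate_initial_mM=float(meta.get("thiosulfate_mM", 0.0)),
        yeast_extract_g_L=float(meta.get("yeast_extract_g_L", 1.0)),
        phases=phases,
        co2_mode=meta.get("co2_mode", "measured" if opt("CO2_mM") is not None
                          else "acetate_stoichiometric"),
        label=meta.get("label", path.stem),
    )


def write_run(run: FermentationRun, path: str | Path) -> Path:
    """Write a fermentation run in the run CSV schema (metadata block + table)."""
    path = Path(path)
    lines = [
        f"# label: {run.label}",
        f"# thiosulfate_mM: {run.thiosulfate_initial_mM}",
        f"# yeast_extract_g_L: {run.yeast_extract_g_L}",
        f"# co2_mode: {run.co2_mode}",
    ]
    if run.phases is not None:
        for i, tval in enumerate(run.phases):
            lines.append(f"# t{i}_h: {tval}")
    cols = {"time_h": run.time_h}
    for csv_name, attr in RUN_COLUMNS.items():
        if csv_name == "time_h":
            continue
        arr = getattr(run, attr)
        if arr is not None:
            cols[csv_name] = arr
    df = pd.DataFrame(cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def load_gas(path: str | Path) -> OutletGasSeries:
    """Read an off-gas record CSV into an OutletGasSeries."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    missing = [c for c in GAS_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} missing required columns {missing}")
    ph = df["pH"].to_numpy(dtype=float) if "pH" in df.columns else None
    return OutletGasSeries(
        time_h=df["time_h"].to_numpy(dtype=float),
        p_n2=df["pN2_pct"].to_numpy(dtype=float),
        p_h2=df["pH2_pct"].to_numpy(dtype=float),
        p_co2=df["pCO2_pct"].to_numpy(dtype=float),
        q_n2_ref=df["qN2_ref_mL_min"].to_numpy(dtype=float),
        ph=ph,
    )


def write_gas(outlet: OutletGasSeries, path: str | Path) -> Path:
    """Write an off-gas record in the gas CSV schema."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": outlet.time_h,
            "pN2_pct": outlet.p_n2,
            "pH2_pct": outlet.p_h2,
            "pCO2_pct": outlet.p_co2,
            "qN2_ref_mL_min": outlet.q_n2_ref,
            "pH": outlet.ph if outlet.ph is not None else np.nan,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_production(production: ProductionSeries, path: str | Path) -> Path:
    """Write a reconstructed production series as CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_h": production.time_h,
            "qH2_mL_min": production.q_h2,
            "qCO2_mL_min": production.q_co2,
            "cumH2_mmol_L": production.cum_h2,
            "cumCO2_mmol_L": production.cum_co2,
        }
    )
    df.to_csv(path, index=False)
    return path


def load_headspace_config(path: str | Path) -> HeadspaceConfig:
    """Load a HeadspaceConfig from a flat YAML mapping; unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping of config fields")
    known = {f.name for f in dataclasses.fields(HeadspaceConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {unknown}")
    return HeadspaceConfig(**data)


def _round_like_table(value: float | None, digits: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return round(value, digits)


def _report_entry(rep: YieldReport) -> dict:
    full = {
        "window_h": list(rep.window_h),
        "c1_recovery_pct": rep.c1_recovery_pct,
        "c2_recovery_pct": rep.c2_recovery_pct,
        "h2_per_acetate": rep.h2_per_acetate,
        "acetate_per_glucose": rep.acetate_per_glucose,
        "lactate_per_glucose": rep.lactate_per_glucose,
        "h2_per_glucose": rep.h2_per_glucose,
        "alanine_per_glucose": rep.alanine_per_glucose,
        "eps_per_glucose": rep.eps_per_glucose,
        "cells_per_glucose_g_mol": rep.cells_per_glucose_g_mol,
        "q_cells_mg_L_h": rep.volumetric.q_cells_mg_L_h,
        "q_glucose_mM_h": rep.volumetric.q_glucose_mM_h,
        "q_h2_mM_h": rep.volumetric.q_h2_mM_h,
        "spec_q_glucose_mmol_g_h": rep.specific.q_glucose if rep.specific else None,
        "spec_q_h2_mmol_g_h": rep.specific.q_h2 if rep.specific else None,
    }
    digits = {"c1_recovery_pct": 1, "c2_recovery_pct": 1, "h2_per_acetate": 2,
              "acetate_per_glucose": 1, "lactate_per_glucose": 1, "h2_per_glucose": 1,
              "alanine_per_glucose": 2, "eps_per_glucose": 2,
              "cells_per_glucose_g_mol": 1, "q_cells_mg_L_h": 2, "q_glucose_mM_h": 2,
              "q_h2_mM_h": 2, "spec_q_glucose_mmol_g_h": 1, "spec_q_h2_mmol_g_h": 1}
    rounded = {k: _round_like_table(full[k], d) for k, d in digits.items()}
    return {"full_precision": full, "rounded": rounded}


def report(
    run: FermentationRun,
    reports: Sequence[YieldReport],
    sulfur: SulfurBudget | None = None,
) -> dict:
    """Assemble the JSON document for a run's derived summaries.

    Values are carried at full precision with a rounded companion view at
    table-style precision; key order is stable and the schema versioned.
    """
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "run": {
            "label": run.label,
            "thiosulfate_mM": run.thiosulfate_initial_mM,
            "yeast_extract_g_L": run.yeast_extract_g_L,
            "co2_mode": run.co2_mode,
            "n_samples": int(run.time_h.size),
        },
        "reports": [_report_entry(r) for r in reports],
    }
    if sulfur is not None:
        doc["sulfur_budget"] = {
            "s_yeast_extract_mM": sulfur.s_yeast_extract,
            "s_thiosulfate_mM": sulfur.s_thiosulfate,
            "s_cells_mM": sulfur.s_cells,
            "incorporation_ratio_pct": sulfur.incorporation_ratio_pct,
        }
    return doc


def write_report(doc: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path
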