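"""File formats: the flat curve-record CSV, JSON configuration and reports.

One CSV holds all three record types (equilibrium titration points,
thermal scan points, kinetic trace points), discriminated by a
``record_type`` column — a single artifact carries a whole study.
User-facing temperatures are Celsius; everything downstream converts to
Kelvin immediately.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import asdict, is_dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .models import CELSIUS_OFFSET

__all__ = [
    "CurveFormatError",
    "REQUIRED_COLUMNS",
    "read_curves",
    "group_curves",
    "AnalysisConfig",
    "round_half_up",
    "write_report",
    "read_report",
]

REQUIRED_COLUMNS = ["record_type", "protein_id", "temperature_C", "denaturant_M",
                    "time_s", "signal", "replicate"]

_RECORD_TYPES = {"equilibrium", "thermal", "kinetic"}


class CurveFormatError(ValueError):
    """A curve CSV failed validation; message lists offending lines."""


def read_curves(path) -> pd.DataFrame:
    """Read and validate a curve-record CSV.

    Validation errors are collected and reported together with their
    1-based file line numbers (header is line 1).  Returns the records
    sorted deterministically by (protein, record_type, condition,
    replicate, abscissa).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CurveFormatError(f"{path}: empty file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CurveFormatError(f"{path}: missing columns: {', '.join(missing)}")
    errors = []
    lines = df.index.to_numpy() + 2  # header occupies line 1

    def flag(mask, msg):
        for ln in lines[np.asarray(mask)][:20]:
            errors.append(f"line {ln}: {msg}")

    rt = df["record_type"].astype(str)
    flag(~rt.isin(_RECORD_TYPES), "record_type must be equilibrium/thermal/kinetic")
    for col in ("temperature_C", "denaturant_M", "time_s", "signal"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        flag(bad, f"{col} is not numeric")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    flag(df["signal"].isna(), "signal is required")
    flag(df["temperature_C"].notna() & (df["temperature_C"] <= -CELSIUS_OFFSET),
         "temperature_C below absolute zero")
    flag(df["denaturant_M"].notna() & (df["denaturant_M"] < 0), "negative denaturant_M")
    flag(df["time_s"].notna() & (df["time_s"] < 0), "negative time_s")
    eq = rt == "equilibrium"
    flag(eq & (df["denaturant_M"].isna() | df["temperature_C"].isna()),
         "equilibrium records need temperature_C and denaturant_M")
    kin = rt == "kinetic"
    flag(kin & df["time_s"].isna(), "kinetic records need time_s")
    flag((rt == "thermal") & df["temperature_C"].isna(),
         "thermal records need temperature_C")
    if errors:
        raise CurveFormatError(f"{path}: " + "; ".join(errors))
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").fillna(1).astype(int)
    sort_cols = ["protein_id", "record_type", "temperature_C", "denaturant_M",
                 "replicate", "time_s"]
    return df.sort_values(sort_cols, kind="stable", na_position="last").reset_index(drop=True)


def group_curves(df: pd.DataFrame) -> dict:
    """Group validated records by (protein_id, record_type, condition).

    The condition key is the titration temperature (°C) for equilibrium
    records, the final denaturant concentration (M) for kinetic records
    and ``None`` for thermal scans (any denaturant present in a melt
    buffer stays attached to the rows as metadata).
    """
    out = {}
    for (protein, rtype), sub in df.groupby(["protein_id", "record_type"], sort=True):
        if rtype == "equilibrium":
            for temp, block in sub.groupby("temperature_C", sort=True):
                out[(protein, rtype, float(temp))] = block.reset_index(drop=True)
        elif rtype == "kinetic":
            for dm, block in sub.groupby("denaturant_M", sort=True):
                out[(protein, rtype, float(dm))] = block.reset_index(drop=True)
        else:
            out[(protein, rtype, None)] = sub.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# configuration


class FitOptions(BaseModel):
    """Fit options shared by all estimators."""

    model_config = ConfigDict(extra="forbid")

    weighting: str = Field("none", pattern="^(none|stderr)$")
    multistart: int = Field(1, ge=1, le=50)


class SimulationDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eq_temperatures_C: list[float] = [10.0, 20.0, 30.0, 40.0, 50.0]
    eq_n_concentrations: int = Field(15, ge=9)
    kinetic_concentrations_M: list[float] = [4.0, 5.0, 6.0]
    kinetic_n_points: int = Field(60, ge=6)
    replicates: int = Field(2, ge=1, le=3)
    noise_fraction: float = Field(0.02, ge=0.0)
    melt_half_span_C: float = Field(25.0, gt=0)
    melt_step_C: float = Field(1.0, gt=0)


class AnalysisConfig(BaseModel):
    """JSON study configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    anchors: dict[str, float] = {}  # protein_id -> Tm in Celsius
    fit: FitOptions = FitOptions()
    simulation: SimulationDesign = SimulationDesign()
    output_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate_json(fh.read())

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.model_dump_json(indent=2))
            fh.write("\n")


# ---------------------------------------------------------------------------
# reports


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table style)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _sig3(x: float) -> float:
    """Round to 3 significant figures for display."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    mag = int(np.floor(np.log10(abs(x))))
    return round_half_up(x, 2 - mag)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report, path) -> None:
    """Serialise a report to JSON with stable key order.

    Full-precision floats are kept; display-rounded companions are added
    for the headline quantities (temperatures at 0.1 °C, energies at 3
    significant figures) under a ``display`` key.
    """
    data = _jsonable(report if isinstance(report, dict) else asdict(report))
    display = {}
    for pid, entry in (data.get("proteins") or {}).items():
        disp = {}
        for key, val in (entry or {}).items():
            if val is None or not isinstance(val, (int, float)):
                continue
            if key.startswith(("tm", "dtm")) or key.endswith("_C"):
                disp[key] = round_half_up(val, 1)
            elif key.startswith(("dh", "dcp", "dg")):
                disp[key] = _sig3(val)
        if disp:
            display[pid] = disp
    if display:
        data = dict(data)
        data["display"] = display
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
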