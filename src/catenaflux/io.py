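"""Schema-validated CSV readers and writers for every pipeline table.

All files are UTF-8 CSV with a header row, '.' decimals and ISO-8601
timestamps; closure intervals are half-open [start, end).  Each reader
validates the column set and coerces types, reporting offending rows by
line number, so a malformed table fails loudly at the stage boundary rather
than as a NaN three stages later.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fluxes import ChamberGeometry, ChamberTrace

__all__ = [
    "FLUXES_SCHEMA",
    "RAINFALL_SCHEMA",
    "SENSORS_SCHEMA",
    "SOIL_CHEM_SCHEMA",
    "SchemaError",
    "TableSchema",
    "read_table",
    "read_traces",
    "write_table",
    "write_traces",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    """Column names -> type codes ('float', 'int', 'str', 'bool',
    'datetime'), plus an optional unique-key column set."""

    name: str
    columns: Mapping[str, str]
    key: tuple[str, ...] = ()


SENSORS_SCHEMA = TableSchema(
    name="sensors",
    columns={"timestamp": "datetime", "transect": "int", "position": "int",
             "zone": "str", "moisture": "float", "o2_pct": "float",
             "temp_c": "float"},
    key=("timestamp", "transect", "position"))

RAINFALL_SCHEMA = TableSchema(
    name="rainfall",
    columns={"date": "datetime", "mm": "float"},
    key=("date",))

FLUXES_SCHEMA = TableSchema(
    name="fluxes",
    columns={"chamber_id": "str", "zone": "str", "closure_start": "datetime",
             "date": "datetime", "gas": "str", "flux": "float",
             "standard_error": "float", "model": "str",
             "uncertainty_ratio": "float", "qc_flags": "str",
             "retained": "bool"},
    key=("chamber_id", "closure_start", "gas"))

SOIL_CHEM_SCHEMA = TableSchema(
    name="soil_chem",
    columns={"period": "str", "zone": "str", "replicate": "int",
             "inorganic_p": "float", "organic_p": "float", "fe2": "float",
             "fe3": "float", "ph": "float"},
    key=("period", "zone", "replicate"))

_TRACE_SCHEMA = TableSchema(
    name="trace",
    columns={"t_s": "float", "co2_ppm": "float", "ch4_ppb": "float"})

_MANIFEST_SCHEMA = TableSchema(
    name="trace_manifest",
    columns={"trace_file": "str", "chamber_id": "str", "zone": "str",
             "closure_start": "datetime", "temp_c": "float",
             "rh_pct": "float", "press_kpa": "float", "volume_m3": "float",
             "area_m2": "float", "ambient_co2_ppm": "float",
             "ambient_ch4_ppb": "float"},
    key=("trace_file",))


def _coerce(series: pd.Series, kind: str, col: str, name: str) -> pd.Series:
    try:
        if kind == "datetime":
            out = pd.to_datetime(series, format="ISO8601")
        elif kind == "float":
            probe = pd.to_numeric(series, errors="coerce")
            bad = probe.isna() & series.notna()
            if bad.any():
                rows = (bad[bad].index + 2).tolist()[:5]
                raise SchemaError(
                    f"{name}: column {col!r} has non-numeric values at "
                    f"file lines {rows}")
            # exact (correctly rounded) parse so round-trips are lossless
            out = series.map(lambda x: float(x) if pd.notna(x)
                             else np.nan).astype(float)
        elif kind == "int":
            out = pd.to_numeric(series, errors="raise").astype(int)
        elif kind == "bool":
            if series.dtype == bool:
                out = series
            else:
                out = series.astype(str).str.lower().map(
                    {"true": True, "false": False, "1": True, "0": False})
                if out.isna().any():
                    raise SchemaError(f"{name}: column {col!r} not boolean")
        else:
            out = series.fillna("").astype(str)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{name}: cannot coerce column {col!r}: {exc}") from exc
    return out


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against ``schema``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name}: missing required columns {missing} in {path}")
    for col, kind in schema.columns.items():
        df[col] = _coerce(df[col], kind, col, schema.name)
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            rows = (dup[dup].index + 2).tolist()[:5]
            raise SchemaError(
                f"{schema.name}: duplicate {schema.key} keys at file lines "
                f"{rows}")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                schema: TableSchema | None = None) -> Path:
    """Write a CSV in the pipeline dialect (UTF-8, ISO dates, repr floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if schema is not None:
        missing = [c for c in schema.columns if c not in out.columns]
        if missing:
            raise SchemaError(
                f"{schema.name}: refusing to write without columns {missing}")
        out = out[list(schema.columns)]
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
    return path


def write_traces(traces: Sequence[ChamberTrace], out_dir: str | Path) -> Path:
    """One CSV per closure plus a manifest carrying geometry, covariates and
    ambient concentrations.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tr in enumerate(traces):
        fname = f"trace_{i:05d}_{tr.chamber_id}.csv"
        pd.DataFrame({"t_s": tr.t_s, "co2_ppm": tr.co2_ppm,
                      "ch4_ppb": tr.ch4_ppb}).to_csv(out_dir / fname,
                                                     index=False)
        rows.append({
            "trace_file": fname, "chamber_id": tr.chamber_id, "zone": tr.zone,
            "closure_start": tr.closure_start, "temp_c": tr.temp_c,
            "rh_pct": tr.rh_pct, "press_kpa": tr.press_kpa,
            "volume_m3": tr.geometry.volume_m3,
            "area_m2": tr.geometry.area_m2,
            "ambient_co2_ppm": tr.ambient["co2"],
            "ambient_ch4_ppb": tr.ambient["ch4"],
        })
    return write_table(pd.DataFrame(rows), out_dir / "manifest.csv",
                       _MANIFEST_SCHEMA)


def read_traces(trace_dir: str | Path) -> list[ChamberTrace]:
    """Round-trip of :func:`write_traces`."""
    trace_dir = Path(trace_dir)
    manifest = read_table(trace_dir / "manifest.csv", _MANIFEST_SCHEMA)
    traces = []
    for _, row in manifest.iterrows():
        tr = read_table(trace_dir / row["trace_file"], _TRACE_SCHEMA)
        traces.append(ChamberTrace(
            chamber_id=row["chamber_id"], zone=row["zone"],
            closure_start=row["closure_start"].to_pydatetime(),
            t_s=tr["t_s"].to_numpy(), co2_ppm=tr["co2_ppm"].to_numpy(),
            ch4_ppb=tr["ch4_ppb"].to_numpy(), temp_c=row["temp_c"],
            rh_pct=row["rh_pct"], press_kpa=row["press_kpa"],
            geometry=ChamberGeometry(volume_m3=row["volume_m3"],
                                     area_m2=row["area_m2"]),
            ambient={"co2": row["ambient_co2_ppm"],
                     "ch4": row["ambient_ch4_ppb"]}))
    return traces


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Timestamp,)):
            return o.isoformat()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_default) + "\n")
    return path
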