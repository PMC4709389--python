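"""Reading and writing observation tables and run configs.

On-disk observation format is a tidy delimited table with columns
exactly (time_min, compartment, value, unit, animal_id); time is always
minutes, values μM for drug and nmol/g for ACh.  Parsing is
locale-independent (dot decimal separator, C locale via pandas).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .exceptions import SchemaError
from .timeseries import COMPARTMENTS, UNIT_FOR_COMPARTMENT, ConcentrationTimeSeries

__all__ = ["read_observations", "write_observations", "load_config"]

OBS_COLUMNS = ("time_min", "compartment", "value", "unit", "animal_id")


def read_observations(path: str | Path, sep: str = "\t") -> dict[str, ConcentrationTimeSeries]:
    """Read a tidy observation table into per-compartment series.

    Every row is validated; schema violations report the offending
    0-based data row index.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, dtype={"animal_id": str},
                     float_precision="round_trip")
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}")
    for i, row in df.iterrows():
        comp = row["compartment"]
        if comp not in COMPARTMENTS:
            raise SchemaError(f"unknown compartment {comp!r}", row=int(i))
        if row["unit"] != UNIT_FOR_COMPARTMENT[comp]:
            raise SchemaError(
                f"unit {row['unit']!r} invalid for compartment {comp!r} "
                f"(expected {UNIT_FOR_COMPARTMENT[comp]!r})",
                row=int(i),
            )
        try:
            t = float(row["time_min"])
            v = float(row["value"])
        except (TypeError, ValueError):
            raise SchemaError("malformed number", row=int(i)) from None
        if t < 0:
            raise SchemaError(f"negative time {t}", row=int(i))
        if v < 0:
            raise SchemaError(f"negative value {v}", row=int(i))
    out = {}
    for comp in df["compartment"].unique():
        out[comp] = ConcentrationTimeSeries.from_frame(df, comp)
    return out


def write_observations(
    series: Iterable[ConcentrationTimeSeries], path: str | Path, sep: str = "\t"
) -> None:
    """Write one or more series to a tidy table (full float precision)."""
    # pandas' default float formatting is the shortest round-trippable repr
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    df.to_csv(path, sep=sep, index=False)


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run config (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
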