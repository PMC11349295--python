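"""Tabular and config I/O.

All tabular interchange is CSV with an optional commented metadata header
(``# key: value`` lines before the column header).  Every file the pipeline
writes records the seed and a hash of the run configuration so outputs are
traceable to their inputs.  Configuration files are YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_intensity_csv",
    "write_csv",
    "read_csv",
    "load_config",
    "save_config",
    "config_hash",
]

REQUIRED_INTENSITY_COLUMNS = ("condition", "replicate", "voltage_V", "gate_index", "intensity")


def write_csv(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a DataFrame as CSV with a ``# key: value`` metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        table.to_csv(fh, index=False)


def read_csv(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv`; returns (table, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        table = pd.read_csv(fh)
    return table, meta


def read_intensity_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a per-gate intensity table.

    ``column_map`` maps the required logical names (``condition, replicate,
    voltage_V, gate_index, intensity``) to the file's actual column names,
    so externally produced tables with different headers can be ingested.

    Raises ``ValueError`` naming offending rows for negative intensities or
    duplicate (condition, replicate, voltage, gate) keys, and for missing
    columns or an empty file.
    """
    table, _ = read_csv(path)
    if table.empty:
        raise ValueError(f"{path}: no data rows")
    if column_map:
        table = table.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    neg = table.index[table["intensity"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative intensity at row(s) {list(neg[:5])}")
    keys = ["condition", "replicate", "voltage_V", "gate_index"]
    dup = table.index[table.duplicated(keys)]
    if len(dup):
        raise ValueError(f"{path}: duplicate (condition, replicate, voltage, gate) at row(s) {list(dup[:5])}")
    if not pd.api.types.is_numeric_dtype(table["gate_index"]):
        raise ValueError(f"{path}: gate_index must be numeric")
    return table


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
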