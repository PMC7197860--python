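"""Tabular I/O and run configuration.

Datasets are plain delimited tables (CSV/TSV) with one row per individual:
observed time in years, a 0/1 event indicator, a categorical covariate
level, and optionally a 0/1/2 genotype column.  Column names and status
encodings are configurable so that externally produced tables can be read
without rewriting.  Residual tables are written back as CSV with a
provenance comment line carrying a hash of the producing configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurvivalRecord",
    "RunConfig",
    "read_dataset",
    "write_residuals",
    "config_hash",
]

SCHEMA_VERSION = 1

_CANONICAL = ("id", "time", "status", "covariate", "genotype")


@dataclass(frozen=True)
class SurvivalRecord:
    """One individual's right-censored observation."""

    id: object
    time: float
    status: int
    covariate: object = 1
    genotype: int | None = None

    def __post_init__(self):
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError("time must be strictly positive and finite")
        if self.status not in (0, 1):
            raise ValueError("status must be exactly 0 or 1")
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise ValueError("genotype must be 0, 1 or 2 copies of allele 1")


@dataclass
class RunConfig:
    """Parameters of one reproducible run; hashable for provenance."""

    command: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def config_hash(config) -> str:
    """Short sha256 of a canonical-JSON rendering of a config mapping."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def read_dataset(
    path,
    column_map: dict | None = None,
    status_map: dict | None = None,
    sep=None,
) -> pd.DataFrame:
    """Read and validate a survival dataset into canonical columns.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file; the delimiter is sniffed unless ``sep`` is given.
        Lines starting with ``#`` are treated as comments.
    column_map : dict, optional
        Maps canonical names (``time``, ``status``, ``covariate``,
        ``genotype``, ``id``) to the file's column names.
    status_map : dict, optional
        Maps raw status values to 0/1, e.g. ``{"event": 1, "censored": 0}``.

    Raises
    ------
    ValueError
        With row-numbered messages for non-positive times or invalid
        status codes; KeyError for missing columns.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", comment="#")
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    missing = [
        v for k, v in column_map.items() if v not in df.columns
    ]
    if missing:
        raise KeyError(f"mapped column(s) {missing} not found in {path}")
    df = df.rename(columns=rename)
    for col in ("time", "status", "covariate"):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path}")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if status_map:
        df["status"] = df["status"].map(lambda v: status_map.get(v, v))
    df["status"] = pd.to_numeric(df["status"], errors="coerce")
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    bad_time = df.index[~(np.isfinite(df["time"]) & (df["time"] > 0))].tolist()
    if bad_time:
        raise ValueError(
            f"non-positive or unparseable time in row(s) {bad_time} of {path}"
        )
    bad_status = df.index[~df["status"].isin([0, 1])].tolist()
    if bad_status:
        raise ValueError(f"invalid status in row(s) {bad_status} of {path}")
    df["status"] = df["status"].astype(int)
    if "genotype" in df.columns:
        bad_g = df.index[~df["genotype"].isin([0, 1, 2])].tolist()
        if bad_g:
            raise ValueError(f"genotype outside 0/1/2 in row(s) {bad_g} of {path}")
    ordered = [c for c in _CANONICAL if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_residuals(table: pd.DataFrame, path, config=None) -> None:
    """Write a residual table as CSV (10 significant digits, lossless
    round-trip at that precision) with a provenance comment header."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty residual table")
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# teres config-hash: {config_hash(config)}\n")
        table.to_csv(fh, index=False, float_format="%.10g")
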