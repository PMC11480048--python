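"""Fermentation-log I/O.

A :class:`FermLog` is a per-minute table of true and measured process
channels plus the control-action audit trail.  Logs are stored as plain
CSV with a small commented header (schema version, seed, config hash) so
a run can be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FermLog", "SCHEMA_VERSION", "SCHEMA_COLUMNS", "read_log", "write_log", "SchemaError"]

SCHEMA_VERSION = 1

SCHEMA_COLUMNS = [
    "t", "N", "feed_rate", "V", "X", "S", "EtOH", "Ara", "Suc", "P", "DO",
    "F_air", "F_O2", "y_O2_in", "y_CO2_in", "qS_true",
    "y_O2_true", "y_CO2_true", "OUR_true", "CER_true", "RQ_true",
    "y_O2_meas", "y_CO2_meas", "humidity_meas",
    "OUR_meas", "CER_meas", "RQ_meas", "RQ_ctrl",
    "cum_fed", "cum_CO2", "cum_O2",
    "action_delta", "action_rule", "epsilon", "K_P",
]


class SchemaError(ValueError):
    """The file does not match the fermentation-log schema."""


@dataclass
class FermLog:
    """Time-indexed fermentation record with provenance metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"log is missing columns: {missing}")
        t = self.df["t"].to_numpy()
        if len(t) == 0:
            raise SchemaError("log has no rows")
        if np.any(np.diff(t) <= 0):
            raise SchemaError("log times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.df)


def write_log(log: FermLog, path: str) -> None:
    """Write a log as CSV with a commented provenance header."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# rqcontrol-fermlog schema={SCHEMA_VERSION}\n")
        for key in sorted(log.meta):
            fh.write(f"# {key}={log.meta[key]}\n")
        log.df.to_csv(fh, index=False, columns=SCHEMA_COLUMNS, float_format="%.17g")


def read_log(path: str) -> FermLog:
    """Read a log written by :func:`write_log` (lossless to ~1e-12)."""
    meta: dict = {}
    lines = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# rqcontrol-fermlog"):
            raise SchemaError("not a fermentation log (missing schema header)")
        try:
            version = int(first.strip().split("schema=")[1])
        except (IndexError, ValueError) as exc:
            raise SchemaError("malformed schema header") from exc
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {version}")
        for line in fh:
            if line.startswith("# "):
                key, _, value = line[2:].strip().partition("=")
                meta[key] = value
            else:
                lines.append(line)
                break
        lines.extend(fh)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"log is missing columns: {missing}")
    return FermLog(df, meta=meta)
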