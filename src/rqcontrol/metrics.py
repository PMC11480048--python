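"""Controller performance statistics.

Accuracy is measured as the mean relative error from the set-point,

    MRE = (1/n) * sum_i |y_i - y_sp| / y_sp,

and precision as the root-mean-square deviation from the trace mean,

    RMSD = sqrt( sum_i (y_i - y_mean)^2 / n ).

Both are computed on the per-minute soft-sensed RQ trace, excluding
samples where the RQ is undefined (the low-signal startup window).  Band
occupancy and disturbance recovery time (with a dwell requirement, so a
single in-band sample does not count as recovery) complete the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RqTrace",
    "mre",
    "rmsd",
    "band_occupancy",
    "recovery_time",
    "trace_from_log",
    "compare_controllers",
    "render_report",
]


@dataclass(frozen=True)
class RqTrace:
    """An ordered RQ time series with its set-point."""

    t: tuple[float, ...]
    y: tuple[float, ...]
    y_sp: float = 1.4

    def __post_init__(self) -> None:
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if len(self.t) == 0:
            raise ValueError("trace must contain at least one sample")
        if any(b <= a for a, b in zip(self.t, self.t[1:])):
            raise ValueError("times must be strictly increasing")
        if self.y_sp <= 0:
            raise ValueError("set-point must be positive")

    @property
    def n(self) -> int:
        return len(self.y)


def trace_from_log(
    log,
    channel: str = "RQ_meas",
    set_point: float = 1.4,
    t_min: float = 0.0,
    t_max: float | None = None,
) -> RqTrace:
    """Extract a defined-RQ trace from a fermentation log."""
    df = log.df
    mask = np.isfinite(df[channel].to_numpy()) & (df["t"].to_numpy() >= t_min)
    if t_max is not None:
        mask &= df["t"].to_numpy() <= t_max
    sub = df.loc[mask]
    if sub.empty:
        raise ValueError("no defined RQ samples in the requested window")
    return RqTrace(tuple(sub["t"]), tuple(sub[channel]), y_sp=set_point)


def mre(trace: RqTrace) -> float:
    """Mean relative error from the set-point (accuracy; 0 is perfect)."""
    y = np.asarray(trace.y)
    return float(np.mean(np.abs(y - trace.y_sp)) / trace.y_sp)


def rmsd(trace: RqTrace) -> float:
    """Root-mean-square deviation from the trace mean (precision)."""
    y = np.asarray(trace.y)
    return float(np.sqrt(np.mean((y - y.mean()) ** 2)))


def mean_absolute_deviation(trace: RqTrace) -> float:
    """Mean |y - set-point| on the trace's own scale."""
    y = np.asarray(trace.y)
    return float(np.mean(np.abs(y - trace.y_sp)))


def band_occupancy(trace: RqTrace, band: tuple[float, float]) -> float:
    """Fraction of samples with y inside [band[0], band[1]]."""
    lo, hi = band
    if hi <= lo:
        raise ValueError("band must be a non-empty interval")
    y = np.asarray(trace.y)
    return float(np.mean((y >= lo) & (y <= hi)))


def recovery_time(
    trace: RqTrace,
    t_dist: float,
    band: tuple[float, float],
    dwell_min: float = 10.0,
) -> float:
    """Hours after ``t_dist`` until RQ stays inside ``band`` for the dwell.

    Returns 0 when the trace never leaves the band after the disturbance,
    and ``inf`` when no window of length ``dwell_min`` ever stays inside.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("band must be a non-empty interval")
    t = np.asarray(trace.t)
    y = np.asarray(trace.y)
    if t_dist < t[0] or t_dist > t[-1]:
        raise ValueError("t_dist outside the trace span")
    sel = t >= t_dist
    t, y = t[sel], y[sel]
    inside = (y >= lo) & (y <= hi)
    dwell_h = dwell_min / 60.0
    # first sample from which the trace remains in-band for >= dwell_h
    start: float | None = None
    for ti, ok in zip(t, inside):
        if ok and start is None:
            start = ti
        elif not ok:
            start = None
        if start is not None and ti - start >= dwell_h - 1e-9:
            return max(0.0, start - t_dist)
    if start is not None and t[-1] - start >= dwell_h - 1e-9:
        return max(0.0, start - t_dist)
    return math.inf


def compare_controllers(
    logs: Mapping[str, Sequence],
    set_point: float = 1.4,
    band: tuple[float, float] = (1.2, 1.6),
    t_min: float = 0.0,
    t_dist: float | None = None,
    recovery_band: tuple[float, float] = (1.3, 1.5),
    dwell_min: float = 10.0,
) -> pd.DataFrame:
    """Per-replicate and mean +/- SD statistics for each strategy."""
    if not logs or any(len(v) == 0 for v in logs.values()):
        raise ValueError("need at least one log per strategy")
    rows = []
    for strategy, runs in logs.items():
        for i, log in enumerate(runs):
            trace = trace_from_log(log, set_point=set_point, t_min=t_min)
            row = {
                "strategy": strategy,
                "replicate": i + 1,
                "MRE": mre(trace),
                "RMSD": rmsd(trace),
                "mean_abs_dev": mean_absolute_deviation(trace),
                "band_occupancy": band_occupancy(trace, band),
            }
            if t_dist is not None and trace.t[0] <= t_dist <= trace.t[-1]:
                row["recovery_h"] = recovery_time(
                    trace, t_dist, recovery_band, dwell_min
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    return df


def summarise(report: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD across replicates, per strategy."""
    value_cols = [c for c in report.columns if c not in ("strategy", "replicate")]
    return report.groupby("strategy")[value_cols].agg(["mean", "std"])


def render_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of the comparison table."""
    lines = ["Controller performance (per replicate)", ""]
    lines.append(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append("Mean +/- SD across replicates")
    lines.append("")
    summary = summarise(report)
    lines.append(summary.to_string(float_format=lambda v: f"{v:.4f}"))
    return "\n".join(lines)
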