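"""Trajectory summary statistics: peaks, interpolated values, decline
rates, value-frequency histograms and skewness.

These are the quantities one reads off a simulated trajectory plot: the
peak level and when it occurs, the terminal level, the average rate of
decline over a window, and the distribution of the trajectory's values
across the saved time samples (the histogram a single simulated run
induces).  Note on terminology: a trajectory that spends most of its
time near zero has most histogram mass in the lowest bin — in the
standard moment convention that is a *right*-skewed (positive g1)
distribution, although such plots are sometimes informally called
left-skewed.  :func:`sample_skewness` implements the standard statistic.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import Trajectory

__all__ = [
    "SummaryError",
    "TrajectorySummary",
    "peak_stats",
    "value_at",
    "trajectory_histogram",
    "sample_skewness",
    "decline_rate",
    "summarize",
    "summaries_to_csv",
]


class SummaryError(ValueError):
    """Codes: UNKNOWN_VARIABLE, OUT_OF_RANGE, DEGENERATE."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


def _series(traj: Trajectory, variable: str) -> np.ndarray:
    try:
        return traj.series[variable]
    except KeyError:
        raise SummaryError("UNKNOWN_VARIABLE", f"no variable {variable!r}") from None


def peak_stats(traj: Trajectory, variable: str) -> tuple[float, float]:
    """Maximum saved value and the earliest time achieving it."""
    values = _series(traj, variable)
    idx = int(np.argmax(values))  # argmax returns the first maximum
    return float(values[idx]), float(traj.times[idx])


def value_at(traj: Trajectory, variable: str, t: float) -> float:
    """Linear interpolation between adjacent saved samples; exact at
    saved times.  ``t`` must lie within the saved horizon."""
    values = _series(traj, variable)
    times = traj.times
    if t < times[0] or t > times[-1]:
        raise SummaryError(
            "OUT_OF_RANGE", f"t={t} outside [{times[0]}, {times[-1]}]")
    return float(np.interp(t, times, values))


def trajectory_histogram(
    traj: Trajectory, variable: str, bin_width: float = 0.1
) -> list[tuple[tuple[float, float], int]]:
    """Frequencies of the trajectory's values over its saved samples.

    Bins are half-open ``[k*w, (k+1)*w)`` anchored at zero (values may
    be negative for unclamped variables; ``k`` can be negative), covering
    the observed range; counts sum to the number of saved samples.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = _series(traj, variable)
    ks = np.floor(values / bin_width).astype(int)
    return [
        ((k * bin_width, (k + 1) * bin_width), int(np.sum(ks == k)))
        for k in range(int(ks.min()), int(ks.max()) + 1)
    ]


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson skewness g1 with the n^2/((n-1)(n-2))
    small-sample bias correction."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise SummaryError("DEGENERATE", "need at least 3 values")
    if np.ptp(values) == 0 or np.isclose(np.var(values), 0.0):
        raise SummaryError("DEGENERATE", "zero variance")
    return float(stats.skew(values, bias=False))


def decline_rate(traj: Trajectory, variable: str, from_t: float, to_t: float) -> float:
    """Average slope (per year) between two times; negative means decline."""
    if not from_t < to_t:
        raise SummaryError("OUT_OF_RANGE", "need from_t < to_t")
    return (value_at(traj, variable, to_t) - value_at(traj, variable, from_t)) / (
        to_t - from_t
    )


@dataclass(frozen=True)
class TrajectorySummary:
    """One variable's headline numbers (million persons unless stated)."""

    variable: str
    peak_value: float
    peak_time: float
    final_value: float
    modal_bin: tuple[float, float]
    skewness: float
    monotone_increasing: bool = False


def summarize(traj: Trajectory, variable: str, bin_width: float = 0.1) -> TrajectorySummary:
    """Full summary of one variable of a trajectory."""
    peak_value, peak_time = peak_stats(traj, variable)
    values = _series(traj, variable)
    hist = trajectory_histogram(traj, variable, bin_width)
    modal_bin = max(hist, key=lambda item: item[1])[0]
    try:
        skew = sample_skewness(values)
    except SummaryError:
        skew = float("nan")
    return TrajectorySummary(
        variable=variable,
        peak_value=peak_value,
        peak_time=peak_time,
        final_value=float(values[-1]),
        modal_bin=modal_bin,
        skewness=skew,
        monotone_increasing=bool(np.all(np.diff(values) >= 0)),
    )


def summaries_to_csv(summaries: list[TrajectorySummary]) -> str:
    """CSV export with one row per summarized variable."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([
        "variable", "peak_value", "peak_time", "final_value",
        "modal_bin_lo", "modal_bin_hi", "skewness",
    ])
    for s in summaries:
        writer.writerow([
            s.variable, repr(s.peak_value), repr(s.peak_time), repr(s.final_value),
            repr(s.modal_bin[0]), repr(s.modal_bin[1]), repr(s.skewness),
        ])
    return buf.getvalue()
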