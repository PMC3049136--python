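"""Fold-change detection statistics and the 10%-amplitude criterion.

A system detects fold changes if its response depends on the ratio of the
input step to the background, not on absolute levels.  Operationally, two
input profiles related by a constant factor (here A2 = 2*A1) are applied at
identical time points and the per-interval peak responses y1_j, y2_j are
compared: fold-change detection is reported when responses agree to within
10% in amplitude.  Consecutive-step statistics probe the same property
along a single doubling profile, where each transition is one 2-fold step
from an adapted baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ResponseMetrics:
    """Per-stimulation-interval response summary of one trajectory.

    ``peaks`` are raw maximal values y_j within each interval (not
    baseline-subtracted), ``pre_values``/``end_values`` the trajectory at
    interval start/end, in the unit the trajectory carries.
    """

    species: str
    unit: str
    intervals: tuple          # interval indices into the signal
    peaks: np.ndarray         # y_j
    peak_times: np.ndarray
    pre_values: np.ndarray
    end_values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.intervals)
        for name in ("peaks", "peak_times", "pre_values", "end_values"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")


@dataclass(frozen=True)
class FCDReport:
    """Verdict of the 10%-amplitude criterion for one statistic."""

    statistic: str
    values: np.ndarray
    threshold: float
    max_value: float
    passed: bool
    violations: tuple  # indices of intervals exceeding the threshold

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "values": [float(v) for v in self.values],
            "threshold": self.threshold,
            "max_value": float(self.max_value),
            "passed": bool(self.passed),
            "violations": list(self.violations),
        }


def _peaks(m: ResponseMetrics, skip_onset: bool) -> np.ndarray:
    y = np.asarray(m.peaks, dtype=float)
    return y[1:] if skip_onset and len(y) > 1 else y


def ratio_statistics(m1: ResponseMetrics, m2: ResponseMetrics | None = None,
                     skip_onset: bool = True) -> dict:
    """Absolute peak ratios |y1_{j+1}/y1_j|, |y1_j/y1_{j+1}| and |y1_j/y2_j|.

    ``skip_onset`` drops the first responsive interval (the onset from the
    zero background), which establishes the adapted baseline and is not a
    fold step; the published criterion applies to the fold transitions.
    """
    y1 = _peaks(m1, skip_onset)
    if np.any(y1 == 0):
        raise ZeroDivisionError("zero peak value in profile 1")
    out = {
        "consecutive_forward": np.abs(y1[1:] / y1[:-1]),
        "consecutive_backward": np.abs(y1[:-1] / y1[1:]),
    }
    if m2 is not None:
        y2 = _peaks(m2, skip_onset)
        if len(y2) != len(y1):
            raise ValueError("profiles have different interval counts")
        if np.any(y2 == 0):
            raise ZeroDivisionError("zero peak value in profile 2")
        out["cross"] = np.abs(y1 / y2)
    return out


def relative_difference_statistics(m1: ResponseMetrics, m2: ResponseMetrics | None = None,
                                   skip_onset: bool = True) -> dict:
    """Relative differences |(y1_{j+1}-y1_j)/y1_j|, |(y1_j-y1_{j+1})/y1_{j+1}|
    and |(y1_j-y2_j)/y2_j| of per-interval peak responses."""
    y1 = _peaks(m1, skip_onset)
    if np.any(y1 == 0):
        raise ZeroDivisionError("zero peak value in profile 1")
    out = {
        "consecutive_forward": np.abs((y1[1:] - y1[:-1]) / y1[:-1]),
        "consecutive_backward": np.abs((y1[:-1] - y1[1:]) / y1[1:]),
    }
    if m2 is not None:
        y2 = _peaks(m2, skip_onset)
        if len(y2) != len(y1):
            raise ValueError("profiles have different interval counts")
        if np.any(y2 == 0):
            raise ZeroDivisionError("zero peak value in profile 2")
        out["cross"] = np.abs((y1 - y2) / y2)
    return out


def fcd_verdict(values, threshold: float = 0.10, statistic: str = "") -> FCDReport:
    """Pass iff every per-interval value is at or below the threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty statistic values")
    viol = tuple(int(i) for i in np.nonzero(values > threshold)[0])
    return FCDReport(statistic=statistic, values=values, threshold=threshold,
                     max_value=float(values.max()), passed=not viol, violations=viol)
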