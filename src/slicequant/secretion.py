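"""Perifusion trace analysis: stimulation indices and windowed AUCs.

Slices are perifused with timed secretagogue switches while the effluent is
sampled every minute.  Each hormone/enzyme trace is normalized to its mean
over a low-glucose baseline window, giving a dimensionless stimulation index
(SI), and responses are summarized as trapezoidal areas under the SI curve
over canonical analysis windows.

Two clocks coexist: the stimulation sequence (G3/G16.7/G1/G3+KCl/G3, 86 min
from the first switch) and the analysis window clock (1–60 min) used for the
canonical AUC windows; both are configurable and treated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusSegment",
    "StimulusSchedule",
    "default_schedule",
    "CANONICAL_WINDOWS",
    "stimulation_index",
    "window_auc",
    "analyze_trace",
]


@dataclass(frozen=True)
class StimulusSegment:
    label: str
    start_min: float
    duration_min: float
    composition: str

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("segment duration must be positive")

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class StimulusSchedule:
    segments: tuple[StimulusSegment, ...]

    def __post_init__(self) -> None:
        segs = self.segments
        for a, b in zip(segs, segs[1:]):
            if not np.isclose(a.end_min, b.start_min):
                raise ValueError("segments must be contiguous and non-overlapping")

    @property
    def total_min(self) -> float:
        return self.segments[-1].end_min - self.segments[0].start_min

    @property
    def starts(self) -> tuple[float, ...]:
        return tuple(s.start_min for s in self.segments)


def default_schedule() -> StimulusSchedule:
    """The five-segment perifusion sequence (86 min total).

    16 min at 3 mM glucose, 20 min at 16.7 mM, 30 min at 1 mM, 5 min of
    3 mM + 30 mM KCl depolarization, then 15 min at 3 mM.
    """
    spec = [
        ("G3", 16.0, "3 mM glucose"),
        ("G16.7", 20.0, "16.7 mM glucose"),
        ("G1", 30.0, "1 mM glucose"),
        ("G3+KCl", 5.0, "3 mM glucose + 30 mM KCl"),
        ("G3", 15.0, "3 mM glucose"),
    ]
    segments = []
    t = 0.0
    for label, dur, comp in spec:
        segments.append(StimulusSegment(label, t, dur, comp))
        t += dur
    return StimulusSchedule(tuple(segments))


#: Analysis-clock AUC windows (min): baseline, high glucose, low glucose, KCl.
CANONICAL_WINDOWS: Mapping[str, tuple[float, float]] = {
    "baseline": (1.0, 10.0),
    "high_glucose": (10.0, 32.0),
    "low_glucose": (32.0, 50.0),
    "kcl": (50.0, 60.0),
}


def _as_arrays(times_min, values):
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, v


def stimulation_index(
    times_min: Sequence[float],
    values: Sequence[float],
    baseline_window: tuple[float, float] = CANONICAL_WINDOWS["baseline"],
) -> np.ndarray:
    """Trace divided by its mean over the baseline window."""
    t, v = _as_arrays(times_min, values)
    lo, hi = baseline_window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    base = v[sel].mean()
    if base <= 0:
        raise ValueError("baseline mean must be positive")
    return v / base


def window_auc(
    times_min: Sequence[float],
    si: Sequence[float],
    window: tuple[float, float],
) -> float:
    """Trapezoidal integral of the SI trace over ``window`` (SI * min).

    Integration uses only samples falling inside the window (no interpolation
    or imputation across missing samples).
    """
    t, v = _as_arrays(times_min, si)
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive width")
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    return float(np.trapezoid(v[sel], t[sel]))


def analyze_trace(
    times_min: Sequence[float],
    values: Sequence[float],
    windows: Mapping[str, tuple[float, float]] | None = None,
    baseline_window: tuple[float, float] = CANONICAL_WINDOWS["baseline"],
) -> dict[str, float]:
    """SI-normalize a trace and report the AUC of every analysis window."""
    windows = dict(CANONICAL_WINDOWS if windows is None else windows)
    si = stimulation_index(times_min, values, baseline_window)
    return {name: window_auc(times_min, si, win) for name, win in windows.items()}
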