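"""Calcium-imaging trace quantification and cell classification.

Per-cell Fluo-4 fluorescence traces are converted to percent change over
baseline (dF/F), responses to each stimulus application are quantified as the
area under the positive part of dF/F, and a response is accepted only when it
was elicited at least twice by the same stimulus with a peak at least twice
the baseline fluctuation.  Cells are classified by their accepted-response
profile: beta cells respond to both high glucose (16.7 mM) and KCl
depolarization; acinar cells respond to carbachol (or CCK8) without KCl
depolarization; everything else stays unclassified (this excludes alpha-like
KCl-only responders).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseRecord",
    "delta_f_over_f",
    "baseline_fluctuation",
    "response_auc",
    "accept_response",
    "classify_cell",
    "analyze_cells",
    "BETA_STIMULI",
    "ACINAR_STIMULI",
]

BETA_STIMULI = ("G16.7", "KCl")
ACINAR_STIMULI = ("carbachol", "CCK8")


@dataclass
class ResponseRecord:
    """Summary of one cell's responses to one stimulus."""

    stimulus: str
    auc_above_baseline: float
    peak_pct: float
    n_elicited: int
    accepted: bool


def _select(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive width")
    sel = (t >= lo) & (t <= hi)
    if not sel.any():
        raise ValueError("window contains no samples")
    return sel


def delta_f_over_f(
    times_s: Sequence[float],
    f: Sequence[float],
    baseline_window: tuple[float, float],
) -> np.ndarray:
    """Percent fluorescence change over baseline: 100 * (F - F0) / F0."""
    t = np.asarray(times_s, dtype=float)
    f = np.asarray(f, dtype=float)
    f0 = f[_select(t, baseline_window)].mean()
    if f0 <= 0:
        raise ValueError("baseline mean fluorescence must be positive")
    return 100.0 * (f - f0) / f0


def baseline_fluctuation(
    times_s: Sequence[float],
    dff: Sequence[float],
    baseline_window: tuple[float, float],
    method: str = "sd",
) -> float:
    """Baseline fluctuation of dF/F: standard deviation (default) or
    half the peak-to-peak excursion over the baseline window."""
    t = np.asarray(times_s, dtype=float)
    d = np.asarray(dff, dtype=float)[_select(t, baseline_window)]
    if method == "sd":
        return float(d.std())
    if method == "ptp2":
        return float(np.ptp(d) / 2.0)
    raise ValueError(f"unknown method {method!r}")


def response_auc(
    times_s: Sequence[float],
    dff: Sequence[float],
    window: tuple[float, float],
) -> float:
    """Area under the positive part of dF/F over ``window`` (% * s).

    Excursions below baseline contribute nothing.
    """
    t = np.asarray(times_s, dtype=float)
    d = np.asarray(dff, dtype=float)
    sel = _select(t, window)
    if sel.sum() < 2:
        raise ValueError("window contains fewer than 2 samples")
    return float(np.trapezoid(np.clip(d[sel], 0.0, None), t[sel]))


def accept_response(n_elicited: int, peak_pct: float, baseline_fluct: float) -> bool:
    """Acceptance rule: elicited >= 2 times AND peak >= 2 x baseline fluctuation."""
    if baseline_fluct <= 0:
        raise ValueError("baseline fluctuation must be positive")
    return n_elicited >= 2 and peak_pct >= 2.0 * baseline_fluct


def classify_cell(accepted: Mapping[str, bool]) -> str:
    """Map accepted-response profile to {beta, acinar, unclassified}."""
    def any_of(labels):
        return any(accepted.get(lbl, False) for lbl in labels)

    if accepted.get("KCl", False) and accepted.get("G16.7", False):
        return "beta"
    if any_of(ACINAR_STIMULI) and not accepted.get("KCl", False):
        return "acinar"
    return "unclassified"


def analyze_cells(
    times_s: Sequence[float],
    traces: np.ndarray,
    stimulus_windows: Mapping[str, Sequence[tuple[float, float]]],
    baseline_window: tuple[float, float],
    cell_ids: Sequence[str] | None = None,
    fluctuation_method: str = "sd",
) -> pd.DataFrame:
    """Full per-cell analysis of a trace matrix (n_cells x n_frames).

    ``stimulus_windows`` maps each stimulus label to the windows of its
    (possibly repeated) applications; the elicitation count is the number of
    windows whose in-window peak clears twice the baseline fluctuation.
    Returns one tidy row per cell x stimulus, plus the cell class label.
    """
    t = np.asarray(times_s, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if cell_ids is None:
        cell_ids = [f"cell{i:03d}" for i in range(traces.shape[0])]

    rows = []
    for cid, f in zip(cell_ids, traces):
        dff = delta_f_over_f(t, f, baseline_window)
        fluct = baseline_fluctuation(t, dff, baseline_window, method=fluctuation_method)
        accepted_map: dict[str, bool] = {}
        records: list[ResponseRecord] = []
        for stim, windows in stimulus_windows.items():
            peaks = [float(dff[_select(t, w)].max()) for w in windows]
            n_elicited = sum(p >= 2.0 * fluct for p in peaks)
            auc = sum(response_auc(t, dff, w) for w in windows)
            ok = accept_response(n_elicited, max(peaks), fluct)
            accepted_map[stim] = ok
            records.append(ResponseRecord(stim, auc, max(peaks), n_elicited, ok))
        label = classify_cell(accepted_map)
        for rec in records:
            rows.append(
                {
                    "cell": cid,
                    "stimulus": rec.stimulus,
                    "auc_above_baseline": rec.auc_above_baseline,
                    "peak_pct": rec.peak_pct,
                    "n_elicited": rec.n_elicited,
                    "accepted": rec.accepted,
                    "baseline_fluctuation_pct": fluct,
                    "cell_class": label,
                }
            )
    return pd.DataFrame(rows)
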