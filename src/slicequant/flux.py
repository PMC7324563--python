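"""Evaporation-corrected metabolic flux rates for daily medium assays.

Slice cultures lose water to evaporation between medium changes, which
inflates every analyte concentration.  Because osmolarity rises in exact
proportion to the lost volume, the ratio of the blank osmolarity to the
culture-sample osmolarity undoes the inflation:

    GCR = (G_blank - G_culture * Osm_blank / Osm_culture) / dT
    LPR = (L_culture * Osm_blank / Osm_culture - L_blank) / dT

with a matched medium blank measured at every timepoint.  Rates are reported
per hour and normalized per microgram of DNA.  The formulas are unit-agnostic
ratios/differences; the table declares one unit per analyte at ingest.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_assay_table",
    "evaporation_correct",
    "gcr",
    "lpr",
    "compute_fluxes",
    "atp_efficiency",
    "daily_rate_auc",
    "fold_change",
]

#: Schema of a medium assay table (one row per day x group x replicate).
REQUIRED_COLUMNS = (
    "day",
    "group",
    "replicate",
    "g_culture",
    "g_blank",
    "l_culture",
    "l_blank",
    "osm_culture",
    "osm_blank",
    "delta_time_h",
    "dna_ug",
)


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table is missing columns: {missing}")
    if not (table["osm_culture"] > 0).all() or not (table["osm_blank"] > 0).all():
        raise ValueError("osmolarity values must be positive")
    if not (table["delta_time_h"] > 0).all():
        raise ValueError("delta_time_h must be positive")
    return table


def evaporation_correct(c_culture, osm_blank, osm_culture):
    """Rescale a culture-sample concentration to blank osmolarity.

    Evaporation concentrates solutes; multiplying by Osm_blank/Osm_culture
    recovers the concentration the sample would have had at blank volume.
    """
    osm_culture = np.asarray(osm_culture, dtype=float)
    osm_blank = np.asarray(osm_blank, dtype=float)
    if np.any(osm_culture <= 0) or np.any(osm_blank <= 0):
        raise ValueError("osmolarity must be positive")
    return c_culture * (osm_blank / osm_culture)


def gcr(g_blank, g_culture, osm_blank, osm_culture, delta_time_h, dna_ug=None):
    """Glucose consumption rate, (amount consumed / h), per ug DNA if given."""
    delta_time_h = np.asarray(delta_time_h, dtype=float)
    if np.any(delta_time_h <= 0):
        raise ValueError("delta_time_h must be positive")
    rate = (g_blank - evaporation_correct(g_culture, osm_blank, osm_culture)) / delta_time_h
    if dna_ug is not None:
        rate = rate / np.asarray(dna_ug, dtype=float)
    return rate


def lpr(l_blank, l_culture, osm_blank, osm_culture, delta_time_h, dna_ug=None):
    """Lactate production rate, (amount produced / h), per ug DNA if given."""
    delta_time_h = np.asarray(delta_time_h, dtype=float)
    if np.any(delta_time_h <= 0):
        raise ValueError("delta_time_h must be positive")
    rate = (evaporation_correct(l_culture, osm_blank, osm_culture) - l_blank) / delta_time_h
    if dna_ug is not None:
        rate = rate / np.asarray(dna_ug, dtype=float)
    return rate


def compute_fluxes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row GCR and LPR for an assay table.

    Negative computed rates are physically possible under measurement noise;
    they are flagged (``qc_negative_rate``) rather than clamped.
    """
    table = validate_assay_table(table)
    out = table.copy()
    out["gcr"] = gcr(
        table["g_blank"].to_numpy(float),
        table["g_culture"].to_numpy(float),
        table["osm_blank"].to_numpy(float),
        table["osm_culture"].to_numpy(float),
        table["delta_time_h"].to_numpy(float),
        table["dna_ug"].to_numpy(float),
    )
    out["lpr"] = lpr(
        table["l_blank"].to_numpy(float),
        table["l_culture"].to_numpy(float),
        table["osm_blank"].to_numpy(float),
        table["osm_culture"].to_numpy(float),
        table["delta_time_h"].to_numpy(float),
        table["dna_ug"].to_numpy(float),
    )
    out["qc_negative_rate"] = (out["gcr"] < 0) | (out["lpr"] < 0)
    return out


def atp_efficiency(atp_pmol_per_ug_protein: float, glucose_ug_per_ug_protein: float) -> float:
    """ATP produced per unit glucose consumed (both protein-normalized)."""
    if glucose_ug_per_ug_protein <= 0:
        raise ValueError("glucose consumption must be positive")
    return atp_pmol_per_ug_protein / glucose_ug_per_ug_protein


def daily_rate_auc(days: Sequence[float], rates: Sequence[float]) -> float:
    """Trapezoidal area under a daily rate series (rate x day)."""
    days = np.asarray(days, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if days.size < 2:
        raise ValueError("need at least 2 days for an AUC")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing without duplicates")
    return float(np.trapezoid(rates, days))


def fold_change(a: float, b: float, nearest: bool = False) -> float:
    """Ratio ``a / b``, optionally rounded to the nearest whole fold."""
    if b == 0:
        raise ValueError("denominator is zero")
    ratio = a / b
    return float(round(ratio)) if nearest else float(ratio)
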