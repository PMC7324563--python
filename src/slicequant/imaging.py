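"""Longitudinal quantification of multi-channel slice images.

Low-magnification slice-wide imaging is quantified per timepoint: the
brightfield channel yields the tissue mask and cross-sectional area, each
fluorescence channel is thresholded within the tissue mask, and lineage
tracing is summarized as the red (dsRED reporter), green (EGFP tracer) and
yellow (pixelwise red AND green co-localization) percentages of slice area.
Viability is area-based (live vs dead channel), nuclei are counted by
smoothed local-maximum detection with minimum-distance suppression, and
marker positivity is scored per nucleus neighbourhood.

Z-stacks are reduced by maximum-intensity projection before 2D analysis.
Fractions are normalized to each day's own tissue area, so no cross-day
registration is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, filters, measure, morphology

__all__ = [
    "SliceImageSeries",
    "segment_tissue",
    "channel_mask",
    "area_fractions",
    "viability",
    "count_nuclei",
    "mfi_per_cell",
    "marker_positive_count",
    "longitudinal_report",
]


@dataclass
class SliceImageSeries:
    """Multi-channel image stacks over culture days.

    ``frames`` holds one dict per timepoint mapping channel role (brightfield,
    red, green, dapi, live, dead, marker names...) to a 2D image (or a 3D
    z-stack, max-projected on use).  All channels of a timepoint must share
    x/y dimensions.
    """

    days: list[int]
    frames: list[dict[str, np.ndarray]]
    pixel_size_um: float
    group: str = "treated"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if len(self.days) != len(self.frames):
            raise ValueError("days and frames must align")
        for frame in self.frames:
            shapes = {np.asarray(img).shape[-2:] for img in frame.values()}
            if len(shapes) > 1:
                raise ValueError("all channels of a timepoint must share dimensions")


def _project(image: np.ndarray) -> np.ndarray:
    """Max-intensity projection of a z-stack; 2D images pass through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.max(axis=0)
    if image.ndim != 2:
        raise ValueError("expected a 2D image or 3D z-stack")
    return image


def segment_tissue(brightfield: np.ndarray, pixel_size_um: float) -> tuple[np.ndarray, float]:
    """Tissue mask and cross-sectional area (mm^2) from brightfield.

    Otsu threshold, morphological closing, hole filling, then the largest
    connected component.  Raises if the image carries no foreground contrast.
    """
    img = _project(brightfield)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        raise ValueError("no tissue found (uniform image)")
    mask = img > filters.threshold_otsu(img)
    mask = morphology.closing(mask, morphology.disk(3))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise ValueError("no tissue found (empty foreground)")
    labels = measure.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    area_mm2 = float(mask.sum()) * (pixel_size_um / 1000.0) ** 2
    return mask, area_mm2


def channel_mask(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    background_radius: int | None = None,
) -> np.ndarray:
    """Binary channel mask restricted to the tissue mask.

    ``method='otsu'`` thresholds automatically over tissue pixels (an all-zero
    channel yields an empty mask); ``method='fixed'`` uses ``threshold``
    inclusively, which must lie within the image intensity range.  Optional
    white-tophat background subtraction with a disk of ``background_radius``
    pixels runs before thresholding.
    """
    img = _project(image)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if img.shape != tissue_mask.shape:
        raise ValueError("image and tissue mask shapes differ")
    if background_radius is not None:
        img = morphology.white_tophat(img, morphology.disk(background_radius))

    if method == "otsu":
        vals = img[tissue_mask]
        if vals.size == 0:
            return np.zeros_like(tissue_mask)
        if np.ptp(vals) == 0:
            # constant channel: empty if dark, full tissue if uniformly bright
            return tissue_mask.copy() if vals.max() > 0 else np.zeros_like(tissue_mask)
        t = filters.threshold_otsu(vals)
        return (img > t) & tissue_mask
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        if not (min(0.0, img.min()) <= threshold <= img.max()):
            raise ValueError("fixed threshold outside intensity range")
        return (img >= threshold) & tissue_mask
    raise ValueError(f"unknown threshold method {method!r}")


def area_fractions(
    red_mask: np.ndarray,
    green_mask: np.ndarray,
    tissue_mask: np.ndarray,
) -> tuple[float, float, float]:
    """(red %, green %, yellow %) of tissue area; yellow = red AND green."""
    red_mask = np.asarray(red_mask, dtype=bool)
    green_mask = np.asarray(green_mask, dtype=bool)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not (red_mask.shape == green_mask.shape == tissue_mask.shape):
        raise ValueError("masks must share a shape")
    total = tissue_mask.sum()
    if total == 0:
        raise ValueError("empty tissue mask")
    red = (red_mask & tissue_mask).sum()
    green = (green_mask & tissue_mask).sum()
    yellow = (red_mask & green_mask & tissue_mask).sum()
    return (100.0 * red / total, 100.0 * green / total, 100.0 * yellow / total)


def viability(live_mask: np.ndarray, dead_mask: np.ndarray) -> float:
    """Area-based viable percentage: 100 * |live| / (|live| + |dead|)."""
    live = np.asarray(live_mask, dtype=bool).sum()
    dead = np.asarray(dead_mask, dtype=bool).sum()
    if live + dead == 0:
        raise ValueError("both masks are empty")
    return 100.0 * live / (live + dead)


def count_nuclei(
    dapi: np.ndarray,
    tissue_mask: np.ndarray,
    min_distance: int = 5,
    sigma: float = 2.0,
    threshold_rel: float = 0.25,
) -> tuple[int, np.ndarray]:
    """Count nuclei as smoothed local maxima inside the tissue mask.

    Peaks closer than ``min_distance`` are merged (the stronger survives).
    Detection thresholds are relative to the image maximum, so counts are
    invariant to uniform intensity gain; a blank channel counts zero.
    Returns the count and the peak coordinates (row, col).
    """
    img = _project(dapi)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if np.ptp(img) == 0:
        return 0, np.empty((0, 2), dtype=int)
    smooth = ndimage.gaussian_filter(img, sigma)
    peaks = feature.peak_local_max(
        smooth,
        min_distance=min_distance,
        threshold_rel=threshold_rel,
        labels=tissue_mask.astype(int),
    )
    return len(peaks), peaks


def mfi_per_cell(
    intensity: np.ndarray,
    tissue_mask: np.ndarray,
    n_cells: int,
) -> float:
    """Mean fluorescence intensity over tissue, normalized per cell."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    img = _project(intensity)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    return float(img[tissue_mask].mean() / n_cells)


def marker_positive_count(
    marker: np.ndarray,
    nuclei_positions: np.ndarray,
    threshold: float,
    radius_px: int = 3,
) -> tuple[int, float]:
    """Count nuclei whose marker neighbourhood mean exceeds ``threshold``.

    Returns (count, fraction of all nuclei).  Fractions over markers need not
    sum to one: multi-negative cells exist.
    """
    img = _project(marker)
    positions = np.asarray(nuclei_positions, dtype=int)
    if positions.size == 0:
        raise ValueError("no nuclei provided")
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = (yy**2 + xx**2) <= radius_px**2
    count = 0
    for r, c in positions:
        r0, r1 = max(r - radius_px, 0), min(r + radius_px + 1, img.shape[0])
        c0, c1 = max(c - radius_px, 0), min(c + radius_px + 1, img.shape[1])
        sub = img[r0:r1, c0:c1]
        dsub = disk[
            r0 - (r - radius_px) : disk.shape[0] - ((r + radius_px + 1) - r1),
            c0 - (c - radius_px) : disk.shape[1] - ((c + radius_px + 1) - c1),
        ]
        if sub[dsub].mean() > threshold:
            count += 1
    return count, count / len(positions)


def longitudinal_report(
    series: SliceImageSeries,
    channel_method: str = "fixed",
    channel_threshold: float | None = 0.5,
    background_radius: int | None = None,
) -> pd.DataFrame:
    """Tidy per-day report of slice area, lineage fractions and viability.

    Red/green channels are required for lineage fractions; live/dead and dapi
    channels are used when present.
    """
    if not series.frames:
        raise ValueError("series has no timepoints")

    def mask_of(img, tissue):
        # a channel with no signal reaching a fixed threshold is simply empty
        if channel_method == "fixed" and _project(img).max() < channel_threshold:
            return np.zeros_like(tissue)
        return channel_mask(img, tissue, channel_method, channel_threshold, background_radius)

    rows = []
    for day, frame in zip(series.days, series.frames):
        if "brightfield" not in frame:
            raise ValueError("each timepoint needs a brightfield channel")
        tissue, area = segment_tissue(frame["brightfield"], series.pixel_size_um)
        row: dict[str, object] = {"day": day, "group": series.group, "slice_area_mm2": area}
        if "red" in frame and "green" in frame:
            red = mask_of(frame["red"], tissue)
            green = mask_of(frame["green"], tissue)
            row["red_pct"], row["green_pct"], row["yellow_pct"] = area_fractions(
                red, green, tissue
            )
        if "live" in frame and "dead" in frame:
            row["viable_pct"] = viability(
                mask_of(frame["live"], tissue), mask_of(frame["dead"], tissue)
            )
        if "dapi" in frame:
            row["nuclei"], _ = count_nuclei(frame["dapi"], tissue)
        rows.append(row)
    return pd.DataFrame(rows)
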