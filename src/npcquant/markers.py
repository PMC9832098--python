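"""Per-cell nuclear-marker intensity profiling and population summaries.

Quantifies mean nuclear gray intensity of transcription-factor markers
(e.g. ASCL1, OLIG2, SOX2) per segmented nucleus and reproduces the
population-level summaries used with such data: percent-positive
fractions, frequency histograms normalized to the maximum bin count
within one comparison, median intensities and their fold changes, and a
top-fraction ("30% brightest") high/low classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters

log = logging.getLogger(__name__)

__all__ = [
    "HistogramSummary",
    "max_project",
    "measure_nuclear_markers",
    "percent_positive",
    "frequency_histograms",
    "top_fraction_high",
    "median_fold_change",
    "otsu_positivity_threshold",
]


@dataclass
class HistogramSummary:
    """Normalized frequency histogram of one population within a comparison."""

    bin_edges: np.ndarray
    counts: np.ndarray              # raw counts, sum == n_cells
    normalized_counts: np.ndarray   # counts / max bin count across the comparison
    median_intensity: float
    n_cells: int


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximal projection of an image stack (per-pixel maximum across planes)."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError("expected a non-empty stack of 2-D planes")
    return arr.max(axis=0)


def measure_nuclear_markers(nuclei: np.ndarray,
                            marker_images: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean gray value per nucleus label and marker.

    Returns a long-format table with one row per (cell, marker):
    ``cell_id``, ``marker``, ``nuclear_mean_intensity``.
    """
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    rows = []
    for name, img in marker_images.items():
        if img.shape != nuclei.shape:
            raise ValueError(f"marker image {name!r} does not match the mask frame")
        if labels.size == 0:
            continue
        m = int(labels.max())
        area = np.bincount(nuclei.ravel(), minlength=m + 1)
        total = np.bincount(nuclei.ravel(), weights=np.asarray(img, float).ravel(),
                            minlength=m + 1)
        for lab in labels:
            rows.append({"cell_id": int(lab), "marker": name,
                         "nuclear_mean_intensity": total[lab] / area[lab]})
    return pd.DataFrame(rows, columns=["cell_id", "marker", "nuclear_mean_intensity"])


def otsu_positivity_threshold(intensities: np.ndarray) -> float:
    """Default positivity threshold: Otsu on the pooled intensity distribution."""
    vals = np.asarray(intensities, dtype=float)
    if vals.size < 2 or vals.max() == vals.min():
        raise ValueError("need at least two distinct intensities for Otsu")
    t = float(filters.threshold_otsu(vals))
    log.info("otsu_positivity_threshold: %g", t)
    return t


def percent_positive(intensities: np.ndarray, positivity_threshold: float,
                     denominator: int | None = None) -> float:
    """Percentage of marker-positive cells.

    ``denominator`` defaults to the number of profiled cells (the
    subpopulation itself); pass the total DAPI count to express the
    percentage relative to all nuclei.
    """
    vals = np.asarray(intensities, dtype=float)
    denom = len(vals) if denominator is None else int(denominator)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * float(np.sum(vals > positivity_threshold)) / denom


def frequency_histograms(populations: dict[str, np.ndarray],
                         bins: int = 50,
                         bin_edges: np.ndarray | None = None
                         ) -> dict[str, HistogramSummary]:
    """Frequency histograms normalized to the maximum count in one comparison.

    All populations in one call form a single comparison: they share bin
    edges (over the pooled min-max range by default) and one normalizer,
    the largest raw bin count across all of them, so the modal bin of
    the dominant population reaches exactly 1.0.
    """
    if not populations:
        raise ValueError("no populations to histogram")
    arrays = {k: np.asarray(v, dtype=float) for k, v in populations.items()}
    nonempty = [v for v in arrays.values() if v.size]
    if not nonempty:
        log.warning("frequency_histograms: all populations empty")
        edges = np.linspace(0.0, 1.0, bins + 1) if bin_edges is None else np.asarray(bin_edges)
        return {k: HistogramSummary(edges, np.zeros(len(edges) - 1),
                                    np.zeros(len(edges) - 1), float("nan"), 0)
                for k in arrays}
    if bin_edges is None:
        pooled = np.concatenate(nonempty)
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, bins + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    counts = {k: np.histogram(v, bins=bin_edges)[0] for k, v in arrays.items()}
    norm = max(int(c.max()) for c in counts.values()) if counts else 0
    out = {}
    for k, v in arrays.items():
        c = counts[k].astype(float)
        out[k] = HistogramSummary(
            bin_edges=bin_edges,
            counts=c,
            normalized_counts=c / norm if norm else c,
            median_intensity=float(np.median(v)) if v.size else float("nan"),
            n_cells=int(v.size),
        )
    return out


def top_fraction_high(intensities: np.ndarray, fraction: float = 0.30
                      ) -> tuple[float, np.ndarray]:
    """Label the top ``fraction`` brightest cells as "high".

    Returns ``(threshold, high_flags)`` where the threshold is the
    intensity of the dimmest high cell (the ceil(fraction*n)-th
    brightest) and every cell at or above it is high.  Ties at the
    threshold are all included, which can push the high set above the
    nominal fraction; that is logged.
    """
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one intensity")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * vals.size)
    threshold = float(np.sort(vals)[::-1][k - 1])
    high = vals >= threshold
    if int(high.sum()) > k:
        log.warning("top_fraction_high: %d ties at threshold %g inflate the high "
                    "set to %d of a nominal %d", int(high.sum()) - k + 1,
                    threshold, int(high.sum()), k)
    return threshold, high


def median_fold_change(condition: np.ndarray, reference: np.ndarray) -> float:
    """Ratio of median intensities, condition over reference.

    Returns NaN (flagged in the log) when the reference median is zero.
    """
    cond = np.asarray(condition, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if cond.size == 0 or ref.size == 0:
        raise ValueError("both populations must be nonempty")
    ref_med = float(np.median(ref))
    if ref_med == 0:
        log.warning("median_fold_change: reference median is zero; no ratio")
        return float("nan")
    return float(np.median(cond)) / ref_med
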