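"""CDK2 translocation-reporter (DHB-mVenus) bioimage analysis workflow.

The reporter is nuclear in newly born / quiescent cells and moves to the
cytoplasm when phosphorylated by CDK2, so the per-cell ratio of mean
cytoplasmic to mean nuclear reporter fluorescence (C/N) is a proxy for
CDK2 activity.  The workflow:

1. segment nuclei from the DAPI channel and the reporter-positive cell
   area from the mVenus channel;
2. discard nuclei of uninfected (reporter-negative) cells;
3. split touching/clumped cells by a seeded Voronoi partition of the
   cell area around the retained nuclei;
4. derive per-cell cytoplasm masks as the set difference (XOR) of each
   cell region and its nucleus;
5. redirect the masks to the reporter image to measure N, C, C/N and
   the cytoplasmic integrated density (IntDens);
6. classify cells with no cytoplasmic mask or C/N below a threshold
   (default 0.65, strict) as G0/G1, and score residual CDK2 activity as
   the mean IntDens of G0/G1 cells, reported as fold change against a
   reference condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

log = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "segment_nuclei",
    "segment_cells",
    "filter_uninfected",
    "voronoi_partition",
    "cytoplasm_masks",
    "measure_cells",
    "classify_cycle_state",
    "score_residual_activity",
    "qc_min_cells",
    "run_workflow",
]


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunable parameters of the reporter workflow.

    ``cn_g0g1_threshold`` is configurable because two conventions exist
    in practice (0.65 and 0.95); the strict-inequality default of 0.65
    classifies a cell as G0/G1 when C/N < 0.65.
    """

    nuclear_threshold_method: str = "otsu"   # "otsu", "triangle", "background", "fixed"
    nuclear_fixed_threshold: float = 0.0
    cell_threshold_method: str = "background"
    cell_fixed_threshold: float = 0.0
    background_k_sigma: float = 3.0
    min_nucleus_area: int = 20
    min_overlap_for_infected: float = 0.5
    cn_g0g1_threshold: float = 0.65
    min_cells_per_culture: int = 250
    background_subtract: float = 0.0
    cell_mask_closing_radius: int = 2

    def __post_init__(self):
        if self.cn_g0g1_threshold <= 0:
            raise ValueError("cn_g0g1_threshold must be positive")
        if self.min_nucleus_area <= 0:
            raise ValueError("min_nucleus_area must be positive")
        if not 0 <= self.min_overlap_for_infected <= 1:
            raise ValueError("min_overlap_for_infected must be in [0, 1]")


def _threshold(image: np.ndarray, method: str, fixed: float,
               k_sigma: float = 3.0) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if method == "fixed":
        return img > fixed
    if img.max() == img.min():
        # constant image: nothing to segment
        return np.zeros(img.shape, dtype=bool)
    if method == "otsu":
        return img > filters.threshold_otsu(img)
    if method == "triangle":
        return img > filters.threshold_triangle(img)
    if method == "background":
        # background statistics: median + k * robust sigma.  Robust to the
        # bi-level (cytoplasm vs nucleus) signal that misleads Otsu when the
        # background dominates the histogram.
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        return img > med + k_sigma * sigma
    raise ValueError(f"unknown threshold method: {method!r}")


def segment_nuclei(dapi_image: np.ndarray, config: WorkflowConfig) -> np.ndarray:
    """Segment nuclei from the DAPI channel into a label image.

    Global threshold (Otsu by default), hole filling, area filter at
    ``min_nucleus_area``, connected-component labeling with labels
    contiguous from 1.  An empty or all-background image yields an
    empty mask (all zeros), not an error.
    """
    binary = _threshold(dapi_image, config.nuclear_threshold_method,
                        config.nuclear_fixed_threshold, config.background_k_sigma)
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2).astype(np.int32)
    if labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < config.min_nucleus_area)
        if small.size:
            labels[np.isin(labels, small[small > 0])] = 0
            # relabel contiguous from 1, preserving scan order
            remap = np.zeros(areas.size, dtype=np.int32)
            survivors = np.unique(labels)
            survivors = survivors[survivors > 0]
            remap[survivors] = np.arange(1, survivors.size + 1, dtype=np.int32)
            labels = remap[labels]
    if labels.max() == 0:
        log.info("segment_nuclei: no nuclei found")
    return labels


def segment_cells(venus_image: np.ndarray, config: WorkflowConfig) -> np.ndarray:
    """Binary mask of reporter-positive area (nuclei + cytoplasm of infected cells).

    Threshold, morphological closing (bridges noise dropouts along the
    dim cytoplasm boundary), hole filling, and removal of sub-nucleus
    specks that would otherwise be claimed as cytoplasm by the Voronoi
    partition.
    """
    binary = _threshold(venus_image, config.cell_threshold_method,
                        config.cell_fixed_threshold, config.background_k_sigma)
    if config.cell_mask_closing_radius > 0 and binary.any():
        closed = morphology.closing(
            binary, morphology.disk(config.cell_mask_closing_radius))
        if config.cell_threshold_method == "background":
            # hysteresis: closing may only admit pixels above a weaker
            # background cut, so junctions between touching cells are not
            # bridged with pure-background pixels
            img = np.asarray(venus_image, dtype=float)
            med = float(np.median(img))
            sigma = 1.4826 * float(np.median(np.abs(img - med)))
            closed &= img > med + sigma
        binary |= closed
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < config.min_nucleus_area)
        binary[np.isin(labels, small[small > 0])] = False
    return binary


def filter_uninfected(nuclei: np.ndarray, cell_mask: np.ndarray,
                      config: WorkflowConfig) -> np.ndarray:
    """Discard nuclei of uninfected (reporter-negative) cells.

    A nucleus is retained iff the fraction of its pixels covered by the
    reporter-positive cell mask is at least ``min_overlap_for_infected``.
    Labels of survivors are preserved.
    """
    if nuclei.shape != cell_mask.shape:
        raise ValueError("nuclei and cell_mask must share the same pixel frame")
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        return nuclei.copy()
    n_lab = int(labels.max())
    area = np.bincount(nuclei.ravel(), minlength=n_lab + 1)
    covered = np.bincount(nuclei.ravel(), weights=cell_mask.astype(float).ravel(),
                          minlength=n_lab + 1)
    keep = np.zeros(n_lab + 1, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(area > 0, covered / np.maximum(area, 1), 0.0)
    keep[labels] = frac[labels] >= config.min_overlap_for_infected
    out = np.where(keep[nuclei], nuclei, 0).astype(np.int32)
    return out


def voronoi_partition(nuclei: np.ndarray, cell_mask: np.ndarray,
                      window_pad: int = 96) -> np.ndarray:
    """Split the cell mask into one region per nucleus (seeded Voronoi).

    Every foreground pixel of ``cell_mask`` is assigned to the nucleus
    whose region is nearest in Euclidean distance (distance to the
    nearest pixel of each seed region); ties go to the lowest label.
    Region labels equal nucleus labels; regions partition the cell-mask
    foreground.  A nucleus whose region would otherwise be empty keeps
    its own pixels, with a warning.

    Exactness: squared pixel distances are exact integers in float64
    and sqrt is monotone on them, so a strict-< running argmin over
    per-seed exact Euclidean distance transforms resolves ties to the
    lowest label deterministically, identical to exhaustive
    nearest-seed search.  Each seed's EDT is evaluated on its bounding
    box padded by ``window_pad``; an assignment with distance below the
    pad is provably correct (any closer seed would have the pixel
    inside its own padded box), and the rare pixels not resolved within
    the pad fall back to full-image transforms.
    """
    if nuclei.shape != cell_mask.shape:
        raise ValueError("nuclei and cell_mask must share the same pixel frame")
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    out = np.zeros(nuclei.shape, dtype=np.int32)
    if labels.size == 0:
        return out
    if not cell_mask.any():
        for lab in labels:
            log.warning("voronoi_partition: nucleus %d has no foreground pixels; "
                        "falling back to its own pixels", lab)
            out[nuclei == lab] = lab
        return out
    fg = cell_mask.astype(bool)
    best = np.full(nuclei.shape, np.inf)
    h, w = nuclei.shape
    boxes = ndimage.find_objects(nuclei)
    for lab in labels:
        sl = boxes[lab - 1]
        if sl is None:
            continue
        y0 = max(0, sl[0].start - window_pad)
        y1 = min(h, sl[0].stop + window_pad)
        x0 = max(0, sl[1].start - window_pad)
        x1 = min(w, sl[1].stop + window_pad)
        win = (slice(y0, y1), slice(x0, x1))
        d = ndimage.distance_transform_edt(nuclei[win] != lab)
        better = fg[win] & (d < best[win])
        best[win][better] = d[better]
        sub = out[win]
        sub[better] = lab
        out[win] = sub
    unresolved = fg & ((out == 0) | (best >= window_pad))
    if unresolved.any():
        best_u = np.full(int(unresolved.sum()), np.inf)
        lab_u = np.zeros(best_u.shape, dtype=np.int32)
        for lab in labels:
            d = ndimage.distance_transform_edt(nuclei != lab)[unresolved]
            closer = d < best_u
            best_u[closer] = d[closer]
            lab_u[closer] = lab
        out[unresolved] = lab_u
    for lab in labels:
        if not np.any(out == lab):
            log.warning("voronoi_partition: nucleus %d has no foreground pixels; "
                        "falling back to its own pixels", lab)
            out[nuclei == lab] = lab
    return out


def cytoplasm_masks(cells: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Per-cell cytoplasm = cell region minus that cell's nucleus pixels (XOR)."""
    if cells.shape != nuclei.shape:
        raise ValueError("cells and nuclei must share the same pixel frame")
    outside = (nuclei > 0) & (cells != nuclei)
    if outside.any():
        log.warning("cytoplasm_masks: %d nucleus pixels fall outside their cell "
                    "region and were clipped", int(outside.sum()))
    out = cells.astype(np.int32).copy()
    out[(nuclei > 0) & (cells == nuclei)] = 0
    return out


def measure_cells(nuclei: np.ndarray, cytoplasms: np.ndarray,
                  venus_image: np.ndarray,
                  config: WorkflowConfig | None = None) -> pd.DataFrame:
    """Redirect masks to the reporter image and measure per-cell signal.

    Returns one row per nucleus label with columns ``cell_id``,
    ``nuclear_mean`` (N), ``cytoplasmic_mean`` (C, NaN when the cell has
    no cytoplasm pixels), ``cn_ratio`` (C/N), ``intdens`` (sum of
    reporter gray values over cytoplasm pixels; 0 for no pixels).
    """
    if nuclei.shape != venus_image.shape or cytoplasms.shape != venus_image.shape:
        raise ValueError("masks and image must share the same pixel frame")
    img = np.asarray(venus_image, dtype=float)
    if config is not None and config.background_subtract:
        img = np.clip(img - config.background_subtract, 0, None)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["cell_id", "nuclear_mean", "cytoplasmic_mean",
                                     "cn_ratio", "intdens"])
    m = int(max(labels.max(), cytoplasms.max()))
    n_area = np.bincount(nuclei.ravel(), minlength=m + 1)
    n_sum = np.bincount(nuclei.ravel(), weights=img.ravel(), minlength=m + 1)
    c_area = np.bincount(cytoplasms.ravel(), minlength=m + 1)
    c_sum = np.bincount(cytoplasms.ravel(), weights=img.ravel(), minlength=m + 1)
    rows = []
    for lab in labels:
        n_mean = n_sum[lab] / n_area[lab]
        has_c = c_area[lab] > 0
        c_mean = c_sum[lab] / c_area[lab] if has_c else np.nan
        ratio = c_mean / n_mean if has_c and n_mean > 0 else np.nan
        rows.append({"cell_id": int(lab), "nuclear_mean": n_mean,
                     "cytoplasmic_mean": c_mean, "cn_ratio": ratio,
                     "intdens": float(c_sum[lab])})
    return pd.DataFrame(rows)


def classify_cycle_state(measurements: pd.DataFrame,
                         config: WorkflowConfig) -> pd.DataFrame:
    """Label each cell G0/G1 or cycling from its C/N ratio.

    G0/G1 iff the cell has no cytoplasmic mask (C/N undefined) or its
    C/N ratio is strictly below ``cn_g0g1_threshold``; otherwise cycling.
    """
    out = measurements.copy()
    ratio = out["cn_ratio"]
    g0g1 = ratio.isna() | (ratio < config.cn_g0g1_threshold)
    out["cycle_class"] = np.where(g0g1, "G0G1", "cycling")
    return out


def score_residual_activity(measurements_by_condition: dict[str, pd.DataFrame],
                            reference_condition: str) -> pd.DataFrame:
    """Score residual CDK2 activity per condition.

    The statistic is the mean cytoplasmic integrated density (IntDens)
    over G0/G1 cells, expressed as fold change relative to the
    reference condition.  Conditions with no G0/G1 cells, and fold
    changes against a zero/absent reference, are flagged degenerate
    rather than reported.
    """
    if reference_condition not in measurements_by_condition:
        raise KeyError(f"reference condition {reference_condition!r} missing")
    rows = []
    ref_mean = None
    for cond, df in measurements_by_condition.items():
        if "cycle_class" not in df.columns:
            raise ValueError("measurements must be classified first")
        g0 = df[df["cycle_class"] == "G0G1"]
        mean_intdens = float(g0["intdens"].mean()) if len(g0) else np.nan
        rows.append({"condition": cond, "n_g0g1": int(len(g0)),
                     "mean_intdens": mean_intdens,
                     "degenerate": len(g0) == 0})
        if cond == reference_condition:
            ref_mean = mean_intdens
    out = pd.DataFrame(rows)
    ref_ok = ref_mean is not None and np.isfinite(ref_mean) and ref_mean > 0
    if not ref_ok:
        log.warning("score_residual_activity: reference condition %r has no "
                    "usable G0/G1 IntDens; fold changes not emitted",
                    reference_condition)
    out["fold_change"] = np.where(
        ref_ok & ~out["degenerate"].to_numpy(), out["mean_intdens"] / (ref_mean or np.nan),
        np.nan)
    return out


def match_labels(segmented: np.ndarray, reference: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the reference label it overlaps most.

    Connected-component labeling orders labels by scan order, so
    segmented labels need not match generator cell ids; this maps them
    by majority pixel overlap (0 = no overlap with any reference label).
    """
    if segmented.shape != reference.shape:
        raise ValueError("label images must share the same pixel frame")
    out: dict[int, int] = {}
    seg = segmented.ravel()
    ref = reference.ravel()
    for lab in np.unique(seg):
        if lab == 0:
            continue
        hit = ref[seg == lab]
        hit = hit[hit > 0]
        out[int(lab)] = int(np.bincount(hit).argmax()) if hit.size else 0
    return out


def qc_min_cells(measurements: pd.DataFrame, config: WorkflowConfig) -> dict:
    """Check the minimum scored-cell count per culture (default 250)."""
    n = int(len(measurements))
    return {"n_cells": n, "min_required": config.min_cells_per_culture,
            "passed": n >= config.min_cells_per_culture}


def run_workflow(dapi_image: np.ndarray, venus_image: np.ndarray,
                 config: WorkflowConfig | None = None) -> dict:
    """Run the full per-field workflow; returns measurements, masks and QC."""
    config = config or WorkflowConfig()
    nuclei = segment_nuclei(dapi_image, config)
    cell_mask = segment_cells(venus_image, config)
    infected = filter_uninfected(nuclei, cell_mask, config)
    cells = voronoi_partition(infected, cell_mask)
    cyto = cytoplasm_masks(cells, infected)
    meas = measure_cells(infected, cyto, venus_image, config)
    meas = classify_cycle_state(meas, config)
    return {
        "nuclei": nuclei,
        "infected_nuclei": infected,
        "cells": cells,
        "cytoplasms": cyto,
        "measurements": meas,
        "qc": qc_min_cells(meas, config),
    }
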