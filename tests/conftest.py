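"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from npcquant import cdk2, synthetic


@pytest.fixture
def config():
    return cdk2.WorkflowConfig()


@pytest.fixture(scope="session")
def clumped_field():
    """One mixed field: clumped pairs, 30% uninfected, noiseless."""
    spec = synthetic.FieldSpec(n_cells=60, width=512, height=512,
                               infected_fraction=0.7, clumped_fraction=0.4,
                               seed=11)
    dapi, venus, truth = synthetic.generate_cell_field(spec)
    return spec, dapi, venus, truth


def nearest_seed_oracle(nuclei: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-seed search, independent of the EDT implementation.

    For every foreground pixel, the exact Euclidean distance to every
    seed region is computed from the seed pixel coordinates; ties break
    to the lowest label via a strict-< scan in ascending label order.
    """
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    fg = np.argwhere(cell_mask)
    best = np.full(len(fg), np.inf)
    out_lab = np.zeros(len(fg), dtype=np.int32)
    for lab in labels:
        seeds = np.argwhere(nuclei == lab)
        d, _ = cKDTree(seeds).query(fg)
        better = d < best
        best[better] = d[better]
        out_lab[better] = lab
    out = np.zeros(nuclei.shape, np.int32)
    out[fg[:, 0], fg[:, 1]] = out_lab
    return out


def brute_force_nearest_seed(nuclei: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Pure-loop nearest-seed assignment over squared integer distances.

    Only for tiny fields; the reference for the reference.
    """
    labels = [int(v) for v in np.unique(nuclei) if v > 0]
    seeds = {lab: np.argwhere(nuclei == lab) for lab in labels}
    out = np.zeros(nuclei.shape, np.int64)
    for y, x in np.argwhere(cell_mask):
        best_d, best_lab = None, 0
        for lab in labels:
            pts = seeds[lab]
            d2 = int(np.min((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2))
            if best_d is None or d2 < best_d:
                best_d, best_lab = d2, lab
        out[y, x] = best_lab
    return out


def brute_force_promoter_assignment(peaks: pd.DataFrame, genes: pd.DataFrame,
                                    window: int = 3000) -> dict[str, list[str]]:
    """All-pairs half-open interval overlap scan (independent of intervaltree)."""
    out: dict[str, list[str]] = {}
    for _, g in genes.iterrows():
        lo, hi = int(g["tss"]) - window, int(g["tss"]) + window
        hits = [
            str(p["name"]) for _, p in peaks.iterrows()
            if p["chrom"] == g["chrom"] and int(p["start"]) < hi and int(p["end"]) > lo
        ]
        out[str(g["gene"])] = sorted(hits)
    return out


def matched_measurements(result: dict, truth) -> pd.DataFrame:
    """Join workflow measurements to ground truth via mask-overlap label matching."""
    m = result["measurements"].copy()
    mapping = cdk2.match_labels(result["infected_nuclei"], truth.nuclei_mask)
    m["true_id"] = m["cell_id"].map(mapping)
    joined = m.merge(truth.cells, left_on="true_id", right_on="cell_id",
                     suffixes=("", "_truth"))
    return joined
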