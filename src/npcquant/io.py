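"""File I/O: TIFF channels, labeled masks, BED-like peak tables, configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .cdk2 import WorkflowConfig

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                "stat", "fdr", "direction"]


def save_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image))


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def save_labels(path: str | Path, labels: np.ndarray) -> None:
    """Labeled masks are written as 16-bit TIFF."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("label image does not fit in 16-bit")
    tifffile.imwrite(path, arr.astype(np.uint16))


def load_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_peaks_bed(path: str | Path, peaks: pd.DataFrame) -> None:
    """BED6+3 (stat, fdr, direction), 0-based half-open, no header."""
    peaks[PEAK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a BED6+3 peak table; set ``one_based`` to convert 1-based starts."""
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS)
    if one_based:
        df["start"] = df["start"] - 1
    return df


def load_workflow_config(path: str | Path | None) -> WorkflowConfig:
    if path is None:
        return WorkflowConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return WorkflowConfig(**data)
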