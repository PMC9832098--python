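"""ATAC x RNA integration: promoter peak assignment and regulation categories.

Differential-accessibility (DA) peaks are assigned to gene promoters —
a window of +-3 kb around the TSS, 0-based half-open — with a
deterministic tie cascade when several peaks hit one gene: closest peak
midpoint to the TSS, then largest overlap with the promoter window,
then lowest start coordinate.  Genes are labeled Closed/Open when their
assigned peak is significant (FDR strictly below threshold, default
0.05) in the corresponding direction, UP/DOWN likewise from the
expression table, and the doubly-significant genes fall into the four
joint categories Closed_UP, Closed_DOWN, Open_UP and Open_DOWN.
Cross-genotype overlap reports per-category Venn counts and the
fraction of one condition's categorized genes lost in the other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "assign_peaks_to_promoters",
    "resolve_multi_peaks",
    "label_da",
    "label_de",
    "combine_categories",
    "categorize",
    "intersect_conditions",
    "CATEGORIES",
]

CATEGORIES = ("Closed_UP", "Closed_DOWN", "Open_UP", "Open_DOWN")


def _check_peaks(peaks: pd.DataFrame) -> None:
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peaks must satisfy start < end (0-based half-open)")


def assign_peaks_to_promoters(peaks: pd.DataFrame, genes: pd.DataFrame,
                              promoter_window: int = 3000,
                              flank: int = 5000) -> dict[str, list[str]]:
    """Map each gene to the set of peaks overlapping its promoter window.

    The promoter window of a gene is ``[TSS - w, TSS + w)`` (0-based
    half-open, symmetric, so strand does not alter it).  A peak is
    promoter-associated iff its half-open interval overlaps the window
    on the same chromosome.  ``flank`` is the maximum assignment
    distance for near-gene annotation and cannot add promoter
    assignments when ``flank >= promoter_window``; it is retained for
    interface completeness.  Peaks on chromosomes absent from the
    annotation are left unassigned with a warning.
    """
    _check_peaks(peaks)
    known = set(genes["chrom"])
    missing = set(peaks["chrom"]) - known
    if missing:
        log.warning("assign_peaks_to_promoters: peaks on chromosomes %s have no "
                    "annotated genes and stay unassigned", sorted(missing))
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in peaks.groupby("chrom"):
        if chrom not in known:
            continue
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), name)
            for s, e, name in zip(grp["start"], grp["end"], grp["name"]))
    out: dict[str, list[str]] = {}
    for gene, chrom, tss in zip(genes["gene"], genes["chrom"], genes["tss"]):
        tree = trees.get(chrom)
        lo, hi = int(tss) - promoter_window, int(tss) + promoter_window
        hits = sorted(iv.data for iv in tree.overlap(lo, hi)) if tree is not None else []
        out[str(gene)] = hits
    return out


def resolve_multi_peaks(assignment: dict[str, list[str]], peaks: pd.DataFrame,
                        genes: pd.DataFrame, promoter_window: int = 3000
                        ) -> dict[str, str | None]:
    """Reduce multi-peak genes to one peak by the tie cascade.

    Keep the peak whose midpoint is nearest the TSS; break ties by the
    largest overlap with the promoter window, then by the lowest start
    coordinate.
    """
    peak_rows = peaks.set_index("name")
    tss_of = dict(zip(genes["gene"].astype(str), genes["tss"].astype(int)))
    out: dict[str, str | None] = {}
    for gene, names in assignment.items():
        if not names:
            out[gene] = None
            continue
        tss = tss_of[gene]
        lo, hi = tss - promoter_window, tss + promoter_window

        def key(name: str):
            s, e = int(peak_rows.at[name, "start"]), int(peak_rows.at[name, "end"])
            mid = (s + e) / 2.0
            overlap = max(0, min(e, hi) - max(s, lo))
            return (abs(mid - tss), -overlap, s)

        out[gene] = min(names, key=key)
    return out


def label_da(assigned_peak: str | None, peaks: pd.DataFrame,
             fdr_threshold: float = 0.05) -> str:
    """Differential-accessibility call for one gene from its assigned peak."""
    if assigned_peak is None:
        return "NoPromoterPeak"
    row = peaks.set_index("name").loc[assigned_peak]
    return _da_from(row["fdr"], row["direction"], fdr_threshold)


def _da_from(fdr: float, direction: str, fdr_threshold: float) -> str:
    if fdr < fdr_threshold:
        if direction == "more_closed":
            return "Closed"
        if direction == "more_open":
            return "Open"
    return "Unchanged"


def label_de(fdr: float, log2fc: float, fdr_threshold: float = 0.05) -> str:
    """Differential-expression call from FDR and fold-change sign."""
    if np.isnan(fdr) or np.isnan(log2fc):
        return "Unchanged"
    if fdr < fdr_threshold:
        if log2fc > 0:
            return "UP"
        if log2fc < 0:
            return "DOWN"
        log.warning("label_de: significant FDR %g with zero fold change", fdr)
    return "Unchanged"


def combine_categories(da: str, de: str) -> str:
    """Joint regulation category; 'none' unless both calls are significant."""
    if da in ("Closed", "Open") and de in ("UP", "DOWN"):
        return f"{da}_{de}"
    return "none"


def categorize(peaks: pd.DataFrame, de: pd.DataFrame, genes: pd.DataFrame,
               promoter_window: int = 3000, flank: int = 5000,
               fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Full integration: one GeneRegulationRecord row per annotated gene.

    Columns: ``gene, assigned_peak, da, de, category``.  Genes absent
    from the expression table are called Unchanged with a warning.
    """
    assignment = assign_peaks_to_promoters(peaks, genes, promoter_window, flank)
    chosen = resolve_multi_peaks(assignment, peaks, genes, promoter_window)
    peak_rows = peaks.set_index("name")
    de_rows = de.set_index("gene")
    missing = [g for g in genes["gene"].astype(str) if g not in de_rows.index]
    if missing:
        log.warning("categorize: %d genes missing from the DE table are called "
                    "Unchanged", len(missing))
    rows = []
    for gene in genes["gene"].astype(str):
        peak = chosen[gene]
        if peak is None:
            da = "NoPromoterPeak"
        else:
            prow = peak_rows.loc[peak]
            da = _da_from(float(prow["fdr"]), str(prow["direction"]), fdr_threshold)
        if gene in de_rows.index:
            drow = de_rows.loc[gene]
            de_call = label_de(float(drow["fdr"]), float(drow["log2fc"]), fdr_threshold)
        else:
            de_call = "Unchanged"
        rows.append({"gene": gene, "assigned_peak": peak or "",
                     "da": da, "de": de_call,
                     "category": combine_categories(da, de_call)})
    return pd.DataFrame(rows)


def intersect_conditions(records_a: pd.DataFrame, records_b: pd.DataFrame,
                         lost_categories: tuple[str, ...] = ("Closed_UP", "Closed_DOWN"),
                         ) -> dict:
    """Cross-condition overlap of categorized genes.

    Reports, per category, the Venn counts ``|A and B|``, ``|A only|``
    and ``|B only|`` over genes carrying that category in each
    condition, plus the "lost fraction": among genes of condition A in
    ``lost_categories`` (default: the Closed chromatin categories), the
    fraction absent from condition B's categorized set.
    """
    a_genes = set(records_a["gene"])
    b_genes = set(records_b["gene"])
    if not a_genes & b_genes:
        raise ValueError("conditions share no genes; same gene universe required")
    per_cat = {}
    for cat in CATEGORIES:
        a = set(records_a.loc[records_a["category"] == cat, "gene"])
        b = set(records_b.loc[records_b["category"] == cat, "gene"])
        per_cat[cat] = {"a_and_b": len(a & b), "a_only": len(a - b),
                        "b_only": len(b - a)}
    a_sel = set(records_a.loc[records_a["category"].isin(lost_categories), "gene"])
    b_categorized = set(records_b.loc[records_b["category"] != "none", "gene"])
    lost = len(a_sel - b_categorized)
    return {
        "per_category": per_cat,
        "lost_categories": list(lost_categories),
        "n_selected_a": len(a_sel),
        "n_lost": lost,
        "lost_fraction": lost / len(a_sel) if a_sel else float("nan"),
    }
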