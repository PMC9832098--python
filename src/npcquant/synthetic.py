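"""Seeded generators for ground-truthed synthetic inputs.

Every downstream stage of the package (CDK2 reporter bioimage workflow,
nuclear-marker profiling, comparative-Ct ChIP quantification, ATAC x RNA
promoter categorization) can be exercised on outputs of this module with
no external data.  Generators are deterministic: identical parameters and
seed yield bit-identical arrays and tables.

Draw order is part of the contract.  ``generate_cell_field`` draws, in
order: infected flags, clumped flags, nucleus radii, cytoplasm
thicknesses, nuclear intensities, cytoplasmic intensities, placement
coordinates, then noise.  Tests replay the leading draws with the same
seeded generator to check fraction conservation exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "FieldCapacityError",
    "GenomeCapacityError",
    "generate_cell_field",
    "generate_marker_field",
    "generate_ct_table",
    "generate_gene_tables",
    "CT_OFFSET_CYCLES",
    "REGULATION_CATEGORIES",
]

#: Fixed template-abundance-to-Ct offset (cycles).  Arbitrary but stated;
#: it cancels in every delta-delta-Ct comparison.
CT_OFFSET_CYCLES = 40.0

REGULATION_CATEGORIES = ("Closed_UP", "Closed_DOWN", "Open_UP", "Open_DOWN")


class FieldCapacityError(RuntimeError):
    """Raised when cells cannot be placed without overlap after bounded retries."""


class GenomeCapacityError(ValueError):
    """Raised when the requested genes do not fit in the requested genome."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic culture field.

    Cells are disk nuclei with concentric annular cytoplasms.  A
    ``clumped_fraction`` of cells is placed touching a neighbor (center
    distance below the sum of outer radii) so that cytoplasm regions
    merge and must be split downstream.  An ``infected_fraction`` of
    cells carries the reporter; uninfected cells show only background in
    the reporter channel but normal DAPI signal.
    """

    width: int = 1024
    height: int = 1024
    n_cells: int = 100
    nucleus_radius_range: tuple[float, float] = (6.0, 9.0)
    cytoplasm_thickness_range: tuple[float, float] = (4.0, 7.0)
    infected_fraction: float = 1.0
    clumped_fraction: float = 0.0
    nuclear_intensity_range: tuple[float, float] = (80.0, 120.0)
    cytoplasmic_intensity_range: tuple[float, float] = (40.0, 80.0)
    background_level: float = 10.0
    dapi_nuclear_level: float = 200.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    cn_class_threshold: float = 0.65
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.infected_fraction <= 1.0:
            raise ValueError("infected_fraction must be in [0, 1]")
        if not 0.0 <= self.clumped_fraction <= 1.0:
            raise ValueError("clumped_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.nucleus_radius_range[0] <= 0:
            raise ValueError("nucleus radius must be positive")
        if self.cytoplasm_thickness_range[0] < 0:
            raise ValueError("cytoplasm thickness must be nonnegative")
        for name in ("nuclear_intensity_range", "cytoplasmic_intensity_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be nonnegative and ordered")
        if self.background_level < 0:
            raise ValueError("background_level must be nonnegative")

    def replace(self, **kw) -> "FieldSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Per-cell ground truth plus reference label masks for one field.

    ``cells`` has one row per cell: centroid, radii, infected/clumped
    flags, the painted (integer) per-compartment reporter intensities,
    the true C/N ratio and the true cell-cycle class.  Masks share the
    pixel frame of the generated images; label ``i`` corresponds to row
    ``cell_id == i``.
    """

    cells: pd.DataFrame
    nuclei_mask: np.ndarray = field(default=None)
    cell_mask: np.ndarray = field(default=None)
    cytoplasm_mask: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# cell placement and geometry


def _place_cells(
    rng: np.random.Generator,
    spec: FieldSpec,
    nucleus_radii: np.ndarray,
    outer_radii: np.ndarray,
    clumped: np.ndarray,
    max_tries: int = 500,
) -> np.ndarray:
    """Place cell centers; clumped cells touch a previously placed neighbor.

    Returns an (n, 2) array of (x, y) centers.  Raises
    :class:`FieldCapacityError` when a cell cannot be placed within
    ``max_tries`` rejection-sampling attempts.
    """
    n = len(nucleus_radii)
    centers = np.zeros((n, 2))
    for i in range(n):
        r_out = outer_radii[i]
        placed = False
        for _ in range(max_tries):
            if clumped[i] and i > 0:
                j = int(rng.integers(i))
                pair_sum = r_out + outer_radii[j]
                # touching: cytoplasms overlap, nuclei stay disjoint
                d_lo = max(nucleus_radii[i] + nucleus_radii[j] + 3.0, 0.70 * pair_sum)
                d_hi = 0.95 * pair_sum
                if d_lo >= d_hi:
                    d_lo = nucleus_radii[i] + nucleus_radii[j] + 3.0
                    d_hi = d_lo + 1.0
                d = rng.uniform(d_lo, d_hi)
                theta = rng.uniform(0, 2 * np.pi)
                x = centers[j, 0] + d * np.cos(theta)
                y = centers[j, 1] + d * np.sin(theta)
                partner = j
            else:
                x = rng.uniform(r_out + 1, spec.width - r_out - 1)
                y = rng.uniform(r_out + 1, spec.height - r_out - 1)
                partner = -1
            if not (r_out + 1 <= x <= spec.width - r_out - 1
                    and r_out + 1 <= y <= spec.height - r_out - 1):
                continue
            if i == 0:
                centers[i] = (x, y)
                placed = True
                break
            dist = np.hypot(centers[:i, 0] - x, centers[:i, 1] - y)
            min_sep = outer_radii[:i] + r_out + 2.0
            if partner >= 0:
                # the chosen partner is allowed (required) to touch
                min_sep[partner] = nucleus_radii[partner] + nucleus_radii[i] + 3.0
            if np.all(dist >= min_sep):
                centers[i] = (x, y)
                placed = True
                break
        if not placed:
            raise FieldCapacityError(
                f"could not place cell {i} of {n} after {max_tries} attempts; "
                f"reduce n_cells or enlarge the field"
            )
    return centers


def _build_masks(
    spec: FieldSpec,
    centers: np.ndarray,
    nucleus_radii: np.ndarray,
    outer_radii: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize reference label masks (nuclei, whole cells, cytoplasms).

    Where two cells' outer disks overlap (clumped pairs) a pixel is
    assigned to the cell whose nucleus disk is nearer (signed distance
    to the nucleus boundary; ties to the lower label), mirroring the
    seeded-Voronoi convention the bioimage workflow uses downstream.
    """
    h, w = spec.height, spec.width
    cell_labels = np.zeros((h, w), dtype=np.int32)
    claim = np.full((h, w), np.inf)
    for i in range(len(centers)):
        cx, cy = centers[i]
        r = outer_radii[i]
        x0, x1 = max(0, int(np.floor(cx - r)) - 1), min(w, int(np.ceil(cx + r)) + 2)
        y0, y1 = max(0, int(np.floor(cy - r)) - 1), min(h, int(np.ceil(cy + r)) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        inside = d <= r
        signed = d - nucleus_radii[i]  # distance to nucleus disk boundary
        sub_claim = claim[y0:y1, x0:x1]
        better = inside & (signed < sub_claim)
        sub_claim[better] = signed[better]
        cell_labels[y0:y1, x0:x1][better] = i + 1
    nuclei = np.zeros_like(cell_labels)
    for i in range(len(centers)):
        cx, cy = centers[i]
        r = nucleus_radii[i]
        x0, x1 = max(0, int(np.floor(cx - r)) - 1), min(w, int(np.ceil(cx + r)) + 2)
        y0, y1 = max(0, int(np.floor(cy - r)) - 1), min(h, int(np.ceil(cy + r)) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = np.hypot(xx - cx, yy - cy) <= r
        nuclei[y0:y1, x0:x1][inside] = i + 1
    cytoplasm = np.where(nuclei == 0, cell_labels, 0).astype(np.int32)
    return nuclei, cell_labels, cytoplasm


def _apply_noise(rng: np.random.Generator, img: np.ndarray, spec: FieldSpec) -> np.ndarray:
    out = img.astype(float)
    if spec.poisson_noise:
        out = rng.poisson(out).astype(float)
    if spec.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sd, out.shape)
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def generate_cell_field(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate one two-channel field (DAPI + reporter) with ground truth.

    The DAPI channel shows every nucleus; the reporter channel shows
    nucleus plus cytoplasm signal only for infected cells.  Painted
    intensities are integers, so measuring the reference masks on a
    noiseless field recovers the generating values exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    infected = rng.random(n) < spec.infected_fraction
    clumped = rng.random(n) < spec.clumped_fraction
    clumped[:1] = False  # first cell has no neighbor to touch
    nucleus_radii = rng.uniform(*spec.nucleus_radius_range, n)
    thickness = rng.uniform(*spec.cytoplasm_thickness_range, n)
    outer_radii = nucleus_radii + thickness
    nuc_int = np.rint(rng.uniform(*spec.nuclear_intensity_range, n))
    cyt_int = np.rint(rng.uniform(*spec.cytoplasmic_intensity_range, n))
    bg = float(np.rint(spec.background_level))

    if n == 0:
        shape = (spec.height, spec.width)
        empty = np.full(shape, bg)
        dapi = _apply_noise(rng, empty, spec)
        venus = _apply_noise(rng, empty.copy(), spec)
        truth = GroundTruth(
            cells=_truth_frame(np.zeros((0, 2)), *(np.zeros(0),) * 3,
                               np.zeros(0, bool), np.zeros(0, bool),
                               np.zeros(0), bg, spec),
            nuclei_mask=np.zeros(shape, np.int32),
            cell_mask=np.zeros(shape, np.int32),
            cytoplasm_mask=np.zeros(shape, np.int32),
        )
        return dapi, venus, truth

    centers = _place_cells(rng, spec, nucleus_radii, outer_radii, clumped)
    nuclei, cells, cytoplasm = _build_masks(spec, centers, nucleus_radii, outer_radii)

    dapi = np.full((spec.height, spec.width), bg)
    venus = np.full((spec.height, spec.width), bg)
    dapi[nuclei > 0] = np.rint(spec.dapi_nuclear_level)
    for i in range(n):
        if infected[i]:
            venus[nuclei == i + 1] = nuc_int[i]
            venus[cytoplasm == i + 1] = cyt_int[i]

    dapi = _apply_noise(rng, dapi, spec)
    venus = _apply_noise(rng, venus, spec)

    truth = GroundTruth(
        cells=_truth_frame(centers, nucleus_radii, outer_radii, nuc_int,
                           infected, clumped, cyt_int, bg, spec),
        nuclei_mask=nuclei,
        cell_mask=cells,
        cytoplasm_mask=cytoplasm,
    )
    return dapi, venus, truth


def _truth_frame(centers, nucleus_radii, outer_radii, nuc_int, infected,
                 clumped, cyt_int, bg, spec) -> pd.DataFrame:
    n = len(centers)
    true_nuc = np.where(infected, nuc_int, bg)
    true_cyt = np.where(infected, cyt_int, bg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(infected & (true_nuc > 0), true_cyt / true_nuc, np.nan)
    cls = np.where(
        infected & ~(ratio < spec.cn_class_threshold), "cycling", "G0G1"
    )
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=int),
            "x": centers[:, 0] if n else np.zeros(0),
            "y": centers[:, 1] if n else np.zeros(0),
            "nucleus_radius": nucleus_radii,
            "cytoplasm_outer_radius": outer_radii,
            "infected": infected,
            "clumped": clumped,
            "true_nuclear_mean": true_nuc,
            "true_cytoplasmic_mean": true_cyt,
            "true_cn_ratio": ratio,
            "true_class": cls,
        }
    )


# ---------------------------------------------------------------------------
# nuclear-marker fields


def generate_marker_field(
    spec: FieldSpec,
    marker_params: dict[str, list[tuple[float, float]]],
    population_fractions: list[float] | None = None,
    population_assignments: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray], GroundTruth]:
    """Generate a DAPI channel plus nuclear-marker channels.

    ``marker_params[name]`` lists one ``(mean_log, sd_log)`` pair per
    population; per-cell marker intensities are log-normal within each
    population (two populations suffice to emulate genotype shifts such
    as wild type vs knockout).  Markers are purely nuclear: marker
    channels show the per-cell value on nucleus pixels over background.

    Draw order: population assignments (unless given), then marker
    values in sorted marker-name order, then geometry, then noise.
    """
    spec.validate()
    if not marker_params:
        raise ValueError("marker_params must name at least one marker")
    n_pop = {len(v) for v in marker_params.values()}
    if len(n_pop) != 1:
        raise ValueError("all markers must define the same number of populations")
    k = n_pop.pop()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    if population_assignments is not None:
        pops = np.asarray(population_assignments, dtype=int)
        if len(pops) != n:
            raise ValueError("population_assignments length must equal n_cells")
    else:
        fractions = population_fractions or [1.0 / k] * k
        if len(fractions) != k or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("population_fractions must sum to 1 with one entry per population")
        pops = np.searchsorted(np.cumsum(fractions), rng.random(n), side="right")
        pops = np.minimum(pops, k - 1)

    marker_values: dict[str, np.ndarray] = {}
    for name in sorted(marker_params):
        mu = np.array([marker_params[name][p][0] for p in pops])
        sd = np.array([marker_params[name][p][1] for p in pops])
        marker_values[name] = np.rint(np.exp(mu + sd * rng.standard_normal(n)))

    nucleus_radii = rng.uniform(*spec.nucleus_radius_range, n)
    thickness = rng.uniform(*spec.cytoplasm_thickness_range, n)
    outer_radii = nucleus_radii + thickness
    clumped = np.zeros(n, dtype=bool)
    bg = float(np.rint(spec.background_level))
    if n:
        centers = _place_cells(rng, spec, nucleus_radii, outer_radii, clumped)
        nuclei, cells, cytoplasm = _build_masks(spec, centers, nucleus_radii, outer_radii)
    else:
        centers = np.zeros((0, 2))
        nuclei = cells = cytoplasm = np.zeros((spec.height, spec.width), np.int32)

    dapi = np.full((spec.height, spec.width), bg)
    dapi[nuclei > 0] = np.rint(spec.dapi_nuclear_level)
    images: dict[str, np.ndarray] = {}
    for name in sorted(marker_params):
        img = np.full((spec.height, spec.width), bg)
        for i in range(n):
            img[nuclei == i + 1] = marker_values[name][i]
        images[name] = img

    dapi = _apply_noise(rng, dapi, spec)
    for name in sorted(images):
        images[name] = _apply_noise(rng, images[name], spec)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1, dtype=int),
            "x": centers[:, 0] if n else np.zeros(0),
            "y": centers[:, 1] if n else np.zeros(0),
            "population": pops,
        }
    )
    for name in sorted(marker_values):
        table[f"true_{name}"] = marker_values[name]
    truth = GroundTruth(cells=table, nuclei_mask=nuclei, cell_mask=cells,
                        cytoplasm_mask=cytoplasm)
    return dapi, images, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_ct_table(
    true_fold: float,
    input_fraction: float = 0.05,
    dilutions: tuple[float, ...] = (1.0, 10.0, 50.0),
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    region: str = "amplicon",
    condition: str = "PRO",
    n_replicates: int = 1,
    bound_recovery: float = 0.01,
) -> pd.DataFrame:
    """Generate a ChIP-qPCR Ct table whose true IP enrichment is ``true_fold``.

    Template abundances: both antibodies share an input abundance of
    ``input_fraction``; the control (NRA) bound fraction recovers
    ``bound_recovery`` of it and the specific IP recovers ``true_fold``
    times that.  Ct values follow ``Ct = offset - log2(abundance / d)``
    for dilution factor ``d`` (a 1:10 dilution is ``d = 10``), with the
    fixed offset :data:`CT_OFFSET_CYCLES`; dilution shifts bound and
    input wells identically, so it cancels in the comparative-Ct method
    and the downstream fold estimate equals ``true_fold`` exactly at
    zero noise.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    abundance = {
        ("IP", "bound"): true_fold * bound_recovery * input_fraction,
        ("IP", "input"): input_fraction,
        ("NRA", "bound"): bound_recovery * input_fraction,
        ("NRA", "input"): input_fraction,
    }
    rows = []
    for antibody in ("IP", "NRA"):
        for fraction in ("bound", "input"):
            for d in dilutions:
                base_ct = CT_OFFSET_CYCLES - np.log2(abundance[(antibody, fraction)] / d)
                for rep in range(1, n_replicates + 1):
                    ct = base_ct
                    if ct_noise_sd > 0:
                        ct = ct + rng.normal(0.0, ct_noise_sd)
                    rows.append(
                        {
                            "region": region,
                            "condition": condition,
                            "antibody": antibody,
                            "fraction": fraction,
                            "dilution": d,
                            "replicate": rep,
                            "ct": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene / peak tables


def generate_gene_tables(
    n_genes: int,
    genome_length: int | None = None,
    peak_width_range: tuple[int, int] = (200, 800),
    fraction_promoter_peaks: float = 0.8,
    da_de_category_probs: dict[str, float] | None = None,
    n_intergenic_peaks: int | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate peak, differential-expression, annotation and truth tables.

    Genes are laid out on two chromosomes with 20 kb spacing between
    transcription start sites, wide enough that each promoter peak can
    only be assigned to its own gene.  Each gene draws a true joint
    regulation category (or ``none``); categorized genes with a promoter
    peak receive a significant peak overlapping the +-3 kb promoter
    window plus a matching significant expression record, so a noiseless
    categorizer must recover the truth labels exactly.  Intergenic
    distractor peaks are placed farther than 8 kb (promoter window plus
    flank) from every TSS.

    Coordinates are 0-based half-open throughout.

    Returns ``(peaks, de, annotation, truth)`` DataFrames.
    """
    if not 0 <= fraction_promoter_peaks <= 1:
        raise ValueError("fraction_promoter_peaks must be in [0, 1]")
    probs = dict(da_de_category_probs or
                 {c: 0.15 for c in REGULATION_CATEGORIES})
    unknown = set(probs) - set(REGULATION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    total_p = sum(probs.values())
    if total_p > 1 + 1e-9:
        raise ValueError("category probabilities must sum to <= 1")

    spacing = 20_000
    needed = n_genes * spacing + spacing
    if genome_length is None:
        genome_length = needed
    elif genome_length < needed:
        raise GenomeCapacityError(
            f"genome_length {genome_length} cannot hold {n_genes} genes "
            f"at {spacing} bp spacing (need >= {needed})"
        )
    rng = np.random.default_rng(seed)

    cats = list(REGULATION_CATEGORIES) + ["none"]
    p = [probs.get(c, 0.0) for c in REGULATION_CATEGORIES] + [1.0 - total_p]
    true_cat = rng.choice(cats, size=n_genes, p=np.clip(p, 0, None) / np.sum(np.clip(p, 0, None)))
    has_peak = rng.random(n_genes) < fraction_promoter_peaks
    strands = rng.choice(["+", "-"], size=n_genes)

    genes, peaks, de_rows, truth_rows = [], [], [], []
    per_chrom_offset = {"chr1": 0, "chr2": 0}
    for i in range(n_genes):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        tss = 10_000 + per_chrom_offset[chrom]
        per_chrom_offset[chrom] += spacing
        strand = strands[i]
        body_len = 5_000
        if strand == "+":
            start, end = tss, tss + body_len
        else:
            start, end = tss - body_len, tss
        gene_id = f"gene{i:05d}"
        genes.append({"gene": gene_id, "chrom": chrom, "tss": tss,
                      "strand": strand, "start": start, "end": end})

        cat = str(true_cat[i])
        da_truth, de_truth = "Unchanged", "Unchanged"
        if cat != "none":
            da_truth = "Closed" if cat.startswith("Closed") else "Open"
            de_truth = "UP" if cat.endswith("UP") else "DOWN"

        peak_id = ""
        if has_peak[i]:
            width = int(rng.integers(peak_width_range[0], peak_width_range[1] + 1))
            p_start = tss + int(rng.integers(-2500, 1500))
            peak_id = f"peak_{gene_id}"
            if da_truth == "Unchanged":
                fdr = float(rng.uniform(0.1, 0.9))
                direction = str(rng.choice(["more_open", "more_closed"]))
            else:
                fdr = float(rng.uniform(5e-4, 0.045))
                direction = "more_closed" if da_truth == "Closed" else "more_open"
            peaks.append({"chrom": chrom, "start": p_start, "end": p_start + width,
                          "name": peak_id, "score": 0, "strand": ".",
                          "stat": float(rng.normal()), "fdr": fdr,
                          "direction": direction})
        elif da_truth != "Unchanged":
            # no promoter peak can carry the accessibility call
            cat, da_truth = "none", "Unchanged"

        if de_truth == "Unchanged":
            de_fdr = float(rng.uniform(0.1, 0.9))
            lfc = float(rng.normal(0.0, 0.2))
        else:
            de_fdr = float(rng.uniform(5e-4, 0.045))
            mag = float(rng.uniform(0.5, 4.0))
            lfc = mag if de_truth == "UP" else -mag
        de_rows.append({"gene": gene_id, "log2fc": lfc, "fdr": de_fdr})

        da_label = da_truth if peak_id else "NoPromoterPeak"
        truth_rows.append({"gene": gene_id, "true_category": cat,
                           "true_da": da_label, "true_de": de_truth,
                           "true_peak": peak_id})

    n_extra = n_intergenic_peaks if n_intergenic_peaks is not None else n_genes // 2
    for j in range(n_extra):
        chrom = "chr1" if j % 2 == 0 else "chr2"
        # midway between consecutive TSSs: >= 10 kb from either, beyond window + flank
        k = int(rng.integers(max(per_chrom_offset[chrom] // spacing, 1)))
        mid = 10_000 + k * spacing + spacing // 2
        width = int(rng.integers(peak_width_range[0], peak_width_range[1] + 1))
        p_start = mid - width // 2
        peaks.append({"chrom": chrom, "start": p_start, "end": p_start + width,
                      "name": f"peak_intergenic{j:05d}", "score": 0, "strand": ".",
                      "stat": float(rng.normal()), "fdr": float(rng.uniform(0.0, 1.0)),
                      "direction": str(rng.choice(["more_open", "more_closed"]))})

    peaks_df = pd.DataFrame(
        peaks, columns=["chrom", "start", "end", "name", "score", "strand",
                        "stat", "fdr", "direction"])
    de_df = pd.DataFrame(de_rows)
    anno_df = pd.DataFrame(genes)
    truth_df = pd.DataFrame(truth_rows)
    return peaks_df, de_df, anno_df, truth_df
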