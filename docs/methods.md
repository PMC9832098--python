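# Methods

This note documents the models, conventions and numerical choices
behind each pipeline stage, what the synthetic generators do and do not
emulate, and the known limitations.

## CDK2 reporter workflow

### Model

The DHB-mVenus sensor shuttles from nucleus to cytoplasm as CDK2
phosphorylates it, so a cell's C/N ratio (mean cytoplasmic / mean
nuclear reporter gray value) tracks CDK2 activity on an ordinal scale.
The workflow estimates C/N per cell from one DAPI plane and one
reporter plane:

1. **Nuclear segmentation** — global threshold on DAPI, hole filling,
   connected components, area filter (`min_nucleus_area`, default 20
   px), labels relabeled contiguously from 1.
2. **Cell-area segmentation** — global threshold on the reporter
   channel, morphological closing, hole filling, removal of
   sub-nucleus specks.  The foreground approximates the union of
   nucleus + cytoplasm of reporter-expressing cells.
3. **Uninfected-cell filtering** — a nucleus is kept iff ≥ 50 % of its
   pixels (`min_overlap_for_infected`) lie inside the cell mask.
   Uninfected cells show only background in the reporter channel, so
   their nuclei fall outside the mask.
4. **Voronoi partition** — the cell-mask foreground is split into one
   region per retained nucleus by nearest-seed-region Euclidean
   distance, ties to the lowest label.
5. **Cytoplasm derivation** — per label, cytoplasm = cell region XOR
   nucleus.
6. **Measurement and classification** — N, C, C/N and IntDens (sum of
   reporter gray over cytoplasm pixels) per cell; G0/G1 iff the
   cytoplasmic mask is empty or C/N < `cn_g0g1_threshold` (strict),
   else cycling.
7. **Residual activity** — mean IntDens over G0/G1 cells per
   condition, as fold change vs a reference; conditions without G0/G1
   cells, or a zero-signal reference, are flagged and no ratio is
   emitted.
8. **QC** — a culture passes with ≥ `min_cells_per_culture`
   (default 250) scored cells.

### Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `cn_g0g1_threshold` | 0.65 | – | G0/G1 cut on C/N; strict `<`.  Both 0.65 and 0.95 circulate as conventions for this sensor, so the cut is configurable rather than hard-coded. |
| `min_overlap_for_infected` | 0.5 | fraction | nucleus-in-mask overlap to count as reporter-positive |
| `min_nucleus_area` | 20 | px | rejects debris/specks |
| `min_cells_per_culture` | 250 | cells | minimum for a scored culture |
| `nuclear_threshold_method` | otsu | – | DAPI is near-bimodal; Otsu is standard and parameter-free |
| `cell_threshold_method` | background | – | see below |
| `background_k_sigma` | 3 | σ | cut at median + 3·(1.4826·MAD) |
| `cell_mask_closing_radius` | 2 | px | bridges noise dropouts in dim cytoplasm |

### Numerical choices

- **Reporter-area thresholding.**  The reporter histogram has three
  modes — dominant background, dim cytoplasm, bright nucleus.  Otsu on
  such a mixture often places the cut *between cytoplasm and nucleus*,
  deleting the cytoplasm outright, and the triangle method hugs the
  background peak and admits large noise areas.  The default is
  therefore a background-statistics rule, median + 3·(1.4826·MAD),
  which is robust because background dominates the pixel population;
  Otsu, triangle and a fixed value remain selectable.
- **Closing with a hysteresis guard.**  Under noise, cytoplasm pixels
  near the threshold drop out of the mask and bite into region
  boundaries, biasing IntDens low for dim cells.  A radius-2 closing
  repairs these, but plain closing also bridges concave junctions
  between touching cells with pure-background pixels; closed-in pixels
  are therefore only admitted above a weaker cut (median + 1 σ).
- **Voronoi exactness.**  Distances are per-seed exact Euclidean
  distance transforms combined by a strict-< running argmin in
  ascending label order.  Squared distances between integer pixel
  coordinates are exact integers in float64 and `sqrt` is monotone and
  injective on them, so the result — including every tie — is
  identical to exhaustive nearest-seed search; the test suite asserts
  this against an independent KD-tree/direct-scan oracle.  Each seed's
  transform is evaluated on its bounding box padded by 96 px: an
  assignment at distance < 96 is provably final (a closer seed would
  contain the pixel in its own padded box), and any pixel not resolved
  within the pad falls back to full-image transforms.
- **Degenerate inputs.**  Constant images yield empty masks (logged,
  not an error); a nucleus with no reachable foreground keeps its own
  pixels as its region (warning); nucleus pixels outside their cell
  region are clipped from the cytoplasm (warning).
- No background subtraction by default; a constant-subtraction config
  flag exists.  Single-plane analysis; the only projection operation
  offered is the maximum projection used for marker stacks.
- Pixel coordinates are 0-based row-major; masks are written as 16-bit
  labeled TIFF.

## Marker profiling

Mean nuclear gray per (cell, marker) from a label mask.  Frequency
histograms within one *comparison* (one function call) share bin edges
(default 50 bins over the pooled min–max) and a single normalizer —
the largest raw bin count across the compared populations — so the
modal bin of the dominant population is exactly 1.  The top-fraction
rule labels the ⌈f·n⌉ brightest cells high (f = 0.30 default); ties at
the cut are all included (logged), which makes the call invariant
under monotone intensity transforms.  Percent-positive uses a
user-supplied threshold per marker, with Otsu on the pooled
distribution as a reproducible default where manual calls are
unavailable.  Whether a top-fraction cut should be pooled across the
compared conditions or applied per condition is genuinely ambiguous in
practice; the pooled form is the default and the per-condition form is
a one-liner on split inputs.

## Comparative-Ct ChIP and luciferase

For each antibody (specific IP and the non-related-antibody control),
ΔCt = mean Ct(bound) − mean Ct(input); fold enrichment =
e^(ΔCt_NRA − ΔCt_IP).  Efficiency e defaults to 2.0 (perfect
doubling) and is configurable per run.  Replicate Cts are arithmetic
means taken before ΔCt, the standard comparative-Ct practice; the
alternative (per-replicate folds averaged afterwards) changes results
only at second order in the noise.  Dilution factors shift bound and
input wells identically and cancel in ΔCt, which the dilution-offset
invariance test asserts.  The reserved-input percentage likewise
cancels in the IP-vs-NRA comparison and is not rescaled.  Positivity
requires Ct(IP) < Ct(NRA), strictly, in ≥ 2 distinct dilutions;
fewer than two usable dilutions yields "insufficient" rather than a
negative call.  Luciferase activity is firefly/Renilla per sample,
optionally relative to the mean activity of a reference condition;
nonpositive Renilla is an error.

## ATAC × RNA integration

Coordinates are 0-based half-open throughout; BED input is native,
with a flag for 1-based sources.  A peak is promoter-associated with a
gene iff it overlaps [TSS − 3000, TSS + 3000) on the same chromosome
(the window is symmetric, so strand does not alter it).  The 5 kb
flanking distance cannot add promoter assignments when it exceeds the
window; it is kept as an interface parameter for near-gene annotation.
Multi-peak genes resolve by (1) smallest |peak midpoint − TSS|, then
(2) largest overlap with the promoter window, then (3) lowest start —
a fixed cascade where "closest or largest" alone would be ambiguous.
DA and DE significance are strict (<) at FDR 0.05; how the FDR was
computed is upstream of this module.  Categories concatenate the two
calls only when both are significant; the per-category Venn counts and
the lost fraction |A\B| / |A| (default over the Closed categories,
against B's full categorized set) quantify cross-condition overlap.

## Synthetic data: what it emulates, what it does not

Fields are disk nuclei with concentric annular cytoplasms on a uniform
background; painted intensities are integers so that measuring the
reference masks on a noiseless field returns the generating values
exactly.  A configurable fraction of cells is uninfected (background
in the reporter channel, normal DAPI) and a configurable fraction is
placed touching a neighbor (center distance below the sum of outer
radii, nuclei kept disjoint), which forces the Voronoi split.  Where
two cells' outer disks overlap, the truth masks assign pixels by
signed distance to the nucleus boundary with ties to the lower label —
for disk nuclei this coincides with the workflow's nearest-seed rule,
so segmentation is evaluated against a consistent convention.  Noise
is optional Poisson on the signal plus additive Gaussian; defaults are
off so exactness tests are exact.  Images are single-plane 16-bit,
clipped to [0, 65535].

Default field geometry (1024×1024 px, nucleus radius 6–9 px, cytoplasm
thickness 4–7 px, nuclear reporter 80–120, cytoplasmic 40–80,
background 10, DAPI nuclear level 200) is chosen to resemble confocal
fields of dissociated NPC cultures at the cell densities where
clumping is common; none of it is calibrated to a specific microscope.
The generators do **not** simulate optics (PSF, z-stacks,
photobleaching), intensity gradients, irregular cell shapes, or
read-level sequencing data — so passing tests demonstrate correctness
of the measurement logic under the stated geometry and noise, not
robustness to every artifact of real microscopy.

Ct tables come from a template-abundance model, Ct = 40 −
log2(abundance/dilution): both antibodies share an input abundance,
the control bound fraction recovers 1 % of it, the IP recovers
`true_fold` times that, and Gaussian Ct noise is optional.  The
40-cycle offset is arbitrary but stated and cancels in ΔΔCt.  Gene
tables lay out genes at 20 kb TSS spacing on two chromosomes — wide
enough that a promoter peak is attributable to exactly one gene —
draw a true category per gene, give categorized genes significant
peaks/expression records and the rest non-significant ones, and add
intergenic distractor peaks ≥ 8 kb from every TSS.  Category recovery
on these tables is exact by construction; the recovery tests therefore
validate the labeling and assignment logic, not statistical power.

Determinism: every generator takes a seed and a fixed draw order is
part of the contract (infected flags first, then clumped flags, radii,
intensities, placement, noise), so tests can replay leading draws with
the same seeded generator and byte-identical reruns are guaranteed.

## Problem sizes

The validation experiments use 300-cell 1024×1024 fields for C/N
recovery and residual-activity scoring, twenty 50-cell 512×512 clumped
fields for the Voronoi oracle, 100 Monte-Carlo replicates for noisy Ct
recovery, and 1,000-gene/1,500-peak tables for the categorizer —
sizes at which every property is measured on thousands of cells,
pixels or genes while the whole suite runs in about a minute.

## Known limitations

- Segmentation is classical global thresholding; heavily overlapping
  nuclei, intensity gradients or out-of-focus fields need a different
  front end (the measurement stages accept any label masks).
- The Voronoi split is Euclidean, not geodesic: a region can in
  principle cross a background gap inside the cell mask's convex
  surroundings.
- Comparative-Ct assumes a common amplification efficiency per run;
  per-amplicon efficiencies are supported but not estimated from
  dilution series.
- The integration stage trusts upstream FDRs and does not model
  peak-boundary uncertainty.
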