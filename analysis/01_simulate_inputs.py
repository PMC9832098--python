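"""Generate one example of every synthetic input the pipeline consumes.

Writes a two-channel reporter field (with reference masks and per-cell
ground truth), a two-population nuclear-marker field, zero-noise and
noisy ChIP-qPCR Ct tables, and a gene/peak/expression table trio with
known regulation categories, all under results/synthetic/.
"""

from pathlib import Path

from npcquant import io, synthetic
from npcquant.synthetic import FieldSpec

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    field_dir = OUT / "field"
    field_dir.mkdir(exist_ok=True)
    spec = FieldSpec(n_cells=120, width=1024, height=1024, seed=SEED,
                     infected_fraction=0.7, clumped_fraction=0.3,
                     gaussian_noise_sd=3.0, poisson_noise=True)
    dapi, venus, truth = synthetic.generate_cell_field(spec)
    io.save_image(field_dir / "dapi.tif", dapi)
    io.save_image(field_dir / "venus.tif", venus)
    io.save_labels(field_dir / "truth_nuclei.tif", truth.nuclei_mask)
    io.save_labels(field_dir / "truth_cells.tif", truth.cell_mask)
    truth.cells.to_csv(field_dir / "truth.csv", index=False)
    print(f"reporter field: {spec.n_cells} cells, "
          f"{int(truth.cells['infected'].sum())} infected, "
          f"{int(truth.cells['clumped'].sum())} clumped -> {field_dir}")

    marker_dir = OUT / "markers"
    marker_dir.mkdir(exist_ok=True)
    mspec = FieldSpec(n_cells=300, width=2048, height=2048, seed=SEED + 1)
    dapi_m, images, mtruth = synthetic.generate_marker_field(
        mspec, {"SOX2": [(4.0, 0.35), (4.7, 0.35)]},
        population_fractions=[0.7, 0.3])
    io.save_image(marker_dir / "dapi.tif", dapi_m)
    io.save_image(marker_dir / "SOX2.tif", images["SOX2"])
    io.save_labels(marker_dir / "truth_nuclei.tif", mtruth.nuclei_mask)
    mtruth.cells.to_csv(marker_dir / "truth.csv", index=False)
    n_hi = int((mtruth.cells["population"] == 1).sum())
    print(f"marker field: 300 cells, {n_hi} in the bright population -> {marker_dir}")

    for fold, sd, name in [(2.5, 0.0, "ct_noiseless.csv"),
                           (2.5, 0.2, "ct_noisy.csv")]:
        table = synthetic.generate_ct_table(fold, ct_noise_sd=sd, seed=SEED,
                                            n_replicates=3)
        table.to_csv(OUT / name, index=False)
        print(f"Ct table (true fold {fold}, noise sd {sd}) -> {OUT / name}")

    gene_dir = OUT / "genes"
    gene_dir.mkdir(exist_ok=True)
    peaks, de, anno, gtruth = synthetic.generate_gene_tables(
        1000, n_intergenic_peaks=700, seed=SEED)
    io.write_peaks_bed(gene_dir / "peaks.bed", peaks)
    de.to_csv(gene_dir / "de.tsv", sep="\t", index=False)
    anno.to_csv(gene_dir / "genes.tsv", sep="\t", index=False)
    gtruth.to_csv(gene_dir / "truth.tsv", sep="\t", index=False)
    n_cat = int((gtruth["true_category"] != "none").sum())
    print(f"gene tables: {len(peaks)} peaks / 1000 genes, "
          f"{n_cat} categorized by construction -> {gene_dir}")


if __name__ == "__main__":
    main()
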