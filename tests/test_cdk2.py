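"""CDK2 reporter workflow: segmentation, Voronoi, mask algebra, C/N, scoring."""

import numpy as np
import pandas as pd
import pytest
from skimage import measure

from npcquant import cdk2, synthetic
from npcquant.cdk2 import WorkflowConfig
from npcquant.synthetic import FieldSpec

from conftest import brute_force_nearest_seed, matched_measurements, nearest_seed_oracle


class TestSegmentNuclei:
    def test_blank_image_gives_empty_mask(self, config):
        assert cdk2.segment_nuclei(np.zeros((64, 64)), config).max() == 0

    def test_disjoint_nuclei_counted_and_located(self, config):
        spec = FieldSpec(n_cells=25, width=512, height=512, seed=0)
        dapi, _, truth = synthetic.generate_cell_field(spec)
        labels = cdk2.segment_nuclei(dapi, config)
        assert labels.max() == 25
        props = measure.regionprops(labels)
        found = np.array([p.centroid[::-1] for p in props])  # (x, y)
        true_c = truth.cells[["x", "y"]].to_numpy()
        for tc in true_c:
            assert np.min(np.hypot(*(found - tc).T)) < 1.0

    def test_subthreshold_speck_removed(self, config):
        img = np.zeros((64, 64))
        img[10:20, 10:20] = 100          # 100 px nucleus
        img[40, 40] = 100                # 1 px speck < min area
        labels = cdk2.segment_nuclei(img, config)
        assert labels.max() == 1
        assert labels[40, 40] == 0

    def test_labels_contiguous_from_one(self, config):
        img = np.zeros((64, 64))
        img[5:15, 5:15] = 100
        img[30, 30] = 100                # removed by area filter
        img[40:50, 40:50] = 100
        labels = cdk2.segment_nuclei(img, config)
        assert sorted(np.unique(labels)) == [0, 1, 2]


class TestSegmentCells:
    def test_blank_reporter_channel_empty_mask(self, config):
        assert not cdk2.segment_cells(np.zeros((64, 64)), config).any()

    def test_single_infected_cell_area_within_5pct(self, config):
        spec = FieldSpec(n_cells=1, width=128, height=128, seed=1)
        _, venus, truth = synthetic.generate_cell_field(spec)
        mask = cdk2.segment_cells(venus, config)
        true_area = (truth.cell_mask > 0).sum()
        assert abs(mask.sum() - true_area) / true_area < 0.05

    def test_uninfected_only_field_empty_mask(self, config):
        spec = FieldSpec(n_cells=10, width=512, height=512,
                         infected_fraction=0.0, seed=2)
        _, venus, _ = synthetic.generate_cell_field(spec)
        assert not cdk2.segment_cells(venus, config).any()


class TestFilterUninfected:
    def test_empty_cell_mask_discards_all(self, config):
        nuclei = np.zeros((32, 32), np.int32)
        nuclei[2:6, 2:6] = 1
        out = cdk2.filter_uninfected(nuclei, np.zeros((32, 32), bool), config)
        assert out.max() == 0

    def test_full_cell_mask_keeps_all_with_labels(self, config):
        nuclei = np.zeros((32, 32), np.int32)
        nuclei[2:6, 2:6] = 1
        nuclei[10:14, 10:14] = 7
        out = cdk2.filter_uninfected(nuclei, np.ones((32, 32), bool), config)
        assert np.array_equal(out, nuclei)

    def test_retained_set_equals_infected_set(self, config, clumped_field):
        """Noiseless field with 30% uninfected: exactly the infected survive."""
        _, dapi, venus, truth = clumped_field
        nuclei = cdk2.segment_nuclei(dapi, config)
        cell_mask = cdk2.segment_cells(venus, config)
        kept = cdk2.filter_uninfected(nuclei, cell_mask, config)
        mapping = cdk2.match_labels(kept, truth.nuclei_mask)
        kept_true_ids = {mapping[int(l)] for l in np.unique(kept) if l > 0}
        infected_ids = set(truth.cells.loc[truth.cells["infected"], "cell_id"])
        assert kept_true_ids == infected_ids

    def test_frame_mismatch_rejected(self, config):
        with pytest.raises(ValueError):
            cdk2.filter_uninfected(np.zeros((4, 4), np.int32),
                                   np.zeros((5, 5), bool), config)


class TestVoronoiPartition:
    def test_single_nucleus_takes_whole_mask(self):
        nuclei = np.zeros((32, 32), np.int32)
        nuclei[14:18, 14:18] = 3
        mask = np.zeros((32, 32), bool)
        mask[5:30, 5:30] = True
        out = cdk2.voronoi_partition(nuclei, mask)
        assert np.array_equal(out > 0, mask)
        assert set(np.unique(out)) == {0, 3}

    def test_symmetric_pair_splits_at_perpendicular_bisector(self):
        nuclei = np.zeros((40, 60), np.int32)
        nuclei[18:23, 10:15] = 1
        nuclei[18:23, 45:50] = 2
        mask = np.ones((40, 60), bool)
        out = cdk2.voronoi_partition(nuclei, mask)
        # bisector between seed edges at columns 14 and 45 -> boundary at x=29.5;
        # the tie column does not exist on the integer grid here
        assert np.all(out[:, :30] == 1)
        assert np.all(out[:, 30:] == 2)

    def test_matches_brute_force_on_small_field(self):
        rng = np.random.default_rng(0)
        nuclei = np.zeros((48, 48), np.int32)
        for lab, (y, x) in enumerate(rng.integers(4, 44, (5, 2)), start=1):
            nuclei[y - 2:y + 2, x - 2:x + 2] = lab
        mask = rng.random((48, 48)) < 0.8
        mask |= nuclei > 0
        out = cdk2.voronoi_partition(nuclei, mask)
        oracle = brute_force_nearest_seed(nuclei, mask)
        assert np.array_equal(out[mask], oracle[mask])

    def test_clumped_field_matches_nearest_seed_oracle(self, config, clumped_field):
        _, dapi, venus, _ = clumped_field
        nuclei = cdk2.segment_nuclei(dapi, config)
        cell_mask = cdk2.segment_cells(venus, config)
        kept = cdk2.filter_uninfected(nuclei, cell_mask, config)
        out = cdk2.voronoi_partition(kept, cell_mask)
        assert np.array_equal(out, nearest_seed_oracle(kept, cell_mask))

    def test_unreachable_nucleus_keeps_own_pixels(self):
        nuclei = np.zeros((32, 32), np.int32)
        nuclei[4:8, 4:8] = 1
        mask = np.zeros((32, 32), bool)  # no foreground at all
        out = cdk2.voronoi_partition(nuclei, mask)
        assert np.array_equal(out == 1, nuclei == 1)


class TestMaskAlgebra:
    def test_cytoplasm_is_cell_minus_nucleus(self):
        cells = np.zeros((16, 16), np.int32)
        cells[2:10, 2:10] = 1
        nuclei = np.zeros((16, 16), np.int32)
        nuclei[4:8, 4:8] = 1
        cyto = cdk2.cytoplasm_masks(cells, nuclei)
        assert not ((cyto > 0) & (nuclei > 0)).any()
        assert np.array_equal((cyto == 1) | (nuclei == 1), cells == 1)

    def test_cell_equal_to_nucleus_gives_empty_cytoplasm(self):
        region = np.zeros((8, 8), np.int32)
        region[2:6, 2:6] = 1
        assert cdk2.cytoplasm_masks(region, region).max() == 0

    def test_partition_properties_on_random_field(self, config, clumped_field):
        """Per label: nucleus and cytoplasm disjoint, their union is the
        Voronoi region, and regions partition the cell mask, pixel-wise."""
        _, dapi, venus, _ = clumped_field
        nuclei = cdk2.segment_nuclei(dapi, config)
        cell_mask = cdk2.segment_cells(venus, config)
        kept = cdk2.filter_uninfected(nuclei, cell_mask, config)
        cells = cdk2.voronoi_partition(kept, cell_mask)
        cyto = cdk2.cytoplasm_masks(cells, kept)
        assert np.array_equal(cells > 0, cell_mask)   # regions cover the mask
        for lab in np.unique(kept):
            if lab == 0:
                continue
            nuc = kept == lab
            cy = cyto == lab
            assert not (nuc & cy).any()
            assert np.array_equal(nuc & (cells == lab) | cy, cells == lab)


class TestMeasureAndClassify:
    def test_uniform_image_gives_unit_ratio(self):
        nuclei = np.zeros((16, 16), np.int32)
        nuclei[2:6, 2:6] = 1
        cyto = np.zeros((16, 16), np.int32)
        cyto[8:12, 8:12] = 1
        m = cdk2.measure_cells(nuclei, cyto, np.full((16, 16), 7.0))
        assert m["nuclear_mean"].iloc[0] == 7
        assert m["cn_ratio"].iloc[0] == 1.0
        assert m["intdens"].iloc[0] == 7.0 * 16

    def test_noiseless_cell_exact_ratio(self, config):
        spec = FieldSpec(n_cells=1, width=128, height=128,
                         nuclear_intensity_range=(100, 100),
                         cytoplasmic_intensity_range=(50, 50), seed=0)
        dapi, venus, truth = synthetic.generate_cell_field(spec)
        res = cdk2.run_workflow(dapi, venus, config)
        assert res["measurements"]["cn_ratio"].iloc[0] == pytest.approx(0.50, abs=0.02)

    def test_noisy_field_ratio_within_10pct_for_95pct_of_cells(self, config):
        spec = FieldSpec(n_cells=300, width=1024, height=1024,
                         gaussian_noise_sd=5.0, clumped_fraction=0.2, seed=8)
        dapi, venus, truth = synthetic.generate_cell_field(spec)
        res = cdk2.run_workflow(dapi, venus, config)
        j = matched_measurements(res, truth)
        j = j[j["infected"]]
        assert len(j) >= 290
        rel = np.abs(j["cn_ratio"] - j["true_cn_ratio"]) / j["true_cn_ratio"]
        assert (rel < 0.10).mean() >= 0.95

    @pytest.mark.parametrize("ratio,expected", [
        (np.nan, "G0G1"),        # no cytoplasmic mask
        (0.64, "G0G1"),
        (0.65, "cycling"),       # strict "lower than"
        (2.0, "cycling"),
    ])
    def test_threshold_is_strict(self, config, ratio, expected):
        df = pd.DataFrame({"cell_id": [1], "nuclear_mean": [100.0],
                           "cytoplasmic_mean": [ratio * 100],
                           "cn_ratio": [ratio], "intdens": [10.0]})
        out = cdk2.classify_cycle_state(df, config)
        assert out["cycle_class"].iloc[0] == expected

    def test_reporter_scaling_leaves_ratio_scales_intdens(self, config):
        """Scaling the reporter channel scales IntDens and fixes C/N."""
        spec = FieldSpec(n_cells=20, width=512, height=512, seed=9)
        dapi, venus, _ = synthetic.generate_cell_field(spec)
        cfg = WorkflowConfig(cell_threshold_method="fixed", cell_fixed_threshold=15)
        r1 = cdk2.run_workflow(dapi, venus, cfg)
        cfg3 = WorkflowConfig(cell_threshold_method="fixed", cell_fixed_threshold=45)
        r3 = cdk2.run_workflow(dapi, venus.astype(float) * 3, cfg3)
        m1, m3 = r1["measurements"], r3["measurements"]
        assert np.allclose(m1["cn_ratio"], m3["cn_ratio"])
        assert np.allclose(m3["intdens"], 3 * m1["intdens"])


class TestScoringAndQc:
    def _classified(self, intdens):
        return pd.DataFrame({"cell_id": range(1, len(intdens) + 1),
                             "nuclear_mean": 100.0, "cytoplasmic_mean": 50.0,
                             "cn_ratio": 0.5, "intdens": intdens,
                             "cycle_class": "G0G1"})

    def test_identical_condition_fold_one(self):
        df = self._classified([10.0, 20.0])
        out = cdk2.score_residual_activity({"WT": df, "KO": df.copy()}, "WT")
        assert out.set_index("condition")["fold_change"]["KO"] == 1.0

    def test_doubled_cytoplasmic_intensity_doubles_fold(self, config):
        base = FieldSpec(n_cells=150, width=1024, height=1024, seed=12,
                         nuclear_intensity_range=(100, 100),
                         cytoplasmic_intensity_range=(30, 30))
        doubled = base.replace(cytoplasmic_intensity_range=(60, 60))
        conds = {}
        for name, spec in [("ref", base), ("high", doubled)]:
            dapi, venus, _ = synthetic.generate_cell_field(spec)
            conds[name] = cdk2.run_workflow(dapi, venus, config)["measurements"]
        out = cdk2.score_residual_activity(conds, "ref").set_index("condition")
        assert out["fold_change"]["high"] == pytest.approx(2.0, rel=0.05)

    def test_zero_signal_reference_flagged(self):
        ref = self._classified([0.0, 0.0])
        out = cdk2.score_residual_activity(
            {"ref": ref, "c": self._classified([5.0])}, "ref")
        assert out["fold_change"].isna().all()

    def test_no_g0g1_cells_flagged_degenerate(self):
        df = self._classified([10.0])
        df["cycle_class"] = "cycling"
        out = cdk2.score_residual_activity({"ref": self._classified([10.0]),
                                            "c": df}, "ref")
        assert bool(out.set_index("condition")["degenerate"]["c"])

    @pytest.mark.parametrize("n,passed", [(250, True), (249, False), (0, False)])
    def test_min_cell_qc_boundary(self, config, n, passed):
        df = pd.DataFrame({"cell_id": range(n)})
        qc = cdk2.qc_min_cells(df, config)
        assert qc["passed"] is passed
        assert qc["n_cells"] == n
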