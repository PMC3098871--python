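"""Synthetic-data generators: invariants, determinism and truth tables."""

import numpy as np
import pandas as pd
import pytest

from promchip import FragmentLengthDist, peak_shape, synthetic
from promchip.errors import LayoutConsistencyError
from promchip.motifs import MotifMatrix


@pytest.fixture(scope="module")
def sharp_motif():
    counts = np.full((8, 4), 1.0)
    for i, b in enumerate("GTCTAGAC"):
        counts[i, "ACGT".index(b)] = 97.0
    return MotifMatrix.from_counts(counts)


class TestLayout:
    def test_invariants(self):
        layout = synthetic.generate_layout(50, seed=7)
        for gene, sub in layout.groupby("gene_id"):
            offsets = np.sort(sub["offset_bp"].to_numpy())
            assert 4 <= len(offsets) <= 6
            assert offsets.min() >= -2000 and offsets.max() <= 800
            gaps = np.diff(offsets)
            assert np.all((gaps >= 250) & (gaps <= 350))

    def test_deterministic(self):
        a = synthetic.generate_layout(20, seed=3)
        b = synthetic.generate_layout(20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_probe_counts_over_many_genes(self):
        layout = synthetic.generate_layout(1000, seed=1)
        counts = layout.groupby("gene_id").size()
        assert set(counts.unique()) <= {4, 5, 6}
        assert len(counts) == 1000

    def test_rejects_zero_genes(self):
        with pytest.raises(ValueError):
            synthetic.generate_layout(0, seed=1)


class TestChipSimulation:
    def test_null_truth_zero_noise_gives_unit_ratios(self):
        layout = synthetic.generate_layout(10, seed=2)
        truth = synthetic.make_chip_truth(layout, 0.0, 3.0, "basal", seed=3)
        arrays = synthetic.simulate_chip_arrays(layout, truth, noise_sd_log2=0.0, seed=4)
        for rep in arrays.replicates("basal"):
            assert np.allclose(arrays.ratios("basal", rep)["ratio"], 1.0)

    def test_probe_at_event_center_reads_full_fold(self):
        layout = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(4)],
                "gene_id": "g",
                "offset_bp": [-800, -500, -200, 100],
            }
        )
        truth = pd.DataFrame(
            [{"gene_id": "g", "true_center": -500, "true_fold": 3.0, "condition": "stim"}]
        )
        arrays = synthetic.simulate_chip_arrays(layout, truth, noise_sd_log2=0.0, seed=0)
        ratios = arrays.ratios("stim", 1).set_index("offset_bp")["ratio"]
        assert ratios.loc[-500] == pytest.approx(3.0)

    def test_truth_gene_missing_from_layout_rejected(self):
        layout = synthetic.generate_layout(3, seed=1)
        truth = pd.DataFrame(
            [{"gene_id": "ALIEN", "true_center": 0, "true_fold": 2.0, "condition": "b"}]
        )
        with pytest.raises(LayoutConsistencyError):
            synthetic.simulate_chip_arrays(layout, truth)

    def test_zero_noise_forward_model_invertible(self, uniform_shape):
        # the peak fitter must exactly invert the noiseless generator
        from promchip.peaks import fit_peak

        layout = synthetic.generate_layout(15, seed=5)
        truth = synthetic.make_chip_truth(layout, 0.5, 4.0, "stim", seed=6, on_grid=25)
        arrays = synthetic.simulate_chip_arrays(
            layout, truth, noise_sd_log2=0.0, seed=7, shape=uniform_shape
        )
        ratios = arrays.ratios("stim", 1)
        for row in truth.itertuples():
            if row.true_fold == 1.0:
                continue
            sub = ratios[ratios["gene_id"] == row.gene_id]
            c, f, _, rss1, _ = fit_peak(
                zip(sub["offset_bp"], sub["ratio"]), uniform_shape
            )
            assert f == pytest.approx(row.true_fold, rel=1e-6)
            assert rss1 == pytest.approx(0.0, abs=1e-10)


class TestPromoterSequences:
    def test_planted_instances_recorded_and_present(self, sharp_motif):
        layout = synthetic.generate_layout(20, seed=8)
        genes = list(layout["gene_id"].unique())
        seqs, truth = synthetic.generate_promoter_sequences(
            layout, sharp_motif, set(genes[:10]), seed=9
        )
        assert set(truth["gene_id"]) == set(genes[:10])
        for row in truth.itertuples():
            seq = seqs[row.gene_id]
            idx = row.offset - synthetic.PROMOTER_SPAN[0]
            planted = seq[idx : idx + sharp_motif.width]
            if row.strand == "+":
                assert planted == row.instance
            else:
                from promchip.motifs import reverse_complement

                assert planted == reverse_complement(row.instance)

    def test_sequences_cover_span(self, sharp_motif):
        layout = synthetic.generate_layout(3, seed=1)
        seqs, _ = synthetic.generate_promoter_sequences(layout, sharp_motif, set(), seed=2)
        lo, hi = synthetic.PROMOTER_SPAN
        assert all(len(s) == hi - lo + 1 for s in seqs.values())

    def test_deterministic(self, sharp_motif):
        layout = synthetic.generate_layout(5, seed=1)
        a, ta = synthetic.generate_promoter_sequences(layout, sharp_motif, set(), seed=3)
        b, tb = synthetic.generate_promoter_sequences(layout, sharp_motif, set(), seed=3)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)

    def test_per_gene_plant_window_respected(self, sharp_motif):
        layout = synthetic.generate_layout(6, seed=4)
        genes = list(layout["gene_id"].unique())
        windows = {g: (-700, -500) for g in genes}
        _, truth = synthetic.generate_promoter_sequences(
            layout, sharp_motif, set(genes), seed=5, plant_window=windows
        )
        assert truth["offset"].between(-700, -500).all()

    def test_invalid_gc_rejected(self, sharp_motif):
        layout = synthetic.generate_layout(2, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_promoter_sequences(
                layout, sharp_motif, set(), background_gc=1.5
            )


class TestExpressionSimulation:
    def test_no_effect_no_bias_no_noise_arrays_identical(self):
        truth = synthetic.make_expression_truth(["a", "b", "c"], 0, 0, seed=0)
        long, _ = synthetic.simulate_expression_timecourse(
            truth, dye_bias=0.0, noise_sd_log2=0.0, seed=1
        )
        wide = long.pivot_table(
            index="probe_id", columns=["arm", "time_h", "replicate"], values="intensity"
        )
        assert np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]])

    def test_full_attenuation_silences_sis3_arm(self):
        truth = synthetic.make_expression_truth(
            ["g1", "g2"], 1, 0, effect_profile=(0, 0, 0, 2.0), sis3_attenuation=0.0, seed=2
        )
        long, _ = synthetic.simulate_expression_timecourse(
            truth, dye_bias=0.0, noise_sd_log2=0.0, seed=3
        )
        up = truth.loc[truth["direction"] == "up", "gene_id"].iloc[0]
        sub = long[(long["gene_id"] == up) & (long["probe_id"].str.endswith("E0"))]
        sis3 = sub[sub["arm"] == "SIS3"].pivot_table(index="time_h", values="intensity")
        dmso = sub[sub["arm"] == "DMSO"].pivot_table(index="time_h", values="intensity")
        assert sis3.loc[24, "intensity"] == pytest.approx(sis3.loc[0, "intensity"])
        assert dmso.loc[24, "intensity"] == pytest.approx(4 * dmso.loc[0, "intensity"])

    def test_design_must_include_baseline(self):
        truth = synthetic.make_expression_truth(["a"], 0, 0, times=(0, 2),
                                                effect_profile=(0.0, 1.0), seed=0)
        with pytest.raises(ValueError):
            synthetic.simulate_expression_timecourse(truth, times=(2, 12))

    def test_truth_nulls_have_zero_effects(self):
        truth = synthetic.make_expression_truth([f"g{i}" for i in range(10)], 2, 2, seed=4)
        nulls = truth[truth["direction"] == "null"]
        for t in (0, 2, 12, 24):
            assert (nulls[f"effect_{t}h"] == 0).all()


class TestGeneSets:
    def test_enriched_set_overlaps_heavily(self):
        universe = [f"g{i}" for i in range(200)]
        enriched = set(universe[:30])
        sets = synthetic.generate_gene_sets(5, 20, enriched, universe, seed=5)
        overlap = len(set(sets["SET_000"]) & enriched)
        assert overlap >= 10
        assert all(len(s) == 20 for s in sets.values())

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_gene_sets(2, 0, set(), ["a", "b"], seed=1)

    def test_deterministic(self):
        universe = [f"g{i}" for i in range(50)]
        a = synthetic.generate_gene_sets(3, 10, set(universe[:5]), universe, seed=2)
        b = synthetic.generate_gene_sets(3, 10, set(universe[:5]), universe, seed=2)
        assert a == b
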