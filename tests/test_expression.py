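"""Normalization, probe summarisation, baseline ratios and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from promchip import expression, synthetic
from promchip.errors import EmptyInputError
from promchip.expression import (
    ExpressionMatrix,
    adjust_pvalues,
    cyclic_loess_normalize,
    delta_delta_ct,
    normalize_to_baseline,
    permutation_de_test,
    summarize_probes_to_genes,
)


def _two_array_matrix(values_a, values_b):
    n = len(values_a)
    long = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)] * 2,
            "gene_id": [f"g{i // 2}" for i in range(n)] * 2,
            "intensity": np.concatenate([2.0**np.asarray(values_a), 2.0**np.asarray(values_b)]),
            "time_h": 0,
            "arm": "DMSO",
            "replicate": [1] * n + [2] * n,
        }
    )
    return ExpressionMatrix.from_long(long)


class TestExpressionMatrix:
    def test_from_long_log2_transforms(self):
        mat = _two_array_matrix([3.0, 4.0], [3.0, 4.0])
        assert np.allclose(mat.values.to_numpy(), [[3, 3], [4, 4]])

    def test_nonpositive_intensity_rejected(self):
        long = pd.DataFrame(
            {
                "probe_id": ["p0"],
                "gene_id": ["g"],
                "intensity": [0.0],
                "time_h": [0],
                "arm": ["DMSO"],
                "replicate": [1],
            }
        )
        with pytest.raises(ValueError):
            ExpressionMatrix.from_long(long)


class TestCyclicLoess:
    def test_identical_arrays_converge_immediately(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 1.5, 500)
        mat = _two_array_matrix(base, base)
        with pytest.warns(UserWarning):
            norm, n_iter, converged, _ = cyclic_loess_normalize(mat, seed=0)
        assert converged and n_iter == 1
        assert np.allclose(norm.values.to_numpy(), mat.values.to_numpy())

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(2)
        base = rng.normal(8, 1.5, 2000)
        mat = _two_array_matrix(base, base + 1.0)
        with pytest.warns(UserWarning):
            norm, _, converged, _ = cyclic_loess_normalize(mat, seed=0)
        V = norm.values.to_numpy()
        assert converged
        assert abs((V[:, 0] - V[:, 1]).mean()) <= 0.01

    def test_smooth_dye_bias_converges_quickly(self):
        truth = synthetic.make_expression_truth(
            [f"g{i:03d}" for i in range(300)], 0, 0, seed=1
        )
        long, _ = synthetic.simulate_expression_timecourse(
            truth, dye_bias=0.3, noise_sd_log2=0.1, seed=2,
            times=(0, 24), arms=("DMSO",), n_replicates=3,
        )
        with pytest.warns(UserWarning):
            _, n_iter, converged, history = cyclic_loess_normalize(
                ExpressionMatrix.from_long(long), seed=3
            )
        assert converged and n_iter <= 5
        # the fitted bias amplitude shrinks across iterations
        assert history == sorted(history, reverse=True)

    def test_needs_two_arrays(self):
        mat = _two_array_matrix([1.0], [2.0])
        single = ExpressionMatrix(
            mat.values.iloc[:, :1], mat.arrays.iloc[:1], mat.probe_to_gene
        )
        with pytest.raises(ValueError):
            cyclic_loess_normalize(single)


class TestSummarizeAndBaseline:
    def test_probe_average(self):
        mat = _two_array_matrix([4.0, 6.0], [5.0, 7.0])  # one gene, two probes
        out = summarize_probes_to_genes(mat)
        assert out.loc["g0"].to_numpy() == pytest.approx([5.0, 6.0])

    def test_single_probe_identity(self):
        mat = _two_array_matrix([4.0], [5.0])
        out = summarize_probes_to_genes(mat)
        assert out.loc["g0"].to_numpy() == pytest.approx([4.0, 5.0])

    def test_baseline_normalization_arithmetic(self):
        arrays = pd.DataFrame(
            {
                "time_h": [0, 0, 24],
                "arm": ["DMSO"] * 3,
                "replicate": [1, 2, 1],
            },
            index=["a0", "a1", "a24"],
        )
        gm = pd.DataFrame({"a0": [3.0], "a1": [5.0], "a24": [6.0]}, index=["g"])
        tc = normalize_to_baseline(gm, arrays)
        assert tc.values.loc["g", "a24"] == pytest.approx(2.0)
        assert tc.values.loc["g", ["a0", "a1"]].mean() == pytest.approx(0.0)

    def test_rescaling_invariance(self):
        # multiplying every intensity of an array by a constant shifts its
        # log2 column; baseline normalization per arm removes equal shifts
        arrays = pd.DataFrame(
            {"time_h": [0, 24], "arm": ["DMSO"] * 2, "replicate": [1, 1]},
            index=["a0", "a24"],
        )
        gm = pd.DataFrame({"a0": [3.0, 1.0], "a24": [6.0, 2.0]}, index=["g1", "g2"])
        t1 = normalize_to_baseline(gm, arrays)
        t2 = normalize_to_baseline(gm + 2.5, arrays)
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_missing_baseline_rejected(self):
        arrays = pd.DataFrame(
            {"time_h": [24], "arm": ["DMSO"], "replicate": [1]}, index=["a24"]
        )
        with pytest.raises(ValueError):
            normalize_to_baseline(pd.DataFrame({"a24": [1.0]}, index=["g"]), arrays)


class TestPermutationTest:
    def test_identical_groups_give_one(self):
        assert permutation_de_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_extreme_split_enumeration(self):
        # all 20 splits of (0,0,0) vs (5,5,5): only the identity and the
        # complete swap reach |mean diff| = 5, so two-sided p = 2/20
        assert permutation_de_test([0, 0, 0], [5, 5, 5]) == pytest.approx(0.1)

    def test_sampled_path_needs_enough_permutations(self):
        x = list(range(7))
        y = [v + 0.5 for v in range(7)]  # C(14,7) = 3432 > exact limit
        with pytest.raises(ValueError):
            permutation_de_test(x, y, n_perm=50)
        p = permutation_de_test(x, y, n_perm=199, seed=1)
        assert 1 / 200 <= p <= 1.0

    def test_type_one_error_at_floor(self):
        # under the null the observed split is the most extreme of the 20
        # with probability 2/20
        rng = np.random.default_rng(3)
        hits = sum(
            permutation_de_test(rng.normal(size=3), rng.normal(size=3)) <= 0.1 + 1e-9
            for _ in range(1000)
        )
        assert hits / 1000 == pytest.approx(0.1, abs=0.03)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            permutation_de_test([1.0], [2.0, 3.0])


class TestAdjustPvalues:
    def test_bonferroni(self):
        out = adjust_pvalues([0.01] + [1.0] * 9, method="bonferroni")
        assert out[0] == pytest.approx(0.1)

    def test_bh_equal_inputs_unchanged(self):
        out = adjust_pvalues([0.2] * 5, method="bh")
        assert out == pytest.approx([0.2] * 5)

    def test_bh_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, 50)
        adj = adjust_pvalues(p, method="bh")
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            adjust_pvalues([])


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "treated,control,expected_ddct,expected_fold",
        [
            ((20.0, 18.0), (20.0, 18.0), 0.0, 1.0),
            ((19.0, 18.0), (20.0, 18.0), -1.0, 2.0),
            ((22.0, 18.0), (20.0, 18.0), 2.0, 0.25),
        ],
    )
    def test_formula(self, treated, control, expected_ddct, expected_fold):
        ddct, fold = delta_delta_ct(treated[0], treated[1], control[0], control[1])
        assert ddct == pytest.approx(expected_ddct)
        assert fold == pytest.approx(expected_fold)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_delta_ct(float("nan"), 18.0, 20.0, 18.0)


class TestPlantedRecovery:
    def test_regulated_genes_reach_permutation_floor(self):
        """Planted |log2| >= 1 effects at noise 0.25 are recovered in the
        vehicle arm at the exact test's achievable floor (p = 2/20), while
        full SIS3 attenuation leaves the same genes at background rates."""
        ids = [f"E{i:03d}" for i in range(120)]
        truth = synthetic.make_expression_truth(ids, 30, 30, sis3_attenuation=0.0, seed=2)
        long, _ = synthetic.simulate_expression_timecourse(
            truth, dye_bias=0.0, noise_sd_log2=0.25, seed=3
        )
        mat = ExpressionMatrix.from_long(long)
        genes = summarize_probes_to_genes(mat)
        tc = normalize_to_baseline(genes, mat.arrays)
        regulated = set(truth.loc[truth["direction"] != "null", "gene_id"])
        res = expression.test_timepoint(tc, "DMSO", 24, seed=5)
        sig = set(res.loc[res["pvalue"] <= 0.1 + 1e-9, "gene_id"])
        assert len(sig & regulated) / len(regulated) >= 0.8
        res_sis3 = expression.test_timepoint(tc, "SIS3", 24, seed=5)
        sig_sis3 = set(res_sis3.loc[res_sis3["pvalue"] <= 0.1 + 1e-9, "gene_id"])
        assert len(sig_sis3 & regulated) / len(regulated) <= 0.25
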