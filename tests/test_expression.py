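"""The DE stack and the set-level circuit statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cernakit.expression import (
    CountMatrix,
    bh_adjust,
    cluster_samples,
    concordance_venn,
    cpm_filter,
    differential_expression,
    ecdf_shift_test,
    gene_de_test,
    gene_log2fc,
    qpcr_rel_expr,
    size_factors_median_of_ratios,
    threshold_gene_set,
)


def _cm(counts: dict, genotypes=None, stimulations=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    samples = pd.DataFrame(
        {
            "sample_id": list(df.columns),
            "genotype": genotypes or ["WT"] * df.shape[1],
            "stimulation": stimulations or ["aCD3"] * df.shape[1],
        }
    )
    return CountMatrix(df, samples)


class TestCpmFilter:
    def test_boundary_kept_below_removed(self):
        # libraries sum to exactly 1e6 per sample
        cm = _cm(
            {
                "s1": [1, 2, 3, 999_994],
                "s2": [1, 2, 3, 999_994],
            }
        )
        out = cpm_filter(cm, min_mean_cpm=2.0)
        assert "g0" not in out.counts.index  # mean CPM 1 -> removed
        assert "g1" in out.counts.index  # exactly 2 -> kept (>= rule)
        assert "g2" in out.counts.index  # 3 -> kept
        assert out.counts.attrs["n_removed"] == 1

    def test_all_removed_errors(self):
        cm = _cm({"s1": [1, 1], "s2": [1, 1]})
        with pytest.raises(ValueError, match="every gene"):
            cpm_filter(cm, min_mean_cpm=1e9)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        sf = size_factors_median_of_ratios(counts)
        assert sf["s1"] == pytest.approx(1.0)
        assert sf["s2"] == pytest.approx(1.0)

    def test_doubled_sample_ratio_two(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = size_factors_median_of_ratios(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_no_reference_gene_errors(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="reference"):
            size_factors_median_of_ratios(counts)

    def test_simulated_depths_recovered_within_5pct(self, rng):
        true = np.array([1.0, 2.0, 4.0])
        base = rng.lognormal(4, 1, 2000)
        r = 1 / 0.05
        counts = pd.DataFrame(
            {
                f"s{j}": rng.negative_binomial(
                    r, r / (r + base * true[j])
                )
                for j in range(3)
            }
        )
        sf = size_factors_median_of_ratios(counts)
        est = (sf / sf["s0"]).to_numpy()
        assert np.all(np.abs(est - true) / true < 0.05)


class TestLogFoldChange:
    def test_identical_groups_zero(self):
        counts = pd.DataFrame(
            {"a1": [5, 9], "a2": [5, 9], "b1": [5, 9], "b2": [5, 9]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        out = gene_log2fc(counts, sf, ["a1", "a2"], ["b1", "b2"])
        assert np.allclose(out["log2fc"], 0.0)

    def test_pseudocount_arithmetic(self):
        counts = pd.DataFrame(
            {"a1": [15], "a2": [16], "b1": [3], "b2": [4]}
        )
        sf = pd.Series(1.0, index=counts.columns)
        out = gene_log2fc(counts, sf, ["a1", "a2"], ["b1", "b2"], pseudocount=0.5)
        # means 15.5 and 3.5 -> log2(16/4) = 2
        assert out.loc[0, "log2fc"] == pytest.approx(2.0, abs=1e-12)

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [1], "b2": [2]})
        sf = pd.Series(1.0, index=counts.columns)
        with pytest.raises(ValueError, match=">= 2"):
            gene_log2fc(counts, sf, ["a1"], ["b1", "b2"])


class TestDeTest:
    def test_degenerate_equal_means_p_one(self):
        counts = pd.DataFrame({"a1": [7], "a2": [7], "b1": [7], "b2": [7]})
        sf = pd.Series(1.0, index=counts.columns)
        p = gene_de_test(counts, sf, ["a1", "a2"], ["b1", "b2"])
        assert p.iloc[0] == 1.0

    def test_degenerate_different_means_p_zero(self):
        counts = pd.DataFrame({"a1": [7], "a2": [7], "b1": [70], "b2": [70]})
        sf = pd.Series(1.0, index=counts.columns)
        p = gene_de_test(counts, sf, ["a1", "a2"], ["b1", "b2"])
        assert p.iloc[0] == 0.0


class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(out, [0.03, 0.03, 0.03], atol=1e-12)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_monotone_bounded_and_order_free(self, ps):
        out = bh_adjust(ps)
        assert np.all(out <= 1.0 + 1e-12)
        assert np.all(out >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(out[order]) >= -1e-12)
        # permuting the input permutes the output identically
        perm = np.random.RandomState(0).permutation(len(ps))
        out_perm = bh_adjust(list(np.asarray(ps)[perm]))
        assert np.allclose(out_perm, out[perm], atol=1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust(pd.Series([0.01, np.nan, 0.5]))
        assert np.isnan(out.iloc[1])
        assert not np.isnan(out.iloc[0])


def _de(values: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"log2fc": pd.Series(values), "p_value": 0.5, "padj": 0.5}
    )


class TestEcdfShift:
    def test_equal_multisets_d_zero(self):
        de = _de({"t1": 1.0, "t2": 2.0, "b1": 1.0, "b2": 2.0})
        res = ecdf_shift_test(de, ["t1", "t2"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_d_one(self):
        de = _de({"t1": 1, "t2": 2, "t3": 3, "b1": 4, "b2": 5, "b3": 6})
        res = ecdf_shift_test(de, ["t1", "t2", "t3"])
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.direction == -1

    def test_interleaved_d_half(self):
        de = _de({"t1": 1, "t2": 3, "b1": 2, "b2": 4})
        res = ecdf_shift_test(de, ["t1", "t2"])
        assert res.statistic == pytest.approx(0.5, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        vals = {f"t{i}": float(v) for i, v in enumerate(rng.normal(1, 1, 30))}
        vals.update({f"b{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 50))})
        de1 = _de(vals)
        de2 = _de({k: math.atan(v) * 3 + 7 for k, v in vals.items()})
        t = [k for k in vals if k.startswith("t")]
        r1, r2 = ecdf_shift_test(de1, t), ecdf_shift_test(de2, t)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_empty_background_errors(self):
        de = _de({"t1": 1, "t2": 2})
        with pytest.raises(ValueError, match="background"):
            ecdf_shift_test(de, ["t1", "t2"])


class TestConcordanceVenn:
    def test_hand_enumeration(self):
        de_scr = _de({"g1": 1.0, "g2": 1.0, "g3": -1.0, "g4": -1.0})
        de_ko = _de({"g1": -1.0, "g2": 1.0, "g3": -1.0, "g4": 1.0})
        v = concordance_venn(de_scr, de_ko, ["g1", "g2", "g3", "g4"])
        assert (v.n_down_in_scr, v.n_up_in_ko, v.n_both, v.n_neither) == (2, 2, 1, 1)
        assert v.n_union == 3
        assert v.percentages()["union"] == pytest.approx(75.0)

    def test_zero_fold_changes_fall_in_neither(self):
        de = _de({"g1": 0.0, "g2": 0.0})
        v = concordance_venn(de, de, ["g1", "g2"])
        assert v.n_neither == 2
        assert v.n_both == v.n_down_in_scr == v.n_up_in_ko == 0

    def test_cells_partition_targets(self, rng):
        genes = [f"g{i}" for i in range(200)]
        de_scr = _de(dict(zip(genes, rng.normal(0, 1, 200))))
        de_ko = _de(dict(zip(genes, rng.normal(0, 1, 200))))
        v = concordance_venn(de_scr, de_ko, genes)
        down_only = v.n_down_in_scr - v.n_both
        up_only = v.n_up_in_ko - v.n_both
        assert v.n_both + down_only + up_only + v.n_neither == v.n_targets == 200

    def test_missing_genes_excluded_from_denominator(self):
        de_scr = _de({"g1": 1.0})
        de_ko = _de({"g1": -1.0})
        v = concordance_venn(de_scr, de_ko, ["g1", "gX"])
        assert v.n_targets == 1
        assert v.missing == ("gX",)


class TestThresholdGeneSet:
    def test_strict_inequalities(self):
        de = pd.DataFrame(
            {
                "log2fc": [2.0, 1.5, 2.0],
                "p_value": [1e-5, 1e-5, 1e-3],
                "padj": [1e-4, 1e-4, 1e-2],
            },
            index=["in_", "at_lfc", "high_padj"],
        )
        gs = threshold_gene_set(de, lfc_min=1.5, padj_max=0.001)
        assert gs.genes == ("in_",)
        assert gs.provenance["lfc_min"] == 1.5


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        expr = pd.DataFrame(
            {
                "s1": [1.0, 2.0, 3.0],
                "s2": [1.0, 2.0, 3.0],
                "s3": [9.0, 8.0, 1.0],
            },
            index=["g1", "g2", "g3"],
        )
        cl = cluster_samples(expr, ["g1", "g2", "g3"], k=2)
        first = cl.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)
        assert cl.labels["s1"] == cl.labels["s2"] != cl.labels["s3"]

    def test_constant_gene_dropped_with_warning(self, caplog):
        expr = pd.DataFrame(
            {
                "s1": [1.0, 5.0, 2.0],
                "s2": [1.0, 6.0, 3.0],
                "s3": [1.0, 9.0, 4.0],
            },
            index=["flat", "g2", "g3"],
        )
        with caplog.at_level("WARNING"):
            cl = cluster_samples(expr, ["flat", "g2", "g3"], k=2)
        assert cl.dropped_genes == ["flat"]

    def test_too_few_samples(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="3 samples"):
            cluster_samples(expr, ["g1", "g2"], k=2)


class TestQpcr:
    def test_examples(self):
        assert qpcr_rel_expr(25.0, 20.0) == pytest.approx(2**-5, abs=1e-12)
        assert qpcr_rel_expr(20.0, 20.0) == pytest.approx(1.0, abs=1e-12)

    def test_duplicates_averaged_before_delta(self):
        assert qpcr_rel_expr((25.0, 25.2), 20.0) == pytest.approx(
            2**-5.1, abs=1e-12
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            qpcr_rel_expr(float("nan"), 20.0)


class TestOrderInvariance:
    def test_filter_then_de_ignores_gene_order(self, rng):
        n = 300
        counts = pd.DataFrame(
            rng.poisson(50, size=(n, 6)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(6)],
        )
        samples = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "genotype": ["WT"] * 3 + ["scr"] * 3,
                "stimulation": ["aCD3"] * 6,
            }
        )
        a_ids = ["s0", "s1", "s2"]
        b_ids = ["s3", "s4", "s5"]

        def run(cdf):
            cm = cpm_filter(CountMatrix(cdf, samples))
            return differential_expression(cm, a_ids, b_ids)

        de1 = run(counts)
        perm = rng.permutation(n)
        de2 = run(counts.iloc[perm])
        joined = de1.join(de2, lsuffix="_1", rsuffix="_2")
        assert np.allclose(joined["log2fc_1"], joined["log2fc_2"])
        assert np.allclose(joined["padj_1"], joined["padj_2"])
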