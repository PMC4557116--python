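"""Tests for growth-correlated expression metrics and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fitflow import simulate
from fitflow.expression import (
    ExpressionTable,
    classify_by_mean_expression,
    compare_metrics,
    concentration_curve,
    expressed_gene_counts,
    gene_set_shift,
    meanpop_metric,
    replicon_fold_change,
    subpop_metric,
)


def table_from(values: dict, **kw) -> ExpressionTable:
    return ExpressionTable(pd.DataFrame(values, index=kw.pop("genes")), **kw)


@pytest.fixture
def tiny_table():
    return table_from(
        {"slow": [10.0, 10.0, 0.0], "fast": [10.0, 20.0, 0.0]},
        genes=["gA", "gB", "gC"],
    )


class TestSubpopMetric:
    def test_examples(self, tiny_table):
        m = subpop_metric(tiny_table, "fast", "slow", pseudocount=0.1)
        assert m.values["gA"] == pytest.approx(0.0)
        assert m.values["gC"] == pytest.approx(0.0)  # 0 vs 0 with pseudocount
        m0 = subpop_metric(
            table_from({"slow": [10.0], "fast": [20.0]}, genes=["g"]),
            "fast",
            "slow",
            pseudocount=0.0,
        )
        assert m0.values["g"] == pytest.approx(1.0)

    def test_zero_fpkm_without_pseudocount_names_genes(self, tiny_table):
        with pytest.raises(ValueError, match="gC"):
            subpop_metric(tiny_table, "fast", "slow", pseudocount=0.0)

    @given(
        fpkm=st.lists(
            st.tuples(
                st.floats(0.0, 1e5, allow_nan=False),
                st.floats(0.0, 1e5, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        ),
        c=st.floats(1e-3, 10.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetric_under_label_swap(self, fpkm, c):
        tab = table_from(
            {"slow": [a for a, _ in fpkm], "fast": [b for _, b in fpkm]},
            genes=[f"g{i}" for i in range(len(fpkm))],
        )
        fwd = subpop_metric(tab, "fast", "slow", c).values
        rev = subpop_metric(tab, "slow", "fast", c).values
        assert np.array_equal(fwd.to_numpy(), -rev.to_numpy())

    def test_pseudocount_continuity(self):
        tab = table_from({"slow": [4.0, 9.0], "fast": [8.0, 3.0]}, genes=["a", "b"])
        exact = subpop_metric(tab, "fast", "slow", 0.0).values
        for c in (1e-4, 1e-7, 1e-10):
            approx = subpop_metric(tab, "fast", "slow", c).values
            assert np.allclose(approx, exact, atol=10 * c)


class TestMeanpopMetric:
    def test_arithmetic(self):
        ratios = pd.DataFrame(
            {"f1": [1.0], "f2": [2.0], "s1": [0.0], "s2": [1.0]}, index=["g"]
        )
        rates = {"f1": 0.3, "f2": 0.3, "s1": 0.05, "s2": 0.05}
        assert meanpop_metric(ratios, rates).values["g"] == pytest.approx(1.0)

    def test_identical_conditions_give_zero(self):
        ratios = pd.DataFrame({"f": [0.7], "s": [0.7]}, index=["g"])
        m = meanpop_metric(ratios, {"f": 0.3, "s": 0.05})
        assert m.values["g"] == pytest.approx(0.0)

    def test_genes_with_missing_values_excluded(self):
        ratios = pd.DataFrame(
            {"f": [1.0, np.nan], "s": [0.0, 0.5]}, index=["g1", "g2"]
        )
        m = meanpop_metric(ratios, {"f": 0.3, "s": 0.05})
        assert list(m.values.index) == ["g1"]

    def test_metric_rank_correlates_with_planted_slopes(self):
        _, chemo, truth = simulate.gen_expression(
            n_genes=2000, noise_sd=0.5, cross_metric_r=0.0, seed=21
        )
        m = meanpop_metric(chemo, truth.params["condition_rates"])
        rho = stats.spearmanr(
            m.values, truth.records.loc[m.values.index, "true_meanpop_metric"]
        ).statistic
        assert rho > 0.95


class TestCompareMetrics:
    def _metric(self, values, genes):
        from fitflow.expression import GrowthExpressionMetric

        return GrowthExpressionMetric(pd.Series(values, index=genes), "subpopulation")

    def test_self_comparison_r_one(self):
        m = self._metric([1.0, -2.0, 0.5, 3.0], list("abcd"))
        assert compare_metrics(m, m).pearson_r == pytest.approx(1.0)

    def test_negated_comparison_r_minus_one(self):
        m = self._metric([1.0, -2.0, 0.5, 3.0], list("abcd"))
        neg = self._metric([-1.0, 2.0, -0.5, -3.0], list("abcd"))
        assert compare_metrics(m, neg).pearson_r == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        m1 = self._metric([1.0, -2.0, 0.5, 3.0, 0.1], list("abcde"))
        m2 = self._metric([0.3, -1.0, 0.2, 2.0, -0.4], list("abcde"))
        assert compare_metrics(m1, m2).pearson_r == pytest.approx(
            compare_metrics(m2, m1).pearson_r
        )

    def test_too_few_shared_genes(self):
        m1 = self._metric([1.0, 2.0], ["a", "b"])
        m2 = self._metric([1.0, 2.0], ["c", "d"])
        with pytest.raises(ValueError):
            compare_metrics(m1, m2)

    def test_quadrant_counts_sum_to_genes(self):
        m1 = self._metric([1.0, -2.0, 0.5, -3.0], list("abcd"))
        m2 = self._metric([1.0, 2.0, -0.5, -3.0], list("abcd"))
        cmp = compare_metrics(m1, m2)
        assert sum(cmp.quadrant_counts.values()) == 4
        assert cmp.quadrants["a"] == "concordant_up"
        assert cmp.quadrants["d"] == "concordant_down"


class TestGeneSetShift:
    def test_null_set_not_significant(self, rng):
        vals = pd.Series(rng.normal(0, 1, 2000), index=[f"g{i}" for i in range(2000)])
        shift = gene_set_shift(vals, [f"g{i}" for i in range(0, 2000, 10)])
        assert shift.pvalue > 0.01
        assert abs(shift.statistic) < 0.2

    def test_separated_set_extremely_significant(self, rng):
        n = 5200
        vals = pd.Series(rng.normal(0, 1, n), index=[f"g{i}" for i in range(n)])
        members = [f"g{i}" for i in range(200)]
        vals[members] += 5.0
        shift = gene_set_shift(vals, members)
        assert shift.pvalue < 1e-10
        assert shift.statistic > 0.9

    def test_single_gene_set_flagged_low_power(self):
        vals = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        shift = gene_set_shift(vals, ["d"])
        assert shift.low_power and np.isfinite(shift.statistic)

    def test_set_equal_to_universe_errors(self):
        vals = pd.Series([0.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            gene_set_shift(vals, ["a", "b"])

    def test_planted_signs_recovered(self):
        fpkm, _, truth = simulate.gen_expression(
            n_genes=3000,
            set_specs={"ribosomal": (100, 1.0), "stress": (100, -1.0)},
            noise_sd=0.5,
            seed=22,
        )
        m = subpop_metric(ExpressionTable(fpkm), "fast", "slow")
        sets = truth.params["gene_sets"]
        ribo = gene_set_shift(m, sets["ribosomal"])
        stress = gene_set_shift(m, sets["stress"])
        assert ribo.statistic > 0 and ribo.pvalue < 0.01
        assert stress.statistic < 0 and stress.pvalue < 0.01


class TestExpressedGeneCounts:
    def test_band_boundaries(self):
        tab = table_from({"s": [0.0, 4.9, 5.0, 29.9, 30.0]}, genes=list("abcde"))
        counts = expressed_gene_counts(tab)["s"]
        assert list(counts) == [2, 2, 1]

    def test_empty_table(self):
        tab = table_from({"s": []}, genes=[])
        assert expressed_gene_counts(tab)["s"].sum() == 0

    def test_planted_midband_excess_recovered(self):
        rng = np.random.default_rng(23)
        n = 4000
        base = 10 ** rng.uniform(-1, 3, n)
        slow = base.copy()
        extra = rng.uniform(5, 30, 500)
        slow[:500] = extra  # 500 extra mid-band genes in the slow sample
        fast = base.copy()
        fast[:500] = 0.1
        tab = table_from(
            {"slow": slow, "fast": fast}, genes=[f"g{i}" for i in range(n)]
        )
        counts = expressed_gene_counts(tab)
        diff = counts.loc["[5,30)", "slow"] - counts.loc["[5,30)", "fast"]
        assert diff == pytest.approx(500, abs=60)


class TestConcentrationCurve:
    def test_uniform_expression_is_diagonal(self):
        tab = table_from({"s": [3.0] * 50}, genes=[f"g{i}" for i in range(50)])
        curve = concentration_curve(tab, "s")
        assert np.allclose(curve["cumulative_fraction"], curve["rank_fraction"])

    def test_single_dominant_gene_jumps_to_one(self):
        tab = table_from({"s": [100.0, 0.0, 0.0]}, genes=list("abc"))
        curve = concentration_curve(tab, "s")
        assert curve["cumulative_fraction"].iloc[0] == pytest.approx(1.0)

    def test_zipf_partial_sum_closed_form(self):
        n, s = 1000, 1.2
        weights = np.arange(1, n + 1, dtype=float) ** -s
        tab = table_from({"x": weights}, genes=[f"g{i}" for i in range(n)])
        curve = concentration_curve(tab, "x")
        k = n // 10
        expected = weights[:k].sum() / weights.sum()
        assert curve["cumulative_fraction"].iloc[k - 1] == pytest.approx(
            expected, abs=1e-6
        )

    def test_monotone_concave_ends_at_one(self, rng):
        vals = 10 ** rng.normal(1, 1.5, 300)
        tab = table_from({"s": vals}, genes=[f"g{i}" for i in range(300)])
        curve = concentration_curve(tab, "s")["cumulative_fraction"].to_numpy()
        steps = np.diff(np.concatenate([[0.0], curve]))
        assert np.all(steps >= -1e-12)  # monotone
        assert np.all(np.diff(steps) <= 1e-12)  # concave: decreasing steps
        assert curve[-1] == pytest.approx(1.0)

    def test_all_zero_sample_errors(self):
        tab = table_from({"s": [0.0, 0.0]}, genes=["a", "b"])
        with pytest.raises(ValueError):
            concentration_curve(tab, "s")


class TestExpressionClassification:
    def test_all_equal_all_mid(self):
        tab = table_from({"s": [5.0] * 10, "f": [5.0] * 10}, genes=[f"g{i}" for i in range(10)])
        assert (classify_by_mean_expression(tab) == "mid").all()

    def test_extreme_outlier_labeled_high(self, rng):
        vals = np.concatenate([10 ** rng.normal(1, 0.3, 999), [1e6]])
        tab = table_from({"s": vals}, genes=[f"g{i}" for i in range(1000)])
        assert classify_by_mean_expression(tab).iloc[-1] == "high"

    def test_invariant_under_global_scaling(self, rng):
        vals = 10 ** rng.normal(1, 1, 200)
        genes = [f"g{i}" for i in range(200)]
        t1 = table_from({"s": vals}, genes=genes)
        t2 = table_from({"s": vals * 1000}, genes=genes)
        # pseudocount must scale with the data for exact invariance
        a = classify_by_mean_expression(t1, pseudocount=0.0)
        b = classify_by_mean_expression(t2, pseudocount=0.0)
        assert (a == b).all()

    def test_single_gene_errors(self):
        tab = table_from({"s": [1.0]}, genes=["a"])
        with pytest.raises(ValueError):
            classify_by_mean_expression(tab)


class TestRepliconFoldChange:
    def _series(self, values, genes):
        return pd.Series(values, index=genes)

    def test_all_zero_metric(self):
        genes = [f"g{i}" for i in range(40)]
        rep = {g: f"chr{i % 4 + 1}" for i, g in enumerate(genes)}
        out = replicon_fold_change(
            self._series(np.zeros(40), genes), rep, [f"chr{i}" for i in range(1, 5)]
        )
        assert np.allclose(out["median"], 0.0)
        assert np.allclose(out["z"], 0.0)

    def test_planted_plasmid_shift_detected(self, rng):
        genes = [f"g{i}" for i in range(16 * 50 + 40)]
        rep = {}
        vals = {}
        for i, g in enumerate(genes[: 16 * 50]):
            rep[g] = f"chr{i % 16 + 1}"
            vals[g] = float(rng.normal(0, 0.1))
        for g in genes[16 * 50 :]:
            rep[g] = "2micron"
            vals[g] = float(rng.normal(-2.0, 0.1))
        out = replicon_fold_change(
            self._series(vals, genes), rep, [f"chr{i}" for i in range(1, 17)]
        ).set_index("replicon")
        assert out.loc["2micron", "z"] < -10

    def test_single_gene_replicon_median_is_value(self):
        out = replicon_fold_change(
            self._series([1.0, 2.0, 7.0], ["a", "b", "c"]),
            {"a": "chr1", "b": "chr2", "c": "virus"},
            ["chr1", "chr2"],
        ).set_index("replicon")
        assert out.loc["virus", "median"] == 7.0
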