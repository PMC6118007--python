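import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ximosaic import (CRE_NEG, CRE_POS, QpcrMeasurement, compare_bins,
                      delta_delta_ct, estimate_reactivation_fraction,
                      filter_low_coverage, normalize_libraries,
                      reactivation_ratio, stratify_by_expression)
from ximosaic.reactivation import CountMatrix


def make_count_matrix(counts: dict, conditions: dict) -> CountMatrix:
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    df.index.name = "gene_id"
    samples = pd.DataFrame({
        "sample_id": list(counts),
        "condition": [conditions[s] for s in counts],
        "replicate": list(range(1, len(counts) + 1)),
        "library_size": [int(df[s].sum()) for s in counts],
    })
    return CountMatrix(df, samples)


def annotation_for(cm: CountMatrix, x_genes=()):
    return pd.DataFrame({
        "gene_id": cm.counts.index,
        "chrom": ["X" if g in x_genes else "autosome_1" for g in cm.counts.index],
    })


class TestNormalizeLibraries:
    def test_equal_totals_give_unit_factors(self):
        cm = make_count_matrix({"a": [10, 20], "b": [15, 15]},
                               {"a": CRE_POS, "b": CRE_NEG})
        norm = normalize_libraries(cm, annotation_for(cm))
        assert np.allclose(norm.scale_factors, 1.0)

    def test_doubled_sample_scaled_to_geometric_mean(self):
        cm = make_count_matrix({"a": [10, 20], "b": [20, 40]},
                               {"a": CRE_POS, "b": CRE_NEG})
        norm = normalize_libraries(cm, annotation_for(cm))
        # totals (30, 60): target sqrt(1800), factors target/total
        target = math.sqrt(30 * 60)
        assert norm.scale_factors["a"] == pytest.approx(target / 30)
        assert norm.scale_factors["b"] == pytest.approx(target / 60)
        assert (norm.values.loc["g0"] * 0 + norm.values.sum()).iloc[0] == \
            pytest.approx(norm.values.sum().iloc[1])

    def test_x_counts_excluded_from_factor_computation(self):
        # X inflated in Cre+ only; autosomal totals equal -> all factors 1
        cm = make_count_matrix({"a": [50, 500], "b": [50, 100]},
                               {"a": CRE_POS, "b": CRE_NEG})
        norm = normalize_libraries(cm, annotation_for(cm, x_genes={"g1"}))
        assert np.allclose(norm.scale_factors, 1.0)

    def test_zero_autosomal_reads_rejected(self):
        cm = make_count_matrix({"a": [0, 10], "b": [5, 5]},
                               {"a": CRE_POS, "b": CRE_NEG})
        with pytest.raises(ValueError, match="zero autosomal"):
            normalize_libraries(cm, annotation_for(cm, x_genes={"g1"}))


class TestFilterLowCoverage:
    def test_threshold_boundary(self):
        cm = make_count_matrix({"a": [10, 10, 5], "b": [9, 10, 5]},
                               {"a": CRE_POS, "b": CRE_NEG})
        retained = filter_low_coverage(cm, 20)
        assert list(retained) == ["g1"]  # total 19 excluded, total 20 retained

    def test_zero_threshold_keeps_everything(self):
        cm = make_count_matrix({"a": [0, 1], "b": [0, 0]},
                               {"a": CRE_POS, "b": CRE_NEG})
        assert len(filter_low_coverage(cm, 0)) == 2

    def test_negative_threshold_rejected(self):
        cm = make_count_matrix({"a": [1], "b": [1]},
                               {"a": CRE_POS, "b": CRE_NEG})
        with pytest.raises(ValueError):
            filter_low_coverage(cm, -1)


class TestReactivationRatio:
    def ratios_for(self, pos, neg, x_genes=("g0",)):
        # the last gene is an autosomal anchor with equal counts, so the
        # normalization factors stay at unity
        cm = make_count_matrix({"a": pos, "b": neg},
                               {"a": CRE_POS, "b": CRE_NEG})
        norm = normalize_libraries(cm, annotation_for(cm, set(x_genes)))
        return reactivation_ratio(norm, filter_low_coverage(cm, 0))

    def test_balanced_counts_give_half(self):
        out = self.ratios_for([100, 100], [100, 100])
        assert out["ratio"].tolist() == [0.5, 0.5]

    def test_three_percent_excess(self):
        out = self.ratios_for([103, 100], [100, 100])
        assert out["ratio"].iloc[0] == pytest.approx(103 / 203)

    def test_zero_numerator_and_zero_denominator(self):
        out = self.ratios_for([0, 0, 50], [50, 0, 50], x_genes=("g0", "g1"))
        assert out["ratio"].iloc[0] == 0.0
        assert np.isnan(out["ratio"].iloc[1])  # undefined, excluded downstream

    def test_missing_condition_rejected(self):
        df = pd.DataFrame({"a": [1], "b": [2]}, index=pd.Index(["g0"], name="gene_id"))
        samples = pd.DataFrame({"sample_id": ["a", "b"],
                                "condition": [CRE_POS, CRE_NEG],
                                "replicate": [1, 1], "library_size": [1, 2]})
        with pytest.raises(ValueError):
            CountMatrix(df, samples.assign(condition=[CRE_POS, CRE_POS]))


class TestStratifyByExpression:
    def ratios_table(self, n):
        return pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(n)],
                             "ratio": [0.5] * n})

    @pytest.mark.parametrize("n,k,sizes", [
        (540, 3, [180, 180, 180]),
        (540, 4, [135, 135, 135, 135]),
        (7, 3, [3, 2, 2]),  # remainders go to the lowest bins
    ])
    def test_bin_sizes(self, n, k, sizes):
        measure = pd.Series(np.arange(n, dtype=float),
                            index=[f"g{i:04d}" for i in range(n)])
        bins = stratify_by_expression(self.ratios_table(n), measure, k)
        assert [int((bins.assignments == b).sum()) for b in range(1, k + 1)] == sizes

    def test_bin_index_tracks_expression(self):
        n = 30
        rng = np.random.default_rng(0)
        measure = pd.Series(rng.random(n), index=[f"g{i:04d}" for i in range(n)])
        bins = stratify_by_expression(self.ratios_table(n), measure, 3)
        med = [measure[bins.genes_in(b)].median() for b in (1, 2, 3)]
        assert med[0] < med[1] < med[2]

    def test_ties_broken_lexicographically(self):
        measure = pd.Series([1.0] * 4, index=["g3", "g1", "g0", "g2"])
        table = pd.DataFrame({"gene_id": ["g3", "g1", "g0", "g2"],
                              "ratio": [0.5] * 4})
        bins = stratify_by_expression(table, measure, 2)
        assert set(bins.genes_in(1)) == {"g0", "g1"}
        assert set(bins.genes_in(2)) == {"g2", "g3"}

    def test_too_many_bins_rejected(self):
        measure = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(ValueError):
            stratify_by_expression(self.ratios_table(2), measure, 3)


class TestCompareBins:
    def build(self, values_a, values_b):
        n = len(values_a) + len(values_b)
        gene_ids = [f"g{i:04d}" for i in range(n)]
        table = pd.DataFrame({"gene_id": gene_ids,
                              "ratio": list(values_a) + list(values_b)})
        assignments = pd.Series([1] * len(values_a) + [2] * len(values_b),
                                index=pd.Index(gene_ids, name="gene_id"))
        from ximosaic.expression import ExpressionBinAssignment
        return table, ExpressionBinAssignment(2, assignments, [])

    def test_identical_groups_give_t0_p1(self):
        table, bins = self.build([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        res = compare_bins(table, bins, 1, 2)
        assert res.t == 0.0 and res.pvalue == 1.0

    def test_matches_closed_form_pooled_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.51, 0.05, 40), rng.normal(0.49, 0.08, 50)
        table, bins = self.build(a, b)
        res = compare_bins(table, bins, 1, 2)
        # independent closed form: pooled-variance two-sample t
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p = 2 * stats.t.sf(abs(t), len(a) + len(b) - 2)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.pvalue == pytest.approx(p, rel=1e-12)

    def test_power_at_reported_group_summaries(self):
        # MC oracle at the printed group summaries (n=180 each,
        # 0.509 +/- 0.047 vs 0.495 +/- 0.096): noncentrality ~1.76, so the
        # pooled t rejects at alpha=0.05 in roughly 42% of draws
        rng = np.random.default_rng(12345)
        rejections = 0
        n_draws = 1000
        for _ in range(n_draws):
            a = rng.normal(0.509, 0.047, 180)
            b = rng.normal(0.495, 0.096, 180)
            table, bins = self.build(a, b)
            if compare_bins(table, bins, 1, 2).pvalue < 0.05:
                rejections += 1
        assert 0.35 <= rejections / n_draws <= 0.50

    def test_aggregate_bins(self):
        table, bins = self.build([0.4, 0.45], [0.5, 0.55])
        res = compare_bins(table, bins, (1, 2), 2)
        assert res.n_a == 4 and res.n_b == 2

    def test_small_group_rejected(self):
        table, bins = self.build([0.5], [0.4, 0.6])
        with pytest.raises(ValueError):
            compare_bins(table, bins, 1, 2)


class TestEstimateReactivationFraction:
    def test_balanced_ratio_means_no_reactivation(self):
        assert estimate_reactivation_fraction(0.5) == 0.0

    def test_algebraic_inversion(self):
        assert estimate_reactivation_fraction(103 / 203) == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_reactivation_fraction(1.0)
        with pytest.raises(ValueError):
            estimate_reactivation_fraction(-0.1)

    def test_below_half_reports_negative(self):
        assert estimate_reactivation_fraction(0.45) < 0

    @given(st.floats(0.0, 0.6))
    def test_round_trips_expected_ratio(self, f):
        r = (1 + f) / (2 + f)
        assert estimate_reactivation_fraction(r) == pytest.approx(f, abs=1e-9)


class TestDeltaDeltaCt:
    def test_no_change_gives_unity(self):
        m = QpcrMeasurement(20, 18, 20, 18)
        assert delta_delta_ct(m) == 1.0

    def test_five_cycles_gives_one_thirtysecond(self):
        m = QpcrMeasurement(25, 18, 20, 18)
        assert delta_delta_ct(m) == 0.03125

    def test_three_cycle_target_shift(self):
        # target 3 cycles above calibrator, reference unchanged -> 2**-3
        m = QpcrMeasurement(23, 18, 20, 18)
        assert delta_delta_ct(m) == 0.125

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrMeasurement(float("nan"), 18, 20, 18)
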