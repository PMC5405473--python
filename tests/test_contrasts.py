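"""Contrast statistics: 2x2 tests and two-sample comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from tajscan.contrasts import (ContingencyTable2x2, ExpressionClass,
                               chi_square_2x2, fisher_exact_2x2, ks_two_sample,
                               rank_sum_test, selection_by_expression_contrast,
                               two_sample_t)
from tajscan.genes import GeneClass, GeneClassification
from tajscan.genome_io import GeneModel

import oracles


class TestChiSquare:
    def test_lifestyle_proportion_contrast(self):
        res = chi_square_2x2(ContingencyTable2x2(214, 5910, 178, 2884))
        assert res.statistic == pytest.approx(26.87, abs=0.01)
        assert res.df == 1 and res.p_value < 3e-7

    def test_invariable_window_contrast(self):
        res = chi_square_2x2(ContingencyTable2x2(400, 69294, 21, 65912))
        assert res.statistic == pytest.approx(321.74, abs=0.1)
        assert res.p_value < 6.1e-72

    def test_equal_proportions_zero(self):
        assert chi_square_2x2(ContingencyTable2x2(10, 90, 20, 180)).statistic \
            == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("table", [(5, 9, 3, 14), (40, 2, 7, 30)])
    def test_invariant_under_transposition_and_swaps(self, table):
        a, b, c, d = table
        base = chi_square_2x2(ContingencyTable2x2(a, b, c, d)).statistic
        for variant in [(a, c, b, d), (c, d, a, b), (b, a, d, c)]:
            assert chi_square_2x2(ContingencyTable2x2(*variant)).statistic \
                == pytest.approx(base, rel=1e-12)

    def test_matches_scipy_without_correction(self):
        t = ContingencyTable2x2(12, 7, 4, 19)
        ours = chi_square_2x2(t)
        ref = sps.chi2_contingency([[12, 7], [4, 19]], correction=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((11, 132, 30, 417), 0.706381),
        ((23, 986, 29, 2055), 0.075006),
        ((11, 132, 74, 1478), 0.15624),
        ((23, 986, 228, 14766), 0.066236),
        ((42, 967, 79, 2005), 0.621698),
        ((42, 967, 530, 14464), 0.292928),
    ])
    def test_expression_contrast_p_values(self, table, expected):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert res.p_value == pytest.approx(expected, abs=1e-4)

    def test_minimal_balanced_table(self):
        # 3 possible tables with margins (2,2,2,2); all qualify -> p = 1
        res = fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1))
        assert res.p_value == pytest.approx(1.0)
        assert res.p_value == pytest.approx(
            oracles.fisher_two_sided_enumeration(1, 1, 1, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
            assert p == pytest.approx(
                oracles.fisher_two_sided_enumeration(a, b, c, d), rel=1e-7)

    def test_doubling_convention_bounded_and_larger_tail(self):
        t = ContingencyTable2x2(2, 10, 12, 3)
        p_min = fisher_exact_2x2(t, convention="min_likelihood").p_value
        p_dbl = fisher_exact_2x2(t, convention="doubling").p_value
        assert 0 <= p_dbl <= 1 and p_dbl >= p_min - 1e-12

    def test_large_totals_do_not_overflow(self):
        res = fisher_exact_2x2(ContingencyTable2x2(400, 69294, 21, 65912))
        assert 0.0 <= res.p_value < 1e-50


class TestDistributionComparisons:
    def test_ks_identical_and_disjoint(self):
        x = np.arange(10.0)
        assert ks_two_sample(x, x).statistic == 0.0
        assert ks_two_sample(x, x + 100).statistic == 1.0

    def test_rank_sum_pair_count_scale(self):
        assert rank_sum_test([0.0], [0.0]).statistic == pytest.approx(0.5)
        assert rank_sum_test([5, 6, 7], [1, 2, 3, 4]).statistic \
            == pytest.approx(12.0)

    def test_t_identical_and_hand_example(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]).statistic \
            == pytest.approx(0.0, abs=1e-12)
        res = two_sample_t([0, 0, 1, 1], [1, 1, 2, 2], pooled=True)
        assert res.statistic == pytest.approx(-2.449, abs=0.01)
        assert res.df == 6

    def test_t_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1, 1], [1, 1])

    def test_shifted_distributions_rejected_by_rank_sum(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.normal(size=500)
            y = rng.normal(size=500) + 0.5
            if rank_sum_test(x, y).p_value < 0.01:
                hits += 1
        assert hits >= 48  # power >= 95% at this shift and size

    def test_equal_mean_t_type_one_error(self, rng):
        rejections = sum(
            two_sample_t(rng.normal(size=50), rng.normal(size=50)).p_value < 0.05
            for _ in range(200))
        assert 2 <= rejections <= 20  # ~5% of 200, generous Monte-Carlo band

    def test_ks_calibration_under_null(self, rng):
        rejections = sum(
            ks_two_sample(rng.normal(size=300), rng.normal(size=300)).p_value < 0.05
            for _ in range(100))
        assert 1 <= rejections <= 12


def make_gene_classes(spec):
    """spec: list of (gene_id, GeneClass)."""
    out = []
    for i, (gid, cls) in enumerate(spec):
        out.append(GeneClassification(
            gene=GeneModel(gid, "c", i * 1000, i * 1000 + 500),
            coverage_fraction=1.0, gene_class=cls))
    return out


class TestSelectionByExpression:
    def test_known_counts_and_six_tests(self):
        spec = (
            [(f"d{i}", GeneClass.SIGNIFICANT_POSITIVE) for i in range(2)]
            + [(f"d{i+2}", GeneClass.SIGNIFICANT_NEGATIVE) for i in range(1)]
            + [(f"d{i+3}", GeneClass.ANALYSED) for i in range(7)]
            + [(f"n{i}", GeneClass.SIGNIFICANT_POSITIVE) for i in range(1)]
            + [(f"n{i+1}", GeneClass.ANALYSED) for i in range(19)]
        )
        classes = make_gene_classes(spec)
        expr = {g: (ExpressionClass.DIFFERENTIAL if g.startswith("d")
                    else ExpressionClass.NON_DIFFERENTIAL)
                for g, _ in spec}
        counts, tests = selection_by_expression_contrast(classes, expr)
        diff = counts.set_index("class").loc["differential"]
        assert diff["n"] == 10 and diff["significant"] == 3
        assert diff["significant_positive"] == 2
        assert diff["significant_pct"] == pytest.approx(30.0)
        assert len(tests) == 6
        assert set(tests["comparison"]) == {"differential_vs_non_differential",
                                            "differential_vs_global_scan"}

    def test_external_global_counts_used(self):
        spec = [("d1", GeneClass.SIGNIFICANT_POSITIVE),
                ("d2", GeneClass.ANALYSED),
                ("n1", GeneClass.ANALYSED)]
        classes = make_gene_classes(spec)
        expr = {"d1": ExpressionClass.DIFFERENTIAL,
                "d2": ExpressionClass.DIFFERENTIAL,
                "n1": ExpressionClass.NON_DIFFERENTIAL}
        gc = {"n": 1000, "significant": 50, "significant_positive": 30,
              "significant_negative": 20}
        counts, tests = selection_by_expression_contrast(classes, expr, gc)
        g = counts.set_index("class").loc["global_scan"]
        assert g["n"] == 1000 and g["significant"] == 50

    def test_empty_class_skips_tests_but_reports_counts(self, caplog):
        spec = [("d1", GeneClass.ANALYSED)]
        classes = make_gene_classes(spec)
        expr = {"d1": ExpressionClass.DIFFERENTIAL}
        with caplog.at_level("WARNING"):
            counts, tests = selection_by_expression_contrast(classes, expr, {
                "n": 0, "significant": 0, "significant_positive": 0,
                "significant_negative": 0})
        assert len(counts) == 3
        nd = counts.set_index("class").loc["non_differential"]
        assert nd["n"] == 0
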