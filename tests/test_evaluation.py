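"""Validation metrics, bootstrap CIs and paired significance tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from gfrmodels.cohort import Cohort
from gfrmodels.errors import InsufficientDataError, ValidationError
from gfrmodels.evaluation import (
    PairedPredictions,
    bias,
    bootstrap_ci,
    compare_accuracy_mcnemar,
    compare_bias_wilcoxon,
    compare_cohorts,
    p30_accuracy,
    paired_predictions,
    precision_iqr,
    table3_report,
)

from conftest import make_record


def paired_from_diffs(diffs, sgfr=100.0):
    """PairedPredictions with one model whose differences are given."""
    diffs = np.asarray(diffs, dtype=float)
    ref = np.full(len(diffs), sgfr)
    return PairedPredictions(sgfr=ref, egfr={"m": ref + diffs})


class TestBias:
    def test_perfect_predictions(self):
        assert bias(paired_from_diffs([0, 0, 0]), "m") == 0.0

    def test_constant_underestimate(self):
        assert bias(paired_from_diffs([-5, -5, -5]), "m") == -5.0

    def test_even_n_mean_of_middle_two(self):
        assert bias(paired_from_diffs([-10, 0, 4, 6]), "m") == 2.0

    def test_sign_convention_flip(self):
        diffs = [-10.0, 0.0, 4.0, 6.0]
        flipped = PairedPredictions(
            sgfr=np.full(4, 100.0),
            egfr={"m": 100.0 + np.array(diffs)},
            sign_convention="sgfr_minus_egfr",
        )
        assert bias(flipped, "m") == -2.0

    def test_unknown_model_keyerror(self):
        with pytest.raises(KeyError):
            bias(paired_from_diffs([1.0]), "nope")


class TestPrecision:
    def test_constant_differences_zero(self):
        assert precision_iqr(paired_from_diffs([3, 3, 3, 3]), "m") == 0.0

    def test_type7_linear_interpolation(self):
        assert precision_iqr(paired_from_diffs([1, 2, 3, 4]), "m") == 1.5

    def test_translation_invariance(self, rng):
        d = rng.normal(size=40)
        assert precision_iqr(paired_from_diffs(d + 7.5), "m") == pytest.approx(
            precision_iqr(paired_from_diffs(d), "m"), rel=1e-12)

    def test_single_record_raises(self):
        with pytest.raises(InsufficientDataError):
            precision_iqr(paired_from_diffs([1.0]), "m")


class TestP30:
    def test_boundary_inclusive_example(self):
        paired = PairedPredictions(sgfr=np.array([100.0, 100.0, 100.0]),
                                   egfr={"m": np.array([70.0, 100.0, 131.0])})
        assert p30_accuracy(paired, "m") == pytest.approx(100 * 2 / 3)

    def test_exact_30_percent_counts_as_within(self):
        paired = PairedPredictions(sgfr=np.array([100.0]), egfr={"m": np.array([130.0])})
        assert p30_accuracy(paired, "m") == 100.0

    def test_perfect_predictions(self):
        paired = paired_from_diffs(np.zeros(10))
        assert p30_accuracy(paired, "m") == 100.0

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            sgfr = rng.uniform(10, 150, n)
            egfr = sgfr * rng.uniform(0.4, 1.8, n)
            paired = PairedPredictions(sgfr=sgfr, egfr={"m": egfr})
            brute = 100.0 * (sum(abs(e - s) / s <= 0.30
                                 for e, s in zip(egfr, sgfr)) / n)
            assert p30_accuracy(paired, "m") == brute


class TestMetricInvariances:
    def test_permutation_invariance(self, rng):
        n = 101
        sgfr = rng.uniform(20, 140, n)
        egfr = sgfr * rng.uniform(0.6, 1.5, n)
        perm = rng.permutation(n)
        a = PairedPredictions(sgfr=sgfr, egfr={"m": egfr})
        b = PairedPredictions(sgfr=sgfr[perm], egfr={"m": egfr[perm]})
        assert bias(a, "m") == pytest.approx(bias(b, "m"), rel=1e-12)
        assert precision_iqr(a, "m") == pytest.approx(precision_iqr(b, "m"), rel=1e-12)
        assert p30_accuracy(a, "m") == p30_accuracy(b, "m")

    def test_median_iqr_against_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 50))
            d = rng.normal(0, 20, n)
            paired = paired_from_diffs(d)
            s = np.sort(d)
            brute_median = (s[(n - 1) // 2] + s[n // 2]) / 2.0

            def q(p):
                h = (n - 1) * p
                lo = int(math.floor(h))
                return s[lo] + (h - lo) * (s[min(lo + 1, n - 1)] - s[lo])

            assert bias(paired, "m") == pytest.approx(brute_median, rel=1e-12)
            assert precision_iqr(paired, "m") == pytest.approx(q(0.75) - q(0.25), rel=1e-9)


class TestBootstrap:
    def test_constant_differences_degenerate_ci(self):
        lo, hi = bootstrap_ci("bias", paired_from_diffs([4.0] * 20), "m", reps=200, seed=0)
        assert lo == hi == 4.0

    def test_single_rep(self):
        paired = paired_from_diffs([1.0, 2.0, 3.0])
        lo, hi = bootstrap_ci("bias", paired, "m", reps=1, seed=5)
        assert lo == hi

    def test_seed_reproducible(self, rng):
        paired = paired_from_diffs(rng.normal(0, 10, 80))
        assert bootstrap_ci("precision", paired, "m", reps=500, seed=9) == \
               bootstrap_ci("precision", paired, "m", reps=500, seed=9)

    def test_ci_brackets_point_estimate_large_n(self, rng):
        paired = paired_from_diffs(rng.normal(3, 10, 500))
        for metric, fn in (("bias", bias), ("precision", precision_iqr),
                           ("p30", p30_accuracy)):
            lo, hi = bootstrap_ci(metric, paired, "m", reps=1000, seed=3)
            assert lo <= fn(paired, "m") <= hi

    def test_generic_callable_path_matches_fast_path(self, rng):
        paired = paired_from_diffs(rng.normal(0, 5, 40))
        fast = bootstrap_ci("bias", paired, "m", reps=300, seed=7)
        slow = bootstrap_ci(bias, paired, "m", reps=300, seed=7)
        assert fast == pytest.approx(slow, rel=1e-12)


class TestWilcoxon:
    def test_identical_models_degenerate(self):
        sgfr = np.linspace(50, 120, 10)
        paired = PairedPredictions(sgfr=sgfr, egfr={"a": sgfr * 1.1, "b": sgfr * 1.1})
        res = compare_bias_wilcoxon(paired, "a", "b")
        assert res.degenerate and res.p_value == 1.0

    def test_six_positive_signs_exact(self):
        # model a uniformly worse by distinct margins: one-sided p = 1/2^6
        sgfr = np.full(6, 100.0)
        a = sgfr + np.array([5.0, 6, 7, 8, 9, 10])
        b = sgfr + np.array([1.0, 1.5, 2, 0.5, 2.5, 3])
        res = compare_bias_wilcoxon(PairedPredictions(sgfr=sgfr, egfr={"a": a, "b": b}),
                                    "a", "b")
        assert res.p_value == pytest.approx(2 * (1 / 2) ** 6)
        assert res.method == "wilcoxon-exact"

    def test_exact_matches_enumeration(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 11))
            sgfr = rng.uniform(50, 120, n)
            a = sgfr + rng.normal(2, 6, n)
            b = sgfr + rng.normal(0, 6, n)
            paired = PairedPredictions(sgfr=sgfr, egfr={"a": a, "b": b})
            res = compare_bias_wilcoxon(paired, "a", "b")
            d = np.abs(a - sgfr) - np.abs(b - sgfr)
            d = d[d != 0]
            ranks = stats.rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            dist = np.array([sum(rk for s, rk in zip(signs, ranks) if s)
                             for signs in itertools.product([0, 1], repeat=len(d))])
            p_enum = min(1.0, 2 * min((dist <= w).mean(), (dist >= w).mean()))
            assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_exact_and_asymptotic_agree_at_crossover(self, rng):
        n = 25
        for _ in range(5):
            sgfr = rng.uniform(40, 130, n)
            a = sgfr + rng.normal(3, 8, n)
            b = sgfr + rng.normal(0, 8, n)
            ea, eb = np.abs(a - sgfr), np.abs(b - sgfr)
            p_exact = stats.wilcoxon(ea, eb, zero_method="wilcox", method="exact").pvalue
            p_approx = stats.wilcoxon(ea, eb, zero_method="wilcox", method="approx",
                                      correction=True).pvalue
            assert abs(p_exact - p_approx) < 0.01


class TestMcNemar:
    def _paired_with_discordance(self, b, c, n_both=5):
        """b records where only model a is within 30%, c where only model b."""
        sgfr, ea, eb = [], [], []
        for _ in range(n_both):
            sgfr.append(100.0)
            ea.append(100.0)
            eb.append(100.0)
        for _ in range(b):
            sgfr.append(100.0)
            ea.append(100.0)   # within
            eb.append(200.0)   # off
        for _ in range(c):
            sgfr.append(100.0)
            ea.append(200.0)
            eb.append(100.0)
        return PairedPredictions(sgfr=np.array(sgfr),
                                 egfr={"a": np.array(ea), "b": np.array(eb)})

    def test_balanced_discordance_p1(self):
        res = compare_accuracy_mcnemar(self._paired_with_discordance(5, 5), "a", "b")
        assert res.p_value == 1.0 and res.method == "mcnemar-exact"

    def test_eight_zero_exact(self):
        res = compare_accuracy_mcnemar(self._paired_with_discordance(8, 0), "a", "b")
        assert res.p_value == pytest.approx(2 * (1 / 2) ** 8)  # 0.0078125

    def test_no_discordance_degenerate(self):
        res = compare_accuracy_mcnemar(self._paired_with_discordance(0, 0), "a", "b")
        assert res.degenerate and res.p_value == 1.0

    def test_exact_matches_binomial_tail_sum(self, rng):
        for _ in range(20):
            b = int(rng.integers(0, 14))
            c = int(rng.integers(0, 26 - b))
            if b + c == 0:
                continue
            res = compare_accuracy_mcnemar(self._paired_with_discordance(b, c), "a", "b")
            k, n = min(b, c), b + c
            tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
            assert res.p_value == pytest.approx(min(1.0, 2 * tail), abs=1e-12)

    def test_exact_and_chi2_agree_at_crossover(self):
        for b, c in ((16, 9), (20, 5), (13, 12)):
            exact = compare_accuracy_mcnemar(self._paired_with_discordance(b, c),
                                             "a", "b").p_value
            chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
            p_chi2 = stats.chi2.sf(chi2, 1)
            assert abs(exact - p_chi2) < 0.01


class TestCompareCohorts:
    def test_identical_groups_mann_whitney_p1(self):
        recs = [make_record(i, "male", 60, s) for i, s in enumerate([0.7, 0.9, 1.2])]
        other = [make_record(i + 10, "male", 60, s) for i, s in enumerate([0.7, 0.9, 1.2])]
        res = compare_cohorts(Cohort(records=recs), Cohort(records=other), "scr")
        assert res.p_value == 1.0
        assert res.method == "mann-whitney-exact"

    def test_mann_whitney_exact_equals_enumeration(self):
        a_vals, b_vals = [0.5, 1.4, 1.5], [0.8, 0.9, 2.7]
        recs_a = [make_record(i, "male", 60, v) for i, v in enumerate(a_vals)]
        recs_b = [make_record(i + 5, "male", 60, v) for i, v in enumerate(b_vals)]
        res = compare_cohorts(Cohort(records=recs_a), Cohort(records=recs_b), "scr")
        pooled = np.array(a_vals + b_vals)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        us = []
        for combo in itertools.combinations(range(6), 3):
            us.append(ranks[list(combo)].sum() - 3 * 4 / 2)
        us = np.array(us)
        p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_t_test_type_i_error_rate(self, rng):
        # equal-mean normals: rejection rate at alpha=0.05 within 3 SE of 5%
        reps, n = 1000, 20
        a = rng.normal(0, 1, (reps, n))
        b = rng.normal(0, 1, (reps, n))
        pvals = stats.ttest_ind(a, b, axis=1).pvalue
        rate = np.mean(pvals < 0.05)
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se

    def test_variable_routing(self):
        rng = np.random.default_rng(0)
        recs_a = [make_record(i, "male", float(rng.uniform(40, 80)), 1.0, sgfr=80.0)
                  for i in range(30)]
        recs_b = [make_record(i + 100, "male", float(rng.uniform(40, 80)), 1.0, sgfr=85.0)
                  for i in range(30)]
        assert compare_cohorts(Cohort(records=recs_a), Cohort(records=recs_b),
                               "age").method == "t-test"
        assert compare_cohorts(Cohort(records=recs_a), Cohort(records=recs_b),
                               "scr").method.startswith("mann-whitney")

    def test_missing_variable_raises(self):
        recs = [make_record(i, "male", 60, 1.0) for i in range(3)]
        with pytest.raises(InsufficientDataError):
            compare_cohorts(Cohort(records=recs), Cohort(records=recs[:2]), "bmi")


class TestTable3Report:
    def test_perfect_model_against_itself(self):
        sgfr = np.linspace(40, 120, 30)
        paired = PairedPredictions(sgfr=sgfr, egfr={"perfect": sgfr.copy()})
        (report,) = table3_report(paired, reference="perfect", reps=100, seed=0)
        assert report.bias == 0.0
        assert report.precision == 0.0
        assert report.accuracy_p30 == 100.0
        assert report.p_bias_vs_reference == 1.0
        assert report.p_accuracy_vs_reference == 1.0

    def test_row_count_and_composition(self, rng):
        sgfr = rng.uniform(30, 140, 60)
        models = {f"m{k}": sgfr * rng.uniform(0.7, 1.3, 60) for k in range(4)}
        paired = PairedPredictions(sgfr=sgfr, egfr=models)
        reports = table3_report(paired, reference="m0", reps=50, seed=1)
        assert len(reports) == 4
        for rep in reports:
            assert rep.bias == pytest.approx(bias(paired, rep.model), rel=1e-12)
            assert rep.precision == pytest.approx(precision_iqr(paired, rep.model), rel=1e-12)
            assert rep.accuracy_p30 == pytest.approx(p30_accuracy(paired, rep.model), rel=1e-12)
            assert rep.bias_ci[0] <= rep.bias <= rep.bias_ci[1]


class TestPairedConstruction:
    def test_records_without_sgfr_rejected(self):
        recs = [make_record(0, "male", 60, 0.9)]
        with pytest.raises(ValidationError):
            paired_predictions(recs, {"m": lambda r: 80.0})

    def test_callable_and_array_models(self, small_cohort):
        paired = paired_predictions(
            small_cohort,
            {"const": lambda r: 80.0, "given": [90, 95, 55, 105, 35, 60]},
        )
        assert np.all(paired.egfr["const"] == 80.0)
        assert bias(paired, "given") == 0.0
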