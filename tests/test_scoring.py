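"""Signature scoring, median split, Kaplan-Meier, log-rank, Cox,
t-test, BH, tumor volume."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from krassig import (
    bh_adjust,
    cell_enrichment_score,
    cohort_signature_score,
    cox_hazard_ratio,
    ellipsoid_volume,
    km_estimate,
    logrank_test,
    median_split,
    two_group_t,
)
from krassig.scoring import _cox_loglik

from conftest import build_matrix


class TestCellEnrichment:
    def make(self):
        counts = np.array(
            [[0, 1, 3], [0, 2, 0], [0, 0, 5], [0, 4, 1]]
        )  # cells detect 0, 3, 3 of 4 genes
        return build_matrix(counts)

    def test_zero_and_partial_and_full_detection(self):
        m = self.make()
        scores = cell_enrichment_score(m, m.gene_ids)
        assert scores.enrichment.tolist() == [0.0, 0.75, 0.75]

    def test_full_detection_scores_one(self):
        m = build_matrix(np.ones((21, 1)))
        scores = cell_enrichment_score(m, m.gene_ids)
        assert scores.enrichment[0] == 1.0

    def test_half_detection(self):
        counts = np.zeros((20, 1)); counts[:10] = 2
        m = build_matrix(counts)
        assert cell_enrichment_score(m, m.gene_ids).enrichment[0] == 0.5

    def test_missing_genes_excluded_with_warning(self):
        m = self.make()
        with pytest.warns(UserWarning, match="absent"):
            scores = cell_enrichment_score(m, m.gene_ids + ["NOPE"])
        assert scores.n_signature[0] == 4

    def test_all_genes_absent_is_error(self):
        with pytest.raises(ValueError):
            cell_enrichment_score(self.make(), ["NOPE"])

    def test_monotone_in_detected_set(self):
        rng = np.random.default_rng(0)
        m = build_matrix(rng.poisson(0.5, size=(30, 40)))
        sub = cell_enrichment_score(m, m.gene_ids[:10])
        # adding detections (larger gene set cannot decrease the count)
        full = cell_enrichment_score(m, m.gene_ids)
        assert (full.n_detected >= sub.n_detected).all()


class TestCohortScore:
    def test_hand_z_scores_two_samples(self):
        expr = pd.DataFrame({"g1": [0.0, 2.0]}, index=["s1", "s2"])
        score = cohort_signature_score(expr, ["g1"], [])
        # sample sd = sqrt(2): z = -/+ 1/sqrt(2)
        np.testing.assert_allclose(score, [-0.70710678, 0.70710678])

    def test_swap_up_down_negates(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 4)),
                            columns=["a", "b", "c", "d"])
        s1 = cohort_signature_score(expr, ["a", "b"], ["c", "d"])
        s2 = cohort_signature_score(expr, ["c", "d"], ["a", "b"])
        np.testing.assert_allclose(s1, -s2, atol=1e-12)

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(25, 6)),
                            columns=[f"g{i}" for i in range(6)])
        score = cohort_signature_score(expr, ["g0", "g1"], ["g2", "g3"])
        assert abs(score.sum()) < 1e-9

    def test_invariance_to_per_gene_affine_rescaling(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(15, 3)), columns=["a", "b", "c"])
        shifted = expr.copy()
        shifted["a"] = 5.0 + 3.0 * shifted["a"]  # affine per gene
        s1 = cohort_signature_score(expr, ["a", "b"], ["c"])
        s2 = cohort_signature_score(shifted, ["a", "b"], ["c"])
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_zero_variance_gene_excluded(self):
        expr = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="excluded"):
            score = cohort_signature_score(expr, ["a", "b"], [])
        expected = cohort_signature_score(expr, ["b"], [])
        np.testing.assert_allclose(score, expected)

    def test_single_sample_rejected(self):
        expr = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            cohort_signature_score(expr, ["a"], [])


class TestMedianSplit:
    def test_median_element_goes_low(self):
        group = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert group.tolist() == ["low", "low", "low", "high", "high"]

    def test_445_distinct_scores_split_223_222(self):
        rng = np.random.default_rng(0)
        scores = rng.permutation(np.linspace(-2, 2, 445))
        group = median_split(scores)
        assert (group == "low").sum() == 223
        assert (group == "high").sum() == 222

    def test_all_equal_everything_low_with_warning(self):
        with pytest.warns(UserWarning):
            group = median_split(np.zeros(6))
        assert (group == "low").all()


class TestKaplanMeier:
    def test_all_events_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_drops_risk_set(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, False, True])
        # S(1) = 2/3; at t=3 one at risk, one death: S(3) = 0
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.times.tolist() == [1.0, 3.0]

    def test_no_events_flat_curve(self):
        km = km_estimate([1.0, 2.0], [False, False])
        assert km(0.5) == 1.0 and km(5.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1.0, 200)
        km = km_estimate(t, np.ones(200, dtype=bool))
        for q in (0.25, 0.5, 0.75):
            x = np.quantile(t, q)
            assert km(x) == pytest.approx((t > x).mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 150)
        e = rng.random(150) < 0.7
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for x in km.times:
            assert km(x) == pytest.approx(
                float(kmf.predict(x)), abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = ["a"] * 3 + ["b"] * 3
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_hand_computed_o_minus_e(self):
        # groups A={1,2}, B={3,4}, all events
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=bool)
        g = np.array(["A", "A", "B", "B"])
        # event tables: t=1: n=4,nB=2,d=1 -> E=0.5,V=0.25
        #               t=2: n=3,nB=2    -> E=2/3,V=2/9
        #               t=3: n=2,nB=2    -> E=1,V=0
        #               t=4: n=1,nB=1    -> E=1,V=0
        # O_B=2, E_B=0.5+2/3+1+1=3.1667, V=0.25+2/9
        chi2, p = logrank_test(t, e, g)
        expected = (2 - 19 / 6) ** 2 / (0.25 + 2 / 9)
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_p_decreases_with_separation(self):
        rng = np.random.default_rng(3)
        base = rng.exponential(1.0, 60)
        e = np.ones(120, dtype=bool)
        g = np.array(["a"] * 60 + ["b"] * 60)
        last_p = 1.1
        for scale in (1.0, 1.5, 2.5, 4.0):
            t = np.concatenate([base, scale * rng.exponential(1.0, 60)])
            _, p = logrank_test(t, e, g)
            assert p < last_p
            last_p = p

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        t = rng.exponential(1.0, 100)
        e = rng.random(100) < 0.8
        g = np.where(rng.random(100) < 0.5, "a", "b")
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == "a"], t[g == "b"], e[g == "a"], e[g == "b"])
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [True, True], ["a", "a"])


class TestCox:
    def test_identical_groups_hr_one(self):
        t = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        e = np.ones(8, dtype=bool)
        g = np.repeat([0, 1], 4)
        assert cox_hazard_ratio(t, e, g) == pytest.approx(1.0, abs=1e-6)

    def test_parametric_recovery_true_hr_two(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.1 * 2.0**x))
        censor = rng.random(n) < 0.2
        obs = np.where(censor, rng.uniform(0, t), t)
        hr = cox_hazard_ratio(obs, ~censor, x)
        assert 1.8 <= hr <= 2.2

    def test_score_equation_satisfied_at_estimate(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1.0, 300)
        e = rng.random(300) < 0.8
        x = rng.integers(0, 2, 300).astype(float)
        hr = cox_hazard_ratio(t, e, x)
        _, score, _ = _cox_loglik(math.log(hr), t, e, x)
        assert abs(score) < 1e-6

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        t = rng.exponential(1.0, 200)
        e = rng.random(200) < 0.75
        x = rng.integers(0, 2, 200)
        hr = cox_hazard_ratio(t, e, x)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert hr == pytest.approx(float(np.exp(ref.params_.x)), rel=1e-5)

    def test_group_without_events_rejected(self):
        with pytest.raises(ValueError):
            cox_hazard_ratio([1.0, 2.0], [True, False], [0, 1])

    def test_complete_separation_capped_with_warning(self):
        t = np.concatenate([np.arange(1, 21), np.arange(100, 120)])
        e = np.ones(40, dtype=bool)
        x = np.repeat([1, 0], 20)  # group 1 dies strictly first
        with pytest.warns(UserWarning, match="separation"):
            hr = cox_hazard_ratio(t, e, x)
        assert np.isfinite(hr)


class TestTwoGroupT:
    def test_identical_groups(self):
        t, p = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_welch(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        # equal variances s^2=1, n=3: t = -3 / sqrt(2/3)
        expected_t = -3.0 / math.sqrt(2.0 / 3.0)
        t, p = two_group_t(a, b)
        assert t == pytest.approx(expected_t, rel=1e-12)

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        t1, p1 = two_group_t(a, b)
        t2, p2 = two_group_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_constant_equal_groups_p_one(self):
        t, p = two_group_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_sort_cummin_oracle(self, p_list):
        p = np.asarray(p_list)
        order = np.argsort(p, kind="stable")
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
        brute = np.empty(m)
        brute[order] = adj
        np.testing.assert_allclose(bh_adjust(p), brute, rtol=1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEllipsoidVolume:
    @pytest.mark.parametrize(
        "length,width,expected", [(2.0, 1.0, 1.0), (0.0, 0.0, 0.0), (1.5, 1.0, 0.75)]
    )
    def test_formula(self, length, width, expected):
        assert ellipsoid_volume(length, width) == pytest.approx(expected)

    def test_swapped_inputs_corrected_with_warning(self):
        with pytest.warns(UserWarning, match="swap"):
            v = ellipsoid_volume(1.0, 2.0)
        assert v == pytest.approx(1.0)
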