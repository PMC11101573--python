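import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import pairwise_auc
from surrogene.biomarker import (
    cox_univariate,
    evaluate_split,
    km_estimate,
    logrank_test,
    long_term_fraction,
    median_split,
    orr,
    responder_labels,
    roc_auc,
)


class TestMedianSplit:
    def _split(self, scores, cohorts=None):
        s = pd.Series(scores, index=[f"p{i}" for i in range(len(scores))], dtype=float)
        c = pd.Series(cohorts or ["c"] * len(scores), index=s.index)
        return {a.patient_id: a.group for a in median_split(s, c)}

    def test_even_split(self):
        groups = self._split([1, 2, 3, 4])
        assert groups == {"p0": "low", "p1": "low", "p2": "high", "p3": "high"}

    def test_ties_at_median_go_low(self):
        groups = self._split([1, 2, 2, 3])
        assert groups == {"p0": "low", "p1": "low", "p2": "low", "p3": "high"}

    def test_pooled_equals_concatenation_of_cohort_splits(self):
        scores = [1, 2, 3, 4, 10, 20, 30, 40]
        cohorts = ["a"] * 4 + ["b"] * 4
        pooled = self._split(scores, cohorts)
        alone_a = self._split(scores[:4])
        alone_b = self._split(scores[4:])
        assert [pooled[f"p{i}"] for i in range(4)] == [alone_a[f"p{i}"] for i in range(4)]
        assert [pooled[f"p{i+4}"] for i in range(4)] == [alone_b[f"p{i}"] for i in range(4)]

    def test_small_cohort_is_error(self):
        with pytest.raises(ValueError, match="need >= 2"):
            self._split([1.0])

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_high_never_larger_than_low(self, scores):
        groups = list(self._split(scores).values())
        n_high = groups.count("high")
        n_low = groups.count("low")
        assert n_high <= n_low


class TestResponseMetrics:
    @pytest.mark.parametrize(
        "labels,expected",
        [(["CR", "PR", "SD", "PD"], 0.5), (["PD", "PD"], 0.0), (["CR", "NA"], 1.0)],
    )
    def test_orr(self, labels, expected):
        assert orr(labels) == pytest.approx(expected)

    def test_orr_undefined_when_all_na(self):
        assert np.isnan(orr(["NA", "NA"]))

    @pytest.mark.parametrize(
        "recist,duration,expected",
        [
            ("CR", np.nan, True),
            ("PR", np.nan, True),
            ("SD", 7.0, True),
            ("SD", 6.0, False),  # strictly more than 6 months
            ("PD", 3.0, False),
        ],
    )
    def test_responder_rules(self, recist, duration, expected):
        out = responder_labels([recist], [duration])
        assert out.iloc[0] == expected

    def test_sd_without_duration_is_unadjudicated(self, caplog):
        with caplog.at_level("WARNING"):
            out = responder_labels(["SD"], [np.nan])
        assert pd.isna(out.iloc[0])

    def test_orr_never_exceeds_responder_rate(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 30)
            recist = rng.choice(["CR", "PR", "SD", "PD"], size=n)
            dur = rng.exponential(6, size=n)
            resp = responder_labels(recist, dur).dropna().astype(bool)
            assert orr(recist) <= resp.mean() + 1e-12

    @pytest.mark.parametrize(
        "times,events,expected",
        [
            ([40.0, 30.0], [1, 1], 0.5),
            ([40.0], [0], 1.0),  # censored after 36 months still evaluable
        ],
    )
    def test_long_term_fraction(self, times, events, expected):
        assert long_term_fraction(times, events) == pytest.approx(expected)

    def test_early_censored_excluded_as_unevaluable(self):
        assert np.isnan(long_term_fraction([20.0], [0]))
        # naive reading keeps them in the denominator
        assert long_term_fraction([20.0, 40.0], [0, 1], include_early_censored=True) == 0.5


class TestKaplanMeier:
    def test_closed_form_two_events(self):
        times, surv = km_estimate([1.0, 2.0], [1, 1])
        s = dict(zip(times, surv))
        assert s[1.0] == pytest.approx(0.5)
        assert s[2.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        _, surv = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        np.testing.assert_allclose(surv, 1.0)

    def test_monotone_nonincreasing_from_one(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        times, surv = km_estimate(t, e)
        assert surv[0] == pytest.approx(1.0)
        assert np.all(np.diff(surv) <= 1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        chi2, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_hand_tabulated_golden_value(self):
        """Risk-set tabulation for A=[(1,1),(2,1)], B=[(3,1),(4,1)]:
        O_A - E_A = 2 - 5/6, V = 1/4 + 2/9 -> chi2 = 49/17."""
        chi2, p = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(49 / 17, 1), rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(5, 20), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_events_sentinel(self):
        chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(chi2) and np.isnan(p)


class TestCox:
    def test_sign_flips_with_negated_covariate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        t = rng.exponential(1 / (0.05 * np.exp(-0.5 * x)))
        e = np.ones(300, dtype=int)
        fit = cox_univariate(x, t, e)
        flipped = cox_univariate(-x, t, e)
        assert fit.cox_beta == pytest.approx(-flipped.cox_beta, rel=1e-6)

    def test_hr_and_ci_consistency(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        t = rng.exponential(1 / (0.05 * np.exp(-0.6 * x)))
        fit = cox_univariate(x, t, np.ones(200, dtype=int))
        assert fit.hr == pytest.approx(np.exp(fit.cox_beta), rel=1e-12)
        assert fit.hr_ci_low <= fit.hr <= fit.hr_ci_high

    def test_constant_covariate_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            cox_univariate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="event"):
            cox_univariate([1.0, 2.0], [1.0, 2.0], [0, 0])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [False, False, False, True, True]) == 1.0

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.5
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_is_nan(self):
        assert np.isnan(roc_auc([1.0, 2.0], [True, True]))


class TestEvaluateSplit:
    def test_full_evaluation_on_synthetic_study(self, default_study):
        expr, _, clinical, truth = default_study
        g = pd.Series(
            np.log2(expr.gene_row(truth.surrogate_gene_id) + 1), index=expr.sample_ids
        )
        cf = clinical.frame.set_index("patient_id")
        assigns = median_split(g, cf.loc[g.index, "cohort_id"])
        out = evaluate_split(clinical.frame, assigns)
        fit = out["fit"]
        assert 0 < fit.hr < np.inf
        assert fit.hr_ci_low <= fit.hr <= fit.hr_ci_high
        assert 0 <= out["response"]["high"].orr <= 1
        for g_ in ("high", "low"):
            s = out["response"][g_]
            assert s.orr <= s.responder_rate + 1e-12
            times, surv = out["km"][g_]
            assert np.all(np.diff(surv) <= 1e-12)
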