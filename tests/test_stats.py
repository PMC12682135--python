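"""First-principles survival/statistics layer versus independent oracles.

Oracles: hand-computed risk tables, exhaustive rank enumeration, permutation
resampling, and the established implementations in lifelines / scipy.
"""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from ctdna_kinetics.dynamics import Trajectory
from ctdna_kinetics.errors import DataError, NotEvaluableError
from ctdna_kinetics.stats import (
    ClinicalCourse,
    baseline_status,
    km_estimate,
    landmark_status,
    logrank_test,
    pearson_correlation,
    stratified_survival,
    survival_time,
    wilcoxon_rank_sum,
)

from util import make_sample


def traj(seq, days, pid="P1"):
    return Trajectory(
        pid, "GNA11_Q209L", tuple(make_sample(d, s) for d, s in zip(days, seq))
    )


def course(pid="P1", prog=None, death=None, fup=600.0):
    return ClinicalCourse(
        patient_id=pid, last_followup_day=fup, progression_day=prog, death_day=death
    )


class TestBaselineStatus:
    def test_latest_pretreatment_sample_wins(self):
        t = traj("LU", [-21.0, -3.0])
        assert baseline_status(t) is False
        t = traj("UL", [-21.0, -3.0])
        assert baseline_status(t) is True

    def test_missing_baseline_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            baseline_status(traj("LL", [10.0, 30.0]))


class TestLandmarkStatus:
    def test_single_detected_sample_positive(self):
        st_ = landmark_status(traj("UL", [-7, 90.0]), course(), (60, 120))
        assert st_.status == "POSITIVE"

    def test_empty_window_not_evaluable(self):
        st_ = landmark_status(traj("UL", [-7, 30.0]), course(), (60, 120))
        assert st_.status == "NOT_EVALUABLE"
        assert st_.n_samples_in_window == 0

    def test_post_progression_samples_excluded(self):
        # detected sample at day 90 but progression at day 80: excluded
        st_ = landmark_status(traj("UL", [-7, 90.0]), course(prog=80.0), (60, 120))
        assert st_.status == "NOT_EVALUABLE"

    def test_all_undetected_negative(self):
        st_ = landmark_status(traj("UUU", [-7, 70.0, 110.0]), course(), (60, 120))
        assert st_.status == "NEGATIVE"
        assert st_.n_samples_in_window == 2

    def test_adding_detected_sample_monotone(self):
        neg = landmark_status(traj("UU", [-7, 70.0]), course(), (60, 120))
        pos = landmark_status(traj("UUL", [-7, 70.0, 100.0]), course(), (60, 120))
        assert (neg.status, pos.status) == ("NEGATIVE", "POSITIVE")


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([2, 4, 6, 8], [True] * 4)
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 4  # smallest time with S <= 0.5

    def test_all_censored(self):
        curve = km_estimate([5, 7], [False, False])
        assert curve.event_times.size == 0
        assert curve.median is None
        assert curve.survival_at(100.0) == 1.0

    def test_single_subject_event(self):
        curve = km_estimate([3.0], [True])
        assert curve.survival_at(3.0) == 0.0
        assert curve.survival_at(2.9) == 1.0

    @given(
        times=st.lists(st.floats(0, 100), min_size=1, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_no_censoring_equals_empirical_survival(self, times):
        curve = km_estimate(times, [True] * len(times))
        t = np.asarray(times)
        for q in np.unique(t):
            assert curve.survival_at(q) == pytest.approx(np.mean(t > q))

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.7
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in curve.event_times:
            assert curve.survival_at(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0])
            )
        assert curve.median == pytest.approx(float(kmf.median_survival_time_))


class TestLogRank:
    def test_identical_groups_null(self):
        g = ([1.0, 2.0, 3.0], [True, True, True])
        chi2, p = logrank_test(g, g)
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_risk_table_oracle(self):
        # groups {1,2,3} and {4,5,6}, all events: accumulate O-E and the
        # hypergeometric variance over the risk table by hand
        ga = ([1.0, 2.0, 3.0], [True] * 3)
        gb = ([4.0, 5.0, 6.0], [True] * 3)
        o_minus_e = 0.0
        var = 0.0
        times = [1, 2, 3, 4, 5, 6]
        for i, t in enumerate(times):
            n = 6 - i
            n_a = max(3 - i, 0)
            d_a = 1 if t <= 3 else 0
            o_minus_e += d_a - n_a / n
            if n > 1:
                var += (n_a / n) * (1 - n_a / n)  # d=1, (n-d)/(n-1)=1
        chi2, p = logrank_test(ga, gb)
        assert chi2 == pytest.approx(o_minus_e**2 / var)
        res = ll_logrank(ga[0], gb[0], event_observed_A=ga[1], event_observed_B=gb[1])
        assert chi2 == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(3)
        ga = (rng.exponential(5, 8), rng.random(8) < 0.8)
        gb = (rng.exponential(9, 6), rng.random(6) < 0.8)
        assert logrank_test(ga, gb)[0] == pytest.approx(logrank_test(gb, ga)[0])

    def test_against_permutation_oracle(self):
        # small-sample p-value approximates the permutation null probability
        times = np.array([1.0, 3.0, 4.0, 6.0, 7.0, 9.0, 11.0, 12.0])
        events = np.array([True, True, False, True, True, True, False, True])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2_obs, p_asym = logrank_test(
            (times[labels == 0], events[labels == 0]),
            (times[labels == 1], events[labels == 1]),
        )
        perm_stats = []
        for idx in itertools.combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(idx)] = True
            chi2, _ = logrank_test(
                (times[mask], events[mask]), (times[~mask], events[~mask])
            )
            perm_stats.append(chi2)
        p_perm = np.mean(np.asarray(perm_stats) >= chi2_obs - 1e-12)
        # asymptotic chi-square vs exhaustive permutation: small-n slack
        assert p_asym == pytest.approx(p_perm, abs=0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            logrank_test(([], []), ([1.0], [True]))


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_correlation(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        r, _ = pearson_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_five_point_oracle(self):
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [2.0, 1.0, 5.0, 3.0, 8.0]
        # direct covariance formula
        mx, my = np.mean(x), np.mean(y)
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(num / den)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert (r, p) == (pytest.approx(r_sp), pytest.approx(p_sp))

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = wilcoxon_rank_sum(x, list(x))
        assert p == 1.0

    def test_extreme_separation_exact_enumeration(self):
        # {1,2} vs {3,4}: only 1 of C(4,2)=6 assignments is as extreme,
        # two-sided p = 2/6
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1.2, 3.4, 2.2, 5.0], [0.5, 4.4, 6.1, 2.9, 3.3]),
            ([1.0, 1.0, 2.0], [2.0, 3.0, 3.0]),  # ties across groups
        ],
    )
    def test_exact_branch_matches_scipy(self, x, y):
        w, p = wilcoxon_rank_sum(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert w == pytest.approx(res.statistic + len(x) * (len(x) + 1) / 2)
        assert p == pytest.approx(res.pvalue, abs=1e-9)

    def test_branches_agree_at_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            _, p_exact = wilcoxon_rank_sum(x, y, exact_max_n=12)
            _, p_approx = wilcoxon_rank_sum(x, y, exact_max_n=0)
            assert p_exact == pytest.approx(p_approx, abs=0.02)

    @given(
        x=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
        y=st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=6),
    )
    @settings(max_examples=60, deadline=None)
    def test_p_in_unit_interval(self, x, y):
        _, p = wilcoxon_rank_sum(x, y)
        assert 0.0 <= p <= 1.0


class TestStratifiedSurvival:
    def _cohort(self):
        # negatives never progress; positives all progress early
        cohort = []
        for i in range(4):
            cohort.append(
                (
                    traj("UU", [-7, 90.0], pid=f"N{i}"),
                    course(pid=f"N{i}", fup=600.0),
                )
            )
        for i in range(4):
            cohort.append(
                (
                    traj("LL", [-7, 90.0], pid=f"P{i}"),
                    course(pid=f"P{i}", prog=100.0 + i, death=200.0 + i, fup=600.0),
                )
            )
        return cohort

    def test_extreme_separation_medians(self):
        res = stratified_survival(self._cohort(), "landmark", "PFS")
        assert res.median_negative_days is None  # never reached
        # events at 100..103: S drops to 0.5 at the second event time
        assert res.median_positive_days == pytest.approx(101.0)
        assert res.n_negative == res.n_positive == 4

    def test_pfs_event_is_first_of_progression_or_death(self):
        c = course(prog=100.0, death=150.0)
        assert survival_time(c, "PFS") == (100.0, True)
        assert survival_time(c, "OS") == (150.0, True)
        c2 = course(fup=300.0)
        assert survival_time(c2, "PFS") == (300.0, False)

    def test_not_evaluable_patients_dropped(self):
        cohort = self._cohort()
        # a patient with no sample in window joins but is dropped
        cohort.append(
            (traj("UL", [-7, 30.0], pid="X"), course(pid="X", fup=600.0))
        )
        res = stratified_survival(cohort, "landmark", "PFS")
        assert res.n_negative + res.n_positive == 8

    def test_single_arm_rejected(self):
        cohort = [c for c in self._cohort() if c[0].patient_id.startswith("N")]
        with pytest.raises(DataError):
            stratified_survival(cohort, "landmark", "PFS")
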