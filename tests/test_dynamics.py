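"""Trajectory classifier versus an independently written rule-table oracle."""

import dataclasses
import itertools

import pytest

from ctdna_kinetics.dynamics import (
    Confirmation,
    ProgressionCategory,
    Trajectory,
    TransitionKind,
    classify_trajectory,
    compare_pair,
    confirm_increase,
    relate_to_progression,
    sankey_counts,
)
from ctdna_kinetics.errors import DataError, OrderingError, UsageError
from ctdna_kinetics.stats import ClinicalCourse

from util import (
    STATES,
    make_sample,
    oracle_events,
    oracle_relation,
)

# days for length-4 sequences: baseline then three on-treatment draws
DAYS = [-7.0, 30.0, 60.0, 90.0]


def traj_from(seq: str, days=None) -> Trajectory:
    days = days or DAYS[: len(seq)]
    return Trajectory(
        "P1", "GNA11_Q209L", tuple(make_sample(d, s) for d, s in zip(days, seq))
    )


def course(pid="P1", prog=None, death=None, fup=400.0) -> ClinicalCourse:
    return ClinicalCourse(
        patient_id=pid,
        last_followup_day=fup,
        progression_day=prog,
        death_day=death,
    )


class TestComparePair:
    def test_detectable_to_undetectable_is_clearance(self):
        ev = compare_pair(make_sample(0, "L"), make_sample(30, "U"))
        assert ev.kind is TransitionKind.CLEARANCE

    def test_redetection_is_increase_regardless_of_level(self):
        # detection after an undetectable sample counts as increase even at
        # low MAF
        ev = compare_pair(make_sample(0, "U"), make_sample(30, "L"))
        assert ev.kind is TransitionKind.INCREASE

    def test_overlapping_cis_are_stable(self):
        # prev CI [1.0, 2.0], curr CI [1.5, 3.0]: neither a significant rise
        # nor a significant fall
        a = dataclasses.replace(
            make_sample(0, "L"), maf_pct=1.5, maf_ci_low=1.0, maf_ci_high=2.0
        )
        b = dataclasses.replace(
            make_sample(30, "L"), maf_pct=2.0, maf_ci_low=1.5, maf_ci_high=3.0
        )
        ev = compare_pair(a, b)
        assert ev.kind is TransitionKind.STABLE

    def test_non_increasing_days_rejected(self):
        with pytest.raises(OrderingError):
            compare_pair(make_sample(30, "L"), make_sample(30, "H"))


class TestRuleTableOracle:
    """Exhaustive enumeration of all symbolic trajectories of length <= 4."""

    @pytest.mark.parametrize("length", [1, 2, 3, 4])
    def test_events_match_oracle(self, length):
        for seq in itertools.product(STATES, repeat=length):
            seq = "".join(seq)
            summary = classify_trajectory(traj_from(seq))
            got = [(e.kind.value, e.confirmed.value) for e in summary.events]
            assert got == oracle_events(seq), f"sequence {seq}"

    @pytest.mark.parametrize("length", [2, 3, 4])
    def test_relations_match_oracle(self, length):
        # progression placed between every pair of days, on a sample day,
        # after follow-up, and absent
        for seq in itertools.product(STATES, repeat=length):
            seq = "".join(seq)
            days = DAYS[:length]
            prog_choices = [None] + [d + 15 for d in days if d + 15 > 0] + [
                d for d in days if d > 0
            ]
            for prog in prog_choices:
                rel = relate_to_progression(traj_from(seq), course(prog=prog))
                cat, lead = oracle_relation(seq, days, prog)
                assert rel.category.value == cat, f"{seq} prog={prog}"
                if lead is None:
                    assert rel.lead_time_days is None
                else:
                    assert rel.lead_time_days == pytest.approx(lead)

    def test_summary_flags_only_post_treatment(self):
        # clearance between two pre-treatment samples must not set the flag
        t = traj_from("LU", days=[-14.0, -7.0])
        s = classify_trajectory(t)
        assert s.events[0].kind is TransitionKind.CLEARANCE
        assert not s.any_clearance

    def test_clearance_increase_symmetry(self):
        # swapping detection states of a pair swaps clearance and increase
        ev1 = compare_pair(make_sample(0, "L"), make_sample(30, "U"))
        ev2 = compare_pair(make_sample(0, "U"), make_sample(30, "L"))
        assert ev1.kind is TransitionKind.CLEARANCE
        assert ev2.kind is TransitionKind.INCREASE


class TestConfirmIncrease:
    def test_followed_by_stable_positive_confirms(self):
        # L -> H increase followed by H (overlapping CI with itself): confirmed
        t = traj_from("LHH")
        assert confirm_increase(t, 0) is Confirmation.CONFIRMED

    def test_final_sample_increase_unconfirmed(self):
        t = traj_from("UH")
        assert confirm_increase(t, 0) is Confirmation.UNCONFIRMED

    def test_followed_by_clearance_unconfirmed(self):
        # early increase then clearance stays unconfirmed
        t = traj_from("UHU")
        assert confirm_increase(t, 0) is Confirmation.UNCONFIRMED

    def test_followed_by_significant_drop_unconfirmed(self):
        t = traj_from("LHL")  # follow-up H -> L is a significant decrease
        assert confirm_increase(t, 0) is Confirmation.UNCONFIRMED

    def test_not_an_increase_is_usage_error(self):
        with pytest.raises(UsageError):
            confirm_increase(traj_from("LL"), 0)
        with pytest.raises(UsageError):
            confirm_increase(traj_from("LH"), 5)


class TestRelateToProgression:
    def test_lead_time_arithmetic(self):
        t = traj_from("UH", days=[-7.0, 100.0])
        rel = relate_to_progression(t, course(prog=180.0, death=200.0))
        assert rel.category is ProgressionCategory.INCREASE_BEFORE_PROGRESSION
        assert rel.lead_time_days == pytest.approx(80.0)

    def test_increase_on_progression_day_is_at_progression(self):
        t = traj_from("UH", days=[-7.0, 180.0])
        rel = relate_to_progression(t, course(prog=180.0, death=200.0))
        assert rel.category is ProgressionCategory.INCREASE_AT_OR_AFTER_PROGRESSION

    def test_no_increase_with_progression(self):
        rel = relate_to_progression(traj_from("LLL"), course(prog=100.0, death=150.0))
        assert rel.category is ProgressionCategory.NO_INCREASE
        assert rel.lead_time_days is None

    def test_progression_before_treatment_rejected(self):
        with pytest.raises(DataError):
            relate_to_progression(traj_from("LL"), course(prog=-5.0, fup=400.0))


class TestSankeyCounts:
    def test_empty_cohort_all_zero(self):
        tab = sankey_counts([])
        assert tab["n"].sum() == 0

    def test_counts_partition_the_cohort(self):
        # constructed cohort: 3 progressors with increase before progression,
        # 1 progressor with increase at progression, 2 progressors without
        # increase, 1 non-progressor with increase, 2 clean non-progressors
        cohort = []
        k = 0

        def add(seq, days, prog):
            nonlocal k
            k += 1
            t = Trajectory(
                f"P{k}", "GNA11_Q209L",
                tuple(make_sample(d, s) for d, s in zip(days, seq)),
            )
            cohort.append((t, course(pid=f"P{k}", prog=prog)))

        for _ in range(3):
            add("UH", [-7, 50], prog=120.0)
        add("UH", [-7, 50], prog=50.0)
        for _ in range(2):
            add("LL", [-7, 50], prog=90.0)
        add("UH", [-7, 50], prog=None)
        for _ in range(2):
            add("UU", [-7, 50], prog=None)

        tab = sankey_counts(cohort).set_index(["progressed", "ctdna_increase", "timing"])
        assert tab.loc[(True, True, "before_progression"), "n"] == 3
        assert tab.loc[(True, True, "at_or_after_progression"), "n"] == 1
        assert tab.loc[(True, False, "n/a"), "n"] == 2
        assert tab.loc[(False, True, "n/a"), "n"] == 1
        assert tab.loc[(False, False, "n/a"), "n"] == 2
        assert tab["n"].sum() == len(cohort)

    def test_duplicate_patients_rejected(self):
        pair = (traj_from("LL"), course())
        with pytest.raises(DataError):
            sankey_counts([pair, pair])
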