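"""Classification of longitudinal ctDNA trajectories.

Consecutive plasma samples of one patient are compared pairwise using the
detection call and the 95% CI of the mutant allele frequency:

* detectable -> undetectable            : **clearance**
* undetectable -> detectable            : **increase** (re-detection)
* both detectable, CIs strictly above   : **increase**
* both detectable, CIs strictly below   : **decrease**
* both detectable, CIs overlapping      : **stable**
* both undetectable                     : **remains negative**

An increase is *confirmed* when the next sample is positive and not a
significant (CI-based) decrease — a point-estimate dip with overlapping CIs
still confirms; an increase that is the last sample of follow-up, or is
followed by an undetectable or significantly lower sample, stays
*unconfirmed*.  Molecular events are then related to radiological
progression: an increase strictly before the progression day yields a
positive lead time (molecular progression anticipating clinical
progression); an increase on the progression day itself counts as
at-progression, keeping lead-time claims conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .ddpcr import ASSAYS, MafEstimate
from .errors import DataError, OrderingError, UsageError


class TransitionKind(str, Enum):
    CLEARANCE = "CLEARANCE"
    DECREASE = "DECREASE"
    INCREASE = "INCREASE"
    STABLE = "STABLE"
    REMAINS_NEGATIVE = "REMAINS_NEGATIVE"


class Confirmation(str, Enum):
    CONFIRMED = "confirmed"
    UNCONFIRMED = "unconfirmed"
    NOT_APPLICABLE = "not_applicable"


class ProgressionCategory(str, Enum):
    INCREASE_BEFORE_PROGRESSION = "INCREASE_BEFORE_PROGRESSION"
    INCREASE_AT_OR_AFTER_PROGRESSION = "INCREASE_AT_OR_AFTER_PROGRESSION"
    NO_INCREASE = "NO_INCREASE"
    NO_PROGRESSION = "NO_PROGRESSION"


@dataclass(frozen=True)
class TransitionEvent:
    kind: TransitionKind
    from_day: float
    to_day: float
    confirmed: Confirmation = Confirmation.NOT_APPLICABLE

    def __post_init__(self) -> None:
        is_inc = self.kind is TransitionKind.INCREASE
        has_conf = self.confirmed is not Confirmation.NOT_APPLICABLE
        if is_inc != has_conf:
            raise UsageError("confirmation status applies to INCREASE events only")


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered MAF estimates of one patient on one hotspot assay."""

    patient_id: str
    assay: str
    samples: tuple[MafEstimate, ...]

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise DataError(f"unknown assay {self.assay!r}")
        if not self.samples:
            raise DataError(f"patient {self.patient_id}: trajectory needs >=1 sample")
        days = [s.collection_day for s in self.samples]
        if any(d is None for d in days):
            raise DataError("every sample needs a collection_day")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise OrderingError(
                f"patient {self.patient_id}: collection days must strictly increase"
            )
        for s in self.samples:
            if s.assay is not None and s.assay != self.assay:
                raise DataError("sample assay does not match trajectory assay")


@dataclass(frozen=True)
class ProgressionRelation:
    category: ProgressionCategory
    lead_time_days: Optional[float]
    any_increase: bool


@dataclass(frozen=True)
class TrajectorySummary:
    events: tuple[TransitionEvent, ...]
    any_clearance: bool
    any_decrease: bool
    any_increase_after_treatment_start: bool


def compare_pair(prev: MafEstimate, curr: MafEstimate) -> TransitionEvent:
    """Classify the transition between two consecutive samples."""
    if prev.collection_day is None or curr.collection_day is None:
        raise DataError("samples need collection days")
    if curr.collection_day <= prev.collection_day:
        raise OrderingError("samples must be compared in increasing time order")
    days = (prev.collection_day, curr.collection_day)

    if prev.detected and not curr.detected:
        return TransitionEvent(TransitionKind.CLEARANCE, *days)
    if not prev.detected and curr.detected:
        return TransitionEvent(TransitionKind.INCREASE, *days, Confirmation.UNCONFIRMED)
    if not prev.detected and not curr.detected:
        return TransitionEvent(TransitionKind.REMAINS_NEGATIVE, *days)
    # both detected: significance by non-overlapping 95% CIs
    if curr.maf_ci_low > prev.maf_ci_high:
        return TransitionEvent(TransitionKind.INCREASE, *days, Confirmation.UNCONFIRMED)
    if curr.maf_ci_high < prev.maf_ci_low:
        return TransitionEvent(TransitionKind.DECREASE, *days)
    return TransitionEvent(TransitionKind.STABLE, *days)


def confirm_increase(traj: Trajectory, increase_index: int) -> Confirmation:
    """Confirmation status of the increase ending at sample ``increase_index + 1``.

    ``increase_index`` indexes the transition list (transition ``i`` compares
    samples ``i`` and ``i + 1``).
    """
    n_trans = len(traj.samples) - 1
    if not 0 <= increase_index < n_trans:
        raise UsageError(f"transition index {increase_index} out of range")
    inc_sample = traj.samples[increase_index + 1]
    if compare_pair(traj.samples[increase_index], inc_sample).kind is not (
        TransitionKind.INCREASE
    ):
        raise UsageError("indexed transition is not an increase")
    if increase_index + 2 >= len(traj.samples):
        return Confirmation.UNCONFIRMED  # end of follow-up
    nxt = traj.samples[increase_index + 2]
    if not nxt.detected:
        return Confirmation.UNCONFIRMED
    follow = compare_pair(inc_sample, nxt)
    if follow.kind in (TransitionKind.DECREASE, TransitionKind.CLEARANCE):
        return Confirmation.UNCONFIRMED
    return Confirmation.CONFIRMED


def classify_trajectory(traj: Trajectory) -> TrajectorySummary:
    """All pairwise transitions plus post-treatment summary flags.

    Flags only consider transitions ending after treatment start
    (``to_day > 0``); the baseline -> first on-treatment transition counts.
    """
    events = []
    for i in range(len(traj.samples) - 1):
        ev = compare_pair(traj.samples[i], traj.samples[i + 1])
        if ev.kind is TransitionKind.INCREASE:
            ev = TransitionEvent(
                ev.kind, ev.from_day, ev.to_day, confirm_increase(traj, i)
            )
        events.append(ev)
    post = [e for e in events if e.to_day > 0]
    return TrajectorySummary(
        events=tuple(events),
        any_clearance=any(e.kind is TransitionKind.CLEARANCE for e in post),
        any_decrease=any(e.kind is TransitionKind.DECREASE for e in post),
        any_increase_after_treatment_start=any(
            e.kind is TransitionKind.INCREASE for e in post
        ),
    )


def relate_to_progression(
    traj: Trajectory, course: "ClinicalCourse"
) -> ProgressionRelation:
    """Relate post-treatment ctDNA increases to radiological progression.

    Lead time is ``progression_day - earliest qualifying increase day``;
    positive when the molecular event anticipates clinical progression.
    """
    from .stats import ClinicalCourse  # noqa: F401  (type reference only)

    prog = course.progression_day
    if prog is not None and prog < 0:
        raise DataError("progression before treatment start")
    summary = classify_trajectory(traj)
    inc_days = sorted(
        e.to_day
        for e in summary.events
        if e.kind is TransitionKind.INCREASE and e.to_day > 0
    )
    any_inc = bool(inc_days)
    if prog is None:
        return ProgressionRelation(ProgressionCategory.NO_PROGRESSION, None, any_inc)
    if not any_inc:
        return ProgressionRelation(ProgressionCategory.NO_INCREASE, None, False)
    lead = prog - inc_days[0]
    if any(d < prog for d in inc_days):
        cat = ProgressionCategory.INCREASE_BEFORE_PROGRESSION
    else:
        cat = ProgressionCategory.INCREASE_AT_OR_AFTER_PROGRESSION
    return ProgressionRelation(cat, lead, True)


#: The five possible cells of the progression / increase / timing cross-tab.
_SANKEY_CELLS = (
    (True, True, "before_progression"),
    (True, True, "at_or_after_progression"),
    (True, False, "n/a"),
    (False, True, "n/a"),
    (False, False, "n/a"),
)


def sankey_counts(
    cohort: Sequence[tuple[Trajectory, "ClinicalCourse"]]
) -> pd.DataFrame:
    """Cross-tabulate progression status, post-treatment ctDNA increase and
    increase timing over a cohort (the flow diagram's node counts).
    """
    ids = [t.patient_id for t, _ in cohort]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate patient ids in cohort")
    counts = {cell: 0 for cell in _SANKEY_CELLS}
    for traj, course in cohort:
        rel = relate_to_progression(traj, course)
        progressed = course.progression_day is not None
        if rel.category is ProgressionCategory.INCREASE_BEFORE_PROGRESSION:
            cell = (True, True, "before_progression")
        elif rel.category is ProgressionCategory.INCREASE_AT_OR_AFTER_PROGRESSION:
            cell = (True, True, "at_or_after_progression")
        else:
            cell = (progressed, rel.any_increase, "n/a")
        counts[cell] += 1
    return pd.DataFrame(
        [
            {"progressed": p, "ctdna_increase": i, "timing": t, "n": counts[(p, i, t)]}
            for p, i, t in _SANKEY_CELLS
        ]
    )


__all__ = [
    "TransitionKind",
    "Confirmation",
    "ProgressionCategory",
    "TransitionEvent",
    "Trajectory",
    "TrajectorySummary",
    "ProgressionRelation",
    "compare_pair",
    "confirm_increase",
    "classify_trajectory",
    "relate_to_progression",
    "sankey_counts",
]
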