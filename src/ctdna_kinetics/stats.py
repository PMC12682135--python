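"""Survival and small-sample statistics for ctDNA biomarker analysis.

Implements the statistical layer of the monitoring analysis from first
principles so its small-sample behaviour is transparent: the Kaplan–Meier
product-limit estimator with right censoring, the two-group log-rank test,
Pearson correlation with the t-transform p-value, and the Wilcoxon rank-sum
test with exact enumeration for small cohorts (the trial-scale regime,
combined n <= 12 by default) and a tie-corrected normal approximation
otherwise.  Also defines the landmark ctDNA status used to stratify
survival: a patient is landmark-positive when at least one pre-progression
sample inside a fixed post-treatment window (default days 60–122,
i.e. 2–4 months) is detected.

Times are measured in days from treatment start (day 0).  Overall survival
uses death as the event; progression-free survival uses progression or death,
whichever comes first; patients without an event are right-censored at last
follow-up.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .ddpcr import MafEstimate
from .dynamics import Trajectory
from .errors import DataError, NotEvaluableError, UsageError

#: "2–4 months" after treatment start, fixed in days (inclusive bounds).
DEFAULT_LANDMARK_WINDOW = (60.0, 122.0)

#: Average Gregorian month length used to report medians in months.
DAYS_PER_MONTH = 30.44

#: Largest combined sample size for which the Wilcoxon test enumerates the
#: exact null distribution.
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class ImagingAssessment:
    day: float
    recist_sum_mm: float
    response_call: str = ""


@dataclass(frozen=True)
class ClinicalCourse:
    """Clinical timeline and baseline covariates of one patient.

    All days are relative to treatment start (day 0); baseline values may
    carry negative days.
    """

    patient_id: str
    last_followup_day: float
    progression_day: Optional[float] = None
    death_day: Optional[float] = None
    ldh_value: Optional[float] = None
    ldh_above_uln: Optional[bool] = None
    m_stage: Optional[str] = None
    extrahepatic: Optional[bool] = None
    recist_sum_mm: Optional[float] = None
    imaging: tuple[ImagingAssessment, ...] = ()

    def __post_init__(self) -> None:
        for name in ("progression_day", "death_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DataError(f"{self.patient_id}: {name} before treatment start")
        events = [d for d in (self.progression_day, self.death_day) if d is not None]
        if events and self.last_followup_day < max(events):
            raise DataError(
                f"{self.patient_id}: last follow-up precedes a recorded event"
            )
        if self.m_stage is not None and self.m_stage not in ("M1a", "M1b", "M1c"):
            raise DataError(f"{self.patient_id}: unknown M stage {self.m_stage!r}")


@dataclass(frozen=True)
class LandmarkStatus:
    patient_id: str
    window: tuple[float, float]
    status: Literal["POSITIVE", "NEGATIVE", "NOT_EVALUABLE"]
    n_samples_in_window: int


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate with right censoring."""

    event_times: np.ndarray  # distinct times with >=1 event
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    @property
    def median(self) -> Optional[float]:
        """Smallest time with S(t) <= 0.5; None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size == 0:
            return None
        return float(self.event_times[below[0]])

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def baseline_status(traj: Trajectory) -> bool:
    """Detection status of the latest sample at or before treatment start."""
    pre = [s for s in traj.samples if s.collection_day <= 0]
    if not pre:
        raise NotEvaluableError(
            f"patient {traj.patient_id} has no baseline (day <= 0) sample"
        )
    return pre[-1].detected


def landmark_status(
    traj: Trajectory,
    course: ClinicalCourse,
    window_days: tuple[float, float] = DEFAULT_LANDMARK_WINDOW,
) -> LandmarkStatus:
    """ctDNA status within a post-treatment window, pre-progression only.

    POSITIVE when any in-window sample taken before progression is detected;
    NEGATIVE when such samples exist and all are undetected; NOT_EVALUABLE
    when the window holds no evaluable sample.
    """
    start, end = window_days
    if not start < end:
        raise UsageError("window start must precede window end")
    prog = course.progression_day
    eligible = [
        s
        for s in traj.samples
        if start <= s.collection_day <= end and (prog is None or s.collection_day < prog)
    ]
    if not eligible:
        status = "NOT_EVALUABLE"
    elif any(s.detected for s in eligible):
        status = "POSITIVE"
    else:
        status = "NEGATIVE"
    return LandmarkStatus(traj.patient_id, (start, end), status, len(eligible))


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier estimator; ties process events before censorings."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise DataError("km_estimate needs at least one subject")
    if t.size != e.size:
        raise DataError("times and events must have equal length")
    if np.any(t < 0):
        raise DataError("survival times must be non-negative")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size
    event_times, at_risk, n_events, surv = [], [], [], []
    s = 1.0
    for ut in np.unique(t[e]):
        r = int(np.sum(t >= ut))  # censored at ut still at risk
        d = int(np.sum((t == ut) & e))
        s *= 1.0 - d / r
        event_times.append(ut)
        at_risk.append(r)
        n_events.append(d)
        surv.append(s)
    return SurvivalCurve(
        np.asarray(event_times),
        np.asarray(at_risk),
        np.asarray(n_events),
        np.asarray(surv),
    )


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[bool]],
    group_b: tuple[Sequence[float], Sequence[bool]],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], bool)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], bool)
    if ta.size == 0 or tb.size == 0:
        raise DataError("log-rank test needs two non-empty groups")

    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])

    o_minus_e = 0.0
    var = 0.0
    for ut in np.unique(t_all[e_all]):
        at_risk = t_all >= ut
        n = int(at_risk.sum())
        n_a = int((at_risk & grp_a).sum())
        d = int((e_all & (t_all == ut)).sum())
        d_a = int((e_all & (t_all == ut) & grp_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise DataError("pearson_correlation needs equal-length vectors, n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt(float(xc @ xc)), math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DataError("correlation undefined for a zero-variance vector")
    r = float(np.clip(xc @ yc / (sx * sy), -1.0, 1.0))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _rank_sum_stat(ranks: np.ndarray, idx: Iterable[int]) -> float:
    return float(sum(ranks[i] for i in idx))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    For combined n <= ``exact_max_n`` the p-value enumerates every assignment
    of the (mid)ranks to the first group exactly; beyond that a normal
    approximation with tie correction and continuity correction is used.
    Returns (rank sum of ``x``, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise DataError("wilcoxon_rank_sum needs two non-empty groups")
    m, n_b = x.size, y.size
    n = m + n_b
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:m].sum())

    if n <= exact_max_n:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, m)),
            dtype=float,
            count=math.comb(n, m),
        )
        eps = 1e-9
        p_le = np.mean(sums <= w + eps)
        p_ge = np.mean(sums >= w - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    mean_w = m * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_w = m * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w == 0.0:
        return w, 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)  # continuity correction
    z = max(z, 0.0)
    return w, float(2.0 * sps.norm.sf(z))


@dataclass(frozen=True)
class StratifiedSurvivalResult:
    endpoint: str
    grouping: str
    curve_negative: SurvivalCurve
    curve_positive: SurvivalCurve
    chi_square: float
    p_value: float
    median_negative_days: Optional[float]
    median_positive_days: Optional[float]
    n_negative: int
    n_positive: int

    def median_months(self, arm: str) -> Optional[float]:
        d = getattr(self, f"median_{arm}_days")
        return None if d is None else d / DAYS_PER_MONTH


def survival_time(
    course: ClinicalCourse, endpoint: Literal["OS", "PFS"]
) -> tuple[float, bool]:
    """(time, event) pair for one patient, days from treatment start."""
    if endpoint == "OS":
        if course.death_day is not None:
            return course.death_day, True
        return course.last_followup_day, False
    if endpoint == "PFS":
        events = [d for d in (course.progression_day, course.death_day) if d is not None]
        if events:
            return min(events), True
        return course.last_followup_day, False
    raise UsageError(f"unknown endpoint {endpoint!r}")


def stratified_survival(
    cohort: Sequence[tuple[Trajectory, ClinicalCourse]],
    grouping: Literal["baseline", "landmark"],
    endpoint: Literal["OS", "PFS"],
    window_days: tuple[float, float] = DEFAULT_LANDMARK_WINDOW,
) -> StratifiedSurvivalResult:
    """Kaplan–Meier curves and log-rank test, ctDNA-negative vs -positive.

    Patients whose status cannot be called (no baseline sample, or no
    evaluable landmark sample) are dropped.
    """
    neg: list[tuple[float, bool]] = []
    pos: list[tuple[float, bool]] = []
    for traj, course in cohort:
        if grouping == "baseline":
            try:
                positive = baseline_status(traj)
            except NotEvaluableError:
                continue
        elif grouping == "landmark":
            st = landmark_status(traj, course, window_days)
            if st.status == "NOT_EVALUABLE":
                continue
            positive = st.status == "POSITIVE"
        else:
            raise UsageError(f"unknown grouping {grouping!r}")
        (pos if positive else neg).append(survival_time(course, endpoint))

    if not neg or not pos:
        raise DataError("stratified survival needs >=1 subject in each arm")
    tn, en = zip(*neg)
    tp, ep = zip(*pos)
    curve_n = km_estimate(tn, en)
    curve_p = km_estimate(tp, ep)
    chi2, p = logrank_test((tn, en), (tp, ep))
    return StratifiedSurvivalResult(
        endpoint=endpoint,
        grouping=grouping,
        curve_negative=curve_n,
        curve_positive=curve_p,
        chi_square=chi2,
        p_value=p,
        median_negative_days=curve_n.median,
        median_positive_days=curve_p.median,
        n_negative=len(neg),
        n_positive=len(pos),
    )


__all__ = [
    "DEFAULT_LANDMARK_WINDOW",
    "DAYS_PER_MONTH",
    "EXACT_WILCOXON_MAX_N",
    "ImagingAssessment",
    "ClinicalCourse",
    "LandmarkStatus",
    "SurvivalCurve",
    "StratifiedSurvivalResult",
    "baseline_status",
    "landmark_status",
    "km_estimate",
    "logrank_test",
    "pearson_correlation",
    "wilcoxon_rank_sum",
    "survival_time",
    "stratified_survival",
]
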