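"""Shared test helpers: sample factories and an independent rule-table oracle.

The oracle enumerates trajectory semantics over three symbolic sample states
with fixed CI geometry —

* ``U``: undetected
* ``L``: detected, MAF 1.0% with CI (0.8, 1.2)
* ``H``: detected, MAF 5.0% with CI (4.0, 6.0)

``L`` and ``H`` have non-overlapping CIs, so L->H is a significant rise and
H->L a significant fall.  The oracle is written as literal nested rules,
independent of the package's classifier implementation.
"""

from __future__ import annotations

from ctdna_kinetics.ddpcr import ConcentrationEstimate, MafEstimate

STATES = ("U", "L", "H")

_MAF = {"U": 0.0, "L": 1.0, "H": 5.0}
_CI = {"U": (0.0, 0.1), "L": (0.8, 1.2), "H": (4.0, 6.0)}


def _dummy_conc(value: float = 0.0) -> ConcentrationEstimate:
    return ConcentrationEstimate(0.0, value, 0.0, value, 0, 1)


def make_sample(day: float, state: str, assay: str = "GNA11_Q209L") -> MafEstimate:
    """A MafEstimate in one of the three symbolic states."""
    detected = state != "U"
    lo, hi = _CI[state]
    return MafEstimate(
        maf_pct=_MAF[state],
        maf_ci_low=lo if detected else 0.0,
        maf_ci_high=hi,
        mut_conc=_dummy_conc(_MAF[state]),
        wt_conc=_dummy_conc(100.0),
        detected=detected,
        mut_droplets=100 if detected else 0,
        sample_id=f"S{day}",
        assay=assay,
        collection_day=day,
    )


def oracle_kind(a: str, b: str) -> str:
    """Transition class of a symbolic pair, by literal rule enumeration."""
    if a == "U" and b == "U":
        return "REMAINS_NEGATIVE"
    if a == "U":
        return "INCREASE"
    if b == "U":
        return "CLEARANCE"
    if a == b:
        return "STABLE"
    if a == "L" and b == "H":
        return "INCREASE"
    return "DECREASE"


def oracle_confirmation(seq: str, i: int) -> str:
    """Confirmation of the increase at transition ``i`` of symbol string
    ``seq`` (comparing seq[i] -> seq[i+1])."""
    assert oracle_kind(seq[i], seq[i + 1]) == "INCREASE"
    if i + 2 >= len(seq):
        return "unconfirmed"
    nxt = seq[i + 2]
    if nxt == "U":
        return "unconfirmed"
    if oracle_kind(seq[i + 1], nxt) == "DECREASE":
        return "unconfirmed"
    return "confirmed"


def oracle_events(seq: str) -> list[tuple[str, str]]:
    """(kind, confirmation) per transition of a symbol string."""
    out = []
    for i in range(len(seq) - 1):
        kind = oracle_kind(seq[i], seq[i + 1])
        conf = oracle_confirmation(seq, i) if kind == "INCREASE" else "not_applicable"
        out.append((kind, conf))
    return out


def oracle_relation(
    seq: str, days: list[float], progression_day: float | None
) -> tuple[str, float | None]:
    """(category, lead_time_days) by direct arithmetic on the symbol string."""
    inc_days = [
        days[i + 1]
        for i in range(len(seq) - 1)
        if oracle_kind(seq[i], seq[i + 1]) == "INCREASE" and days[i + 1] > 0
    ]
    if progression_day is None:
        return "NO_PROGRESSION", None
    if not inc_days:
        return "NO_INCREASE", None
    lead = progression_day - min(inc_days)
    if any(d < progression_day for d in inc_days):
        return "INCREASE_BEFORE_PROGRESSION", lead
    return "INCREASE_AT_OR_AFTER_PROGRESSION", lead
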