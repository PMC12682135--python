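"""Droplet digital PCR quantification with Poisson partition statistics.

A dPCR reaction partitions the sample into ~20 000 droplets; after PCR each
droplet reads positive or negative per channel.  With ``k`` of ``N`` droplets
positive, the mean number of target copies per droplet is

    lambda = -ln((N - k) / N)

because droplet occupancy is Poisson and the negative fraction estimates
``exp(-lambda)``.  Absolute concentration follows by dividing by the droplet
volume.  This module turns raw droplet counts into concentrations with 95%
confidence intervals, pools replicate wells, derives a detection floor (limit
of blank) from no-template-control wells, and reports the mutant allele
frequency (MAF, %) of a hotspot assay with a per-sample CI — the quantity the
downstream trajectory classifier consumes.

Confidence intervals: the negative droplet fraction is a binomial proportion,
so a 95% Wilson score interval on it is pushed through the monotone map
``p -> -ln(p) / V``; bounds map to bounds and the interval never collapses to
zero width at boundary counts.  The MAF interval uses the delta method on the
log concentration ratio, with each concentration's CI half-width standing in
for its standard error, mapped back through ``x -> 100 x / (1 + x)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DataError,
    EmptyWellError,
    InconsistentWellsError,
    NoTemplateError,
    SaturatedWellError,
)

#: The three uveal-melanoma hotspot assays (mutually exclusive per tumor).
ASSAYS = ("GNA11_Q209L", "GNAQ_Q209L", "GNAQ_Q209P")

#: Droplet volume of the Bio-Rad QX200 system, nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Minimum mutant-droplet count for a detection call, before the NTC-derived
#: limit of blank is taken into account.
DEFAULT_K_MIN = 3

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class DropletWell:
    """Accepted-droplet counts for one well of one sample/assay."""

    well_id: str
    sample_id: str
    assay: str
    n_total: int
    n_mut_pos: int
    n_wt_pos: int
    is_ntc: bool = False
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise DataError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.n_total <= 0:
            raise EmptyWellError(f"well {self.well_id}: n_total must be positive")
        if not 0 <= self.n_mut_pos <= self.n_total:
            raise DataError(f"well {self.well_id}: n_mut_pos outside [0, n_total]")
        if not 0 <= self.n_wt_pos <= self.n_total:
            raise DataError(f"well {self.well_id}: n_wt_pos outside [0, n_total]")
        if self.droplet_volume_nl <= 0:
            raise DataError(f"well {self.well_id}: droplet volume must be positive")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute target concentration in the reaction, copies per microlitre."""

    lambda_: float
    conc_per_ul: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_total: int


@dataclass(frozen=True)
class MafEstimate:
    """Mutant allele frequency call for one plasma sample.

    ``maf_pct`` is the mutant target concentration as a percentage of mutant
    plus wild type.  ``detected`` applies the limit-of-blank rule to the
    merged mutant-positive droplet count; undetected samples report a MAF of
    0 with a one-sided upper bound so they remain comparable on plots.
    """

    maf_pct: float
    maf_ci_low: float
    maf_ci_high: float
    mut_conc: ConcentrationEstimate
    wt_conc: ConcentrationEstimate
    detected: bool
    mut_droplets: int
    sample_id: str | None = None
    assay: str | None = None
    collection_day: float | None = None


def _check_counts(n_pos: int, n_total: int) -> None:
    if n_total <= 0:
        raise EmptyWellError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise DataError(f"n_pos={n_pos} outside [0, {n_total}]")
    if n_pos == n_total:
        raise SaturatedWellError(
            f"all {n_total} droplets positive: concentration not estimable, "
            "dilute the sample"
        )


def lambda_from_counts(n_pos: int, n_total: int) -> float:
    """Mean copies per droplet from positive/total droplet counts.

    Raises :class:`SaturatedWellError` when every droplet is positive (the
    point estimate would be infinite) and :class:`EmptyWellError` for an
    empty well.
    """
    _check_counts(n_pos, n_total)
    return -math.log1p(-n_pos / n_total)


def _conc_ci_arrays(
    n_pos: np.ndarray, n_total: np.ndarray, droplet_volume_nl: np.ndarray
):
    """Vectorised concentration point estimate and 95% CI (copies/µl)."""
    n_pos = np.asarray(n_pos, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    vol_ul = np.asarray(droplet_volume_nl, dtype=float) * 1e-3
    lam = -np.log1p(-n_pos / n_total)
    # Wilson score interval on the negative droplet fraction.
    p_low, p_high = proportion_confint(
        n_total - n_pos, n_total, alpha=0.05, method="wilson"
    )
    p_high = np.minimum(p_high, 1.0)
    conc = lam / vol_ul
    ci_low = np.maximum(-np.log(p_high) / vol_ul, 0.0)
    # guard against round-off at boundary counts (p_high = 1 - eps)
    ci_low = np.minimum(ci_low, conc)
    ci_high = -np.log(p_low) / vol_ul
    return lam, conc, ci_low, ci_high


def concentration_with_ci(
    n_pos: int, n_total: int, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
) -> ConcentrationEstimate:
    """Absolute concentration (copies/µl of reaction) with a 95% CI.

    The CI is a Wilson score interval on the negative droplet fraction mapped
    through the monotone transform ``p -> -ln(p)/V`` and clipped at zero.
    """
    _check_counts(n_pos, n_total)
    if droplet_volume_nl <= 0:
        raise DataError("droplet volume must be positive")
    lam, conc, lo, hi = _conc_ci_arrays(
        np.array([n_pos]), np.array([n_total]), np.array([droplet_volume_nl])
    )
    return ConcentrationEstimate(
        lambda_=float(lam[0]),
        conc_per_ul=float(conc[0]),
        ci_low=float(lo[0]),
        ci_high=float(hi[0]),
        n_pos=int(n_pos),
        n_total=int(n_total),
    )


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool replicate wells of one sample/assay into a single meta-well.

    Summing counts is the maximum-likelihood way to combine replicates under
    the Poisson partition model (the estimate depends on pooled counts only,
    not on the mean of per-well estimates).
    """
    if not wells:
        raise DataError("cannot merge an empty list of wells")
    first = wells[0]
    for w in wells:
        if w.is_ntc:
            raise InconsistentWellsError(f"well {w.well_id} is an NTC; cannot merge")
        if (w.sample_id, w.assay) != (first.sample_id, first.assay):
            raise InconsistentWellsError(
                "cannot merge wells from different samples or assays"
            )
        if w.droplet_volume_nl != first.droplet_volume_nl:
            raise InconsistentWellsError("cannot merge wells with different volumes")
    if len(wells) == 1:
        return first
    return replace(
        first,
        well_id="+".join(w.well_id for w in wells),
        n_total=sum(w.n_total for w in wells),
        n_mut_pos=sum(w.n_mut_pos for w in wells),
        n_wt_pos=sum(w.n_wt_pos for w in wells),
    )


def estimate_lob(ntc_wells: Sequence[DropletWell], k_min: int = DEFAULT_K_MIN) -> int:
    """Limit of blank: minimum mutant-droplet count that calls detection.

    One more than the worst false-positive count seen in any no-template
    control, floored at ``k_min`` so a clean NTC run does not drop the
    threshold below common ddPCR practice.
    """
    if k_min < 1:
        raise DataError("k_min must be >= 1")
    if not ntc_wells:
        warnings.warn(
            "no NTC wells provided; falling back to the configured floor "
            f"k_min={k_min}",
            stacklevel=2,
        )
        return k_min
    for w in ntc_wells:
        if not w.is_ntc:
            raise DataError(f"well {w.well_id} is not flagged as NTC")
    worst = max(w.n_mut_pos for w in ntc_wells)
    return max(k_min, worst + 1)


def _ci_halfwidth_se(est: ConcentrationEstimate) -> float:
    # CI half-width as a standard-error surrogate on the concentration scale.
    return (est.ci_high - est.ci_low) / (2.0 * _Z95)


def maf_with_ci(
    mut: ConcentrationEstimate,
    wt: ConcentrationEstimate,
    lob: int,
    mut_droplets: int | None = None,
) -> MafEstimate:
    """Mutant allele frequency (%) with 95% CI and a detection call.

    ``detected`` is true when the merged mutant-positive droplet count
    reaches the limit of blank.  Undetected samples are reported as MAF 0
    with CI ``[0, u]`` where ``u`` is the MAF implied by the upper
    concentration bound at a hypothetical mutant count of ``lob - 1`` — the
    largest count still called negative.
    """
    if mut_droplets is None:
        mut_droplets = mut.n_pos
    total = mut.conc_per_ul + wt.conc_per_ul
    if total == 0.0:
        raise NoTemplateError("no mutant or wild-type target detected in sample")
    detected = mut_droplets >= lob

    if not detected:
        if wt.conc_per_ul > 0.0:
            hypo = concentration_with_ci(
                min(lob - 1, mut.n_total - 1), mut.n_total, _volume_of(mut)
            )
            x = hypo.ci_high / wt.conc_per_ul
            upper = 100.0 * x / (1.0 + x)
        else:
            upper = 100.0
        return MafEstimate(0.0, 0.0, upper, mut, wt, False, int(mut_droplets))

    maf = 100.0 * mut.conc_per_ul / total
    if wt.conc_per_ul == 0.0:
        # No wild-type signal at all: one-sided lower bound against the
        # wild-type upper bound.
        x = mut.ci_low / wt.ci_high if wt.ci_high > 0 else math.inf
        lo = 100.0 * x / (1.0 + x)
        return MafEstimate(maf, lo, 100.0, mut, wt, True, int(mut_droplets))

    se_log = math.hypot(
        _ci_halfwidth_se(mut) / mut.conc_per_ul,
        _ci_halfwidth_se(wt) / wt.conc_per_ul,
    )
    log_ratio = math.log(mut.conc_per_ul / wt.conc_per_ul)
    x_lo = math.exp(log_ratio - _Z95 * se_log)
    x_hi = math.exp(log_ratio + _Z95 * se_log)
    lo = 100.0 * x_lo / (1.0 + x_lo)
    hi = 100.0 * x_hi / (1.0 + x_hi)
    return MafEstimate(maf, lo, hi, mut, wt, True, int(mut_droplets))


def _volume_of(est: ConcentrationEstimate) -> float:
    # Recover the droplet volume (nl) the estimate was computed with.
    if est.lambda_ > 0:
        return est.lambda_ / est.conc_per_ul * 1e3
    return DEFAULT_DROPLET_VOLUME_NL


def quantify_sample(
    wells: Sequence[DropletWell], lob: int
) -> MafEstimate:
    """Merge replicate wells of one sample/assay and call its MAF."""
    meta = merge_wells(list(wells))
    v = meta.droplet_volume_nl
    mut = concentration_with_ci(meta.n_mut_pos, meta.n_total, v)
    wt = concentration_with_ci(meta.n_wt_pos, meta.n_total, v)
    est = maf_with_ci(mut, wt, lob, meta.n_mut_pos)
    return replace(est, sample_id=meta.sample_id, assay=meta.assay)


__all__ = [
    "ASSAYS",
    "DEFAULT_DROPLET_VOLUME_NL",
    "DEFAULT_K_MIN",
    "DropletWell",
    "ConcentrationEstimate",
    "MafEstimate",
    "lambda_from_counts",
    "concentration_with_ci",
    "merge_wells",
    "estimate_lob",
    "maf_with_ci",
    "quantify_sample",
]
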