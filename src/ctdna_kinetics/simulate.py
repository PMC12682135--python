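"""Synthetic metastatic uveal-melanoma ctDNA monitoring cohorts.

Generates, with a known ground truth, the three inputs the analysis pipeline
consumes: droplet-level dPCR well counts (including no-template controls),
a plasma sample manifest, and a clinical events table with an imaging
timeline.  The generative model is deliberately simple but carries the
statistical structure the analysis assumes:

* each patient has one hotspot assay (GNA11 Q209L / GNAQ Q209L / GNAQ Q209P,
  mixed 9:5:4 as in the trial population);
* baseline tumor burden (RECIST sum of target-lesion diameters, mm) is
  log-normal, and plasma mutant-copy concentration is proportional to burden
  through a patient-specific shedding coefficient (log-normal, heavy-tailed,
  so a realistic fraction of low-burden patients is below detection);
* burden follows the patient's response class — exponential clearance (CR,
  with true molecular clearance once burden falls below 2% of baseline),
  partial decay to a floor (PR), slow drift (SD), or regrowth (PD);
* progression is exponential with a hazard multiplied by the *true* landmark
  ctDNA status (the true hazard ratio is a parameter — set it to 1 for null
  calibration studies); death follows progression after a log-normal lag;
* each scheduled plasma draw converts concentration to expected copies in
  the dPCR reaction (2 ml plasma, a fixed extraction-to-reaction fraction)
  and partitions them into droplets: a droplet is mutant-positive when it
  holds at least one mutant molecule or a false-positive event occurs;
* LDH is simulated as burden-correlated noise so baseline correlations are
  recoverable by the analysis.

With the default seed the whole cohort is reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ddpcr import ASSAYS, DEFAULT_DROPLET_VOLUME_NL, DropletWell
from .errors import DataError

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD")

#: Mass of one haploid genome equivalent, nanograms.
NG_PER_GENOME = 0.0033


@dataclass(frozen=True)
class CohortParams:
    """All knobs of the generator.  Defaults are the study conditions."""

    n_patients: int = 18
    # trial assay mix 9:5:4
    assay_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "GNA11_Q209L": 9 / 18,
            "GNAQ_Q209P": 5 / 18,
            "GNAQ_Q209L": 4 / 18,
        }
    )
    # baseline tumor burden: RECIST sum of target lesions, mm
    baseline_recist_median_mm: float = 60.0
    baseline_recist_log_sd: float = 0.6
    largest_lesion_frac: tuple[float, float] = (0.35, 0.8)
    extrahepatic_prob: float = 0.28
    ldh_uln: float = 250.0
    # ctDNA shedding: mutant haploid genome-equivalents per ml plasma per mm.
    # A two-component mixture: most patients shed around shedding_median
    # (log-normal), while a low-shedder subpopulation (biologically: low
    # tumor burden / poorly shedding disease, typically undetectable in
    # plasma) sheds a small fraction of that.
    shedding_median: float = 0.5
    shedding_log_sd: float = 1.5
    low_shedder_prob: float = 0.4
    low_shedder_factor: float = 0.002
    # wild-type background cfDNA, genome-equivalents per ml plasma
    background_cfdna_median: float = 3000.0
    background_cfdna_log_sd: float = 0.5
    response_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CR": 0.10, "PR": 0.25, "SD": 0.40, "PD": 0.25}
    )
    # per-day exponential rates; negative = regrowth
    decay_rates: Mapping[str, float] = field(
        default_factory=lambda: {"CR": 0.05, "PR": 0.025, "SD": 0.003, "PD": -0.008}
    )
    pr_floor_frac: float = 0.30
    cr_clearance_frac: float = 0.02
    pd_cap_frac: float = 3.0
    # progression hazard per day; multiplied by landmark_hr for patients whose
    # true ctDNA status in the landmark window is positive
    base_progression_hazard: float = 1.0 / 450.0
    landmark_hr: float = 3.0
    landmark_window: tuple[float, float] = (60.0, 122.0)
    death_lag_median_days: float = 120.0
    death_lag_log_sd: float = 0.6
    followup_days: float = 540.0
    sampling_days: tuple[float, ...] = (
        -7, 21, 42, 63, 84, 105, 126, 168, 210, 252, 294, 336, 420, 504,
    )
    imaging_days: tuple[float, ...] = (-14, 84, 168, 252, 336, 420, 504)
    # dPCR physics
    mean_droplets: float = 18000.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    false_positive_rate: float = 1e-5
    plasma_ml: float = 2.0
    extraction_to_reaction_fraction: float = 0.5
    n_replicate_wells: int = 1
    n_ntc_wells: int = 6
    # ground-truth detectability: a draw is "truly detectable" when, under
    # Poisson partitioning of its expected reaction copies (plus false
    # positives), at least truth_lob_droplets droplets read positive with
    # probability > 0.5; the true landmark status is positive when detection
    # of at least one window draw is more likely than not
    truth_lob_droplets: int = 3
    recist_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DataError("n_patients must be >= 1")
        for name, probs, keys in (
            ("assay_probs", self.assay_probs, ASSAYS),
            ("response_probs", self.response_probs, RESPONSE_CLASSES),
        ):
            if set(probs) != set(keys):
                raise DataError(f"{name} must cover exactly {keys}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise DataError(f"{name} must sum to 1")
        if not self.sampling_days or not self.imaging_days:
            raise DataError("sampling and imaging schedules must be non-empty")
        for name in ("base_progression_hazard", "landmark_hr", "false_positive_rate"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


@dataclass
class SimulatedCohort:
    droplets: pd.DataFrame
    manifest: pd.DataFrame
    clinical: pd.DataFrame
    imaging: pd.DataFrame
    truth: dict
    params: CohortParams

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the four observable tables plus ground truth, fixed dialect."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("droplets", self.droplets),
            ("manifest", self.manifest),
            ("clinical", self.clinical),
            ("imaging", self.imaging),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
            paths[name] = p
        p = outdir / "truth.json"
        with open(p, "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["truth"] = p
        return paths


def simulate_well(
    mut_copies: float,
    wt_copies: float,
    rng: np.random.Generator,
    *,
    mean_droplets: float = 18000.0,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    false_positive_rate: float = 0.0,
    well_id: str = "W0",
    sample_id: str = "S0",
    assay: str = "GNA11_Q209L",
    is_ntc: bool = False,
) -> DropletWell:
    """Partition ``mut_copies`` / ``wt_copies`` into one droplet well.

    Occupancy is Poisson per droplet; a droplet reads mutant-positive when it
    holds >=1 mutant molecule or a false-positive event fires (mutant channel
    only).
    """
    if mut_copies < 0 or wt_copies < 0:
        raise DataError("copy numbers must be non-negative")
    n_total = int(rng.poisson(mean_droplets))
    n_total = max(n_total, 1)
    p_mut = 1.0 - math.exp(-mut_copies / n_total)
    p_mut = 1.0 - (1.0 - p_mut) * (1.0 - false_positive_rate)
    p_wt = 1.0 - math.exp(-wt_copies / n_total)
    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        assay=assay,
        n_total=n_total,
        n_mut_pos=int(rng.binomial(n_total, p_mut)),
        n_wt_pos=int(rng.binomial(n_total, p_wt)),
        is_ntc=is_ntc,
        droplet_volume_nl=droplet_volume_nl,
    )


def _burden_frac(cls: str, t: float, p: CohortParams) -> float:
    """Tumor burden at day t as a fraction of baseline, by response class."""
    if t <= 0:
        return 1.0
    frac = math.exp(-p.decay_rates[cls] * t)
    if cls == "PR":
        frac = max(frac, p.pr_floor_frac)
    elif cls == "PD":
        frac = min(frac, p.pd_cap_frac)
    return frac


def _mut_conc_per_ml(cls: str, t: float, b0: float, shed: float, p: CohortParams) -> float:
    """True mutant copies per ml plasma at day t (0 after CR clearance)."""
    frac = _burden_frac(cls, t, p)
    if cls == "CR" and frac < p.cr_clearance_frac:
        return 0.0
    return shed * b0 * frac


def simulate_cohort(params: CohortParams) -> SimulatedCohort:
    """Draw one full cohort; ``params.seed`` fixes it bit for bit."""
    p = params
    rng = np.random.default_rng(p.seed)
    assays = list(p.assay_probs)
    assay_pr = np.array([p.assay_probs[a] for a in assays])
    classes = list(p.response_probs)
    class_pr = np.array([p.response_probs[c] for c in classes])
    react_factor = p.plasma_ml * p.extraction_to_reaction_fraction  # ml -> reaction

    droplet_rows: list[DropletWell] = []
    manifest_rows = []
    clinical_rows = []
    imaging_rows = []
    truth: dict[str, dict] = {}

    for i in range(p.n_patients):
        pid = f"P{i + 1:02d}"
        assay = assays[int(rng.choice(len(assays), p=assay_pr))]
        b0 = float(
            p.baseline_recist_median_mm
            * math.exp(rng.normal(0.0, p.baseline_recist_log_sd))
        )
        shed = float(p.shedding_median * math.exp(rng.normal(0.0, p.shedding_log_sd)))
        low_shedder = bool(rng.random() < p.low_shedder_prob)
        if low_shedder:
            shed *= p.low_shedder_factor
        background = float(
            p.background_cfdna_median
            * math.exp(rng.normal(0.0, p.background_cfdna_log_sd))
        )
        cls = classes[int(rng.choice(len(classes), p=class_pr))]
        largest = b0 * float(rng.uniform(*p.largest_lesion_frac))
        m_stage = "M1a" if largest <= 30 else ("M1b" if largest <= 80 else "M1c")
        extrahepatic = bool(rng.random() < p.extrahepatic_prob)
        ldh = float(
            p.ldh_uln
            * 0.9
            * (b0 / p.baseline_recist_median_mm) ** 0.5
            * math.exp(rng.normal(0.0, 0.25))
        )

        # ground-truth landmark status from the noiseless kinetics: positive
        # when detection of at least one window draw is more likely than not
        w0, w1 = p.landmark_window
        window_days = [d for d in p.sampling_days if w0 <= d <= w1]
        fp_mean = p.false_positive_rate * p.mean_droplets
        p_miss_all = 1.0
        for d in window_days:
            lam = _mut_conc_per_ml(cls, d, b0, shed, p) * react_factor + fp_mean
            p_det = float(sps.poisson.sf(p.truth_lob_droplets - 1, lam))
            p_miss_all *= 1.0 - p_det
        truly_pos = (1.0 - p_miss_all) > 0.5

        hazard = p.base_progression_hazard * (p.landmark_hr if truly_pos else 1.0)
        prog = float(rng.exponential(1.0 / hazard)) if hazard > 0 else math.inf
        progression_day: Optional[float] = prog if prog < p.followup_days else None
        death_day: Optional[float] = None
        if progression_day is not None:
            lag = float(
                p.death_lag_median_days * math.exp(rng.normal(0.0, p.death_lag_log_sd))
            )
            d = progression_day + lag
            if d < p.followup_days:
                death_day = d
        last_obs = death_day if death_day is not None else p.followup_days

        clinical_rows.append(
            {
                "patient_id": pid,
                "treatment_start_day": 0,
                "progression_day": progression_day,
                "death_day": death_day,
                "last_followup_day": last_obs,
                "ldh_value": round(ldh, 1),
                "ldh_above_uln": ldh > p.ldh_uln,
                "m_stage": m_stage,
                "extrahepatic": extrahepatic,
                "recist_sum_mm": round(b0, 1),
            }
        )

        for day in p.imaging_days:
            if day > last_obs:
                break
            sum_mm = b0 * _burden_frac(cls, day, p) * math.exp(
                rng.normal(0.0, p.recist_noise_sd)
            )
            if day <= 0:
                call = ""
            elif sum_mm < 2.0:
                call = "CR"
            else:
                change = (sum_mm - b0) / b0
                call = "PR" if change <= -0.30 else ("PD" if change >= 0.20 else "SD")
            imaging_rows.append(
                {
                    "patient_id": pid,
                    "day": day,
                    "recist_sum_mm": round(sum_mm, 1),
                    "response_call": call,
                }
            )

        draws = []
        for j, day in enumerate(p.sampling_days):
            if day > last_obs:
                break
            sample_id = f"{pid}_S{j:02d}"
            conc = _mut_conc_per_ml(cls, day, b0, shed, p)
            mut_copies = conc * react_factor
            p_det = float(
                sps.poisson.sf(p.truth_lob_droplets - 1, mut_copies + fp_mean)
            )
            wt_copies = background * react_factor
            for r in range(p.n_replicate_wells):
                droplet_rows.append(
                    simulate_well(
                        mut_copies / p.n_replicate_wells,
                        wt_copies / p.n_replicate_wells,
                        rng,
                        mean_droplets=p.mean_droplets,
                        droplet_volume_nl=p.droplet_volume_nl,
                        false_positive_rate=p.false_positive_rate,
                        well_id=f"{sample_id}_W{r}",
                        sample_id=sample_id,
                        assay=assay,
                    )
                )
            manifest_rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": pid,
                    "collection_day": day,
                    "plasma_ml": p.plasma_ml,
                    "cfdna_ng": round(wt_copies * NG_PER_GENOME, 2),
                }
            )
            draws.append(
                {
                    "day": day,
                    "burden_mm": b0 * _burden_frac(cls, day, p),
                    "mut_conc_per_ml": conc,
                    "expected_mut_copies_in_reaction": mut_copies,
                    "truly_detectable": p_det > 0.5,
                }
            )

        truth[pid] = {
            "assay": assay,
            "response_class": cls,
            "baseline_recist_mm": b0,
            "shedding_coef": shed,
            "low_shedder": low_shedder,
            "background_cfdna_per_ml": background,
            "true_landmark_positive": truly_pos,
            "progression_day": progression_day,
            "death_day": death_day,
            "draws": draws,
        }

    # NTC wells: false positives only, one run per assay in round robin
    ntc_assays = [assays[k % len(assays)] for k in range(p.n_ntc_wells)]
    for k, assay in enumerate(ntc_assays):
        droplet_rows.append(
            simulate_well(
                0.0,
                0.0,
                rng,
                mean_droplets=p.mean_droplets,
                droplet_volume_nl=p.droplet_volume_nl,
                false_positive_rate=p.false_positive_rate,
                well_id=f"NTC{k:02d}",
                sample_id=f"NTC{k:02d}",
                assay=assay,
                is_ntc=True,
            )
        )

    droplets = pd.DataFrame([dataclasses.asdict(w) for w in droplet_rows])
    return SimulatedCohort(
        droplets=droplets,
        manifest=pd.DataFrame(manifest_rows),
        clinical=pd.DataFrame(clinical_rows),
        imaging=pd.DataFrame(imaging_rows),
        truth=truth,
        params=p,
    )


__all__ = [
    "RESPONSE_CLASSES",
    "CohortParams",
    "SimulatedCohort",
    "simulate_well",
    "simulate_cohort",
]
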