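"""File-based pipeline tying quantification, classification and statistics.

Stages read and write plain CSV/JSON artifacts so every number in the final
report is traceable to an upstream file, and reruns on unchanged inputs are
byte-identical.  The stage functions operate on paths via :class:`RunConfig`;
the underlying table-level helpers (:func:`quantify_droplets`,
:func:`trajectories_from_maf`, :func:`courses_from_clinical`) work on
in-memory DataFrames and are what the simulation studies and tests use
directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ddpcr
from .ddpcr import (
    ASSAYS,
    ConcentrationEstimate,
    DropletWell,
    MafEstimate,
    estimate_lob,
    maf_with_ci,
    _conc_ci_arrays,
)
from .dynamics import (
    ProgressionCategory,
    Trajectory,
    classify_trajectory,
    relate_to_progression,
    sankey_counts,
)
from .errors import DataError, DependencyError, SchemaError
from .stats import (
    DAYS_PER_MONTH,
    DEFAULT_LANDMARK_WINDOW,
    ClinicalCourse,
    ImagingAssessment,
    baseline_status,
    landmark_status,
    pearson_correlation,
    stratified_survival,
    wilcoxon_rank_sum,
)

DROPLET_COLUMNS = [
    "well_id",
    "sample_id",
    "assay",
    "n_total",
    "n_mut_pos",
    "n_wt_pos",
    "is_ntc",
    "droplet_volume_nl",
]

MAF_COLUMNS = [
    "sample_id",
    "patient_id",
    "assay",
    "collection_day",
    "maf_pct",
    "maf_ci_low",
    "maf_ci_high",
    "mut_conc",
    "wt_conc",
    "detected",
    "mut_droplets",
]


@dataclass(frozen=True)
class RunConfig:
    """Paths and analysis settings of one pipeline run."""

    droplets_csv: str
    manifest_csv: str
    clinical_csv: str
    imaging_csv: str
    outdir: str
    window_days: tuple[float, float] = DEFAULT_LANDMARK_WINDOW
    k_min: int = ddpcr.DEFAULT_K_MIN
    days_per_month: float = DAYS_PER_MONTH
    undetected_as_zero: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "window_days" in raw:
            raw["window_days"] = tuple(raw["window_days"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_days"] = list(self.window_days)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def read_droplets_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: droplet table is empty")
    _require_columns(df, DROPLET_COLUMNS, str(path))
    for idx, row in df.iterrows():
        if row["assay"] not in ASSAYS:
            raise SchemaError(f"{path} row {idx}: unknown assay {row['assay']!r}")
        if row["n_total"] <= 0 or not (
            0 <= row["n_mut_pos"] <= row["n_total"]
            and 0 <= row["n_wt_pos"] <= row["n_total"]
        ):
            raise SchemaError(f"{path} row {idx}: invalid droplet counts")
    return df


def quantify_droplets(
    droplets: pd.DataFrame,
    manifest: Optional[pd.DataFrame] = None,
    k_min: int = ddpcr.DEFAULT_K_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample MAF table from a droplet-count table.

    Replicate wells of a sample/assay are pooled; the limit of blank is
    estimated per assay from the NTC wells.  Saturated samples (every droplet
    positive in a channel) are excluded and recorded in the metadata, which
    also carries the LOB per assay and the exclusion list.
    """
    _require_columns(droplets, DROPLET_COLUMNS, "droplet table")
    is_ntc = droplets["is_ntc"].astype(bool)
    ntc = droplets[is_ntc]
    lob_by_assay: dict[str, int] = {}
    for assay in ASSAYS:
        wells = [
            DropletWell(
                str(r.well_id), str(r.sample_id), r.assay, int(r.n_total),
                int(r.n_mut_pos), int(r.n_wt_pos), True, float(r.droplet_volume_nl),
            )
            for r in ntc[ntc["assay"] == assay].itertuples()
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lob_by_assay[assay] = estimate_lob(wells, k_min=k_min)

    samples = droplets[~is_ntc]
    grouped = samples.groupby(["sample_id", "assay"], sort=True)
    vol = grouped["droplet_volume_nl"].agg(["min", "max"])
    if (vol["min"] != vol["max"]).any():
        raise DataError("mixed droplet volumes within one sample/assay group")
    agg = grouped.agg(
        n_total=("n_total", "sum"),
        n_mut_pos=("n_mut_pos", "sum"),
        n_wt_pos=("n_wt_pos", "sum"),
        droplet_volume_nl=("droplet_volume_nl", "first"),
    ).reset_index()

    saturated = agg[
        (agg["n_mut_pos"] >= agg["n_total"]) | (agg["n_wt_pos"] >= agg["n_total"])
    ]
    excluded = sorted(saturated["sample_id"].tolist())
    agg = agg[~agg["sample_id"].isin(excluded)].reset_index(drop=True)

    n_tot = agg["n_total"].to_numpy(float)
    v = agg["droplet_volume_nl"].to_numpy(float)
    mut = _conc_ci_arrays(agg["n_mut_pos"].to_numpy(float), n_tot, v)
    wt = _conc_ci_arrays(agg["n_wt_pos"].to_numpy(float), n_tot, v)

    rows = []
    for i, r in agg.iterrows():
        mut_est = ConcentrationEstimate(
            float(mut[0][i]), float(mut[1][i]), float(mut[2][i]), float(mut[3][i]),
            int(r.n_mut_pos), int(r.n_total),
        )
        wt_est = ConcentrationEstimate(
            float(wt[0][i]), float(wt[1][i]), float(wt[2][i]), float(wt[3][i]),
            int(r.n_wt_pos), int(r.n_total),
        )
        est = maf_with_ci(mut_est, wt_est, lob_by_assay[r.assay], int(r.n_mut_pos))
        rows.append(
            {
                "sample_id": r.sample_id,
                "assay": r.assay,
                "maf_pct": est.maf_pct,
                "maf_ci_low": est.maf_ci_low,
                "maf_ci_high": est.maf_ci_high,
                "mut_conc": mut_est.conc_per_ul,
                "wt_conc": wt_est.conc_per_ul,
                "detected": est.detected,
                "mut_droplets": int(r.n_mut_pos),
            }
        )
    maf = pd.DataFrame(rows)

    if manifest is not None:
        _require_columns(manifest, ["sample_id", "patient_id", "collection_day"],
                         "sample manifest")
        maf = maf.merge(
            manifest[["sample_id", "patient_id", "collection_day"]],
            on="sample_id",
            how="left",
        )
        if maf["patient_id"].isna().any():
            orphans = maf.loc[maf["patient_id"].isna(), "sample_id"].tolist()
            raise DataError(f"samples missing from manifest: {orphans}")
    else:
        maf["patient_id"] = maf["sample_id"]
        maf["collection_day"] = np.nan
    maf = maf[MAF_COLUMNS].sort_values(
        ["patient_id", "collection_day", "sample_id"]
    ).reset_index(drop=True)
    meta = {
        "k_min": k_min,
        "lob_by_assay": lob_by_assay,
        "saturated_samples": excluded,
        "n_samples": int(len(maf)),
    }
    return maf, meta


def _maf_estimate_from_row(row) -> MafEstimate:
    def _conc(value: float, n_pos: int, n_total: int) -> ConcentrationEstimate:
        return ConcentrationEstimate(
            float("nan"), float(value), float("nan"), float("nan"), n_pos, n_total
        )

    return MafEstimate(
        maf_pct=float(row.maf_pct),
        maf_ci_low=float(row.maf_ci_low),
        maf_ci_high=float(row.maf_ci_high),
        mut_conc=_conc(row.mut_conc, int(row.mut_droplets), 0),
        wt_conc=_conc(row.wt_conc, 0, 0),
        detected=bool(row.detected),
        mut_droplets=int(row.mut_droplets),
        sample_id=str(row.sample_id),
        assay=str(row.assay),
        collection_day=float(row.collection_day),
    )


def trajectories_from_maf(maf: pd.DataFrame) -> dict[str, Trajectory]:
    """One time-ordered trajectory per patient from a MAF table."""
    _require_columns(maf, MAF_COLUMNS, "MAF table")
    out: dict[str, Trajectory] = {}
    for pid, grp in maf.groupby("patient_id", sort=True):
        assays = grp["assay"].unique()
        if len(assays) != 1:
            raise DataError(f"patient {pid}: multiple assays in MAF table")
        grp = grp.sort_values("collection_day")
        samples = tuple(_maf_estimate_from_row(r) for r in grp.itertuples())
        out[str(pid)] = Trajectory(str(pid), str(assays[0]), samples)
    return out


def _opt(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def courses_from_clinical(
    clinical: pd.DataFrame, imaging: Optional[pd.DataFrame] = None
) -> dict[str, ClinicalCourse]:
    _require_columns(
        clinical,
        ["patient_id", "progression_day", "death_day", "last_followup_day"],
        "clinical table",
    )
    if clinical["patient_id"].duplicated().any():
        raise DataError("duplicate patient ids in clinical table")
    img_by_pid: dict[str, tuple[ImagingAssessment, ...]] = {}
    if imaging is not None:
        _require_columns(imaging, ["patient_id", "day", "recist_sum_mm"], "imaging")
        for pid, grp in imaging.groupby("patient_id"):
            grp = grp.sort_values("day")
            def _call(r):
                v = getattr(r, "response_call", "")
                return "" if pd.isna(v) else str(v)

            img_by_pid[str(pid)] = tuple(
                ImagingAssessment(float(r.day), float(r.recist_sum_mm), _call(r))
                for r in grp.itertuples()
            )
    out = {}
    for r in clinical.itertuples():
        pid = str(r.patient_id)
        out[pid] = ClinicalCourse(
            patient_id=pid,
            last_followup_day=float(r.last_followup_day),
            progression_day=_opt(r.progression_day),
            death_day=_opt(r.death_day),
            ldh_value=_opt(getattr(r, "ldh_value", float("nan"))),
            ldh_above_uln=(
                None if pd.isna(getattr(r, "ldh_above_uln", None))
                else bool(r.ldh_above_uln)
            ),
            m_stage=(
                None if pd.isna(getattr(r, "m_stage", None)) else str(r.m_stage)
            ),
            extrahepatic=(
                None if pd.isna(getattr(r, "extrahepatic", None))
                else bool(r.extrahepatic)
            ),
            recist_sum_mm=_opt(getattr(r, "recist_sum_mm", float("nan"))),
            imaging=img_by_pid.get(pid, ()),
        )
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_quantify(config: RunConfig) -> Path:
    """Droplet counts -> per-sample MAF table + metadata sidecar."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    droplets = read_droplets_csv(config.droplets_csv)
    manifest = pd.read_csv(config.manifest_csv)
    maf, meta = quantify_droplets(droplets, manifest, k_min=config.k_min)
    _write_csv(maf, outdir / "maf_table.csv")
    meta["config_hash"] = config.config_hash
    _write_json(meta, outdir / "quantify_meta.json")
    return outdir / "maf_table.csv"


def _load_cohort(config: RunConfig):
    outdir = Path(config.outdir)
    maf_path = outdir / "maf_table.csv"
    if not maf_path.exists():
        raise DependencyError(f"missing upstream artifact {maf_path}; run quantify")
    maf = pd.read_csv(maf_path)
    trajs = trajectories_from_maf(maf)
    clinical = pd.read_csv(config.clinical_csv)
    imaging = pd.read_csv(config.imaging_csv)
    courses = courses_from_clinical(clinical, imaging)
    missing = sorted(set(trajs) - set(courses))
    if missing:
        raise DataError(f"patients missing from clinical table: {missing}")
    return maf, trajs, courses


def run_classify(config: RunConfig) -> dict[str, Path]:
    """Trajectory events, progression relations, Sankey table, swimmer JSON."""
    outdir = Path(config.outdir)
    maf, trajs, courses = _load_cohort(config)
    pids = sorted(trajs)

    event_rows, relation_rows, swimmer = [], [], {}
    for pid in pids:
        traj, course = trajs[pid], courses[pid]
        summary = classify_trajectory(traj)
        for ev in summary.events:
            event_rows.append(
                {
                    "patient_id": pid,
                    "kind": ev.kind.value,
                    "from_day": ev.from_day,
                    "to_day": ev.to_day,
                    "confirmed": ev.confirmed.value,
                }
            )
        rel = relate_to_progression(traj, course)
        relation_rows.append(
            {
                "patient_id": pid,
                "category": rel.category.value,
                "lead_time_days": rel.lead_time_days,
                "any_increase": rel.any_increase,
            }
        )
        calls = [a.response_call for a in course.imaging if a.response_call]
        bor = min(calls, key=("CR", "PR", "SD", "PD").index) if calls else ""
        swimmer[pid] = {
            "samples": [
                {"day": s.collection_day, "detected": s.detected, "maf_pct": s.maf_pct}
                for s in traj.samples
            ],
            "events": [
                {"kind": e.kind.value, "day": e.to_day, "confirmed": e.confirmed.value}
                for e in summary.events
            ],
            "progression_day": course.progression_day,
            "death_day": course.death_day,
            "last_followup_day": course.last_followup_day,
            "best_overall_response": bor,
        }

    sankey = sankey_counts([(trajs[p], courses[p]) for p in pids])
    paths = {
        "events": outdir / "events.csv",
        "relations": outdir / "relations.csv",
        "sankey": outdir / "sankey.csv",
        "swimmer": outdir / "swimmer.json",
    }
    _write_csv(pd.DataFrame(event_rows), paths["events"])
    _write_csv(pd.DataFrame(relation_rows), paths["relations"])
    _write_csv(sankey, paths["sankey"])
    _write_json({"config_hash": config.config_hash, "patients": swimmer},
                paths["swimmer"])
    return paths


def run_landmark(config: RunConfig) -> Path:
    """Per-patient landmark ctDNA status inside the configured window."""
    outdir = Path(config.outdir)
    _, trajs, courses = _load_cohort(config)
    rows = []
    for pid in sorted(trajs):
        st = landmark_status(trajs[pid], courses[pid], config.window_days)
        base: Optional[bool]
        try:
            base = baseline_status(trajs[pid])
        except DataError:
            base = None
        rows.append(
            {
                "patient_id": pid,
                "window_start_day": st.window[0],
                "window_end_day": st.window[1],
                "landmark_status": st.status,
                "n_samples_in_window": st.n_samples_in_window,
                "baseline_detected": base,
            }
        )
    _write_csv(pd.DataFrame(rows), outdir / "landmark.csv")
    return outdir / "landmark.csv"


def _baseline_maf_frame(maf, trajs, courses, undetected_as_zero: bool):
    rows = []
    for pid in sorted(trajs):
        pre = [s for s in trajs[pid].samples if s.collection_day <= 0]
        if not pre:
            continue
        s = pre[-1]
        if not s.detected and not undetected_as_zero:
            continue
        c = courses[pid]
        rows.append(
            {
                "patient_id": pid,
                "maf_pct": s.maf_pct if s.detected else 0.0,
                "detected": s.detected,
                "ldh_value": c.ldh_value,
                "ldh_above_uln": c.ldh_above_uln,
                "extrahepatic": c.extrahepatic,
                "m_stage": c.m_stage,
                "recist_sum_mm": c.recist_sum_mm,
            }
        )
    return pd.DataFrame(rows)


def baseline_association_report(
    maf: pd.DataFrame,
    trajs: Mapping[str, Trajectory],
    courses: Mapping[str, ClinicalCourse],
    undetected_as_zero: bool = True,
) -> pd.DataFrame:
    """Baseline MAF vs clinical covariates: correlations and group tests."""
    df = _baseline_maf_frame(maf, trajs, courses, undetected_as_zero)
    rows = []

    def _corr(name, x_col):
        sub = df.dropna(subset=[x_col])
        try:
            r, p = pearson_correlation(sub[x_col], sub["maf_pct"])
            rows.append({"analysis": name, "test": "pearson", "n": len(sub),
                         "statistic": r, "p_value": p})
        except DataError as exc:
            rows.append({"analysis": name, "test": "pearson", "n": len(sub),
                         "statistic": float("nan"), "p_value": float("nan"),
                         "note": str(exc)})

    def _group(name, mask_col, split):
        sub = df.dropna(subset=[mask_col])
        grp_a = sub.loc[split(sub), "maf_pct"]
        grp_b = sub.loc[~split(sub), "maf_pct"]
        if grp_a.empty or grp_b.empty:
            rows.append({"analysis": name, "test": "wilcoxon", "n": len(sub),
                         "statistic": float("nan"), "p_value": float("nan"),
                         "note": "a group is empty"})
            return
        w, p = wilcoxon_rank_sum(grp_a.to_numpy(), grp_b.to_numpy())
        rows.append({"analysis": name, "test": "wilcoxon", "n": len(sub),
                     "statistic": w, "p_value": p})

    _corr("baseline_maf_vs_ldh", "ldh_value")
    _corr("baseline_maf_vs_recist_sum", "recist_sum_mm")
    _group("baseline_maf_by_ldh_above_uln", "ldh_above_uln",
           lambda d: d["ldh_above_uln"].astype(bool))
    _group("baseline_maf_by_extrahepatic", "extrahepatic",
           lambda d: d["extrahepatic"].astype(bool))
    _group("baseline_maf_by_m_stage_m1bc", "m_stage",
           lambda d: d["m_stage"].isin(["M1b", "M1c"]))
    return pd.DataFrame(rows)


def survival_report(
    trajs: Mapping[str, Trajectory],
    courses: Mapping[str, ClinicalCourse],
    window_days: tuple[float, float],
    days_per_month: float = DAYS_PER_MONTH,
) -> tuple[dict, pd.DataFrame]:
    """Stratified OS/PFS summaries plus KM curve coordinates."""
    cohort = [(trajs[p], courses[p]) for p in sorted(trajs)]
    summary: dict = {"window_days": list(window_days)}
    curve_rows = []
    for grouping in ("baseline", "landmark"):
        for endpoint in ("OS", "PFS"):
            key = f"{grouping}_{endpoint.lower()}"
            try:
                res = stratified_survival(cohort, grouping, endpoint, window_days)
            except DataError as exc:
                summary[key] = {"error": str(exc)}
                continue
            summary[key] = {
                "n_negative": res.n_negative,
                "n_positive": res.n_positive,
                "median_negative_months": res.median_months("negative"),
                "median_positive_months": res.median_months("positive"),
                "median_negative_days": res.median_negative_days,
                "median_positive_days": res.median_positive_days,
                "logrank_chi_square": res.chi_square,
                "logrank_p": res.p_value,
            }
            for arm, curve in (
                ("negative", res.curve_negative),
                ("positive", res.curve_positive),
            ):
                for t, r, d, s in zip(
                    curve.event_times, curve.at_risk, curve.n_events, curve.survival
                ):
                    curve_rows.append(
                        {
                            "grouping": grouping,
                            "endpoint": endpoint,
                            "arm": arm,
                            "time_days": t,
                            "at_risk": r,
                            "n_events": d,
                            "survival": s,
                        }
                    )
    return summary, pd.DataFrame(curve_rows)


def patient_series(
    maf: pd.DataFrame, courses: Mapping[str, ClinicalCourse]
) -> pd.DataFrame:
    """Long table of per-patient MAF and RECIST %-change series (overlay data).

    Percent change of the target-lesion sum is relative to the baseline
    imaging row (day <= 0), so the baseline row is 0 by construction.
    """
    rows = []
    for r in maf.itertuples():
        rows.append(
            {
                "patient_id": r.patient_id,
                "day": r.collection_day,
                "series": "maf_pct",
                "value": r.maf_pct,
                "ci_low": r.maf_ci_low,
                "ci_high": r.maf_ci_high,
            }
        )
    for pid, course in courses.items():
        base = [a for a in course.imaging if a.day <= 0]
        if not base:
            continue
        b = base[-1].recist_sum_mm
        for a in course.imaging:
            rows.append(
                {
                    "patient_id": pid,
                    "day": a.day,
                    "series": "recist_pct_change",
                    "value": 100.0 * (a.recist_sum_mm - b) / b if b else float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["patient_id", "series", "day"])
        .reset_index(drop=True)
    )


def run_report(config: RunConfig) -> dict[str, Path]:
    """Assemble the report bundle: survival, correlations, overlay series."""
    outdir = Path(config.outdir)
    for upstream in ("maf_table.csv", "events.csv", "landmark.csv"):
        if not (outdir / upstream).exists():
            raise DependencyError(f"missing upstream artifact {outdir / upstream}")
    maf, trajs, courses = _load_cohort(config)
    summary, curves = survival_report(
        trajs, courses, config.window_days, config.days_per_month
    )
    summary["config_hash"] = config.config_hash
    assoc = baseline_association_report(
        maf, trajs, courses, config.undetected_as_zero
    )
    series = patient_series(maf, courses)
    paths = {
        "survival_summary": outdir / "survival_summary.json",
        "km_curves": outdir / "km_curves.csv",
        "correlations": outdir / "correlations.csv",
        "patient_series": outdir / "patient_series.csv",
    }
    _write_json(summary, paths["survival_summary"])
    _write_csv(curves, paths["km_curves"])
    _write_csv(assoc, paths["correlations"])
    _write_csv(series, paths["patient_series"])
    return paths


__all__ = [
    "DROPLET_COLUMNS",
    "MAF_COLUMNS",
    "RunConfig",
    "read_droplets_csv",
    "quantify_droplets",
    "trajectories_from_maf",
    "courses_from_clinical",
    "baseline_association_report",
    "survival_report",
    "patient_series",
    "run_quantify",
    "run_classify",
    "run_landmark",
    "run_report",
]
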