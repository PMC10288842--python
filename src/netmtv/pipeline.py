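"""End-to-end orchestration: imaging -> response -> biomarker -> survival.

`run_pipeline` ties the stages together in the order of the clinical
workflow: segment baseline and interim PET scans against the
liver-referenced threshold, classify the volumetric response, build the
MTV / chromogranin A composite on the cohort table, and run the survival
analyses (univariable and multivariable Cox with Schoenfeld diagnostics,
Kaplan-Meier, fixed-horizon ROC, log-rank on the ROC split).  Every
threshold and seed used is recorded in the report for provenance, and a
rerun with identical config and seed produces byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker, mtvseg, petvol, response, survival

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("netmtv")

DEFAULT_COVARIATES = ("age", "gender", "grading", "ldh", "ggt_log", "mtv_cga_composite")


@dataclass(frozen=True)
class RunConfig:
    cohort_csv: str | Path | None = None
    baseline_pet: str | Path | None = None
    interim_pet: str | Path | None = None
    exclusion_mask: str | Path | None = None
    liver_voi_center: tuple[float, float, float] | None = None
    liver_voi_ml: float = 5.0
    threshold_override: float | None = None
    pr_threshold_pct: float = response.PR_THRESHOLD_PCT
    pd_threshold_pct: float = response.PD_THRESHOLD_PCT
    roc_horizon_months: float = 60.0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    seed: int = 0
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if not self.pr_threshold_pct < 0 < self.pd_threshold_pct:
            raise ValueError(
                f"response thresholds must satisfy PR < 0 < PD, got "
                f"({self.pr_threshold_pct}, {self.pd_threshold_pct})"
            )
        if self.roc_horizon_months <= 0:
            raise ValueError("ROC horizon must be > 0")
        if self.baseline_pet is not None and self.liver_voi_center is None and self.threshold_override is None:
            raise ValueError("imaging stage needs a liver VOI center or a threshold override")


def _segment(cfg: RunConfig, pet_path: str | Path, threshold: float) -> mtvseg.SegmentationResult:
    vol = petvol.read_volume(pet_path)
    excl = None
    if cfg.exclusion_mask is not None:
        excl = petvol.read_volume(cfg.exclusion_mask).voxels > 0.5
    return mtvseg.segment_mtv(vol, threshold, exclusion_mask=excl)


def _imaging_stage(cfg: RunConfig) -> dict:
    assert cfg.baseline_pet is not None
    baseline = petvol.read_volume(cfg.baseline_pet)
    if cfg.threshold_override is not None:
        thr = float(cfg.threshold_override)
        liver_stats = None
    else:
        voi = petvol.SphereVOI(center=cfg.liver_voi_center, volume_ml=cfg.liver_voi_ml, label="liver")
        liver_stats = petvol.reference_stats(baseline, voi)
        thr = mtvseg.segmentation_threshold(liver_stats)
    logger.info("segmentation threshold: %.4f SUV", thr)

    seg_b = _segment(cfg, cfg.baseline_pet, thr)
    block = {
        "threshold_suv": thr,
        "threshold_source": "override" if cfg.threshold_override is not None else "liver_voi",
        "liver_stats": None
        if liver_stats is None
        else {
            "suv_mean": liver_stats.suv_mean,
            "suv_max": liver_stats.suv_max,
            "suv_sd": liver_stats.suv_sd,
            "n_voxels": liver_stats.n_voxels,
        },
        "baseline": _seg_block(seg_b),
    }
    if cfg.interim_pet is not None:
        seg_i = _segment(cfg, cfg.interim_pet, thr)
        block["interim"] = _seg_block(seg_i)
        pct = response.percent_change(seg_b.total_mtv_ml, seg_i.total_mtv_ml)
        cls = response.classify_response(pct, cfg.pr_threshold_pct, cfg.pd_threshold_pct)
        block["response"] = {
            "pct_change": pct,
            "class": cls.value,
            "responder": response.is_responder(cls),
        }
    return block


def _seg_block(seg: mtvseg.SegmentationResult) -> dict:
    out = {
        "total_mtv_ml": seg.total_mtv_ml,
        "n_lesions": len(seg.lesions),
        "excluded_component_count": seg.excluded_component_count,
        "lesions": [
            {"lesion_id": i, "volume_ml": L.volume_ml, "suv_max": L.suv_max, "suv_mean": L.suv_mean}
            for i, L in enumerate(seg.lesions)
        ],
    }
    if seg.lesions:
        mx, mn = mtvseg.largest_lesion_metrics(seg)
        out["largest_lesion"] = {"suv_max": mx, "suv_mean": mn}
    return out


def add_composite(df: pd.DataFrame) -> pd.DataFrame:
    """Append `ggt_log` and the `mtv_cga_composite` column to a cohort table."""
    out = df.copy()
    ids = tuple(out["id"])
    comp = biomarker.composite_score(
        biomarker.MarkerVector(ids, out["mtv_ml"].to_numpy()),
        biomarker.MarkerVector(ids, out["cga"].to_numpy()),
    )
    out["mtv_cga_composite"] = comp.scores
    if "ggt_log" not in out.columns:
        out["ggt_log"] = np.log(out["ggt"].to_numpy())
    return out


def _encode(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if out["gender"].dtype == object:
        out["gender"] = (out["gender"] == "male").astype(int)
    if out["grading"].dtype == object:
        out["grading"] = out["grading"].map({"G1": 1, "G2": 2, "G3": 3})
    return out


def _cox_block(fit: survival.CoxFit, ph: pd.Series | None = None) -> dict:
    rows = {}
    for cov in fit.summary.index:
        rows[cov] = {
            "coef": float(fit.summary.loc[cov, "coef"]),
            "hazard_ratio": float(fit.summary.loc[cov, "hazard_ratio"]),
            "ci95_low": float(fit.summary.loc[cov, "ci95_low"]),
            "ci95_high": float(fit.summary.loc[cov, "ci95_high"]),
            "p_value": float(fit.summary.loc[cov, "p_value"]),
        }
        if ph is not None:
            rows[cov]["p_schoenfeld"] = float(ph[cov])
    return {"n": fit.n, "n_events": fit.n_events, "covariates": rows}


def _roc_block(r: survival.RocResult) -> dict:
    return {
        "auc": r.auc,
        "auc_ci95": list(r.auc_ci95),
        "cutoff": r.cutoff,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
        "ci_method": r.ci_method,
    }


def _survival_stage(cfg: RunConfig, cohort: pd.DataFrame) -> dict:
    df = _encode(add_composite(cohort))
    n_events = int(df["event"].sum())
    if n_events < 10 * len(cfg.covariates):
        logger.warning(
            "only %d events for %d covariates (< 10 per covariate); "
            "multivariable estimates may be unstable",
            n_events,
            len(cfg.covariates),
        )

    uni = {}
    for cov in cfg.covariates:
        try:
            fit = survival.fit_cox(df, [cov])
            uni[cov] = _cox_block(fit, survival.schoenfeld_ph_test(fit))["covariates"][cov]
        except survival.DegenerateModelError as exc:
            uni[cov] = {"error": str(exc)}
    multi_fit = survival.fit_cox(df, list(cfg.covariates))
    multi = _cox_block(multi_fit, survival.schoenfeld_ph_test(multi_fit))

    km = survival.km_estimate(df["os_months"], df["event"])
    horizon = cfg.roc_horizon_months
    block: dict = {
        "univariable_cox": uni,
        "multivariable_cox": multi,
        "km_overall": {
            "event_times": km.event_times.tolist(),
            "survival_prob": km.survival_prob.tolist(),
            "n_at_risk": km.n_at_risk.tolist(),
            "survival_at_horizon": survival.survival_at(km, horizon),
        },
    }
    for marker in ("mtv_ml", "cga"):
        try:
            roc = survival.roc_fixed_horizon(
                df[marker], df["os_months"], df["event"], horizon, seed=cfg.seed
            )
        except survival.DegenerateOutcomeError as exc:
            block[f"roc_{marker}"] = {"error": str(exc)}
            continue
        block[f"roc_{marker}"] = _roc_block(roc)
        hi = df[marker] > roc.cutoff
        if hi.any() and (~hi).any():
            chi2, p = survival.logrank(
                df.loc[hi, "os_months"], df.loc[hi, "event"],
                df.loc[~hi, "os_months"], df.loc[~hi, "event"],
            )
            block[f"logrank_{marker}_cutoff"] = {"chi2": chi2, "p_value": p, "cutoff": roc.cutoff}
        u, p = survival.mannwhitney(
            df.loc[df["event"] == 1, marker], df.loc[df["event"] == 0, marker]
        )
        block[f"mannwhitney_{marker}_by_event"] = {"U": u, "p_value": p}
    return block


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and return (and optionally write) the report."""
    cfg.validate()
    report: dict = {
        "config": {
            "seed": cfg.seed,
            "threshold_override": cfg.threshold_override,
            "pr_threshold_pct": cfg.pr_threshold_pct,
            "pd_threshold_pct": cfg.pd_threshold_pct,
            "roc_horizon_months": cfg.roc_horizon_months,
            "covariates": list(cfg.covariates),
            "liver_voi_ml": cfg.liver_voi_ml,
        }
    }
    if cfg.baseline_pet is not None:
        report["imaging"] = _imaging_stage(cfg)
    if cfg.cohort_csv is not None:
        cohort = pd.read_csv(cfg.cohort_csv)
        report["survival"] = _survival_stage(cfg, cohort)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if cfg.cohort_csv is not None:
            add_composite(pd.read_csv(cfg.cohort_csv)).to_csv(out / "cohort_with_composite.csv", index=False)
        logger.info("report written to %s", out / "report.json")
    return report
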