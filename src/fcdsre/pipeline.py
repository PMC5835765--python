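"""End-to-end run: normalization -> threshold search -> size classification ->
association analyses, with table-shaped TSV reports.

The run is deterministic given its inputs: every reported number is computed
once, stored on the RunReport, and rendering only formats stored values.
Lesion volumes may be supplied directly in the cohort CSV (the common case);
label-map volumetry is available separately through :mod:`fcdsre.volumetry`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import association as assoc
from .association import ModelSpec, Predictor
from .cohort import (Cohort, CrossTab2x2, build_published_cohort, cross_tab,
                     percent, read_cohort)
from .threshold import find_threshold
from .volumetry import cohort_mean_icv, log10_volume, normalize_volume, thalamus_sides

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_tables"]


@dataclass
class RunConfig:
    cohort_csv: Optional[str] = None  # None -> built-in fixture cohort
    out_dir: Optional[str] = None
    gain_mode: str = "standard"
    mean_icv_scope: str = "all"       # all | measurable
    threshold_on: str = "normalized"  # normalized | raw
    test_dialect: str = "auto"        # auto | fisher | pearson | yates
    fixed_threshold_mm3: Optional[float] = None  # skip the search, classify here
    seed: int = 0

    def validate(self):
        if self.gain_mode not in ("standard", "literal"):
            raise ValueError("gain_mode must be standard or literal")
        if self.mean_icv_scope not in ("all", "measurable"):
            raise ValueError("mean_icv_scope must be all or measurable")
        if self.threshold_on not in ("normalized", "raw"):
            raise ValueError("threshold_on must be normalized or raw")
        if self.test_dialect not in ("auto", "fisher", "pearson", "yates"):
            raise ValueError("unknown test dialect")


@dataclass
class RunReport:
    config: RunConfig
    n_patients: int
    n_measurable: int
    mean_icv_mm3: float
    threshold: dict
    n_small: int
    n_large: int
    volumes: pd.DataFrame = field(repr=False)
    table1: pd.DataFrame = field(repr=False)
    table2: pd.DataFrame = field(repr=False)
    table3: pd.DataFrame = field(repr=False)
    table4: pd.DataFrame = field(repr=False)


def _dialect_test(tab: CrossTab2x2, dialect: str) -> assoc.TestResult:
    if dialect == "fisher":
        return assoc.fisher_exact_2x2(tab)
    if dialect == "pearson":
        return assoc.chi_square_2x2(tab, yates=False)
    if dialect == "yates":
        return assoc.chi_square_2x2(tab, yates=True)
    return assoc.auto_2x2_test(tab)


def _fmt_p(p: float) -> str:
    return f"{p:.3f}"


def _binary_row(cohort, name, pred, dialect) -> dict:
    sre = [r for r in cohort if r.sre]
    non = [r for r in cohort if not r.sre]
    a = sum(1 for r in sre if pred(r))
    c = sum(1 for r in non if pred(r))
    tab = CrossTab2x2(a, len(sre) - a, c, len(non) - c,
                      row_label=name, col_label="sre")
    test = _dialect_test(tab.transpose(), dialect)
    return {"characteristic": name,
            "sre": f"{a} ({percent(a, len(sre))}%)",
            "non_sre": f"{c} ({percent(c, len(non))}%)",
            "p": _fmt_p(test.p_two_sided), "method": test.method}


def _continuous_row(cohort, name, getter) -> dict:
    xs = np.array([getter(r) for r in cohort if r.sre], dtype=float)
    ys = np.array([getter(r) for r in cohort if not r.sre], dtype=float)
    test = assoc.wilcoxon_rank_sum(xs, ys)
    fmt = lambda v: (f"{np.mean(v):,.1f} ({np.min(v):,.1f}–{np.max(v):,.1f})")
    return {"characteristic": name, "sre": fmt(xs), "non_sre": fmt(ys),
            "p": _fmt_p(test.p_two_sided), "method": test.method}


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the fixed stage order and (optionally) persist artifacts.

    Stages: load/validate cohort; cohort mean ICV; ICV normalization; entropy
    threshold search on the measurable (volume, initial-report) pairs; size
    classification; clinical, volumetric, regression, and subgroup analyses.
    """
    config.validate()
    cohort = (read_cohort(config.cohort_csv) if config.cohort_csv
              else build_published_cohort())
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "tables").mkdir(exist_ok=True)

    mean_icv = cohort_mean_icv(cohort, scope=config.mean_icv_scope)
    meas = cohort.measurable
    vol_rows = []
    for r in meas:
        norm = normalize_volume(r.lesion_volume_mm3, r.icv_mm3, mean_icv)
        row = {"patient_id": r.patient_id, "raw_mm3": r.lesion_volume_mm3,
               "icv_mm3": r.icv_mm3, "normalized_mm3": norm,
               "log10_normalized": log10_volume(norm)}
        if r.thal_left_mm3 is not None and r.thal_right_mm3 is not None:
            ipsi, contra = thalamus_sides(r.thal_left_mm3, r.thal_right_mm3,
                                          r.side)
            row["thal_ipsi_mm3"] = normalize_volume(ipsi, r.icv_mm3, mean_icv)
            row["thal_contra_mm3"] = normalize_volume(contra, r.icv_mm3, mean_icv)
        vol_rows.append(row)
    volumes = pd.DataFrame(vol_rows)

    key = "normalized_mm3" if config.threshold_on == "normalized" else "raw_mm3"
    v = volumes[key].to_numpy()
    labels = np.array([r.mri_report_positive for r in meas])
    if config.fixed_threshold_mm3 is not None:
        t = float(config.fixed_threshold_mm3)
        thr_dict = {"threshold_mm3": t, "mode": "fixed",
                    "gain_bits": None, "parent_entropy_bits": None,
                    "n_small": int((v < t).sum()),
                    "n_large": int((v >= t).sum()), "gain_curve": []}
        thr = None
        small_by_id = dict(zip(volumes["patient_id"], v < t))
    else:
        thr = find_threshold(v, labels, mode=config.gain_mode)
        thr_dict = thr.to_dict()
        small_by_id = dict(zip(volumes["patient_id"], v < thr.threshold))
    volumes["small"] = volumes["patient_id"].map(small_by_id)

    def small(r):
        return small_by_id.get(r.patient_id, False)

    n_small = int(sum(small_by_id.values()))
    n_large = len(meas) - n_small

    dialect = config.test_dialect
    # clinical comparison (one row per characteristic)
    table1 = pd.DataFrame([
        _binary_row(cohort, "male", lambda r: r.sex == "M", dialect),
        _continuous_row(cohort, "age_at_onset_years", lambda r: r.age_at_onset),
        _continuous_row(cohort, "age_at_mri_years", lambda r: r.age_at_mri),
        _continuous_row(cohort, "duration_months", lambda r: r.duration_months),
        _binary_row(cohort, "low_seizure_frequency",
                    lambda r: r.seizure_frequency == "low", dialect),
        _binary_row(cohort, "mri_report_positive",
                    lambda r: r.mri_report_positive, dialect),
        _binary_row(cohort, "left_side", lambda r: r.side == "left", dialect),
        _binary_row(cohort, "bosd", lambda r: r.bosd, dialect),
        _binary_row(cohort, "fcd_type_iib",
                    lambda r: r.fcd_subtype == "IIb", dialect),
        _binary_row(cohort, "invasive_eeg", lambda r: r.invasive_eeg, dialect),
        _binary_row(cohort, "engel_I", lambda r: r.engel_I, dialect),
        _binary_row(cohort, "small_lesion", small, dialect),
    ])

    # volumetric comparison with ANCOVA on age, sex, ICV (Bonferroni over the
    # three volumetric comparisons: lesion, ipsilateral and contralateral
    # thalamus)
    sre_mask = np.array([r.sre for r in meas])
    covs = pd.DataFrame({
        "age": [r.age_at_mri for r in meas],
        "male": [1.0 if r.sex == "M" else 0.0 for r in meas],
        "icv": [r.icv_mm3 for r in meas],
    })
    # a zero-variance covariate (e.g. constant ICV) carries no information
    # and would make the design singular
    covs = covs.loc[:, covs.nunique() > 1]
    t2_rows = []
    rng_fmt = lambda x: (f"{np.median(x):,.2f} "
                         f"({np.min(x):,.2f}–{np.max(x):,.2f})")
    ms_fmt = lambda x: f"{np.mean(x):,.2f} ± {np.std(x, ddof=1):,.2f}"
    nv = volumes["normalized_mm3"].to_numpy()
    t2_rows.append({"measure": "lesion_normalized_mm3_center_range",
                    "sre": rng_fmt(nv[sre_mask]), "non_sre": rng_fmt(nv[~sre_mask]),
                    "p": "", "significant": ""})
    lg = volumes["log10_normalized"].to_numpy()
    res = assoc.ancova_group_test(lg, sre_mask.astype(float),
                                  covariates=covs[["age", "male"]],
                                  alpha_family=3)
    t2_rows.append({"measure": "log10_lesion_normalized",
                    "sre": ms_fmt(lg[sre_mask]), "non_sre": ms_fmt(lg[~sre_mask]),
                    "p": _fmt_p(res.p_two_sided),
                    "significant": str(res.significant_bonferroni)})
    for col, label in (("thal_ipsi_mm3", "thalamus_ipsilateral_mm3"),
                       ("thal_contra_mm3", "thalamus_contralateral_mm3")):
        if col in volumes.columns and volumes[col].notna().all():
            tv = volumes[col].to_numpy()
            res = assoc.ancova_group_test(tv, sre_mask.astype(float),
                                          covariates=covs, alpha_family=3)
            t2_rows.append({"measure": label, "sre": ms_fmt(tv[sre_mask]),
                            "non_sre": ms_fmt(tv[~sre_mask]),
                            "p": _fmt_p(res.p_two_sided),
                            "significant": str(res.significant_bonferroni)})
    table2 = pd.DataFrame(t2_rows)

    # multivariable logistic regression; frontal lobe is the location reference
    df = cohort.to_frame()
    df["small"] = [small(r) for r in cohort]
    df["male"] = df["sex"] == "M"
    meas_df = df[df["lesion_volume_mm3"].notna()].reset_index(drop=True)
    spec = ModelSpec("sre", [
        Predictor("age_at_mri", "continuous"),
        Predictor("male", "binary"),
        Predictor("small", "binary"),
        Predictor("location", "categorical", reference="frontal"),
    ])
    t3_rows = [{"predictor": "location[frontal]", "risk_ratio": "1",
                "ci": "–", "p": "–", "note": "reference"}]
    for est in assoc.logistic_fit(meas_df, spec):
        t3_rows.append({
            "predictor": est.term,
            "risk_ratio": f"{est.ratio:.2f}" if est.ratio < 1e4 else f"{est.ratio:.2E}",
            "ci": f"{est.ci_low:.2f}–{est.ci_high:.2f}"
                  if "separated" not in est.diagnostics else "–",
            "p": _fmt_p(est.p),
            "note": ";".join(est.diagnostics)})
    table3 = pd.DataFrame(t3_rows)

    # subgroup analysis by FCD subtype
    t4_rows = []
    for subtype in ("IIa", "IIb"):
        sub = [r for r in meas if r.fcd_subtype == subtype]
        if not sub:
            continue
        s_m = [small(r) for r in sub]
        sre_m = [r.sre for r in sub]
        tab = CrossTab2x2(sum(a and b for a, b in zip(s_m, sre_m)),
                          sum(a and not b for a, b in zip(s_m, sre_m)),
                          sum(b and not a for a, b in zip(s_m, sre_m)),
                          sum(not a and not b for a, b in zip(s_m, sre_m)),
                          row_label="small", col_label="sre")
        test = _dialect_test(tab, dialect)
        vols_s = np.array([r.lesion_volume_mm3 for r in sub])
        t4_rows.append({
            "subtype": subtype, "n_measurable": len(sub),
            "small_sre": tab.a, "small_non_sre": tab.b,
            "large_sre": tab.c, "large_non_sre": tab.d,
            "pct_small_in_sre": percent(tab.a, tab.a + tab.c),
            "pct_small_in_non_sre": percent(tab.b, tab.b + tab.d),
            "volume_range": rng_fmt(vols_s),
            "p": _fmt_p(test.p_two_sided), "method": test.method})
    table4 = pd.DataFrame(t4_rows)

    report = RunReport(
        config=config, n_patients=len(cohort), n_measurable=len(meas),
        mean_icv_mm3=mean_icv, threshold=thr_dict,
        n_small=n_small, n_large=n_large, volumes=volumes,
        table1=table1, table2=table2, table3=table3, table4=table4)

    if out_dir:
        volumes.to_csv(out_dir / "volumes.csv", index=False)
        payload = dict(report.threshold)
        payload["mean_icv_mm3"] = mean_icv
        (out_dir / "threshold.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        render_tables(report, out_dir / "tables")
        logger.info("pipeline artifacts written to %s", out_dir)
    return report


def render_tables(report: RunReport, out_dir, style: str = "all") -> list:
    """Write the stored report tables as TSV; formatting only, no
    recomputation.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    styles = ("table1", "table2", "table3", "table4") if style == "all" else (style,)
    written = []
    for s in styles:
        df = getattr(report, s, None)
        if df is None:
            raise ValueError(f"unknown table style {style!r}")
        path = out_dir / f"{s}.tsv"
        df.fillna("NA").to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
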