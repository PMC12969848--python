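"""End-to-end study analysis.

Primary endpoint: region-level absolute TBSA error of the model versus the
physician-median error, both referenced to the panel consensus. With
``delta_i = |model_i - panel_i| - |physmedian_i - panel_i|`` per region-case,
non-inferiority is declared when the one-sided 95% upper bound of the
patient-level cluster-bootstrap distribution of the Hodges-Lehmann median of
the deltas is at or below the margin (default 3 percentage points);
superiority when that bound is below 0. Secondary battery: accuracy and
agreement tables, calibration, depth cross-tabulation and weighted kappa,
subgroups, threshold discrimination, and image-quality sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement_metrics as am
from .consensus import ConsensusResult, consensus_for_tables, preconsensus_agreement, ratings_matrices
from .resampling import BootstrapConfig, ClusteredValues, cluster_bootstrap, cluster_bootstrap_ci_for_metric, hodges_lehmann
from .study_data import AnalysisSet, StudyTables, build_analysis_sets


@dataclass(frozen=True)
class PairedDelta:
    region_case_id: str
    patient_id: str
    model_abs_error: float
    physician_abs_error: float

    @property
    def delta(self) -> float:
        return self.model_abs_error - self.physician_abs_error


@dataclass
class NonInferiorityResult:
    hl_estimate: float
    upper_bound_95: float
    margin: float
    decision: str  # superior | non_inferior | not_demonstrated
    n_cases: int
    n_patients: int
    config: BootstrapConfig = field(default_factory=BootstrapConfig)
    replicates: Optional[np.ndarray] = None  # bootstrap HL values, for audit


@dataclass
class SubgroupSummary:
    stratum_kind: str
    stratum: str
    n: int
    model_mean_abs_error: Optional[float] = None
    model_median_abs_error: Optional[float] = None
    physician_mean_abs_error: Optional[float] = None
    physician_median_abs_error: Optional[float] = None


def compute_paired_deltas(
    tables: StudyTables,
    case_ids: Sequence[str],
    panel: dict[str, ConsensusResult],
    physicians: dict[str, ConsensusResult],
) -> list[PairedDelta]:
    """One paired delta per analysis-set case; errors are absolute, vs panel."""
    deltas = []
    for cid in sorted(case_ids):
        model = [r for r in tables.ratings_for(cid, "model") if r.usable_tbsa]
        if not model or cid not in panel or cid not in physicians:
            raise ValueError(f"case {cid} lacks a model rating or a consensus")
        ref = panel[cid].consensus_tbsa
        deltas.append(
            PairedDelta(
                region_case_id=cid,
                patient_id=tables.case(cid).patient_id,
                model_abs_error=abs(model[0].tbsa_percent - ref),
                physician_abs_error=abs(physicians[cid].consensus_tbsa - ref),
            )
        )
    return deltas


def _decide(upper_bound: float, margin: float) -> str:
    if upper_bound < 0.0:
        return "superior"
    if upper_bound <= margin:
        return "non_inferior"
    return "not_demonstrated"


def primary_analysis(
    deltas: Sequence[PairedDelta],
    margin: float = 3.0,
    boot: Optional[BootstrapConfig] = None,
) -> NonInferiorityResult:
    """Paired non-inferiority test of the model vs the physician median.

    Hodges-Lehmann point estimate of the deltas; one-sided 95% upper bound
    from the patient-level cluster bootstrap (5000 resamples by default).
    The strongest applicable label is reported: superior (upper bound < 0)
    implies non-inferior.
    """
    if not deltas:
        raise ValueError("no paired deltas")
    if margin <= 0:
        raise ValueError("margin must be positive")
    boot = boot or BootstrapConfig(n_resamples=5000, side="upper_one_sided")
    if boot.side != "upper_one_sided":
        raise ValueError("primary analysis uses the one-sided upper bound")
    data = ClusteredValues(
        np.array([d.delta for d in deltas]),
        np.array([d.patient_id for d in deltas]),
    )
    res = cluster_bootstrap(data, hodges_lehmann, boot)
    return NonInferiorityResult(
        hl_estimate=res.point_estimate,
        upper_bound_95=res.ci_high,
        margin=margin,
        decision=_decide(res.ci_high, margin),
        n_cases=len(deltas),
        n_patients=int(np.unique(data.cluster_ids).size),
        config=boot,
        replicates=res.replicate_values,
    )


def sensitivity_one_region_per_patient(
    deltas: Sequence[PairedDelta],
    margin: float = 3.0,
    n_repeats: int = 200,
    seed: int = 0,
    boot_resamples: int = 5000,
) -> dict:
    """Primary analysis repeated on one randomly chosen region-case per patient.

    Each repeat samples one region-case uniformly per patient (clusters then
    singletons) and reruns the primary analysis; reports the distribution of
    upper bounds and how often each decision was reached.
    """
    by_patient: dict[str, list[PairedDelta]] = {}
    for d in deltas:
        by_patient.setdefault(d.patient_id, []).append(d)
    patients = sorted(by_patient)
    rng = np.random.default_rng(seed)
    upper_bounds, decisions = [], []
    for rep in range(n_repeats):
        chosen = [
            by_patient[p][rng.integers(0, len(by_patient[p]))] for p in patients
        ]
        res = primary_analysis(
            chosen,
            margin=margin,
            boot=BootstrapConfig(
                n_resamples=boot_resamples, side="upper_one_sided", seed=seed + rep + 1
            ),
        )
        upper_bounds.append(res.upper_bound_95)
        decisions.append(res.decision)
    ub = np.asarray(upper_bounds)
    return {
        "n_repeats": n_repeats,
        "max_upper_bound": float(ub.max()),
        "median_upper_bound": float(np.median(ub)),
        "fraction_non_inferior": float(np.mean([d != "not_demonstrated" for d in decisions])),
        "decisions": decisions,
    }


def subgroup_analysis(
    tables: StudyTables,
    deltas: Sequence[PairedDelta],
    strata: Sequence[str] = ("age_group", "anatomical_region"),
) -> list[SubgroupSummary]:
    """Descriptive per-stratum error summaries for both methods."""
    out: list[SubgroupSummary] = []
    for kind in strata:
        levels: dict[str, list[PairedDelta]] = {}
        for d in deltas:
            case = tables.case(d.region_case_id)
            label = case.age_group if kind == "age_group" else case.anatomical_region
            levels.setdefault(label, []).append(d)
        domain = (
            ("pediatric", "adult")
            if kind == "age_group"
            else ("face_head", "torso", "upper_extremity", "lower_extremity")
        )
        for label in domain:
            ds = levels.get(label, [])
            if not ds:
                out.append(SubgroupSummary(kind, label, 0))
                continue
            me = np.array([d.model_abs_error for d in ds])
            pe = np.array([d.physician_abs_error for d in ds])
            out.append(
                SubgroupSummary(
                    kind,
                    label,
                    len(ds),
                    float(me.mean()),
                    float(np.median(me)),
                    float(pe.mean()),
                    float(np.median(pe)),
                )
            )
    return out


@dataclass
class ThresholdDiscrimination:
    level: str  # "patient" or "region"
    n: int
    n_positive: int
    model: Optional[am.RocResult]
    physician: Optional[am.RocResult]
    delong_z: Optional[float]
    delong_p: Optional[float]
    note: str = ""


def threshold_discrimination(
    tables: StudyTables,
    case_ids: Sequence[str],
    panel: dict[str, ConsensusResult],
    physicians: dict[str, ConsensusResult],
    adult_threshold: float = 20.0,
    pediatric_threshold: float = 10.0,
    level: str = "patient",
) -> ThresholdDiscrimination:
    """Discrimination of clinically large burns (adults >= 20%, pediatrics
    >= 10% whole-body TBSA by default).

    TBSA is aggregated to the patient by summing region contributions (the
    clinical cut-points are whole-body); the panel sum defines the binary
    truth. Reports AUC per method and the DeLong comparison; if a class is
    absent the result is undefined and returned with count diagnostics.
    """
    rows = []
    for cid in sorted(case_ids):
        case = tables.case(cid)
        model = [r for r in tables.ratings_for(cid, "model") if r.usable_tbsa][0]
        rows.append(
            {
                "patient_id": case.patient_id,
                "age_group": case.age_group,
                "model": model.tbsa_percent,
                "physician": physicians[cid].consensus_tbsa,
                "panel": panel[cid].consensus_tbsa,
            }
        )
    df = pd.DataFrame(rows)
    if level == "patient":
        df = df.groupby("patient_id", as_index=False).agg(
            age_group=("age_group", "first"),
            model=("model", "sum"),
            physician=("physician", "sum"),
            panel=("panel", "sum"),
        )
    thr = np.where(df["age_group"] == "adult", adult_threshold, pediatric_threshold)
    labels = (df["panel"].to_numpy() >= thr).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        return ThresholdDiscrimination(
            level, len(labels), n_pos, None, None, None, None,
            note=f"discrimination undefined: {n_pos} of {len(labels)} units above threshold",
        )
    # distance to the age-specific threshold makes scores comparable across ages
    ra, rb, z, p = am.roc_auc_delong(
        df["model"].to_numpy() - thr, df["physician"].to_numpy() - thr, labels
    )
    return ThresholdDiscrimination(level, len(labels), n_pos, ra, rb, z, p)


def image_quality_sensitivity(
    tables: StudyTables,
    deltas: Sequence[PairedDelta],
    low_quality_cutoff: float = 8.0,
) -> dict:
    """Association of image quality with absolute error, and a re-run of the
    error summaries excluding low-quality cases (quality < cutoff)."""
    qual, me, pe, keep = [], [], [], []
    for d in deltas:
        q = tables.case(d.region_case_id).image_quality
        if q is None:
            continue
        qual.append(q)
        me.append(d.model_abs_error)
        pe.append(d.physician_abs_error)
        keep.append(q >= low_quality_cutoff)
    if len(qual) < 3:
        raise ValueError("need image quality for >= 3 cases")
    try:
        rho_model = am.spearman_rho(qual, me)
    except am.DegenerateInputError:
        rho_model = None
    try:
        rho_phys = am.spearman_rho(qual, pe)
    except am.DegenerateInputError:
        rho_phys = None
    keep_arr = np.asarray(keep)
    me_a, pe_a = np.asarray(me), np.asarray(pe)
    filtered = {}
    if keep_arr.any():
        fm = am.abs_error_summary(me_a[keep_arr], np.zeros(keep_arr.sum()))
        fp = am.abs_error_summary(pe_a[keep_arr], np.zeros(keep_arr.sum()))
        filtered = {
            "model_mean_abs_error": fm[0],
            "model_median_abs_error": fm[1],
            "physician_mean_abs_error": fp[0],
            "physician_median_abs_error": fp[1],
        }
    return {
        "n_with_quality": len(qual),
        "n_retained": int(keep_arr.sum()),
        "spearman_model": rho_model,
        "spearman_physician": rho_phys,
        "filtered_summary": filtered,
    }


def agreement_report(
    tables: StudyTables,
    case_ids: Sequence[str],
    panel: dict[str, ConsensusResult],
    physicians: dict[str, ConsensusResult],
    boot: Optional[BootstrapConfig] = None,
) -> dict:
    """Accuracy/agreement analogues of the study's summary tables.

    TBSA block (per method vs panel): mean/median absolute error, inclusive
    3/5 p.p. tolerance bands, Lin's CCC (with cluster-bootstrap CI when a
    config is given), Bland-Altman bias and limits, calibration fit. Depth
    block: distributions, exact agreement and quadratic-weighted kappa of
    model and physician consensus vs panel.
    """
    cids = sorted(case_ids)
    panel_tbsa = np.array([panel[c].consensus_tbsa for c in cids])
    model_tbsa = np.array(
        [[r for r in tables.ratings_for(c, "model") if r.usable_tbsa][0].tbsa_percent for c in cids]
    )
    phys_tbsa = np.array([physicians[c].consensus_tbsa for c in cids])
    patient_ids = np.array([tables.case(c).patient_id for c in cids])
    panel_depth = np.array([panel[c].consensus_depth for c in cids])
    model_depth = np.array(
        [[r for r in tables.ratings_for(c, "model") if r.assessable][0].depth_class for c in cids]
    )
    phys_depth = np.array([physicians[c].consensus_depth for c in cids])

    def tbsa_block(est: np.ndarray) -> dict:
        mean_ae, med_ae, w3, w5 = am.abs_error_summary(est, panel_tbsa)
        bias, lo, hi = am.bland_altman(est, panel_tbsa)
        cal = am.calibration_fit(est, panel_tbsa)
        block = {
            "mean_abs_error": mean_ae,
            "median_abs_error": med_ae,
            "within_3pp": w3,
            "within_5pp": w5,
            "ccc": am.lin_ccc(est, panel_tbsa),
            "bias": bias,
            "loa_low": lo,
            "loa_high": hi,
            "calibration_intercept": cal.intercept,
            "calibration_slope": cal.slope,
            "calibration_r_squared": cal.r_squared,
        }
        if boot is not None:
            res = cluster_bootstrap_ci_for_metric(
                est, panel_tbsa, patient_ids, lambda a, b: am.lin_ccc(a, b), boot
            )
            block["ccc_ci_low"], block["ccc_ci_high"] = res.ci_low, res.ci_high
        return block

    def depth_block(cmp_depth: np.ndarray) -> dict:
        cm = am.confusion_matrix(panel_depth, cmp_depth)
        try:
            kw = am.weighted_kappa(cm, "quadratic")
        except am.DegenerateInputError:
            kw = None
        block = {
            "confusion": cm,
            "exact_agreement": cm.exact_agreement,
            "kappa_w": kw,
        }
        if boot is not None and kw is not None:
            res = cluster_bootstrap_ci_for_metric(
                panel_depth.astype(float),
                cmp_depth.astype(float),
                patient_ids,
                lambda a, b: am.weighted_kappa(am.confusion_matrix(a.astype(int), b.astype(int))),
                boot,
            )
            block["kappa_w_ci_low"], block["kappa_w_ci_high"] = res.ci_low, res.ci_high
        return block

    phys_tbsa_mat, phys_depth_mat, _ = ratings_matrices(tables, cids, "physician")
    panel_tbsa_mat, panel_depth_mat, _ = ratings_matrices(tables, cids, "panelist")
    phys_agree = (
        preconsensus_agreement(phys_tbsa_mat, phys_depth_mat)
        if phys_tbsa_mat.shape[0] >= 2 and phys_tbsa_mat.shape[1] >= 2
        else None
    )
    panel_agree = (
        preconsensus_agreement(panel_tbsa_mat, panel_depth_mat)
        if panel_tbsa_mat.shape[0] >= 2 and panel_tbsa_mat.shape[1] >= 2
        else None
    )
    return {
        "n_cases": len(cids),
        "model_vs_panel": tbsa_block(model_tbsa),
        "physician_vs_panel": tbsa_block(phys_tbsa),
        "model_depth": depth_block(model_depth),
        "physician_depth": depth_block(phys_depth),
        "physician_preconsensus": phys_agree,
        "panel_preconsensus": panel_agree,
    }


@dataclass
class StudyReport:
    fas: AnalysisSet
    pp: AnalysisSet
    agreement: dict
    primary: NonInferiorityResult
    sensitivity: dict
    subgroups: list[SubgroupSummary]
    discrimination: ThresholdDiscrimination
    quality: dict
    deltas: list[PairedDelta]


def run_study(
    tables: StudyTables,
    margin: float = 3.0,
    boot_resamples: int = 5000,
    agreement_resamples: int = 2000,
    seed: int = 0,
    adult_threshold: float = 20.0,
    pediatric_threshold: float = 10.0,
    quality_cutoff: float = 8.0,
    sensitivity_repeats: int = 200,
    sensitivity_boot_resamples: Optional[int] = None,
    with_agreement_ci: bool = True,
) -> StudyReport:
    """Execute the full analysis pipeline on validated study tables."""
    fas, pp = build_analysis_sets(tables)
    if not fas.included_case_ids:
        raise ValueError("full analysis set is empty")
    cids = sorted(fas.included_case_ids)
    panel = consensus_for_tables(tables, cids, "panelist")
    physicians = consensus_for_tables(tables, cids, "physician")
    agree_boot = (
        BootstrapConfig(n_resamples=agreement_resamples, side="two_sided", seed=seed)
        if with_agreement_ci
        else None
    )
    agreement = agreement_report(tables, cids, panel, physicians, boot=agree_boot)
    deltas = compute_paired_deltas(tables, cids, panel, physicians)
    primary = primary_analysis(
        deltas,
        margin=margin,
        boot=BootstrapConfig(n_resamples=boot_resamples, side="upper_one_sided", seed=seed),
    )
    sensitivity = sensitivity_one_region_per_patient(
        deltas,
        margin=margin,
        n_repeats=sensitivity_repeats,
        seed=seed,
        boot_resamples=sensitivity_boot_resamples or boot_resamples,
    )
    subgroups = subgroup_analysis(tables, deltas)
    discrimination = threshold_discrimination(
        tables, cids, panel, physicians, adult_threshold, pediatric_threshold
    )
    quality = image_quality_sensitivity(tables, deltas, quality_cutoff)
    return StudyReport(fas, pp, agreement, primary, sensitivity, subgroups, discrimination, quality, deltas)


def write_report_tables(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Render the report as deterministic CSV/JSON files (fixed column order,
    values rounded to the precision the summary tables use)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    tbsa_rows = []
    for method in ("model_vs_panel", "physician_vs_panel"):
        b = report.agreement[method]
        tbsa_rows.append(
            {
                "comparison": method,
                "n": report.agreement["n_cases"],
                "mean_abs_error_pp": round(b["mean_abs_error"], 3),
                "median_abs_error_pp": round(b["median_abs_error"], 3),
                "within_3pp_pct": round(100 * b["within_3pp"], 1),
                "within_5pp_pct": round(100 * b["within_5pp"], 1),
                "ccc": round(b["ccc"], 3),
                "bias_pp": round(b["bias"], 3),
                "loa_low_pp": round(b["loa_low"], 3),
                "loa_high_pp": round(b["loa_high"], 3),
                "calibration_intercept": round(b["calibration_intercept"], 3),
                "calibration_slope": round(b["calibration_slope"], 3),
                "calibration_r_squared": round(b["calibration_r_squared"], 3),
            }
        )
    p = out / "table2_analogue.csv"
    pd.DataFrame(tbsa_rows).to_csv(p, index=False)
    paths.append(p)

    depth_rows = []
    for method in ("model_depth", "physician_depth"):
        b = report.agreement[method]
        depth_rows.append(
            {
                "comparison": method,
                "exact_agreement_pct": round(100 * b["exact_agreement"], 1),
                "kappa_w": round(b["kappa_w"], 3) if b["kappa_w"] is not None else "",
                "confusion_matrix": json.dumps([list(r) for r in b["confusion"].counts]),
            }
        )
    p = out / "table3_analogue.csv"
    pd.DataFrame(depth_rows).to_csv(p, index=False)
    paths.append(p)

    sub_rows = [
        {
            "stratum_kind": s.stratum_kind,
            "stratum": s.stratum,
            "n": s.n,
            "model_mean_abs_error_pp": "" if s.model_mean_abs_error is None else round(s.model_mean_abs_error, 3),
            "model_median_abs_error_pp": "" if s.model_median_abs_error is None else round(s.model_median_abs_error, 3),
            "physician_mean_abs_error_pp": "" if s.physician_mean_abs_error is None else round(s.physician_mean_abs_error, 3),
            "physician_median_abs_error_pp": "" if s.physician_median_abs_error is None else round(s.physician_median_abs_error, 3),
        }
        for s in report.subgroups
    ]
    p = out / "subgroups.csv"
    pd.DataFrame(
        sub_rows,
        columns=[
            "stratum_kind",
            "stratum",
            "n",
            "model_mean_abs_error_pp",
            "model_median_abs_error_pp",
            "physician_mean_abs_error_pp",
            "physician_median_abs_error_pp",
        ],
    ).to_csv(p, index=False)
    paths.append(p)

    primary = {
        "hl_estimate_pp": round(report.primary.hl_estimate, 4),
        "upper_bound_95_pp": round(report.primary.upper_bound_95, 4),
        "margin_pp": report.primary.margin,
        "decision": report.primary.decision,
        "n_cases": report.primary.n_cases,
        "n_patients": report.primary.n_patients,
        "n_resamples": report.primary.config.n_resamples,
        "seed": report.primary.config.seed,
        "sensitivity_one_region_per_patient": {
            k: v for k, v in report.sensitivity.items() if k != "decisions"
        },
    }
    p = out / "primary_result.json"
    p.write_text(json.dumps(primary, indent=2, sort_keys=True) + "\n")
    paths.append(p)

    if report.primary.replicates is not None:
        rep_dir = out / "replicates"
        rep_dir.mkdir(exist_ok=True)
        p = rep_dir / "primary_hl.csv"
        np.savetxt(p, report.primary.replicates, fmt="%.6f", header="hl_delta_pp", comments="")
        paths.append(p)

    p = out / "run_log.txt"
    lines = [
        f"full analysis set: {len(report.fas.included_case_ids)} region-cases",
        f"per-protocol set: {len(report.pp.included_case_ids)} region-cases",
        *(f"excluded {cid}: {reason}" for cid, reason in report.pp.exclusion_log),
        f"primary decision: {report.primary.decision} "
        f"(HL {report.primary.hl_estimate:.4f}, ub {report.primary.upper_bound_95:.4f}, "
        f"margin {report.primary.margin})",
        f"discrimination: n={report.discrimination.n}, "
        f"positives={report.discrimination.n_positive} {report.discrimination.note}".rstrip(),
    ]
    p.write_text("\n".join(lines) + "\n")
    paths.append(p)
    return paths
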