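"""Exploratory subgroup summaries (age group, anatomical region), patient-level
threshold discrimination (adults >= 20% TBSA, pediatrics >= 10%), and the
image-quality sensitivity analysis on the synthetic study.
"""

import json
from pathlib import Path

from burneval.analysis_pipeline import (
    compute_paired_deltas,
    image_quality_sensitivity,
    subgroup_analysis,
    threshold_discrimination,
)
from burneval.consensus import consensus_for_tables
from burneval.study_data import build_analysis_sets, read_study

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "synthetic_study"


def main() -> None:
    tables = read_study(DATA / "cases.csv", DATA / "ratings.csv")
    fas, _ = build_analysis_sets(tables)
    cids = sorted(fas.included_case_ids)
    panel = consensus_for_tables(tables, cids, "panelist")
    physicians = consensus_for_tables(tables, cids, "physician")
    deltas = compute_paired_deltas(tables, cids, panel, physicians)

    subgroups = subgroup_analysis(tables, deltas)
    for s in subgroups:
        if s.n:
            print(
                f"{s.stratum_kind}/{s.stratum}: n={s.n}, model MAE "
                f"{s.model_mean_abs_error:.2f}, physician MAE {s.physician_mean_abs_error:.2f}"
            )

    disc = threshold_discrimination(tables, cids, panel, physicians)
    if disc.model is None:
        print(f"threshold discrimination: {disc.note}")
        disc_out = {"note": disc.note, "n": disc.n, "n_positive": disc.n_positive}
    else:
        print(
            f"threshold discrimination ({disc.n_positive}/{disc.n} patients above cut): "
            f"model AUC {disc.model.auc:.3f}, physician AUC {disc.physician.auc:.3f}, "
            f"DeLong p {disc.delong_p:.3f}"
        )
        disc_out = {
            "n": disc.n,
            "n_positive": disc.n_positive,
            "model_auc": disc.model.auc,
            "physician_auc": disc.physician.auc,
            "delong_z": disc.delong_z,
            "delong_p": disc.delong_p,
        }

    quality = image_quality_sensitivity(tables, deltas, low_quality_cutoff=8.0)
    print(
        f"image quality: Spearman rho (model) {quality['spearman_model']:.3f}, "
        f"(physician) {quality['spearman_physician']:.3f}; "
        f"{quality['n_retained']}/{quality['n_with_quality']} cases retained at cutoff 8"
    )

    out = {
        "threshold_discrimination": disc_out,
        "image_quality": {k: v for k, v in quality.items()},
    }
    (ROOT / "subgroups_and_sensitivity.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
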