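"""Generate the synthetic study: 52 patients, ~64 burn region-cases, rated by
one calibration-compressed model rater, 18 physicians and a 3-member expert
panel. Writes cases.csv / ratings.csv / truth.csv under results/synthetic_study/.
"""

from pathlib import Path

from burneval.study_data import write_study
from burneval.synthetic_cohort import generate_study, preset_emulated_study, write_truth

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_study"


def main() -> None:
    config, raters = preset_emulated_study(seed=SEED)
    tables, truth = generate_study(config, raters)
    OUT.mkdir(parents=True, exist_ok=True)
    write_study(tables, OUT / "cases.csv", OUT / "ratings.csv")
    write_truth(truth, OUT / "truth.csv")
    n_patients = len({c.patient_id for c in tables.cases})
    print(
        f"simulated {len(tables.cases)} region-cases on {n_patients} patients "
        f"({len(tables.ratings)} ratings) -> {OUT}"
    )


if __name__ == "__main__":
    main()
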