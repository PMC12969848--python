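import json

import numpy as np
import pytest

from burneval.analysis_pipeline import (
    PairedDelta,
    compute_paired_deltas,
    image_quality_sensitivity,
    primary_analysis,
    run_study,
    sensitivity_one_region_per_patient,
    subgroup_analysis,
    threshold_discrimination,
    write_report_tables,
)
from burneval.consensus import consensus_for_tables
from burneval.resampling import BootstrapConfig
from burneval.study_data import build_analysis_sets
from burneval.synthetic_cohort import (
    CohortConfig,
    generate_study,
    noise_free_raters,
    preset_emulated_study,
)
from conftest import make_case, make_rating
from burneval.study_data import Rating, StudyTables


def _deltas(values, patient_ids=None):
    patient_ids = patient_ids or [f"P{i}" for i in range(len(values))]
    return [
        PairedDelta(f"C{i}", pid, model_abs_error=max(v, 0.0) + 1.0, physician_abs_error=max(v, 0.0) + 1.0 - v)
        for i, (v, pid) in enumerate(zip(values, patient_ids))
    ]


class TestPairedDeltas:
    def test_arithmetic(self, small_study):
        fas, _ = build_analysis_sets(small_study)
        cids = sorted(fas.included_case_ids)
        panel = consensus_for_tables(small_study, cids, "panelist")
        phys = consensus_for_tables(small_study, cids, "physician")
        deltas = compute_paired_deltas(small_study, cids, panel, phys)
        # model = base+1, panel median = base, physician median = base -> delta = 1
        for d in deltas:
            assert d.model_abs_error == pytest.approx(1.0)
            assert d.physician_abs_error == pytest.approx(0.0)
            assert d.delta == pytest.approx(1.0)

    def test_noise_free_cohort_all_deltas_zero(self):
        tables, _ = generate_study(CohortConfig(seed=12), noise_free_raters())
        fas, _ = build_analysis_sets(tables)
        cids = sorted(fas.included_case_ids)
        panel = consensus_for_tables(tables, cids, "panelist")
        phys = consensus_for_tables(tables, cids, "physician")
        deltas = compute_paired_deltas(tables, cids, panel, phys)
        assert all(d.delta == pytest.approx(0.0) for d in deltas)

    def test_missing_consensus_raises(self, small_study):
        with pytest.raises(ValueError):
            compute_paired_deltas(small_study, ["C1"], {}, {})


class TestPrimaryAnalysis:
    def test_all_zero_deltas_non_inferior_not_superior(self):
        res = primary_analysis(_deltas([0.0] * 10), boot=BootstrapConfig(200, side="upper_one_sided"))
        assert res.hl_estimate == 0.0 and res.upper_bound_95 == 0.0
        assert res.decision == "non_inferior"

    def test_large_deltas_not_demonstrated(self):
        res = primary_analysis(_deltas([10.0] * 10), boot=BootstrapConfig(200, side="upper_one_sided"))
        assert res.hl_estimate == 10.0 and res.decision == "not_demonstrated"

    def test_clearly_negative_effect_detected_as_superior(self, rng):
        wins = 0
        for rep in range(40):
            vals = rng.normal(-1.0, 0.5, size=64)
            res = primary_analysis(
                _deltas(list(vals)),
                boot=BootstrapConfig(500, side="upper_one_sided", seed=rep),
            )
            wins += res.decision == "superior"
        assert wins >= 38  # >= 95% power at this effect size

    def test_decision_monotone_in_shift(self, rng):
        vals = list(rng.normal(0.0, 1.0, size=30))
        order = {"superior": 0, "non_inferior": 1, "not_demonstrated": 2}
        prev = -1
        for shift in (-3.0, 0.0, 3.0, 6.0):
            res = primary_analysis(
                _deltas([v + shift for v in vals]),
                boot=BootstrapConfig(300, side="upper_one_sided", seed=1),
            )
            assert order[res.decision] >= prev
            prev = order[res.decision]

    def test_margin_bracketing(self, rng):
        vals = list(rng.normal(1.0, 1.0, size=30))
        huge = primary_analysis(_deltas(vals), margin=1e9, boot=BootstrapConfig(300, side="upper_one_sided"))
        assert huge.decision != "not_demonstrated"
        tiny = primary_analysis(_deltas(vals), margin=1e-9, boot=BootstrapConfig(300, side="upper_one_sided"))
        assert tiny.decision == "not_demonstrated"

    def test_empty_and_bad_margin(self):
        with pytest.raises(ValueError):
            primary_analysis([])
        with pytest.raises(ValueError):
            primary_analysis(_deltas([1.0]), margin=0.0)


class TestSensitivityOneRegion:
    def test_single_region_patients_every_repeat_identical(self):
        deltas = _deltas([0.5, 1.0, -0.2, 0.1])
        out = sensitivity_one_region_per_patient(deltas, n_repeats=5, boot_resamples=200)
        assert out["max_upper_bound"] == pytest.approx(out["median_upper_bound"])

    def test_all_zero_deltas(self):
        deltas = _deltas([0.0] * 6, patient_ids=["P1", "P1", "P2", "P2", "P3", "P3"])
        out = sensitivity_one_region_per_patient(deltas, n_repeats=10, boot_resamples=100)
        assert out["max_upper_bound"] == 0.0
        assert out["fraction_non_inferior"] == 1.0


class TestSubgroups:
    def test_constructed_stratum_means(self):
        cases = [
            make_case("C1", "P1", age=5.0),
            make_case("C2", "P2", age=40.0),
        ]
        tables = StudyTables(cases=cases, ratings=[])
        deltas = [
            PairedDelta("C1", "P1", model_abs_error=1.0, physician_abs_error=1.0),
            PairedDelta("C2", "P2", model_abs_error=2.0, physician_abs_error=2.0),
        ]
        out = subgroup_analysis(tables, deltas, strata=("age_group",))
        by = {s.stratum: s for s in out}
        assert by["pediatric"].model_mean_abs_error == 1.0
        assert by["adult"].model_mean_abs_error == 2.0

    def test_empty_stratum_emitted_with_zero_n(self):
        tables = StudyTables(cases=[make_case("C1", "P1", age=5.0)], ratings=[])
        deltas = [PairedDelta("C1", "P1", 1.0, 1.0)]
        out = subgroup_analysis(tables, deltas, strata=("age_group",))
        adult = [s for s in out if s.stratum == "adult"][0]
        assert adult.n == 0 and adult.model_mean_abs_error is None

    def test_strata_partition_the_analysis_set(self):
        tables, _ = generate_study(CohortConfig(seed=13), noise_free_raters())
        fas, _ = build_analysis_sets(tables)
        cids = sorted(fas.included_case_ids)
        panel = consensus_for_tables(tables, cids, "panelist")
        phys = consensus_for_tables(tables, cids, "physician")
        deltas = compute_paired_deltas(tables, cids, panel, phys)
        out = subgroup_analysis(tables, deltas)
        for kind in ("age_group", "anatomical_region"):
            assert sum(s.n for s in out if s.stratum_kind == kind) == len(deltas)


class TestThresholdDiscrimination:
    def _setup(self, seed=14):
        tables, _ = generate_study(CohortConfig(seed=seed), noise_free_raters())
        fas, _ = build_analysis_sets(tables)
        cids = sorted(fas.included_case_ids)
        panel = consensus_for_tables(tables, cids, "panelist")
        phys = consensus_for_tables(tables, cids, "physician")
        return tables, cids, panel, phys

    def test_noise_free_perfect_discrimination(self):
        tables, cids, panel, phys = self._setup()
        out = threshold_discrimination(
            tables, cids, panel, phys, adult_threshold=3.0, pediatric_threshold=3.0
        )
        if out.model is None:
            pytest.skip("degenerate class split for this seed")
        assert out.model.auc == 1.0 and out.physician.auc == 1.0
        assert out.delong_p == 1.0

    def test_all_below_threshold_undefined_with_diagnostics(self):
        tables, cids, panel, phys = self._setup()
        out = threshold_discrimination(
            tables, cids, panel, phys, adult_threshold=1e6, pediatric_threshold=1e6
        )
        assert out.model is None and "0 of" in out.note

    def test_patient_level_aggregation_sums_regions(self):
        cases = [
            make_case("C1", "P1", age=40.0),
            make_case("C2", "P1", age=40.0),
        ]
        ratings = []
        for cid, t in (("C1", 12.0), ("C2", 12.0)):
            ratings.append(make_rating(cid, "m", "model", t, 1))
            ratings.append(make_rating(cid, "d", "physician", t, 1))
            ratings.append(make_rating(cid, "p", "panelist", t, 1))
        # one more patient below threshold so both classes exist
        cases.append(make_case("C3", "P2", age=40.0))
        ratings += [
            make_rating("C3", "m", "model", 1.0, 1),
            make_rating("C3", "d", "physician", 1.0, 1),
            make_rating("C3", "p", "panelist", 1.0, 1),
        ]
        tables = StudyTables(cases=cases, ratings=ratings)
        panel = consensus_for_tables(tables, ["C1", "C2", "C3"], "panelist")
        phys = consensus_for_tables(tables, ["C1", "C2", "C3"], "physician")
        out = threshold_discrimination(tables, ["C1", "C2", "C3"], panel, phys)
        # P1 sums to 24 >= 20: a positive exists only through summation
        assert out.n == 2 and out.n_positive == 1


class TestImageQuality:
    def test_all_cases_above_cutoff_rerun_identical(self, small_study):
        fas, _ = build_analysis_sets(small_study)
        cids = sorted(fas.included_case_ids)
        panel = consensus_for_tables(small_study, cids, "panelist")
        phys = consensus_for_tables(small_study, cids, "physician")
        deltas = compute_paired_deltas(small_study, cids, panel, phys)
        deltas.append(PairedDelta("C1", "P1", 2.0, 1.0))  # pad to 3 for rho
        out = image_quality_sensitivity(small_study, deltas, low_quality_cutoff=1.0)
        assert out["n_retained"] == out["n_with_quality"]
        all_me = np.array([d.model_abs_error for d in deltas])
        assert out["filtered_summary"]["model_mean_abs_error"] == pytest.approx(all_me.mean())

    def test_injected_monotone_relation_detected(self):
        cases = [make_case(f"C{i}", f"P{i}", quality=min(10, 1 + i)) for i in range(9)]
        tables = StudyTables(cases=cases, ratings=[])
        deltas = [
            PairedDelta(f"C{i}", f"P{i}", model_abs_error=10.0 - i, physician_abs_error=10.0 - i)
            for i in range(9)
        ]
        out = image_quality_sensitivity(tables, deltas)
        assert out["spearman_model"] < -0.9  # higher quality, lower error

    def test_constant_quality_rho_none(self):
        cases = [make_case(f"C{i}", f"P{i}", quality=9) for i in range(4)]
        tables = StudyTables(cases=cases, ratings=[])
        deltas = [PairedDelta(f"C{i}", f"P{i}", float(i), float(i)) for i in range(4)]
        out = image_quality_sensitivity(tables, deltas)
        assert out["spearman_model"] is None


class TestRunStudyEndToEnd:
    def test_noise_free_invariants(self):
        """Every agreement statistic attains its perfect value when raters
        reproduce the truth exactly."""
        tables, _ = generate_study(CohortConfig(seed=15), noise_free_raters())
        report = run_study(
            tables,
            seed=15,
            boot_resamples=300,
            agreement_resamples=100,
            sensitivity_repeats=5,
            sensitivity_boot_resamples=100,
            with_agreement_ci=False,
        )
        a = report.agreement
        for method in ("model_vs_panel", "physician_vs_panel"):
            assert a[method]["mean_abs_error"] == pytest.approx(0.0, abs=1e-12)
            assert a[method]["ccc"] == pytest.approx(1.0)
            assert a[method]["within_3pp"] == 1.0
        assert a["model_depth"]["kappa_w"] == pytest.approx(1.0)
        assert a["model_depth"]["exact_agreement"] == 1.0
        assert a["physician_preconsensus"].tbsa_icc == pytest.approx(1.0)
        assert report.primary.hl_estimate == 0.0
        assert report.primary.decision == "non_inferior"

    def test_report_tables_deterministic_bytes(self, tmp_path):
        tables, _ = generate_study(*preset_emulated_study(seed=16))
        kwargs = dict(
            seed=16,
            boot_resamples=200,
            agreement_resamples=100,
            sensitivity_repeats=3,
            sensitivity_boot_resamples=100,
            with_agreement_ci=False,
        )
        r1 = run_study(tables, **kwargs)
        r2 = run_study(tables, **kwargs)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_report_tables(r1, d1)
        p2 = write_report_tables(r2, d2)
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_report_schema(self, tmp_path):
        tables, _ = generate_study(*preset_emulated_study(seed=17))
        report = run_study(
            tables,
            seed=17,
            boot_resamples=200,
            agreement_resamples=100,
            sensitivity_repeats=3,
            sensitivity_boot_resamples=100,
            with_agreement_ci=False,
        )
        paths = write_report_tables(report, tmp_path)
        names = {p.name for p in paths}
        assert names == {
            "table2_analogue.csv",
            "table3_analogue.csv",
            "subgroups.csv",
            "primary_result.json",
            "primary_hl.csv",
            "run_log.txt",
        }
        assert (tmp_path / "replicates" / "primary_hl.csv").exists()
        primary = json.loads((tmp_path / "primary_result.json").read_text())
        assert primary["decision"] in ("superior", "non_inferior", "not_demonstrated")
        assert primary["margin_pp"] == 3.0
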