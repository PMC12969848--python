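"""Synthetic burn-study generator.

Generates cohorts with the clustered, multi-rater structure the analysis
assumes: patients contribute one to three region-cases; each region-case has
a latent true TBSA contribution (right-skewed, small regions dominate) and a
true ordinal depth; raters then produce TBSA and depth ratings under a
simple measurement model

    rating = intercept + slope * true_tbsa + b_rater + eps,   clipped to [0,100]

with a rater random effect ``b_rater ~ N(0, sigma_rater^2)`` shared across a
rater's cases and residual noise ``eps ~ N(0, sigma_resid^2)`` per rating.
Depth ratings are drawn from the true-class row of a row-stochastic confusion
matrix, conditionally independent across raters given the true class.

Under this model the theoretical single-rater ICC for a rater group with
slope 1 is

    ICC = var(true) / (var(true) + sigma_rater^2 + sigma_resid^2),

which the emulated-study preset uses to calibrate physician noise to ICC 0.71
and panel noise to ICC 0.97.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import REGIONS, Rating, RegionCase, StudyTables

# Table-1-like marginal structure of the emulated study
_REGIONS_PER_PATIENT_PROBS = (43 / 52, 6 / 52, 3 / 52)
_REGION_SITE_PROBS = (7 / 64, 6 / 64, 21 / 64, 30 / 64)
_DEPTH_PROBS = (47 / 64, 16 / 64, 1 / 64)
_PEDIATRIC_FRACTION = 35 / 64


@dataclass(frozen=True)
class TbsaDistribution:
    """Right-skewed true regional TBSA: ``scale * Beta(a, b)`` on (0, scale]."""

    a: float = 1.5
    b: float = 4.0
    scale: float = 15.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        x = self.scale * rng.beta(self.a, self.b, size=size)
        return np.maximum(x, 1e-6)

    @property
    def variance(self) -> float:
        a, b = self.a, self.b
        return self.scale**2 * a * b / ((a + b) ** 2 * (a + b + 1))


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 52
    regions_per_patient_probs: tuple[float, float, float] = _REGIONS_PER_PATIENT_PROBS
    pediatric_fraction: float = _PEDIATRIC_FRACTION
    region_site_probs: tuple[float, float, float, float] = _REGION_SITE_PROBS
    depth_probs: tuple[float, float, float] = _DEPTH_PROBS
    true_tbsa_distribution: TbsaDistribution = field(default_factory=TbsaDistribution)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, p in (
            ("regions_per_patient_probs", self.regions_per_patient_probs),
            ("region_site_probs", self.region_site_probs),
            ("depth_probs", self.depth_probs),
        ):
            arr = np.asarray(p, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be non-negative and sum to 1")


@dataclass(frozen=True)
class RaterModel:
    """Measurement model for one rater group."""

    kind: str  # model | physician | panelist
    n_raters: int
    tbsa_intercept: float = 0.0
    tbsa_slope: float = 1.0
    sigma_rater: float = 0.0
    sigma_resid: float = 0.0
    depth_confusion: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.sigma_rater < 0 or self.sigma_resid < 0:
            raise ValueError("noise SDs must be >= 0")
        cm = np.asarray(self.depth_confusion, dtype=float)
        if cm.shape != (3, 3) or (cm < 0).any():
            raise ValueError("depth_confusion must be a non-negative 3x3 matrix")
        if np.abs(cm.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("depth_confusion rows must sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth per region-case, kept for parameter-recovery tests."""

    region_case_ids: tuple[str, ...]
    true_tbsa: np.ndarray
    true_depth: np.ndarray  # ordinal 1/2/3

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_case_id": self.region_case_ids,
                "true_tbsa": self.true_tbsa,
                "true_depth": self.true_depth,
            }
        )


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed).jumped(stream))


def generate_cohort(config: CohortConfig) -> tuple[StudyTables, SyntheticTruth]:
    """Draw patients, their region-cases and the latent truth.

    Patients are i.i.d.; all regions of a patient share its age and sex.
    With the default mix (43/52, 6/52, 3/52) the expected number of
    region-cases per 52 patients is exactly 64. Deterministic in the seed.
    """
    rng = _substream(config.seed, 0)
    cases: list[RegionCase] = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:04d}"
        pediatric = rng.random() < config.pediatric_fraction
        age = float(rng.uniform(0.5, 17.5)) if pediatric else float(rng.uniform(18.0, 75.0))
        sex = "male" if rng.random() < 0.5 else "female"
        n_regions = int(rng.choice((1, 2, 3), p=config.regions_per_patient_probs))
        for k in range(n_regions):
            site = REGIONS[int(rng.choice(4, p=config.region_site_probs))]
            quality = int(np.clip(round(rng.normal(8.7, 0.8)), 1, 10))
            cases.append(
                RegionCase(
                    region_case_id=f"{pid}R{k + 1}",
                    patient_id=pid,
                    age_years=round(age, 1),
                    sex=sex,
                    anatomical_region=site,
                    image_quality=quality,
                )
            )
    n_cases = len(cases)
    true_tbsa = config.true_tbsa_distribution.sample(rng, n_cases)
    true_depth = rng.choice((1, 2, 3), size=n_cases, p=config.depth_probs)
    truth = SyntheticTruth(
        region_case_ids=tuple(c.region_case_id for c in cases),
        true_tbsa=true_tbsa,
        true_depth=true_depth.astype(int),
    )
    tables = StudyTables(cases=cases, ratings=[])
    return tables, truth


def simulate_ratings(
    truth: SyntheticTruth, raters: list[RaterModel], seed: int
) -> list[Rating]:
    """Simulate every rater group's ratings of every region-case.

    Each rater group gets its own random substream, so adding a group never
    perturbs another group's draws. TBSA is clipped to [0,100] after noise.
    """
    n = len(truth.region_case_ids)
    if n == 0:
        raise ValueError("empty truth")
    ratings: list[Rating] = []
    for g, model in enumerate(raters):
        rng = _substream(seed, g + 1)
        cm = np.asarray(model.depth_confusion, dtype=float)
        b = rng.normal(0.0, model.sigma_rater, size=model.n_raters)
        for j in range(model.n_raters):
            rater_id = f"{model.kind}_{j + 1:02d}"
            mu = model.tbsa_intercept + model.tbsa_slope * truth.true_tbsa + b[j]
            tbsa = np.clip(mu + rng.normal(0.0, model.sigma_resid, size=n), 0.0, 100.0)
            # vectorized draw from the per-case confusion row
            u = rng.random(n)
            cum = cm.cumsum(axis=1)[truth.true_depth - 1]
            depth = 1 + (u[:, None] >= cum[:, :2]).sum(axis=1)
            for i, cid in enumerate(truth.region_case_ids):
                ratings.append(
                    Rating(
                        region_case_id=cid,
                        rater_id=rater_id,
                        rater_kind=model.kind,
                        tbsa_percent=float(tbsa[i]),
                        depth_class=int(depth[i]),
                    )
                )
    return ratings


def theoretical_icc(tbsa_var: float, sigma_rater: float, sigma_resid: float) -> float:
    """Closed-form ICC of the generating model (slope 1): case variance over total."""
    return tbsa_var / (tbsa_var + sigma_rater**2 + sigma_resid**2)


def _noise_for_icc(tbsa_var: float, icc: float, rater_share: float = 0.3) -> tuple[float, float]:
    """Split total noise so the generating-model ICC equals ``icc`` exactly."""
    total = tbsa_var * (1.0 / icc - 1.0)
    return float(np.sqrt(rater_share * total)), float(np.sqrt((1.0 - rater_share) * total))


# Depth confusion of the model rater: deeper burns are systematically
# downgraded (deep partial mostly reported superficial partial, full
# thickness always downgraded).
MODEL_DEPTH_CONFUSION = (
    (45 / 47, 2 / 47, 0.0),
    (13 / 16, 3 / 16, 0.0),
    (1.0, 0.0, 0.0),
)

PHYSICIAN_DEPTH_CONFUSION = (
    (0.85, 0.13, 0.02),
    (0.25, 0.65, 0.10),
    (0.05, 0.35, 0.60),
)

# diagonal reliability calibrated so the expected pairwise quadratic-weighted
# kappa between two independent panelists equals 0.86 at the default depth
# prevalence (47/64, 16/64, 1/64)
_PANEL_DEPTH_RELIABILITY = 0.965057124690222

PANEL_DEPTH_CONFUSION = (
    (_PANEL_DEPTH_RELIABILITY, 1 - _PANEL_DEPTH_RELIABILITY, 0.0),
    (
        0.9 * (1 - _PANEL_DEPTH_RELIABILITY),
        _PANEL_DEPTH_RELIABILITY,
        0.1 * (1 - _PANEL_DEPTH_RELIABILITY),
    ),
    (0.0, 1 - _PANEL_DEPTH_RELIABILITY, _PANEL_DEPTH_RELIABILITY),
)


def preset_emulated_study(seed: int = 0) -> tuple[CohortConfig, list[RaterModel]]:
    """Default study conditions: 52 patients / ~64 region-cases, 18 physicians
    calibrated to ICC 0.71, a 3-member panel calibrated to ICC 0.97, and a
    single model rater with calibration compression (intercept 1.05,
    slope 0.71) and severity-downgrading depth errors."""
    config = CohortConfig(seed=seed)
    v = config.true_tbsa_distribution.variance
    phys_sr, phys_se = _noise_for_icc(v, 0.71)
    panel_sr, panel_se = _noise_for_icc(v, 0.97)
    raters = [
        RaterModel(
            kind="model",
            n_raters=1,
            tbsa_intercept=1.05,
            tbsa_slope=0.71,
            sigma_rater=0.0,
            sigma_resid=1.5,
            depth_confusion=MODEL_DEPTH_CONFUSION,
        ),
        RaterModel(
            kind="physician",
            n_raters=18,
            tbsa_intercept=0.0,
            tbsa_slope=1.0,
            sigma_rater=phys_sr,
            sigma_resid=phys_se,
            depth_confusion=PHYSICIAN_DEPTH_CONFUSION,
        ),
        RaterModel(
            kind="panelist",
            n_raters=3,
            tbsa_intercept=0.0,
            tbsa_slope=1.0,
            sigma_rater=panel_sr,
            sigma_resid=panel_se,
            depth_confusion=PANEL_DEPTH_CONFUSION,
        ),
    ]
    return config, raters


def noise_free_raters() -> list[RaterModel]:
    """Raters that reproduce the truth exactly; the end-to-end smoke limit."""
    return [
        RaterModel(kind="model", n_raters=1),
        RaterModel(kind="physician", n_raters=18),
        RaterModel(kind="panelist", n_raters=3),
    ]


def generate_study(
    config: CohortConfig, raters: list[RaterModel]
) -> tuple[StudyTables, SyntheticTruth]:
    """Cohort + ratings in one call; ratings are attached to the tables."""
    tables, truth = generate_cohort(config)
    ratings = simulate_ratings(truth, raters, seed=config.seed)
    return (
        StudyTables(cases=tables.cases, ratings=ratings, margin_pp=tables.margin_pp),
        truth,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.frame().to_csv(path, index=False)
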