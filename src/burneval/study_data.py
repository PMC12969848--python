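"""Domain types, CSV I/O and analysis-set construction for a burn-assessment study.

The analytic unit is the *region-case*: one anatomically distinct burn region
(Lund-Browder area) on one patient. Patients may contribute several
region-cases, so observations are clustered by patient. Each region-case is
rated by one multimodal model, a group of emergency physicians, and an expert
reference panel; ratings carry a TBSA contribution in percentage points and a
3-level ordinal depth class (superficial partial < deep partial < full
thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

SEXES = ("male", "female")
REGIONS = ("face_head", "torso", "upper_extremity", "lower_extremity")
RATER_KINDS = ("model", "physician", "panelist")

#: fixed ordinal coding of the depth ontology
DEPTH_LEVELS = {"superficial_partial": 1, "deep_partial": 2, "full_thickness": 3}
DEPTH_NAMES = {v: k for k, v in DEPTH_LEVELS.items()}
NON_ASSESSABLE = "non_assessable"

CASES_COLUMNS = [
    "region_case_id",
    "patient_id",
    "age_years",
    "sex",
    "anatomical_region",
    "image_quality",
]
RATINGS_COLUMNS = ["region_case_id", "rater_id", "rater_kind", "tbsa_percent", "depth_class"]

ADULT_AGE_YEARS = 18.0


class StudyDataError(ValueError):
    """Raised on malformed or internally inconsistent study tables."""


@dataclass(frozen=True)
class RegionCase:
    """One anatomically distinct burn region on one patient."""

    region_case_id: str
    patient_id: str
    age_years: float
    sex: str
    anatomical_region: str
    image_quality: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise StudyDataError(f"negative age for {self.region_case_id}")
        if self.sex not in SEXES:
            raise StudyDataError(f"unknown sex {self.sex!r} for {self.region_case_id}")
        if self.anatomical_region not in REGIONS:
            raise StudyDataError(
                f"unknown anatomical_region {self.anatomical_region!r} for {self.region_case_id}"
            )
        if self.image_quality is not None and not 1 <= self.image_quality <= 10:
            raise StudyDataError(
                f"image_quality {self.image_quality} outside [1,10] for {self.region_case_id}"
            )

    @property
    def age_group(self) -> str:
        """Pediatric below 18 years, adult at or above."""
        return "adult" if self.age_years >= ADULT_AGE_YEARS else "pediatric"


@dataclass(frozen=True)
class Rating:
    """One rater's (TBSA, depth) assessment of one region-case.

    ``tbsa_percent`` outside [0, 100] is retained but ``entry_error`` is set;
    flagged values are excluded from every computation downstream.
    ``depth_class`` is the ordinal code 1/2/3 or ``None`` for non-assessable.
    """

    region_case_id: str
    rater_id: str
    rater_kind: str
    tbsa_percent: float
    depth_class: Optional[int]
    entry_error: bool = False

    def __post_init__(self) -> None:
        if self.rater_kind not in RATER_KINDS:
            raise StudyDataError(f"unknown rater_kind {self.rater_kind!r}")
        if self.depth_class is not None and self.depth_class not in (1, 2, 3):
            raise StudyDataError(f"depth_class {self.depth_class!r} outside ontology")

    @property
    def assessable(self) -> bool:
        return self.depth_class is not None

    @property
    def usable_tbsa(self) -> bool:
        return not self.entry_error


@dataclass
class StudyTables:
    """A validated study: region-cases, their ratings and the margin."""

    cases: list[RegionCase]
    ratings: list[Rating]
    margin_pp: float = 3.0
    entry_error_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.margin_pp <= 0:
            raise StudyDataError("margin_pp must be positive")
        ids = [c.region_case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise StudyDataError(f"duplicate region_case_id(s): {dup}")
        known = set(ids)
        seen_pairs: set[tuple[str, str]] = set()
        for r in self.ratings:
            if r.region_case_id not in known:
                raise StudyDataError(f"rating references unknown region_case_id {r.region_case_id!r}")
            key = (r.region_case_id, r.rater_id)
            if key in seen_pairs:
                raise StudyDataError(f"duplicate rating for (case, rater) = {key}")
            seen_pairs.add(key)
        model_counts: dict[str, int] = {}
        for r in self.ratings:
            if r.rater_kind == "model":
                model_counts[r.region_case_id] = model_counts.get(r.region_case_id, 0) + 1
        bad = sorted(cid for cid, n in model_counts.items() if n > 1)
        if bad:
            raise StudyDataError(f"more than one model rating for case(s): {bad}")

    def case(self, region_case_id: str) -> RegionCase:
        for c in self.cases:
            if c.region_case_id == region_case_id:
                return c
        raise KeyError(region_case_id)

    def ratings_for(self, region_case_id: str, rater_kind: Optional[str] = None) -> list[Rating]:
        return [
            r
            for r in self.ratings
            if r.region_case_id == region_case_id
            and (rater_kind is None or r.rater_kind == rater_kind)
        ]

    def cases_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_case_id": c.region_case_id,
                "patient_id": c.patient_id,
                "age_years": c.age_years,
                "sex": c.sex,
                "anatomical_region": c.anatomical_region,
                "image_quality": c.image_quality,
            }
            for c in self.cases
        ]
        return pd.DataFrame(rows, columns=CASES_COLUMNS)

    def ratings_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_case_id": r.region_case_id,
                "rater_id": r.rater_id,
                "rater_kind": r.rater_kind,
                "tbsa_percent": r.tbsa_percent,
                "depth_class": DEPTH_NAMES[r.depth_class] if r.depth_class else NON_ASSESSABLE,
            }
            for r in self.ratings
        ]
        return pd.DataFrame(rows, columns=RATINGS_COLUMNS)


@dataclass
class AnalysisSet:
    """An analysis population: full-analysis or per-protocol."""

    set_kind: str  # "full_analysis" | "per_protocol"
    included_case_ids: set[str]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)


def _parse_depth(label: str, where: str) -> Optional[int]:
    label = str(label).strip()
    if label == NON_ASSESSABLE:
        return None
    if label not in DEPTH_LEVELS:
        raise StudyDataError(f"{where}: unknown depth_class {label!r}")
    return DEPTH_LEVELS[label]


def read_study(cases_path: str | Path, ratings_path: str | Path, margin_pp: float = 3.0) -> StudyTables:
    """Read and validate the two long-format CSV tables.

    TBSA values outside [0, 100] are retained with an entry-error flag and a
    log line (they never enter computations); any structural problem (unknown
    labels, duplicate ratings, dangling case ids) raises ``StudyDataError``
    naming the offending row.
    """
    cases_path, ratings_path = Path(cases_path), Path(ratings_path)
    for p in (cases_path, ratings_path):
        if not p.exists():
            raise FileNotFoundError(p)
    cases_df = pd.read_csv(cases_path, dtype={"region_case_id": str, "patient_id": str})
    ratings_df = pd.read_csv(ratings_path, dtype={"region_case_id": str, "rater_id": str})
    missing = [c for c in CASES_COLUMNS if c not in cases_df.columns]
    if missing:
        raise StudyDataError(f"{cases_path}: missing columns {missing}")
    missing = [c for c in RATINGS_COLUMNS if c not in ratings_df.columns]
    if missing:
        raise StudyDataError(f"{ratings_path}: missing columns {missing}")

    cases = []
    for i, row in cases_df.iterrows():
        iq = row["image_quality"]
        cases.append(
            RegionCase(
                region_case_id=row["region_case_id"],
                patient_id=row["patient_id"],
                age_years=float(row["age_years"]),
                sex=row["sex"],
                anatomical_region=row["anatomical_region"],
                image_quality=None if pd.isna(iq) else int(iq),
            )
        )

    ratings: list[Rating] = []
    entry_error_log: list[str] = []
    for i, row in ratings_df.iterrows():
        line_no = i + 2  # header is line 1
        tbsa = float(row["tbsa_percent"])
        entry_error = not 0.0 <= tbsa <= 100.0
        if entry_error:
            entry_error_log.append(
                f"{ratings_path.name}:{line_no}: tbsa_percent={tbsa} outside [0,100] "
                f"for case {row['region_case_id']} rater {row['rater_id']} (flagged, excluded)"
            )
        ratings.append(
            Rating(
                region_case_id=row["region_case_id"],
                rater_id=row["rater_id"],
                rater_kind=str(row["rater_kind"]).strip(),
                tbsa_percent=tbsa,
                depth_class=_parse_depth(row["depth_class"], f"{ratings_path.name}:{line_no}"),
                entry_error=entry_error,
            )
        )
    return StudyTables(cases=cases, ratings=ratings, margin_pp=margin_pp, entry_error_log=entry_error_log)


def write_study(tables: StudyTables, cases_path: str | Path, ratings_path: str | Path) -> None:
    tables.cases_frame().to_csv(cases_path, index=False)
    tables.ratings_frame().to_csv(ratings_path, index=False)


def build_analysis_sets(tables: StudyTables) -> tuple[AnalysisSet, AnalysisSet]:
    """Construct the Full Analysis and Per-Protocol populations.

    Full analysis: region-cases with a usable model rating, at least one
    usable physician rating, and at least one assessable panelist rating.
    Per-protocol additionally excludes cases rated non-assessable by two or
    more panelists. Outcome is independent of input row order.
    """
    fas_ids: set[str] = set()
    fas_log: list[tuple[str, str]] = []
    pp_ids: set[str] = set()
    pp_log: list[tuple[str, str]] = []

    for case in sorted(tables.cases, key=lambda c: c.region_case_id):
        cid = case.region_case_id
        model = [r for r in tables.ratings_for(cid, "model") if r.usable_tbsa]
        phys = [r for r in tables.ratings_for(cid, "physician") if r.usable_tbsa]
        panel = tables.ratings_for(cid, "panelist")
        panel_ok = [r for r in panel if r.assessable and r.usable_tbsa]

        if not model:
            fas_log.append((cid, "missing_model_rating"))
        elif not phys:
            fas_log.append((cid, "missing_physician_rating"))
        elif not panel_ok:
            fas_log.append((cid, "missing_panel_rating"))
        else:
            fas_ids.add(cid)
            n_na = sum(1 for r in panel if not r.assessable)
            if n_na >= 2:
                pp_log.append((cid, "panel_non_assessable_ge2"))
            else:
                pp_ids.add(cid)

    fas = AnalysisSet("full_analysis", fas_ids, fas_log)
    pp = AnalysisSet("per_protocol", pp_ids, fas_log + pp_log)
    return fas, pp
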