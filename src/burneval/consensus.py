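"""Expert-panel and physician-group consensus for region-case ratings.

The reference standard for each region-case is the panel consensus: median
TBSA and majority depth class, with a three-way depth tie defaulting to deep
partial. A case is auto-accepted when the panel TBSA range is at most
2 percentage points AND a strict depth majority exists; otherwise the
consensus is still computed but flagged ``needs_adjudication`` — the human
adjudication round that would follow in a live study cannot be executed by
software, so the flag makes those cases auditable.

The physician comparator uses the median TBSA across physicians (midpoint
convention for even counts) and the modal depth class, ties broken toward
the deeper class by analogy with the panel's tie default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .agreement_metrics import icc_2way_random_single, mean_pairwise_weighted_kappa
from .study_data import StudyTables

AUTO_ACCEPT_TBSA_RANGE_PP = 2.0


@dataclass(frozen=True)
class ConsensusResult:
    region_case_id: str
    consensus_tbsa: float
    consensus_depth: int
    adjudication_flag: str  # "auto_accepted" | "needs_adjudication"
    n_raters_used: int


@dataclass(frozen=True)
class PreConsensusAgreement:
    tbsa_icc: Optional[float]
    depth_kappa_w: Optional[float]


def _majority_depth(depths: Sequence[int], tie_break: str = "deeper") -> tuple[int, bool]:
    """Modal depth class and whether a strict majority (> n/2) held it.

    Ties among modal classes are broken toward the deeper class; a three-way
    tie therefore lands on deep partial for a panel of three (never full
    thickness unless full thickness is itself modal).
    """
    counts = Counter(depths)
    top = max(counts.values())
    modal = sorted(c for c, k in counts.items() if k == top)
    if len(modal) == 1:
        cls = modal[0]
    elif len(modal) == len(counts) == 3:
        cls = 2  # three-way tie defaults to deep partial
    else:
        cls = max(modal) if tie_break == "deeper" else min(modal)
    strict = top > len(depths) / 2.0
    return cls, strict


def panel_consensus(
    region_case_id: str,
    tbsa_values: Sequence[float],
    depth_values: Sequence[int],
    auto_accept_range_pp: float = AUTO_ACCEPT_TBSA_RANGE_PP,
) -> ConsensusResult:
    """Panel reference consensus for one region-case.

    Inputs are the assessable panelist ratings only; raises ``ValueError``
    when none remain (such cases are flagged for per-protocol exclusion
    upstream).
    """
    tbsa = np.asarray(tbsa_values, dtype=float)
    depths = list(depth_values)
    if tbsa.size == 0 or len(depths) != tbsa.size:
        raise ValueError(f"no assessable panel ratings for {region_case_id}")
    depth, strict_majority = _majority_depth(depths)
    tbsa_range = float(tbsa.max() - tbsa.min())
    flag = (
        "auto_accepted"
        if tbsa_range <= auto_accept_range_pp and strict_majority
        else "needs_adjudication"
    )
    return ConsensusResult(
        region_case_id=region_case_id,
        consensus_tbsa=float(np.median(tbsa)),
        consensus_depth=depth,
        adjudication_flag=flag,
        n_raters_used=int(tbsa.size),
    )


def physician_consensus(
    region_case_id: str,
    tbsa_values: Sequence[float],
    depth_values: Sequence[int],
    tie_break: str = "deeper",
) -> ConsensusResult:
    """Physician-group consensus: median TBSA, modal depth, deeper-class ties."""
    tbsa = np.asarray(tbsa_values, dtype=float)
    depths = list(depth_values)
    if tbsa.size == 0:
        raise ValueError(f"no physician ratings for {region_case_id}")
    depth, strict = _majority_depth(depths, tie_break=tie_break)
    return ConsensusResult(
        region_case_id=region_case_id,
        consensus_tbsa=float(np.median(tbsa)),
        consensus_depth=depth,
        adjudication_flag="auto_accepted" if strict else "needs_adjudication",
        n_raters_used=int(tbsa.size),
    )


def consensus_for_tables(
    tables: StudyTables, case_ids: Sequence[str], rater_kind: str
) -> dict[str, ConsensusResult]:
    """Panel or physician consensus for each listed case from a study table."""
    if rater_kind not in ("panelist", "physician"):
        raise ValueError("rater_kind must be 'panelist' or 'physician'")
    fn = panel_consensus if rater_kind == "panelist" else physician_consensus
    out: dict[str, ConsensusResult] = {}
    for cid in case_ids:
        ratings = [
            r
            for r in tables.ratings_for(cid, rater_kind)
            if r.assessable and r.usable_tbsa
        ]
        ratings.sort(key=lambda r: r.rater_id)
        out[cid] = fn(
            cid,
            [r.tbsa_percent for r in ratings],
            [r.depth_class for r in ratings],
        )
    return out


def preconsensus_agreement(
    tbsa_matrix: np.ndarray, depth_matrix: np.ndarray
) -> PreConsensusAgreement:
    """Pre-consensus agreement of a rater group: ICC(2,1) for TBSA, mean
    pairwise quadratic-weighted kappa for depth.

    Matrices are cases x raters and must be complete. Either statistic may be
    undefined on degenerate inputs; it is then reported as ``None`` rather
    than raising.
    """
    tbsa = np.asarray(tbsa_matrix, dtype=float)
    depth = np.asarray(depth_matrix, dtype=int)
    if tbsa.ndim != 2 or tbsa.shape[0] < 2 or tbsa.shape[1] < 2:
        raise ValueError("need >= 2 cases and >= 2 raters")
    from .agreement_metrics import DegenerateInputError

    try:
        icc = icc_2way_random_single(tbsa)
    except DegenerateInputError:
        icc = None
    try:
        kw = mean_pairwise_weighted_kappa(depth)
    except DegenerateInputError:
        kw = None
    return PreConsensusAgreement(tbsa_icc=icc, depth_kappa_w=kw)


def ratings_matrices(
    tables: StudyTables, case_ids: Sequence[str], rater_kind: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete cases x raters TBSA and depth matrices for one rater group.

    Cases with any missing/non-assessable rating from the group are dropped
    (complete-case restriction); rater columns are in sorted rater_id order.
    """
    rater_ids = sorted(
        {r.rater_id for r in tables.ratings if r.rater_kind == rater_kind}
    )
    tbsa_rows, depth_rows, kept = [], [], []
    for cid in case_ids:
        ratings = {r.rater_id: r for r in tables.ratings_for(cid, rater_kind)}
        if any(
            rid not in ratings
            or not ratings[rid].assessable
            or not ratings[rid].usable_tbsa
            for rid in rater_ids
        ):
            continue
        tbsa_rows.append([ratings[rid].tbsa_percent for rid in rater_ids])
        depth_rows.append([ratings[rid].depth_class for rid in rater_ids])
        kept.append(cid)
    return np.asarray(tbsa_rows, dtype=float), np.asarray(depth_rows, dtype=int), kept
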