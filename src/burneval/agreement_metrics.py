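"""Closed-form agreement, accuracy and calibration statistics.

All functions accept plain numeric vectors/matrices. Degenerate inputs
(zero variance, single-class labels, chance agreement of one) raise
``DegenerateInputError`` rather than returning NaN silently, so callers —
in particular the bootstrap engine, which must count undefined replicates —
can handle them explicitly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEPTH_LABELS = ("superficial_partial", "deep_partial", "full_thickness")


class DegenerateInputError(ValueError):
    """A statistic is undefined on this input (zero variance, single class, ...)."""


class AmbiguousReconstructionError(ValueError):
    """Margin-constrained matrix reconstruction has no unique solution."""

    def __init__(self, n_solutions: int):
        self.n_solutions = n_solutions
        super().__init__(
            f"reconstruction not unique: {n_solutions} matrices satisfy the constraints"
        )


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 ordinal confusion matrix; rows = reference class, columns = comparator."""

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (a < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_array(cls, a: np.ndarray) -> "ConfusionMatrix3":
        return cls(tuple(tuple(int(x) for x in row) for row in np.asarray(a)))

    def to_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=float)

    @property
    def total(self) -> int:
        return int(self.to_array().sum())

    @property
    def exact_agreement(self) -> float:
        a = self.to_array()
        if a.sum() == 0:
            raise DegenerateInputError("empty confusion matrix")
        return float(np.trace(a) / a.sum())


@dataclass(frozen=True)
class CalibrationFit:
    intercept: float
    slope: float
    r_squared: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_variance: float
    sensitivity: float
    specificity: float


def _vec(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise ValueError("non-finite values in input")
    return a


def abs_error_summary(estimates, reference) -> tuple[float, float, float, float]:
    """Mean/median absolute error and inclusive 3 p.p. / 5 p.p. tolerance bands.

    ``within_tpp`` counts |estimate - reference| <= t (boundary included).
    """
    e, r = _vec(estimates), _vec(reference)
    if e.size != r.size:
        raise ValueError("length mismatch")
    if e.size == 0:
        raise ValueError("empty input")
    err = np.abs(e - r)
    return (
        float(err.mean()),
        float(np.median(err)),
        float((err <= 3.0).mean()),
        float((err <= 5.0).mean()),
    )


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    CCC = 2 cov(x,y) / (var x + var y + (mean x - mean y)^2). The 1/n
    convention follows the original definition; at n = 64 the 1/(n-1)
    variant changes the third decimal.
    """
    x, y = _vec(x), _vec(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    vx, vy = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0.0:
        raise DegenerateInputError("CCC undefined: both vectors constant and equal")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / denom)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement for differences x - y.

    LoA = bias +/- 1.96 * SD(d) with the sample (n-1) standard deviation.
    """
    x, y = _vec(x), _vec(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def confusion_matrix(ref_labels, cmp_labels) -> ConfusionMatrix3:
    """Cross-tabulate ordinal labels in {1,2,3}: rows reference, columns comparator."""
    ref = np.asarray(ref_labels, dtype=int).ravel()
    cmp_ = np.asarray(cmp_labels, dtype=int).ravel()
    if ref.size != cmp_.size:
        raise ValueError("length mismatch")
    for a in (ref, cmp_):
        if ((a < 1) | (a > 3)).any():
            raise ValueError("labels outside the 3-level ontology")
    counts = np.zeros((3, 3), dtype=int)
    for i, j in zip(ref, cmp_):
        counts[i - 1, j - 1] += 1
    return ConfusionMatrix3.from_array(counts)


def reconstruct_confusion_from_margins(
    row_totals, col_totals, diagonal_total: int
) -> ConfusionMatrix3:
    """Recover the unique 3x3 count matrix from its margins and diagonal total.

    Exhaustive search over non-negative integer matrices with the given row
    sums, column sums and trace. Returns the matrix iff exactly one exists;
    raises ``AmbiguousReconstructionError`` (with the count) otherwise, and
    ``ValueError`` on infeasible margins.
    """
    rows = tuple(int(x) for x in row_totals)
    cols = tuple(int(x) for x in col_totals)
    diag = int(diagonal_total)
    if len(rows) != 3 or len(cols) != 3:
        raise ValueError("need three row and three column totals")
    if min(rows) < 0 or min(cols) < 0 or diag < 0:
        raise ValueError("negative totals")
    if sum(rows) != sum(cols):
        raise ValueError("row and column totals disagree")
    if diag > sum(rows):
        raise ValueError("diagonal total exceeds grand total")

    solutions: list[np.ndarray] = []
    # free cells: first two entries of rows 0 and 1; the rest are forced
    for m00 in range(min(rows[0], cols[0]) + 1):
        for m01 in range(min(rows[0] - m00, cols[1]) + 1):
            m02 = rows[0] - m00 - m01
            if m02 > cols[2]:
                continue
            for m10 in range(min(rows[1], cols[0] - m00) + 1):
                for m11 in range(min(rows[1] - m10, cols[1] - m01) + 1):
                    m12 = rows[1] - m10 - m11
                    if m12 > cols[2] - m02:
                        continue
                    m20 = cols[0] - m00 - m10
                    m21 = cols[1] - m01 - m11
                    m22 = cols[2] - m02 - m12
                    if min(m20, m21, m22) < 0 or m20 + m21 + m22 != rows[2]:
                        continue
                    if m00 + m11 + m22 == diag:
                        solutions.append(
                            np.array([[m00, m01, m02], [m10, m11, m12], [m20, m21, m22]])
                        )
                        if len(solutions) > 1:
                            # keep counting for the error message
                            pass
    if not solutions:
        raise ValueError("infeasible margins: no matrix satisfies the constraints")
    if len(solutions) > 1:
        raise AmbiguousReconstructionError(len(solutions))
    m = solutions[0]
    assert tuple(m.sum(axis=1)) == rows and tuple(m.sum(axis=0)) == cols
    assert int(np.trace(m)) == diag
    return ConfusionMatrix3.from_array(m)


def _kappa_weights(k: int, scheme: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if scheme == "quadratic":
        return 1.0 - ((i - j) ** 2) / (k - 1) ** 2
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(m: ConfusionMatrix3 | np.ndarray, weight_scheme: str = "quadratic") -> float:
    """Cohen's kappa with agreement weights w_ij = 1 - (i-j)^2/(k-1)^2 (quadratic).

    kappa = (P_o - P_e) / (1 - P_e) where P_o and P_e are the weighted
    observed and chance-expected agreement proportions from the margins.
    """
    a = m.to_array() if isinstance(m, ConfusionMatrix3) else np.asarray(m, dtype=float)
    n = a.sum()
    if n <= 0:
        raise ValueError("empty matrix")
    p = a / n
    w = _kappa_weights(a.shape[0], weight_scheme)
    p_row = p.sum(axis=1)
    p_col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(p_row, p_col)).sum())
    if pe >= 1.0 - 1e-15:
        raise DegenerateInputError("kappa undefined: chance agreement equals 1")
    return float((po - pe) / (1.0 - pe))


def mean_pairwise_weighted_kappa(label_matrix: np.ndarray, weight_scheme: str = "quadratic") -> float:
    """Average quadratic-weighted kappa over all rater pairs.

    ``label_matrix`` is cases x raters with ordinal labels in {1,2,3}.
    Multi-rater generalization used for >= 3 raters.
    """
    lm = np.asarray(label_matrix, dtype=int)
    if lm.ndim != 2 or lm.shape[1] < 2:
        raise ValueError("need a cases x raters matrix with >= 2 raters")
    kappas = []
    for a, b in itertools.combinations(range(lm.shape[1]), 2):
        kappas.append(weighted_kappa(confusion_matrix(lm[:, a], lm[:, b]), weight_scheme))
    return float(np.mean(kappas))


def icc_2way_random_single(ratings_matrix) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the two-way ANOVA mean squares of a complete n cases x k raters
    matrix:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R the between-cases, MS_C the between-raters and MS_E the
    residual mean square.
    """
    x = np.asarray(ratings_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 cases and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("incomplete matrix: restrict to complete cases first")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0.0:
        raise DegenerateInputError("ICC undefined: zero total variance")
    return float((ms_r - ms_e) / denom)


def calibration_fit(estimate, reference) -> CalibrationFit:
    """OLS of estimate on reference: slope/intercept calibration and R^2.

    Slope < 1 indicates compression of extremes toward the centre.
    """
    e, r = _vec(estimate), _vec(reference)
    if e.size != r.size or e.size < 3:
        raise ValueError("need >= 3 paired values")
    if r.var() == 0.0:
        raise DegenerateInputError("reference has zero variance")
    if e.var() == 0.0:
        # flat estimate: slope 0, no variance explained
        return CalibrationFit(intercept=float(e.mean()), slope=0.0, r_squared=0.0)
    res = stats.linregress(r, e)
    return CalibrationFit(
        intercept=float(res.intercept), slope=float(res.slope), r_squared=float(res.rvalue**2)
    )


def spearman_rho(a, b) -> float:
    """Spearman rank correlation with midrank ties."""
    x, y = _vec(a), _vec(b)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _auc_and_placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Midrank AUC with the DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    allr = stats.rankdata(np.concatenate([pos, neg]))
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (allr[:m] - rank_pos) / n  # P(neg < pos) per positive, ties half
    v01 = 1.0 - (allr[m:] - rank_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc_delong(scores_a, scores_b, labels) -> tuple[RocResult, RocResult, float, float]:
    """Paired ROC-AUC comparison by DeLong's method.

    AUC uses midranks (ties get half credit); the covariance of the two AUCs
    is estimated from placement values on the shared cases; the returned
    z statistic and two-sided p test AUC_a = AUC_b. Sensitivity/specificity
    in the per-method results are at the Youden-optimal threshold.
    """
    sa, sb = _vec(scores_a), _vec(scores_b)
    y = np.asarray(labels, dtype=int).ravel()
    if not (sa.size == sb.size == y.size):
        raise ValueError("scores and labels must be the same length")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise DegenerateInputError("both classes must be present")

    def one(scores: np.ndarray) -> tuple[RocResult, np.ndarray, np.ndarray]:
        auc, v10, v01 = _auc_and_placements(scores, y)
        s10 = v10.var(ddof=1) if m > 1 else 0.0
        s01 = v01.var(ddof=1) if n > 1 else 0.0
        var = s10 / m + s01 / n
        sens, spec = _youden_operating_point(scores, y)
        return RocResult(auc, float(var), sens, spec), v10, v01

    ra, v10a, v01a = one(sa)
    rb, v10b, v01b = one(sb)
    c10 = np.cov(v10a, v10b, ddof=1)[0, 1] if m > 1 else 0.0
    c01 = np.cov(v01a, v01b, ddof=1)[0, 1] if n > 1 else 0.0
    var_diff = ra.auc_variance + rb.auc_variance - 2.0 * (c10 / m + c01 / n)
    diff = ra.auc - rb.auc
    if var_diff <= 0.0:
        z = 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    else:
        z = float(diff / np.sqrt(var_diff))
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return ra, rb, z, p


def _youden_operating_point(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    thresholds = np.unique(scores)
    best = (-np.inf, 0.0, 0.0)
    pos = labels == 1
    neg = ~pos
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & pos).sum() / pos.sum())
        spec = float((~pred & neg).sum() / neg.sum())
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, sens, spec)
    return best[1], best[2]


def binary_operating_point(scores, labels, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity of ``score >= threshold`` against binary labels."""
    s = _vec(scores)
    y = np.asarray(labels, dtype=int).ravel()
    pos = y == 1
    neg = ~pos
    if pos.sum() == 0 or neg.sum() == 0:
        raise DegenerateInputError("both classes must be present")
    pred = s >= threshold
    return float((pred & pos).sum() / pos.sum()), float((~pred & neg).sum() / neg.sum())
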