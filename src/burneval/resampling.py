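"""Hodges-Lehmann estimation and the patient-level cluster bootstrap.

All inferential statements in the analysis go through this module: no
model-based standard errors are used anywhere. The bootstrap resamples whole
patients (clusters) with replacement, keeping every region-case of a drawn
patient, so within-patient correlation is respected. Replicate b's cluster
draws are a fixed function of (seed, b) — row b of an index matrix drawn
from a Philox generator keyed by the seed — which, together with canonical
cluster ordering, makes the replicate vector independent of input row order
and of any execution strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

from .agreement_metrics import DegenerateInputError


@dataclass(frozen=True)
class ClusteredValues:
    """A value vector with a parallel vector of cluster (patient) ids."""

    values: np.ndarray
    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        c = np.asarray(self.cluster_ids)
        if v.size != c.size:
            raise ValueError("values and cluster_ids must have equal length")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cluster_ids", c)

    @property
    def n_clusters(self) -> int:
        return np.unique(self.cluster_ids).size


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: 5000 replicates for the primary endpoint,
    2000 for agreement metrics, percentile intervals at level 1 - alpha."""

    n_resamples: int = 5000
    alpha: float = 0.05
    side: str = "two_sided"  # or "upper_one_sided"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.side not in ("two_sided", "upper_one_sided"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class BootstrapResult:
    point_estimate: float
    replicate_values: np.ndarray
    ci_low: float
    ci_high: float
    n_undefined: int = 0
    config: BootstrapConfig = field(default_factory=BootstrapConfig)


@lru_cache(maxsize=64)
def _walsh_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def hodges_lehmann(values) -> float:
    """Hodges-Lehmann location estimate: median of all Walsh averages.

    Walsh averages are (x_i + x_j)/2 over every pair i <= j, self-pairs
    included; the estimate is their median. Robust and translation
    equivariant; equals the sample median for n <= 2.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    iu, ju = _walsh_indices(x.size)
    walsh = (x[iu] + x[ju]) / 2.0
    return float(np.median(walsh))


def _group_clusters(data: ClusteredValues) -> list[np.ndarray]:
    """Member values per cluster, clusters in canonical (sorted id) order."""
    order = np.argsort(data.cluster_ids, kind="stable")
    ids_sorted = data.cluster_ids[order]
    vals_sorted = data.values[order]
    uniq, starts = np.unique(ids_sorted, return_index=True)
    bounds = list(starts) + [ids_sorted.size]
    return [vals_sorted[bounds[i] : bounds[i + 1]] for i in range(uniq.size)]


def _replicate_index_matrix(seed: int, n_resamples: int, n_clusters: int) -> np.ndarray:
    """Cluster draws for every replicate: row b belongs to replicate b.

    Drawn in one pass from a Philox generator keyed by the seed, so the draws
    for replicate b are a fixed function of (seed, b) regardless of how the
    replicate loop is executed.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    return rng.integers(0, n_clusters, size=(n_resamples, n_clusters))


def cluster_bootstrap(
    data: ClusteredValues,
    statistic: Callable[[np.ndarray], float],
    config: BootstrapConfig,
    max_undefined_fraction: float = 0.01,
) -> BootstrapResult:
    """Percentile cluster bootstrap of a statistic of the value vector.

    Each replicate draws ``n_clusters`` cluster ids with replacement and
    concatenates all member values (a cluster drawn m times contributes m
    copies), so replicate sample sizes vary with the drawn cluster sizes.
    Quantiles use the inclusive (type-7) convention. A replicate on which the
    statistic raises ``DegenerateInputError`` is recorded as undefined; more
    than ``max_undefined_fraction`` undefined replicates aborts.

    ``upper_one_sided`` returns the (1 - alpha) quantile as ``ci_high`` with
    ``ci_low = -inf``.
    """
    clusters = _group_clusters(data)
    n_clusters = len(clusters)
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    point = float(statistic(data.values))

    singleton = all(c.size == 1 for c in clusters)
    flat = np.concatenate(clusters) if singleton else None

    B = config.n_resamples
    index_matrix = _replicate_index_matrix(config.seed, B, n_clusters)
    reps = np.empty(B)
    n_undef = 0
    for b in range(B):
        idx = index_matrix[b]
        sample = flat[idx] if singleton else np.concatenate([clusters[i] for i in idx])
        try:
            reps[b] = statistic(sample)
        except DegenerateInputError:
            reps[b] = np.nan
            n_undef += 1
    if n_undef > max_undefined_fraction * B:
        raise RuntimeError(
            f"{n_undef}/{B} bootstrap replicates were undefined "
            f"(> {max_undefined_fraction:.0%} cap); statistic too unstable on resamples"
        )
    valid = reps[~np.isnan(reps)]
    if config.side == "two_sided":
        lo = float(np.quantile(valid, config.alpha / 2.0))
        hi = float(np.quantile(valid, 1.0 - config.alpha / 2.0))
    else:
        lo = -math.inf
        hi = float(np.quantile(valid, 1.0 - config.alpha))
    return BootstrapResult(point, reps, lo, hi, n_undef, config)


def cluster_bootstrap_ci_for_metric(
    x: Sequence[float],
    y: Sequence[float],
    cluster_ids: Sequence,
    metric: Callable[[np.ndarray, np.ndarray], float],
    config: BootstrapConfig,
) -> BootstrapResult:
    """Cluster-bootstrap CI for a paired-sample agreement metric.

    ``metric(x_sub, y_sub)`` is evaluated per replicate on the patient-
    resampled pairs (used for kappa, CCC, calibration slope, ...). The pair
    structure travels with the case, so both vectors are resampled jointly.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    cid = np.asarray(cluster_ids)
    if not (xa.size == ya.size == cid.size):
        raise ValueError("x, y and cluster_ids must have equal length")
    # index trick: bootstrap the case indices, apply metric to the pairs
    idx_data = ClusteredValues(np.arange(xa.size, dtype=float), cid)

    def stat(indices: np.ndarray) -> float:
        ii = indices.astype(int)
        return metric(xa[ii], ya[ii])

    metric(xa, ya)  # must be defined on the full sample
    return cluster_bootstrap(idx_data, stat, config)
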