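"""Target-cluster schedule, k-means partitioning and the bait loop.

Positive target genes are partitioned by k-means at a schedule of average
cluster sizes; every cluster serves as the Y block of one ASCCA fit against
the full TF block X, and the TFs with nonzero loadings form a hooked set
that is passed through the enrichment retention test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ascca import (
    PenaltyParams,
    ascca_iterate,
    cv_select,
    initial_vectors,
    penalty_grid,
    svd_reference_vectors,
)
from .enrichment import HookedTFSet, enrichment_filter
from .matrix import ExpressionMatrix, cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSchedule",
    "TargetCluster",
    "BaitConfig",
    "cluster_schedule",
    "kmeans_partition",
    "run_bait_loop",
    "coarse_grid",
]


@dataclass(frozen=True)
class ClusterSchedule:
    """One (average size s, cluster count n_s) entry per scheduled k-means run."""

    entries: tuple[tuple[int, int], ...]

    @property
    def total_runs(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TargetCluster:
    gene_ids: tuple[str, ...]
    source: tuple[int, int]  # (average size s, cluster index within the run)

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("a target cluster must be nonempty")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


def cluster_schedule(T: int, s_min: int = 4, s_max: int = 20) -> ClusterSchedule:
    """Schedule one k-means run per integer average size in [s_min, s_max].

    The cluster count for size s is ``max(1, round(T / s))`` with
    round-half-to-even; a count of 1 keeps the whole target set as a single
    cluster.
    """
    if T < 2:
        raise ValueError("need at least 2 target genes to schedule clustering")
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    entries = tuple((s, max(1, round(T / s))) for s in range(s_min, s_max + 1))
    return ClusterSchedule(entries=entries)


def kmeans_partition(
    Y: ExpressionMatrix,
    n_clusters: int,
    seed: int,
    restarts: int = 10,
) -> list[TargetCluster]:
    """Partition target genes by k-means on their expression profiles.

    Genes are points, samples are dimensions, distance is Euclidean; the
    best of ``restarts`` seeded initializations (by within-cluster sum of
    squares) is kept and empty clusters are dropped.  Cluster order and
    within-cluster gene order follow the input gene order, so the result is
    deterministic for a fixed seed.
    """
    T = Y.n_genes
    if n_clusters > T:
        raise ValueError(f"n_clusters = {n_clusters} exceeds target count {T}")
    if n_clusters == 1:
        return [TargetCluster(gene_ids=Y.gene_ids, source=(0, 0))]
    km = KMeans(n_clusters=n_clusters, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Y.values.T)
    clusters: dict[int, list[str]] = {}
    order: list[int] = []
    for gene, lab in zip(Y.gene_ids, labels):
        if lab not in clusters:
            clusters[lab] = []
            order.append(lab)
        clusters[lab].append(gene)
    return [
        TargetCluster(gene_ids=tuple(clusters[lab]), source=(0, i))
        for i, lab in enumerate(order)
    ]


def coarse_grid() -> list[PenaltyParams]:
    """Desk-scale penalty grid: lambda in {0, 0.05, ..., 0.4}, gamma in {0, 0.5, ..., 2}."""
    return penalty_grid(0.4, 0.05, 0.4, 0.05, 2.0, 0.5)


@dataclass(frozen=True)
class BaitConfig:
    """Settings for the cluster-bait loop."""

    s_min: int = 4
    s_max: int = 20
    grid: tuple[PenaltyParams, ...] = field(default_factory=lambda: tuple(coarse_grid()))
    cv_k: int = 5
    ef: float = 3.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    kmeans_restarts: int = 10


def run_bait_loop(
    X_tfs: ExpressionMatrix,
    Y_targets: ExpressionMatrix,
    positive_tf_ids,
    config: BaitConfig,
) -> list[HookedTFSet]:
    """Run one ASCCA bait per scheduled target cluster.

    For every cluster: penalties are chosen by cross-validation on
    (X, Y_cluster), the pair is refitted on all samples at the selected
    triple, and the TFs with nonzero u-loadings are filtered through the
    enrichment test.  Sets are returned in schedule order with provenance
    (s, cluster index, chosen params).  A degenerate fit yields an empty,
    non-retained set and is logged, not fatal.
    """
    if not (X_tfs.standardized and Y_targets.standardized):
        raise ValueError("X and Y must be standardized")
    overlap = set(X_tfs.gene_ids) & set(Y_targets.gene_ids)
    if overlap:
        raise ValueError(f"targets must be disjoint from TFs; shared: {sorted(overlap)}")
    positives = frozenset(positive_tf_ids)
    unknown = positives - set(X_tfs.gene_ids)
    if unknown:
        raise ValueError(f"positive TFs absent from the TF block: {sorted(unknown)}")

    schedule = cluster_schedule(Y_targets.n_genes, config.s_min, config.s_max)
    grid = list(config.grid)
    N = X_tfs.n_genes
    rng = np.random.default_rng(config.seed)

    hooked: list[HookedTFSet] = []
    for s, n_s in schedule.entries:
        km_seed = int(rng.integers(2**31))
        clusters = kmeans_partition(
            Y_targets, n_s, seed=km_seed, restarts=config.kmeans_restarts
        )
        for ci, cluster in enumerate(clusters):
            cv_seed = int(rng.integers(2**31))
            Yc = Y_targets.select(cluster.gene_ids)
            best, _ = cv_select(
                X_tfs, Yc, grid, k=config.cv_k, seed=cv_seed,
                tol=config.tol, max_iter=config.max_iter,
            )
            K = cross_correlation(X_tfs, Yc)
            if not np.any(K.values):
                logger.warning("all-zero K for s=%d cluster %d; nothing hooked", s, ci)
                hooked.append(
                    enrichment_filter((), positives, N, config.ef, (s, ci, best))
                )
                continue
            weights = svd_reference_vectors(K)
            u0, v0 = initial_vectors(K)
            pair = ascca_iterate(
                K, best, weights, u0, v0, tol=config.tol, max_iter=config.max_iter
            )
            tf_ids = frozenset(X_tfs.gene_ids[i] for i in pair.support_u)
            if not tf_ids:
                logger.info("degenerate fit for s=%d cluster %d; nothing hooked", s, ci)
            hooked.append(
                enrichment_filter(tf_ids, positives, N, config.ef, (s, ci, best))
            )
            logger.debug(
                "s=%d cluster=%d params=%s hooked=%d overlap=%d retained=%s",
                s, ci, best, len(tf_ids), hooked[-1].n_pos_overlap, hooked[-1].retained,
            )
    return hooked
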