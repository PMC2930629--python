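"""Intersection-of-Coexpression baseline.

Each candidate TF is scored by the number of known positive TFs whose
expression profile it is Spearman-correlated with above a threshold rho0
(strictly greater).  Candidates are ranked by that link count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ICEResult", "spearman", "ice_rank"]


@dataclass(frozen=True)
class ICEResult:
    tf_id: str
    link_count: int
    linked_positive_ids: frozenset[str]
    rank: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "linked_positive_ids", frozenset(self.linked_positive_ids)
        )
        if self.link_count != len(self.linked_positive_ids):
            raise ValueError("link_count must equal |linked_positive_ids|")


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (mean ranks for ties).

    A constant vector has no rank ordering; the correlation is undefined and
    is reported as 0 (no association) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant vector in spearman(); returning 0")
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _rank_standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise fractional ranks, centered and unit-norm (constants -> 0)."""
    ranks = stats.rankdata(values, axis=0)
    ranks = ranks - ranks.mean(axis=0)
    norms = np.linalg.norm(ranks, axis=0)
    constant = norms == 0.0
    norms[constant] = 1.0
    return ranks / norms, constant


def ice_rank(
    X_candidates: ExpressionMatrix,
    Y_positives: ExpressionMatrix,
    rho0: float = 0.6,
    use_abs: bool = False,
) -> list[ICEResult]:
    """Rank candidate TFs by the number of positives they are linked to.

    A candidate/positive pair is linked when its Spearman correlation is
    strictly greater than ``rho0`` (or ``|rho| > rho0`` with ``use_abs``).
    Ties in link count are broken lexicographically; ranks are 1-based.
    Candidate and positive id sets must be disjoint.
    """
    overlap = set(X_candidates.gene_ids) & set(Y_positives.gene_ids)
    if overlap:
        raise ValueError(
            f"candidate and positive TF sets must be disjoint; shared: {sorted(overlap)}"
        )
    if X_candidates.sample_ids != Y_positives.sample_ids:
        raise ValueError("candidate and positive blocks must share sample order")

    rx, const_x = _rank_standardize(X_candidates.values)
    ry, const_y = _rank_standardize(Y_positives.values)
    if const_x.any() or const_y.any():
        logger.warning("constant expression profiles treated as unlinked")
    rho = rx.T @ ry  # (n_candidates, m) Spearman correlations
    linked = np.abs(rho) > rho0 if use_abs else rho > rho0

    results = []
    for i, tf in enumerate(X_candidates.gene_ids):
        ids = frozenset(
            Y_positives.gene_ids[j] for j in np.flatnonzero(linked[i])
        )
        results.append((tf, ids))
    results.sort(key=lambda r: (-len(r[1]), r[0]))
    return [
        ICEResult(tf_id=tf, link_count=len(ids), linked_positive_ids=ids, rank=i + 1)
        for i, (tf, ids) in enumerate(results)
    ]
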