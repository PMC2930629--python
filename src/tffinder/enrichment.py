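"""Retention test for hooked TF sets and pooled frequency ranking.

A hooked set (the TFs with nonzero loadings from one bait run) is retained
only if it contains strictly more known positive TFs than EF times the
count expected by chance, ``EF * (N_pos / N) * n_ascca``.  Retained sets
are pooled: each TF is ranked by the number of retained sets it appears in.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .ascca import PenaltyParams

logger = logging.getLogger(__name__)

__all__ = ["HookedTFSet", "RankedTF", "enrichment_filter", "frequency_rank", "top_k"]


@dataclass(frozen=True)
class HookedTFSet:
    """TFs hooked by one bait run, with enrichment statistics."""

    tf_ids: frozenset[str]
    n_ascca: int
    n_pos_overlap: int
    retained: bool
    provenance: Optional[tuple[int, int, PenaltyParams]] = None  # (s, cluster, params)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tf_ids", frozenset(self.tf_ids))
        if self.n_ascca != len(self.tf_ids):
            raise ValueError("n_ascca must equal |tf_ids|")
        if not 0 <= self.n_pos_overlap <= self.n_ascca:
            raise ValueError("n_pos_overlap out of range")


@dataclass(frozen=True)
class RankedTF:
    tf_id: str
    frequency: int
    rank: int
    is_known_positive: bool


def enrichment_filter(
    tf_ids: Iterable[str],
    positive_tf_ids: Iterable[str],
    N: int,
    EF: float = 3.0,
    provenance: Optional[tuple[int, int, PenaltyParams]] = None,
) -> HookedTFSet:
    """Decide whether a hooked TF set is retained.

    Retained iff ``overlap > EF * (N_pos / N) * n_ascca`` (strict), where
    ``N`` is the size of the TF universe and ``N_pos`` the number of known
    positives in it.
    """
    if N <= 0:
        raise ValueError("N (size of the TF universe) must be positive")
    if EF <= 0:
        raise ValueError("EF must be positive")
    tf_ids = frozenset(tf_ids)
    positives = frozenset(positive_tf_ids)
    if len(positives) > N:
        raise ValueError("more positive TFs than the universe size N")
    if len(positives) == 0:
        logger.warning(
            "no known positive TFs: every nonempty hooked set will be discarded"
        )
    n_ascca = len(tf_ids)
    overlap = len(tf_ids & positives)
    threshold = EF * (len(positives) / N) * n_ascca
    return HookedTFSet(
        tf_ids=tf_ids,
        n_ascca=n_ascca,
        n_pos_overlap=overlap,
        retained=overlap > threshold,
        provenance=provenance,
    )


def frequency_rank(
    sets: Sequence[HookedTFSet],
    positive_tf_ids: Iterable[str] = (),
) -> list[RankedTF]:
    """Count, over retained sets only, how many sets contain each TF.

    Sorted by frequency descending with lexicographic tf_id tie-break;
    ranks are 1-based and consecutive.  Discarded sets contribute nothing.
    """
    positives = frozenset(positive_tf_ids)
    counts: Counter[str] = Counter()
    for s in sets:
        if s.retained:
            counts.update(s.tf_ids)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        RankedTF(
            tf_id=tf,
            frequency=freq,
            rank=i + 1,
            is_known_positive=tf in positives,
        )
        for i, (tf, freq) in enumerate(ordered)
    ]


def top_k(ranked: Sequence[RankedTF], k: int = 70) -> list[RankedTF]:
    """First min(k, len) entries of a ranked list, order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(ranked[:k])
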