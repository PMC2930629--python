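"""Expression-matrix container, column standardization and cross-correlation.

The internal orientation is samples x genes: each column is one gene's
expression profile across samples.  Two standardized blocks (TFs as ``X``,
targets as ``Y``) share their sample axis, and their cross-correlation
matrix ``K`` is the Pearson correlation of every TF column with every
target column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CrossCorrelationMatrix",
    "standardize",
    "cross_correlation",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes: list[str] = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes block of real-valued expression data.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers, length ``n``.
    gene_ids
        Ordered gene identifiers, one per column.
    values
        ``(n, len(gene_ids))`` float array.  Missing values are rejected.
    standardized
        True once every column has mean 0 and sample variance 1.
    """

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, gene {self.gene_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.gene_ids, "gene_ids")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def select(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix restricted to ``gene_ids`` (given order)."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"gene ids not present in matrix: {missing}")
        cols = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            sample_ids=self.sample_ids,
            gene_ids=tuple(gene_ids),
            values=self.values[:, cols],
            standardized=self.standardized,
        )


@dataclass(frozen=True)
class CrossCorrelationMatrix:
    """Pearson cross-correlation block between TF and target columns."""

    values: np.ndarray
    row_gene_ids: tuple[str, ...]
    col_gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_gene_ids", tuple(self.row_gene_ids))
        object.__setattr__(self, "col_gene_ids", tuple(self.col_gene_ids))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.row_gene_ids), len(self.col_gene_ids)):
            raise ValueError("shape does not match row/col gene id counts")
        if not np.isfinite(values).all():
            raise ValueError("cross-correlation matrix contains non-finite values")
        if np.abs(values).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("cross-correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center every column to mean 0 and scale to sample variance 1.

    Uses the n-1 denominator, so a standardized block's cross-products are
    exactly Pearson correlations.  Idempotent up to floating-point noise.

    Raises
    ------
    ValueError
        If the matrix has fewer than 3 samples or any column is constant;
        the error names the offending gene so it can be removed upstream.
    """
    if matrix.n_samples < 3:
        raise ValueError(
            f"standardization needs at least 3 samples, got {matrix.n_samples}"
        )
    means = matrix.values.mean(axis=0)
    stds = matrix.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(stds == 0.0)
    if zero.size:
        names = [matrix.gene_ids[j] for j in zero[:10]]
        raise ValueError(
            f"constant (zero-variance) column(s) {names}; "
            "remove these genes upstream before standardizing"
        )
    return replace(
        matrix,
        values=(matrix.values - means) / stds,
        standardized=True,
    )


def cross_correlation(
    X: ExpressionMatrix, Y: ExpressionMatrix
) -> CrossCorrelationMatrix:
    """Pearson correlation of every X column against every Y column.

    Both blocks must already be standardized and share the exact sample
    order; no silent reordering is attempted.
    """
    if not (X.standardized and Y.standardized):
        raise ValueError("both blocks must be standardized before correlation")
    if X.sample_ids != Y.sample_ids:
        raise ValueError(
            "sample ids differ or are ordered differently between X and Y"
        )
    n = X.n_samples
    K = (X.values.T @ Y.values) / (n - 1)
    # tiny float excursions beyond +-1 are legitimate rounding
    np.clip(K, -1.0, 1.0, out=K)
    return CrossCorrelationMatrix(
        values=K, row_gene_ids=X.gene_ids, col_gene_ids=Y.gene_ids
    )
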