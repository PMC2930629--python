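"""Readers and writers for the plain-text input/output formats.

Expression data is a tab-separated table with a ``gene_id`` header column
followed by sample ids, one gene per row; gene lists are one identifier per
line with ``#`` comments.  Output tables are TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import HookedTFSet, RankedTF
from .ice import ICEResult
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "write_ranked_tsv",
    "write_hooked_sets_tsv",
    "write_ice_tsv",
]


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Parse a genes x samples TSV into the internal samples x genes layout.

    Handles both Unix and Windows line endings.  Duplicate gene ids and
    non-numeric cells are errors that name the offending coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty expression file")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate gene id(s): {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values & df.notna().values)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if numeric.isna().values.any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(
        sample_ids=tuple(str(c) for c in df.columns),
        gene_ids=tuple(str(g) for g in df.index),
        values=numeric.values.T,
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write genes as rows, samples as columns, full float repr (lossless)."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.values.T, index=list(matrix.gene_ids), columns=list(matrix.sample_ids)
    )
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blanks and ``#`` comments skipped.

    Duplicates are collapsed (first occurrence wins) with a warning; an
    empty result is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: dict[str, None] = {}
    dupes = []
    for line in path.read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            dupes.append(token)
        seen[token] = None
    if dupes:
        logger.warning("%s: duplicate id(s) collapsed: %s", path, sorted(set(dupes)))
    if not seen:
        raise ValueError(f"{path}: no gene identifiers found")
    return list(seen)


def write_ranked_tsv(ranked: Sequence[RankedTF], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("rank\ttf_id\tfrequency\tis_known_positive\n")
        for r in ranked:
            fh.write(f"{r.rank}\t{r.tf_id}\t{r.frequency}\t{int(r.is_known_positive)}\n")
    return path


def write_hooked_sets_tsv(sets: Sequence[HookedTFSet], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(
            "s\tcluster\tlambda_u\tlambda_v\tgamma\tn_ascca\tn_pos_overlap\tretained\n"
        )
        for h in sets:
            s, ci, params = h.provenance if h.provenance else (-1, -1, None)
            lu = f"{params.lambda_u:g}" if params else ""
            lv = f"{params.lambda_v:g}" if params else ""
            g = f"{params.gamma:g}" if params else ""
            fh.write(
                f"{s}\t{ci}\t{lu}\t{lv}\t{g}\t{h.n_ascca}\t{h.n_pos_overlap}"
                f"\t{int(h.retained)}\n"
            )
    return path


def write_ice_tsv(results: Sequence[ICEResult], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("rank\ttf_id\tlink_count\tlinked_positive_ids\n")
        for r in results:
            ids = ",".join(sorted(r.linked_positive_ids))
            fh.write(f"{r.rank}\t{r.tf_id}\t{r.link_count}\t{ids}\n")
    return path
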