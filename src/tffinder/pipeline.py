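"""End-to-end pipeline: inputs -> cluster-bait ASCCA -> ranked candidates.

Wires the stages together: read and validate the four inputs, standardize,
run the cluster-bait loop, apply the enrichment retention test, pool
retained sets into a frequency ranking, and optionally run the ICE baseline
for comparison.  All randomness flows from the single config seed and the
result files are byte-reproducible for a fixed config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .ascca import PenaltyParams, penalty_grid
from .cluster import BaitConfig, coarse_grid, run_bait_loop
from .enrichment import frequency_rank, top_k
from .ice import ice_rank
from .io import (
    read_expression_tsv,
    read_gene_list,
    write_hooked_sets_tsv,
    write_ice_tsv,
    write_ranked_tsv,
)
from .matrix import standardize

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated settings for one pipeline run."""

    expression_path: Path
    all_tfs_path: Path
    positive_tfs_path: Path
    positive_targets_path: Path
    out_dir: Path
    s_min: int = 4
    s_max: int = 20
    ef: float = 3.0
    grid: str = "coarse"  # "coarse" | "full" | explicit tuple via custom_grid
    custom_grid: tuple[PenaltyParams, ...] = ()
    cv_k: int = 5
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    top_k: int = 70
    rho0: float = 0.6
    run_ice: bool = True
    kmeans_restarts: int = 10

    def __post_init__(self) -> None:
        problems = []
        if self.s_min < 1 or self.s_min > self.s_max:
            problems.append(f"invalid cluster-size range [{self.s_min}, {self.s_max}]")
        if not 0 < self.ef:
            problems.append(f"EF must be positive, got {self.ef}")
        if self.cv_k < 2:
            problems.append(f"cv_k must be >= 2, got {self.cv_k}")
        if self.tol <= 0:
            problems.append(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            problems.append(f"max_iter must be >= 1, got {self.max_iter}")
        if self.top_k < 1:
            problems.append(f"top_k must be >= 1, got {self.top_k}")
        if not -1 <= self.rho0 <= 1:
            problems.append(f"rho0 must be in [-1, 1], got {self.rho0}")
        if self.grid not in ("coarse", "full", "custom"):
            problems.append(f"grid must be coarse|full|custom, got {self.grid!r}")
        if self.grid == "custom" and not self.custom_grid:
            problems.append("grid='custom' requires custom_grid")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
        for name in ("expression_path", "all_tfs_path", "positive_tfs_path",
                     "positive_targets_path", "out_dir"):
            object.__setattr__(self, name, Path(getattr(self, name)))

    def resolve_grid(self) -> list[PenaltyParams]:
        if self.grid == "full":
            return penalty_grid()
        if self.grid == "custom":
            return list(self.custom_grid)
        return coarse_grid()


def _validate_ids(matrix_genes, all_tfs, positive_tfs, positive_targets):
    genes = set(matrix_genes)
    problems = []
    missing_tfs = [g for g in all_tfs if g not in genes]
    if missing_tfs:
        problems.append(f"TF ids absent from expression matrix: {missing_tfs[:10]}")
    missing_tgts = [g for g in positive_targets if g not in genes]
    if missing_tgts:
        problems.append(f"target ids absent from expression matrix: {missing_tgts[:10]}")
    not_in_universe = [g for g in positive_tfs if g not in set(all_tfs)]
    if not_in_universe:
        problems.append(
            f"positive TFs not in the TF universe: {not_in_universe[:10]}"
        )
    overlap = set(all_tfs) & set(positive_targets)
    if overlap:
        problems.append(
            f"positive targets overlap the TF list: {sorted(overlap)[:10]}"
        )
    if problems:
        raise ValueError("input validation failed:\n  " + "\n  ".join(problems))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full workflow and write result tables under out_dir.

    Returns paths for: ranked (full frequency ranking), top (first top_k),
    hooked_sets (per-run provenance), run_log, and, when ICE is enabled,
    ice (baseline ranking) and comparison (ids shared by both top lists).
    """
    t0 = time.perf_counter()
    expression = read_expression_tsv(config.expression_path)
    all_tfs = read_gene_list(config.all_tfs_path)
    positive_tfs = read_gene_list(config.positive_tfs_path)
    positive_targets = read_gene_list(config.positive_targets_path)
    _validate_ids(expression.gene_ids, all_tfs, positive_tfs, positive_targets)
    t_read = time.perf_counter() - t0

    t0 = time.perf_counter()
    used = list(all_tfs) + list(positive_targets)
    std = standardize(expression.select(used))
    X = std.select(all_tfs)
    Y = std.select(positive_targets)
    bait = BaitConfig(
        s_min=config.s_min,
        s_max=config.s_max,
        grid=tuple(config.resolve_grid()),
        cv_k=config.cv_k,
        ef=config.ef,
        tol=config.tol,
        max_iter=config.max_iter,
        seed=config.seed,
        kmeans_restarts=config.kmeans_restarts,
    )
    hooked = run_bait_loop(X, Y, positive_tfs, bait)
    ranked = frequency_rank(hooked, positive_tfs)
    top = top_k(ranked, config.top_k)
    t_bait = time.perf_counter() - t0

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranked": write_ranked_tsv(ranked, out / "ranked_tfs.tsv"),
        "top": write_ranked_tsv(top, out / f"top_{config.top_k}_tfs.tsv"),
        "hooked_sets": write_hooked_sets_tsv(hooked, out / "hooked_sets.tsv"),
    }

    t0 = time.perf_counter()
    if config.run_ice:
        candidates = [g for g in all_tfs if g not in set(positive_tfs)]
        ice = ice_rank(X.select(candidates), X.select(positive_tfs), rho0=config.rho0)
        paths["ice"] = write_ice_tsv(ice, out / "ice_ranked_tfs.tsv")
        ice_top = {r.tf_id for r in ice[: config.top_k]}
        finder_top = {r.tf_id for r in top}
        common = sorted(finder_top & ice_top)
        comparison = out / "comparison.tsv"
        with comparison.open("w", newline="\n") as fh:
            fh.write("tf_id\tin_tf_finder_top\tin_ice_top\n")
            for tf in common:
                fh.write(f"{tf}\t1\t1\n")
        paths["comparison"] = comparison
    t_ice = time.perf_counter() - t0

    # timings go to the stderr log only; run_log.txt stays byte-reproducible
    logger.info(
        "timings: read=%.2fs bait=%.2fs ice=%.2fs", t_read, t_bait, t_ice
    )
    run_log = out / "run_log.txt"
    retained = sum(1 for h in hooked if h.retained)
    with run_log.open("w", newline="\n") as fh:
        fh.write("tffinder run log\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"s_min\t{config.s_min}\ns_max\t{config.s_max}\n")
        fh.write(f"ef\t{config.ef}\ngrid\t{config.grid}\ncv_k\t{config.cv_k}\n")
        fh.write(f"tol\t{config.tol}\nmax_iter\t{config.max_iter}\n")
        fh.write(f"top_k\t{config.top_k}\nrho0\t{config.rho0}\n")
        fh.write(f"n_tfs\t{len(all_tfs)}\nn_positive_tfs\t{len(positive_tfs)}\n")
        fh.write(f"n_targets\t{len(positive_targets)}\n")
        fh.write(f"n_bait_runs\t{len(hooked)}\nn_retained_sets\t{retained}\n")
        fh.write(f"n_ranked_tfs\t{len(ranked)}\n")
    paths["run_log"] = run_log
    return paths
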