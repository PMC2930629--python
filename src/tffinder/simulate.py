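"""Seeded synthetic expression datasets with planted regulatory modules.

Each module has a handful of "true" TF profiles (iid standard normal) and
target genes built as linear combinations of the module's TFs plus Gaussian
noise; decoy TFs and targets are independent noise.  Half of the true TFs
(rounded up, per module) play the role of known positive TFs, and all
module targets are the known positive targets, so the planted truth exposes
every pipeline stage to an exact oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SyntheticDataset", "simulate_regulatory_dataset", "write_fixture"]


@dataclass(frozen=True)
class SyntheticDataset:
    expression: ExpressionMatrix
    all_tf_ids: tuple[str, ...]
    positive_tf_ids: tuple[str, ...]
    positive_target_ids: tuple[str, ...]
    truth: dict[str, dict[str, list[str]]]
    seed: int
    noise_sd: float


def simulate_regulatory_dataset(
    n_samples: int = 60,
    n_modules: int = 2,
    tfs_per_module: int = 3,
    targets_per_module: int = 10,
    n_decoy_tfs: int = 200,
    n_decoy_targets: int = 0,
    noise_sd: float = 0.2,
    effect_matrix_scale: float = 1.0,
    seed: int = 0,
    positive_fraction: float = 0.5,
    mixed_sign: bool = False,
) -> SyntheticDataset:
    """Generate a dataset with ``n_modules`` planted TF -> target modules.

    Target weights are Uniform(0.5, 1.5) * effect_matrix_scale, positive by
    default; ``mixed_sign`` flips each weight's sign at random, emulating
    activator/repressor mixtures that defeat purely positive coexpression.
    Regeneration with the same seed is byte-identical.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if min(n_modules, tfs_per_module, targets_per_module) < 1:
        raise ValueError("module counts must be >= 1")
    if min(n_decoy_tfs, n_decoy_targets) < 0:
        raise ValueError("decoy counts must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < positive_fraction <= 1:
        raise ValueError("positive_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    gene_ids: list[str] = []
    all_tf_ids: list[str] = []
    positive_tf_ids: list[str] = []
    positive_target_ids: list[str] = []
    truth: dict[str, dict[str, list[str]]] = {}

    n_pos_per_module = int(np.ceil(positive_fraction * tfs_per_module))
    module_targets: list[tuple[str, np.ndarray]] = []
    for m in range(1, n_modules + 1):
        tf_block = rng.standard_normal((n_samples, tfs_per_module))
        tf_ids = [f"TF_m{m}_{i}" for i in range(1, tfs_per_module + 1)]
        for i, tf in enumerate(tf_ids):
            gene_ids.append(tf)
            columns.append(tf_block[:, i])
        all_tf_ids.extend(tf_ids)
        positive_tf_ids.extend(tf_ids[:n_pos_per_module])

        tgt_ids = [f"TGT_m{m}_{j}" for j in range(1, targets_per_module + 1)]
        for tgt in tgt_ids:
            w = rng.uniform(0.5, 1.5, tfs_per_module) * effect_matrix_scale
            if mixed_sign:
                w *= rng.choice([-1.0, 1.0], tfs_per_module)
            profile = tf_block @ w + rng.normal(0.0, noise_sd, n_samples)
            module_targets.append((tgt, profile))
        positive_target_ids.extend(tgt_ids)
        truth[f"m{m}"] = {"tfs": tf_ids, "targets": tgt_ids}

    for i in range(1, n_decoy_tfs + 1):
        tf = f"DECOY_TF_{i}"
        gene_ids.append(tf)
        all_tf_ids.append(tf)
        columns.append(rng.standard_normal(n_samples))

    for tgt, profile in module_targets:
        gene_ids.append(tgt)
        columns.append(profile)

    for j in range(1, n_decoy_targets + 1):
        gene_ids.append(f"DECOY_TGT_{j}")
        columns.append(rng.standard_normal(n_samples))

    expression = ExpressionMatrix(
        sample_ids=tuple(f"S{i}" for i in range(1, n_samples + 1)),
        gene_ids=tuple(gene_ids),
        values=np.column_stack(columns),
    )
    return SyntheticDataset(
        expression=expression,
        all_tf_ids=tuple(all_tf_ids),
        positive_tf_ids=tuple(positive_tf_ids),
        positive_target_ids=tuple(positive_target_ids),
        truth=truth,
        seed=seed,
        noise_sd=noise_sd,
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the four pipeline input files plus a truth JSON for tests.

    Returns a mapping of logical names to paths:
    expression, all_tfs, positive_tfs, positive_targets, truth.
    """
    from .io import write_expression_tsv  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "all_tfs": directory / "all_tfs.txt",
        "positive_tfs": directory / "positive_tfs.txt",
        "positive_targets": directory / "positive_targets.txt",
        "truth": directory / "truth.json",
    }
    try:
        write_expression_tsv(dataset.expression, paths["expression"])
        paths["all_tfs"].write_text("\n".join(dataset.all_tf_ids) + "\n")
        paths["positive_tfs"].write_text("\n".join(dataset.positive_tf_ids) + "\n")
        paths["positive_targets"].write_text(
            "\n".join(dataset.positive_target_ids) + "\n"
        )
        paths["truth"].write_text(json.dumps(dataset.truth, indent=1, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return paths
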