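# tffinder

Candidate transcription-factor (TF) discovery from genome-wide expression
data.  Known positive target genes are partitioned into clusters at a range
of average sizes; each cluster baits TFs through an adaptive sparse
canonical correlation analysis (ASCCA) against the full TF expression
block; every hooked TF set is kept only if it is enriched for known
positive TFs; retained sets are pooled and TFs are ranked by how many sets
they appear in.  An Intersection-of-Coexpression (ICE) baseline — ranking
candidates by the number of positive TFs they are Spearman-correlated with
above a threshold — is included for comparison.

## Method sketch

For standardized blocks `X` (samples × TFs) and `Y` (samples × targets),
the cross-correlation matrix `K = X'Y/(n−1)` is attacked by alternating
power steps with adaptive soft-thresholding: each coefficient's L1
threshold is `λ/2` scaled by `|reference|^(−γ)`, where the reference is the
first SVD pair of `K`.  Penalties `(λu, λv, γ)` are chosen on a grid by
k-fold cross-validation of the held-out canonical correlation.  The default
full grid screens λ from 0 to 0.4 in steps of 0.01 and γ from 0 to 2 in
steps of 0.1 (35301 triples); a coarse grid is the default for pipeline
runs.  Target clusters are produced by k-means at every integer average
cluster size from 4 to 20.  A hooked set with `n` TFs is retained when its
overlap with the `N_pos` known positives (of `N` total TFs) strictly
exceeds `EF · (N_pos/N) · n`, with `EF = 3` by default.

## Command line

```sh
# make a synthetic dataset with planted regulatory modules
tffinder simulate --out-dir data --n-modules 2 --n-decoy-tfs 200 --seed 1

# run the full pipeline (writes ranked_tfs.tsv, hooked_sets.tsv, ...)
tffinder run \
    --expression data/expression.tsv \
    --all-tfs data/all_tfs.txt \
    --positive-tfs data/positive_tfs.txt \
    --positive-targets data/positive_targets.txt \
    --out-dir results --seed 1

# ICE baseline and a top-k overlap report
tffinder ice --expression data/expression.tsv \
    --candidates data/candidates.txt --positives data/positive_tfs.txt \
    --out results/ice.tsv
tffinder compare results/ranked_tfs.tsv results/ice_ranked_tfs.tsv --top-k 70

# one ASCCA fit with fixed or cross-validated penalties
tffinder ascca --expression data/expression.tsv \
    --x-genes data/all_tfs.txt --y-genes data/positive_targets.txt \
    --lambda-u 0.1 --lambda-v 0.1 --gamma 1.0 --out loadings.tsv
```

Inputs: a tab-separated expression table (`gene_id` column then one column
per sample, one row per gene, already normalized) and three gene-list files
(one id per line, `#` comments allowed): all TF ids, known positive TF ids,
and known positive target ids (disjoint from the TFs).

## Library use

```python
from tffinder import (
    simulate_regulatory_dataset, standardize, BaitConfig,
    run_bait_loop, frequency_rank,
)

ds = simulate_regulatory_dataset(seed=1)
std = standardize(ds.expression)
X, Y = std.select(ds.all_tf_ids), std.select(ds.positive_target_ids)
hooked = run_bait_loop(X, Y, ds.positive_tf_ids, BaitConfig(seed=1))
ranked = frequency_rank(hooked, ds.positive_tf_ids)
```

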