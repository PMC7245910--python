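# countthin

Add a known, user-specified signal to a real (or synthetic) RNA-seq count
matrix by **binomial thinning**: each count `y_gn` is subsampled as
`Binomial(y_gn, 2**q_gn)` with a non-positive log2 factor matrix `Q` built
from design and coefficient blocks. Because a binomial subsample of a
Poisson or negative binomial count stays in the family, this shifts the
log2-mean of the data by exactly `Q` while preserving every source of
unwanted variation already present in the source data — which makes the
result a far more realistic benchmark for differential-expression,
confounder-adjustment, library-size and factor-analysis methods than fully
parametric simulation.

## Features

- **`thin_diff`** — arbitrary signal injection from a fixed block
  `(X2, B2)` and a permutable block `(X3, B3)` whose design rows are
  reordered by a random permutation; a custom non-positive `Q` matrix can
  be supplied directly for non-linear signals.
- **`thin_2group`** — the classic two-group benchmark: binary indicator,
  per-gene log2 fold-changes drawn from a user sampler, optionally scaled
  by `s_g**alpha` (the per-gene sd of `log2(Y + 0.5)`).
- **`thin_lib` / `thin_gene` / `thin_all`** — per-sample, per-gene and
  global uniform depth reduction.
- **Correlation targeting** — choose the permutation so the permuted
  design columns have a requested correlation with latent factors
  estimated by truncated SVD: conditional-normal latent target, Schur
  feasibility repair by iterative shrinkage, and exact (Hungarian), greedy
  or Gale–Shapley row matching. `estimate_realized_correlation` reports
  the correlation the pipeline actually attains.
- **Effects & summaries** — effect-size generation and per-gene / median
  proportion of variance explained (PVE).
- **Synthetic base generator** — Poisson, negative binomial or
  zero-inflated negative binomial counts with optional low-rank structure,
  so everything is testable without downloads.

## CLI

All subcommands take `--seed` and write their outputs plus a
`manifest.json` into `--out`; `countthin replay` reruns any manifest
bit-exactly.

```sh
# synthetic base counts (genes x samples TSV; MTX also supported)
countthin simulate --config model.yaml --out base/ --seed 1

# two-group benchmark: N(0, 0.8^2) log2 fold-changes on 25% of genes
countthin thin 2group --counts base/counts.tsv --prop-null 0.75 \
    --effect-sd 0.8 --out run/ --seed 2

# arbitrary designs, with the permuted block steered toward a target
# correlation with 2 latent factors
countthin thin diff --counts base/counts.tsv \
    --design-perm x3.tsv --coef-perm b3.tsv \
    --target-cor r.tsv --num-sv 2 --match-method hungarian \
    --out run/ --seed 3

# depth manipulation
countthin thin lib  --counts base/counts.tsv --factors lib_factors.txt --out l/ --seed 4
countthin thin gene --counts base/counts.tsv --factors gene_factors.txt --out g/ --seed 5
countthin thin all  --counts base/counts.tsv --factor -1.0 --out a/ --seed 6

# what correlation will the permutation pipeline really achieve?
countthin estimate-cor --counts base/counts.tsv --design-perm x3.tsv \
    --target-cor r.tsv --n-mc 100 --out cor/ --seed 7

# per-gene PVE of the injected signal for a finished run
countthin pve --result-dir run/ --out pve/

# reproduce any recorded run
countthin replay --manifest run/manifest.json --out run_copy/
```

File conventions: counts are TSV (first column `gene`, header = sample
ids) or MatrixMarket MTX with `<stem>.genes.txt` / `<stem>.samples.txt`
label sidecars; designs, coefficients and target correlations are headered
TSV with a leading label column; factor vectors are one value per line.
Permutations are serialized 0-based with the convention that permuted
design row `n` is original row `pi[n]`.

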