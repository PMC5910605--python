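# metanorm

Benchmarking normalization methods for shotgun-metagenomic gene-abundance
count data.

## The problem

Shotgun metagenomics measures the functional content of a microbial
community as counts of sequencing reads assigned to genes: a matrix
`Y_ij` of counts for gene `i = 1..m` in sample `j = 1..n`. These counts
carry large systematic between-sample variability — sequencing depth
alone commonly varies by an order of magnitude — and removing it
(*normalization*) is a prerequisite for identifying differentially
abundant genes (DAGs) between experimental conditions. The choice of
normalization method materially changes the result: when true effects
sit asymmetrically in one condition, abundance-based scaling factors
absorb part of the signal, deflating power and inflating the false
discovery rate.

`metanorm` is for bioinformaticians and statisticians who want to
benchmark normalization strategies under controlled, fully reproducible
conditions, or simply to normalize and test a gene × sample count table.

## What it implements

**Nine normalization methods** behind one contract. Scaling methods
produce a per-sample factor `N_j` consumed as a log offset; the other
two replace the counts:

| method | factor / transform |
|---|---|
| total count | `N_j = Σ_i Y_ij` |
| median | `N_j = median_{i∈G*} Y_ij`, `G*` = genes non-zero in ≥1 sample |
| upper quartile | 75th percentile over `G*` |
| TMM | trimmed, inverse-variance-weighted mean of log2 relative-abundance ratios vs a reference sample, × library size |
| RLE | `N_j = median_i Y_ij / (Π_j' Y_ij')^{1/n}` (median-of-ratios) |
| CSS | sum of counts up to a data-derived quantile threshold (≥ 50th pct.) |
| RCSS | sum of counts at or above the sample median |
| quantile–quantile | counts replaced by a per-rank median reference distribution |
| rarefying | subsample without replacement to the minimum library size |

**Differential-abundance inference.** Each gene is fit with the
overdispersed (quasi-)Poisson GLM

```
log E[Y_ij | x_j] = α_i + β_i x_j + log N_j,   Var[Y_ij] = φ_i E[Y_ij],
```

with `x_j` the 0/1 condition indicator; `φ_i` is the Pearson dispersion
of the full model. The DAG call is an F-test on the scaled deviance
drop, `F = (D_null − D_full)/φ̂ ~ F(1, n−2)`, with Benjamini–Hochberg
(or Benjamini–Yekutieli / Storey q-value) FDR control.

**Effect injection by binomial thinning.** Benchmark datasets are built
by resampling samples without replacement into two groups and replacing
the counts of randomly selected DAGs in one group by
`Binomial(Y_ij, q)` draws with `q = 1/fold_change` — an exact
`fold_change`-fold reduction in expectation that preserves the discrete,
never-increasing character of real counts. Four effect placements are
supported: balanced (10% DAGs, 50/50 across groups), lightly unbalanced
(10%, 75/25), unbalanced (10%, all in one group), heavily unbalanced
(20%, all in one group).

**Evaluation.** TPR at FPR 0.01, FPR at TPR 0.50, and true FDR at
estimated FDR 0.05, aggregated over iterations, plus p-value uniformity
(QQ/KS) and factor-correlation diagnostics.

**Synthetic data.** A hierarchical negative-binomial generator emulates
the marginal structure of real gene-abundance tables (heavy-tailed gene
baselines, log-uniform depth factors, Gamma-distributed gene-specific
overdispersion, emergent sparsity); see `docs/methods.md`.

## Worked example

Generate a synthetic dataset, then benchmark two methods under a
heavily-unbalanced effect scenario:

```python
import metanorm as mn

cm = mn.filter_genes(mn.generate_counts(mn.PRESETS["gut_like"], seed=1))
spec = mn.ScenarioSpec(samples_per_group=10, balance="heavily_unbalanced",
                       fold_change=3.0)
summaries, extras = mn.run_iteration(cm, spec, ["tmm", "total_count"],
                                     iteration=0, master_seed=1)
for s in summaries:
    print(f"{s.method}: TPR@FPR0.01={s.tpr_at_fpr:.2f}  "
          f"FPR@TPR0.50={s.fpr_at_tpr:.4f}  tFDR@eFDR0.05={s.tfdr_at_efdr:.2f}")
```

prints

```
tmm: TPR@FPR0.01=0.41  FPR@TPR0.50=0.0239  tFDR@eFDR0.05=0.13
total_count: TPR@FPR0.01=0.31  FPR@TPR0.50=0.0466  tFDR@eFDR0.05=0.16
```

Reading this: with 20% of genes thinned three-fold in one group, TMM
recovers 41% of the true DAGs at a 1% false-positive budget while total
count recovers 31%; at the cutoff where half the DAGs are found, total
count lets through roughly twice the false positives. One iteration is
noisy — `run_benchmark` repeats this over many resampled datasets.

The same is available from the shell:

```
metanorm simulate --preset gut_like --out counts.tsv --seed 1
metanorm normalize --counts counts.tsv --method tmm --out factors.tsv
metanorm test --counts counts.tsv --groups 0,0,...,1,1 --method tmm --out dags.tsv
metanorm run --config benchmark.yaml
```

`metanorm test` writes a per-gene table (`alpha`, `beta`, `dispersion`,
`F`, `p_value`, `p_adjusted`, `flag`); `metanorm run` writes a
long-format per-iteration table, an aggregated summary and a manifest
with every seed needed to reproduce the run bitwise.

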