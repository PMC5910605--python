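# Methods

## Data model

Gene abundances are non-negative integer counts `Y_ij` (gene `i = 1..m`,
sample `j = 1..n`). Before analysis, genes with more than 75% zero
counts or a mean count below three are removed (both thresholds strict
on the removal side, so exactly 75% zeros or a mean of exactly three
survives). The filter is applied once to the matrix as given; it is not
re-applied after effect injection, since thinning is part of the
simulated truth rather than of data preparation.

## Normalization

Seven scaling methods return a per-sample factor `N_j` consumed
downstream as the offset `log N_j`; two methods (quantile–quantile,
rarefying) replace the counts and run with zero offsets. Conventions
that the underlying formulas leave open were fixed as follows:

- **Percentiles** use linear interpolation between order statistics
  (the numpy default), uniformly across median, upper quartile, CSS and
  RCSS. The test oracles share the convention.
- **TMM**: the reference sample under `auto` is the one whose upper
  quartile of relative abundances is closest to the across-sample mean
  upper quartile. Genes with a zero in either the sample or the
  reference are excluded (their log-ratio is undefined). Trims are
  symmetric two-sided, `trim_m/2` and `trim_a/2` per tail (defaults
  0.30 and 0.05 total), with ties resolved by stable sort order. The
  weights are the inverse delta-method variances
  `1/w_i = (T_j−Y_ij)/(T_j Y_ij) + (T_r−Y_ir)/(T_r Y_ir)`. Because
  these weights depend on raw counts and not only on relative
  abundances, the adjustment `f_j` is only *approximately* invariant to
  rescaling one sample's depth (the M-values, A-values and trimmed set
  are exactly invariant; the weight mix shifts by O(1%)). An empty
  post-trim gene set falls back to `f_j = 1` with a logged warning.
- **RLE**: the per-gene pseudo-reference is the geometric mean across
  samples, restricted to genes positive in every sample; `N_j` is the
  median of the raw ratios `Y_ij/g_i` (not of log-ratios — the two
  differ when an even count makes the median interpolate).
- **CSS**: per-sample quantiles of the *positive* counts are evaluated
  on a 0.01-step grid of levels; the instability at level `l` is
  `d_l = median_j |q_j^l − median_j' q_j'^l|`. The shared level `l̂` is
  the smallest grid level ≥ 0.50 whose relative instability increase
  `(d_l − d_{l−1})/d_l` exceeds the stability threshold (default 0.10);
  degenerate cases (all `d_l = 0`, or no qualifying level) fall back to
  0.50 with a logged warning. `N_j` sums sample `j`'s counts at or
  below its own count threshold `q_j^(l̂)`.
- **RCSS** sums counts `≥` the per-sample median (inclusive, matching
  the set-builder form of the definition; an exclusive `>` variant is
  selectable).
- **Quantile–quantile** preserves discreteness: the reference is the
  per-rank median of the sorted columns, and with an even number of
  samples one of the two middle order statistics is chosen at random
  per rank. Ties within a sample receive ranks in random order. The
  defining property — every transformed column sorts to the reference —
  is asserted on every call.
- **Rarefying** draws each column from the multivariate hypergeometric
  distribution (sampling fragments without replacement) at the minimum
  library size by default.

Offsets use the raw `N_j` without rescaling: a global constant is
absorbed by the intercept `α_i`, so inference is invariant to it.
Diagnostics that compare factor magnitudes across methods rescale to
geometric mean 1 first.

## Inference

Counts are modeled per gene with the overdispersed Poisson GLM
`log E[Y_ij|x_j] = α_i + β_i x_j + log N_j`,
`Var = φ_i · E`. For a two-group design with offsets the Poisson
maximum-likelihood estimates are closed-form — the fitted rate in each
group is the offset-weighted group mean — so the package fits all genes
in one vectorized pass with no iteration; the estimates are the exact
MLEs (verified against an iteratively fitted GLM in the tests). The
dispersion is the standard quasi-Poisson estimator, Pearson `χ²/(n−2)`
from the full model, not floored at one (under-dispersion is allowed).

The DAG test is `F = (D_null − D_full)/φ̂` referred to `F(1, n−2)`.
Genes that are all-zero get `p = 1` and a `degenerate` flag; genes with
one group all-zero keep their actual deviance-based p-value but are
flagged (their reported `β̂` uses a 0.5-count continuity floor on the
empty group's total, since the raw MLE is infinite). `φ̂` is floored at
`1e−12` only to avoid division by zero in the exactly-fitted case.

Multiplicity: Benjamini–Hochberg (default) and Benjamini–Yekutieli via
statsmodels; Storey q-values use the fixed-λ estimator
`π̂₀ = min(1, #{p>0.5}/(0.5 m))`, chosen over the smoother for
small-m stability.

## Effect injection

Two groups of `k` samples are drawn uniformly without replacement.
`round(dag_fraction · m)` genes (ties round half away from zero) are
flagged as DAGs and split between the groups according to the balance
preset; in fully unbalanced presets the affected group is always group
1 (sufficient by symmetry). Each affected cell is independently
replaced by `Binomial(Y_ij, q)`, `q = 1/fold_change`, giving
`E[Ŷ] = qY` and `Var[Ŷ] = q(1−q)Y`. DAG selection is re-drawn each
iteration. Random streams are keyed by (master seed, scenario seed,
iteration, stage index), so stages are independent, results are
bitwise reproducible, and a method's stream does not depend on which
other methods run.

## Synthetic data generator

The generator stands in for real gene-abundance tables and reproduces
their marginal structure:

- gene baselines `μ_i ~ LogNormal(mean_log_mu, mean_log_sigma)` — the
  heavy tail concentrates most of the library in few genes;
- depth factors `d_j ~ 10^Uniform(0, depth_log10_range)`, rescaled to
  geometric mean 1 so `mean_log_mu` keeps its meaning;
- dispersions `φ_i ~ 1 + Gamma(shape, rate)` (variance/mean ratio ≥ 1);
- `Y_ij ~ NB(mean = d_j μ_i, variance = d_j μ_i φ_i)`.

Defaults (`mean_log_mu 2`, `mean_log_sigma 1.5`, one decade of depth,
dispersion mean 3) describe a moderately deep, moderately overdispersed
dataset; the `gut_like` preset is shallower and sparser, `marine_like`
deeper with a heavier tail. These values are the package's own
calibration of qualitative features — realistic orders of magnitude for
between-sample depth spread and overdispersion — not estimates from any
specific study. Sparsity is emergent (small `μ_i × d_j`), not injected.

What the generator deliberately omits: gene–gene correlation,
sample–sample correlation, and compositional closure. Benchmark results
on synthetic data therefore demonstrate the *relative* behavior of the
methods under asymmetric effects — which is driven by the mechanics of
scaling-factor estimation and reproduces cleanly — but absolute TPR/FDR
levels on real data, where genes co-vary and effects correlate, may
differ. `estimate_profile` provides a method-of-moments fit so users
can mimic the marginal structure of their own matrix.

## Evaluation conventions

Genes are ranked by ascending p-value, ties broken by gene index
(stable sort; the brute-force test oracles share the rule). Operating
points on discrete ranks use no interpolation: TPR is read at the
*largest* cutoff whose FPR does not exceed 0.01 (conservative), FPR at
the *smallest* cutoff whose TPR reaches 0.50 (1.0 with a warning if
unreachable). True FDR is evaluated on the selection
`{p_adjusted ≤ 0.05}`; an empty selection is reported as 0 with a
separate flag so aggregation can audit the convention. Aggregation
reports mean, median and the 2.5/97.5 percentiles across iterations
(both mean and median are of interest; they can differ noticeably for
skewed FDR distributions).

## Benchmark sizes and budgets

The shipped directional benchmark uses 2,000 genes × 60 samples,
10+10 samples per group, fold-change 3, and 25 iterations per scenario
— sizes chosen so a full two-scenario, nine-method run completes in a
few seconds on one CPU while keeping Monte-Carlo error small enough for
the method ordering to be stable across seeds. The calibration checks
use 5,000 null genes (type-I error standard error ≈ 0.003).

## Known limitations

- The closed-form fit covers exactly the two-group-with-offset design;
  covariate extensions would need a genuine IRLS loop.
- CSS's selection rule is one concrete reading of a heuristic with
  several published variants; the level grid and threshold are
  configurable.
- The F-test's small-sample calibration degrades at 3+3 (df = 4), as
  expected for a dispersion estimated from six observations; this
  mirrors the method's intended use, not an implementation defect.
- Iterations run serially; the stage-keyed seed schedule makes them
  independent, so parallel execution would be byte-identical, but no
  parallel backend is wired in.
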