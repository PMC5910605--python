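"""Nine normalization methods for gene-abundance count data.

Seven *scaling* methods derive a per-sample factor ``N_j`` that enters the
inference model as a log offset:

- total count: library size (column sum);
- median / upper quartile: 50th / 75th percentile of the counts of genes
  that are non-zero in at least one sample (the set ``G*``);
- TMM: trimmed, inverse-variance-weighted mean of log2 fold-changes of
  relative abundances against a reference sample, times the library size;
- RLE: median ratio of counts to a per-gene geometric-mean pseudo-reference;
- CSS: cumulative sum of counts up to a data-derived quantile threshold
  chosen where the sample-specific quantiles start to diverge;
- RCSS: cumulative sum of the counts at or above the sample median.

Two *count-replacing* methods return transformed counts instead (their
factors are all 1 and inference runs with zero offsets):

- quantile-quantile: each sample's count distribution is replaced by a
  per-rank median reference distribution, ties broken at random;
- rarefying: each sample is subsampled without replacement to a common
  depth (a multivariate hypergeometric draw).

All percentile computations use linear interpolation between order
statistics (the ``numpy`` default); the test-suite oracles share this
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .count_data import CountMatrix

__all__ = [
    "NormalizationResult",
    "NormalizationInternals",
    "SCALING_METHODS",
    "COUNT_REPLACING_METHODS",
    "METHODS",
    "normalize",
    "norm_total_count",
    "norm_median",
    "norm_upper_quartile",
    "norm_tmm",
    "norm_rle",
    "norm_css",
    "norm_rcss",
    "norm_quantile_quantile",
    "norm_rarefy",
]

logger = logging.getLogger(__name__)

SCALING_METHODS = (
    "total_count",
    "median",
    "upper_quartile",
    "tmm",
    "rle",
    "css",
    "rcss",
)
COUNT_REPLACING_METHODS = ("quantile_quantile", "rarefy")
METHODS = SCALING_METHODS + COUNT_REPLACING_METHODS


@dataclass
class NormalizationInternals:
    """Method-specific by-products, kept for diagnostics/reproducibility."""

    tmm_adjustment: np.ndarray | None = None  # f_j^(r)
    tmm_reference: str | None = None
    css_quantile: float | None = None  # selected level l-hat
    css_thresholds: np.ndarray | None = None  # per-sample count threshold q_j^(l-hat)
    qq_reference: np.ndarray | None = None  # sorted reference vector
    rarefy_depth: int | None = None


@dataclass
class NormalizationResult:
    """Per-sample factors and/or replacement counts for one method.

    Scaling methods populate ``factors`` (all strictly positive) and leave
    ``transformed`` as ``None``; count-replacing methods set every factor
    to 1 and provide ``transformed``.
    """

    method: str
    factors: np.ndarray
    transformed: CountMatrix | None = None
    internals: NormalizationInternals = field(default_factory=NormalizationInternals)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if not np.all(np.isfinite(self.factors)) or np.any(self.factors <= 0):
            raise ValueError(f"{self.method}: factors must be positive and finite")

    @property
    def offsets(self) -> np.ndarray:
        """log N_j, the offsets consumed by the inference model."""
        if self.transformed is not None:
            return np.zeros_like(self.factors)
        return np.log(self.factors)

    def counts_for_inference(self, cm: CountMatrix) -> CountMatrix:
        """The matrix the inference model should analyze."""
        return self.transformed if self.transformed is not None else cm


# ---------------------------------------------------------------------------
# scaling methods


def norm_total_count(cm: CountMatrix) -> NormalizationResult:
    """N_j = total gene count of sample j."""
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [cm.sample_ids[j] for j in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero-total sample(s): {bad}")
    return NormalizationResult("total_count", totals)


def _gstar(cm: CountMatrix) -> np.ndarray:
    """Rows of genes that are non-zero in at least one sample."""
    keep = cm.counts.sum(axis=1) > 0
    return cm.counts[keep]


def _percentile_factor(cm: CountMatrix, pct: float, method: str) -> NormalizationResult:
    sub = _gstar(cm)
    if sub.shape[0] == 0:
        raise ValueError("all genes are zero in every sample")
    factors = np.percentile(sub, pct, axis=0)
    if np.any(factors <= 0):
        bad = [cm.sample_ids[j] for j in np.flatnonzero(factors <= 0)]
        raise ValueError(
            f"{method}: zero {pct:g}th percentile in sample(s) {bad}; "
            "filter sparse genes first"
        )
    return NormalizationResult(method, factors)


def norm_median(cm: CountMatrix) -> NormalizationResult:
    """N_j = median count over G* in sample j."""
    return _percentile_factor(cm, 50.0, "median")


def norm_upper_quartile(cm: CountMatrix) -> NormalizationResult:
    """N_j = 75th percentile of counts over G* in sample j."""
    return _percentile_factor(cm, 75.0, "upper_quartile")


def _tmm_pick_reference(p: np.ndarray) -> int:
    """Sample whose upper quartile of relative abundances is closest to
    the across-sample mean upper quartile."""
    uq = np.percentile(p, 75.0, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def norm_tmm(
    cm: CountMatrix,
    reference: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Trimmed mean of M-values.

    With relative abundances ``p_ij = Y_ij / T_j`` (``T_j`` the library
    size), each sample is compared with a reference sample ``r`` over the
    genes positive in both.  The log2 fold-changes ``M`` are trimmed
    symmetrically by ``trim_m`` (total) and the average log2 abundances
    ``A`` by ``trim_a``; the surviving ``M`` values are averaged with
    inverse-delta-method weights, and ``N_j = 2**mean * T_j``.
    """
    if not (0.0 <= trim_m < 1.0 and 0.0 <= trim_a < 1.0):
        raise ValueError("trims must be in [0, 1)")
    totals = cm.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample")
    p = cm.counts / totals

    if reference is None:
        r = _tmm_pick_reference(p)
    else:
        if reference not in cm.sample_ids:
            raise ValueError(f"unknown reference sample {reference!r}")
        r = cm.sample_ids.index(reference)

    f = np.ones(cm.n_samples)
    for j in range(cm.n_samples):
        if j == r:
            continue
        f[j] = _tmm_adjustment(
            cm.counts[:, j], cm.counts[:, r], totals[j], totals[r], trim_m, trim_a
        )
    return NormalizationResult(
        "tmm",
        f * totals,
        internals=NormalizationInternals(
            tmm_adjustment=f, tmm_reference=cm.sample_ids[r]
        ),
    )


def _tmm_adjustment(
    y: np.ndarray,
    y_ref: np.ndarray,
    total: float,
    total_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    ok = (y > 0) & (y_ref > 0)
    if not ok.any():
        logger.warning("TMM: no gene positive in both sample and reference; f = 1")
        return 1.0
    yj, yr = y[ok].astype(float), y_ref[ok].astype(float)
    pj, pr = yj / total, yr / total_ref
    m = np.log2(pj / pr)
    a = 0.5 * np.log2(pj * pr)
    w = 1.0 / ((total - yj) / (total * yj) + (total_ref - yr) / (total_ref * yr))

    keep = _double_trim_mask(m, a, trim_m, trim_a)
    if not keep.any():
        logger.warning("TMM: trimming removed every gene; f = 1")
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def _double_trim_mask(
    m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float
) -> np.ndarray:
    """Symmetric two-sided trims; ties resolved by stable sort order."""
    n = m.size
    keep = np.ones(n, dtype=bool)
    for values, trim in ((m, trim_m), (a, trim_a)):
        cut = int(np.floor(n * trim / 2.0))
        if cut == 0:
            continue
        order = np.argsort(values, kind="stable")
        keep[order[:cut]] = False
        keep[order[n - cut:]] = False
    return keep


def norm_rle(cm: CountMatrix) -> NormalizationResult:
    """Relative log expression (median-of-ratios).

    The pseudo-reference for gene *i* is the geometric mean of its counts
    across samples, computed only over genes positive in every sample;
    ``N_j`` is the median ratio of sample *j*'s counts to the reference.
    """
    all_pos = np.all(cm.counts > 0, axis=1)
    if not all_pos.any():
        raise ValueError(
            "RLE needs at least one gene with positive counts in every sample; "
            "apply a stronger gene filter"
        )
    sub = cm.counts[all_pos].astype(float)
    geo = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    return NormalizationResult("rle", factors)


def norm_css(
    cm: CountMatrix, stability_threshold: float = 0.10
) -> NormalizationResult:
    """Cumulative sum scaling.

    Per-sample quantiles of the *positive* counts are computed on a
    percent grid; at each level the instability ``d_l`` is the median
    absolute deviation of the sample quantiles from their across-sample
    median.  The selected level ``l-hat`` is the smallest grid level at
    or above 0.50 where the relative increase of ``d_l`` over the
    previous level exceeds ``stability_threshold``; if the instabilities
    are degenerate (e.g. identical samples) the level falls back to 0.50.
    ``N_j`` then sums the counts of sample ``j`` at or below its own
    count threshold ``q_j^(l-hat)``.
    """
    if cm.n_samples < 2:
        raise ValueError("CSS needs at least 2 samples")
    if not 0.0 < stability_threshold < 1.0:
        raise ValueError("stability_threshold must be in (0, 1)")

    levels = np.arange(0.0, 1.0 + 1e-12, 0.01)
    q = np.empty((levels.size, cm.n_samples))
    for j in range(cm.n_samples):
        pos = cm.counts[cm.counts[:, j] > 0, j]
        if pos.size == 0:
            raise ValueError(f"sample {cm.sample_ids[j]} has no positive counts")
        q[:, j] = np.percentile(pos, levels * 100.0)

    ref = np.median(q, axis=1)
    d = np.median(np.abs(q - ref[:, None]), axis=1)

    l_hat = _css_select_level(levels, d, stability_threshold)
    idx = int(np.argmin(np.abs(levels - l_hat)))
    thresholds = q[idx]
    factors = np.array(
        [
            cm.counts[cm.counts[:, j] <= thresholds[j], j].sum()
            for j in range(cm.n_samples)
        ],
        dtype=float,
    )
    if np.any(factors <= 0):
        bad = [cm.sample_ids[j] for j in np.flatnonzero(factors <= 0)]
        raise ValueError(f"CSS produced a zero factor for sample(s) {bad}")
    return NormalizationResult(
        "css",
        factors,
        internals=NormalizationInternals(css_quantile=l_hat, css_thresholds=thresholds),
    )


def _css_select_level(
    levels: np.ndarray, d: np.ndarray, stability_threshold: float
) -> float:
    """Smallest level >= 0.50 whose relative instability increase exceeds
    the threshold; 0.50 fallback when no level qualifies."""
    if np.all(d <= 0):
        logger.warning("CSS: instabilities all zero; falling back to the median level")
        return 0.50
    for i in range(1, levels.size):
        if levels[i] < 0.50:
            continue
        if d[i] <= 0:
            continue
        rel_increase = (d[i] - d[i - 1]) / d[i]
        if rel_increase > stability_threshold:
            return float(levels[i])
    logger.warning("CSS: no unstable level found; falling back to the median level")
    return 0.50


def norm_rcss(cm: CountMatrix, inclusive: bool = True) -> NormalizationResult:
    """Reversed cumulative sum scaling.

    ``N_j`` sums the counts of the genes at or above sample ``j``'s median
    count (over all genes).  High-abundance genes have a lower coefficient
    of variation in metagenomic data, which motivates summing the top half
    of the distribution.  ``inclusive=False`` switches to a strict
    ``> median`` threshold.
    """
    medians = np.percentile(cm.counts, 50.0, axis=0)
    factors = np.empty(cm.n_samples)
    for j in range(cm.n_samples):
        col = cm.counts[:, j]
        sel = col >= medians[j] if inclusive else col > medians[j]
        factors[j] = col[sel].sum()
    if np.any(factors <= 0):
        bad = [cm.sample_ids[j] for j in np.flatnonzero(factors <= 0)]
        raise ValueError(f"RCSS produced a zero factor for sample(s) {bad}")
    return NormalizationResult("rcss", factors)


# ---------------------------------------------------------------------------
# count-replacing methods


def norm_quantile_quantile(
    cm: CountMatrix, rng: np.random.Generator
) -> NormalizationResult:
    """Quantile-quantile normalization with a discrete reference.

    The reference distribution is the per-rank median of the samples'
    sorted count vectors; with an even number of samples one of the two
    middle order statistics is picked at random per rank, which keeps the
    reference integer-valued.  Each sample's counts are then replaced by
    the reference value at their rank, with ties in the original counts
    assigned ranks in random order.
    """
    if cm.n_samples < 2:
        raise ValueError("quantile-quantile needs at least 2 samples")
    sorted_cols = np.sort(cm.counts, axis=0)  # (m, n)
    n = cm.n_samples
    if n % 2 == 1:
        reference = np.median(sorted_cols, axis=1).astype(np.int64)
    else:
        mid = np.sort(sorted_cols, axis=1)[:, n // 2 - 1 : n // 2 + 1]
        pick = rng.integers(0, 2, size=cm.n_genes)
        reference = mid[np.arange(cm.n_genes), pick]

    transformed = np.empty_like(cm.counts)
    for j in range(cm.n_samples):
        col = cm.counts[:, j]
        # random tie-break: shuffle, then stable sort by count
        perm = rng.permutation(cm.n_genes)
        order = perm[np.argsort(col[perm], kind="stable")]
        transformed[order, j] = reference
    result = NormalizationResult(
        "quantile_quantile",
        np.ones(cm.n_samples),
        transformed=cm.with_counts(transformed),
        internals=NormalizationInternals(qq_reference=np.asarray(reference)),
    )
    # defining property: every transformed column sorts to the reference
    assert np.array_equal(
        np.sort(result.transformed.counts, axis=0),
        np.tile(np.sort(reference)[:, None], (1, cm.n_samples)),
    )
    return result


def norm_rarefy(
    cm: CountMatrix, rng: np.random.Generator, depth: int | None = None
) -> NormalizationResult:
    """Rarefying: subsample every column to a common depth.

    Each column is replaced by a multivariate hypergeometric draw of
    ``depth`` fragments without replacement; the default depth is the
    smallest library size in the matrix.
    """
    totals = cm.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    if np.any(totals < depth):
        bad = [cm.sample_ids[j] for j in np.flatnonzero(totals < depth)]
        raise ValueError(f"depth {depth} exceeds the total of sample(s) {bad}")
    transformed = np.empty_like(cm.counts)
    for j in range(cm.n_samples):
        transformed[:, j] = rng.multivariate_hypergeometric(
            cm.counts[:, j], depth, method="marginals"
        )
    return NormalizationResult(
        "rarefy",
        np.ones(cm.n_samples),
        transformed=cm.with_counts(transformed),
        internals=NormalizationInternals(rarefy_depth=depth),
    )


# ---------------------------------------------------------------------------
# dispatcher

_NEEDS_RNG = {"quantile_quantile", "rarefy"}


def normalize(
    cm: CountMatrix,
    method: str,
    rng: np.random.Generator | None = None,
    **options,
) -> NormalizationResult:
    """Run one normalization method by name.

    ``rng`` is required for the stochastic methods (quantile-quantile and
    rarefying) and ignored by the deterministic ones.  Extra keyword
    options are forwarded to the method function.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {list(METHODS)}")
    if method in _NEEDS_RNG:
        if rng is None:
            raise ValueError(f"{method} requires a seeded random generator")
        return {
            "quantile_quantile": norm_quantile_quantile,
            "rarefy": norm_rarefy,
        }[method](cm, rng, **options)
    func = {
        "total_count": norm_total_count,
        "median": norm_median,
        "upper_quartile": norm_upper_quartile,
        "tmm": norm_tmm,
        "rle": norm_rle,
        "css": norm_css,
        "rcss": norm_rcss,
    }[method]
    return func(cm, **options)


def rescale_to_geometric_mean(factors: np.ndarray) -> np.ndarray:
    """Rescale positive factors to geometric mean 1 (for cross-method
    comparison only; inference is invariant to a global factor constant)."""
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


def write_factors(result: NormalizationResult, sample_ids: list[str], path) -> None:
    """Two-column TSV of per-sample factors."""
    import pandas as pd

    pd.DataFrame({"sample_id": sample_ids, "factor": result.factors}).to_csv(
        path, sep="\t", index=False
    )
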