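"""Performance measures for differential-abundance benchmarks.

Given per-gene p-values and the ground-truth DAG labels of an injected
dataset, genes are ranked by increasing p-value (ties broken by gene
index, stable) and cumulative true/false positive counts are formed at
every cutoff position *k*:

    TPR(k) = TP(k) / #DAGs        FPR(k) = FP(k) / #non-DAGs
    tFDR(k) = FP(k) / (TP(k) + FP(k))

The benchmark reports three fixed operating points: TPR at FPR = 0.01,
FPR at TPR = 0.50, and the true FDR of the set selected at estimated
FDR 0.05 (adjusted p <= 0.05).  With discrete ranks the targets are not
exactly attainable, so FPR targets use the largest cutoff not exceeding
the target (conservative) and TPR targets the smallest cutoff reaching
it; no interpolation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .count_data import CountMatrix
from .normalization import NormalizationResult, rescale_to_geometric_mean

__all__ = [
    "PerfSummary",
    "rate_curve",
    "tpr_at_fpr",
    "fpr_at_tpr",
    "true_fdr_at_estimated",
    "pvalue_uniformity",
    "factor_diagnostics",
    "gene_correlation_change",
    "aggregate",
]

logger = logging.getLogger(__name__)

MEASURES = ("tpr_at_fpr", "fpr_at_tpr", "tfdr_at_efdr")


@dataclass
class PerfSummary:
    """One iteration's operating-point measures for one method."""

    method: str
    iteration: int
    tpr_at_fpr: float
    fpr_at_tpr: float
    tfdr_at_efdr: float
    n_dags: int
    n_non_dags: int
    empty_selection: bool = False  # tFDR selection was empty (0 by convention)


def rate_curve(
    p: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative (k, TP(k), FP(k)) along the p-value ranking.

    Ties share the ordering of a stable sort by (p, gene index).
    Returns arrays of positions ``1..m`` and cumulative TP/FP counts.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if p.shape != truth.shape:
        raise ValueError("p and truth must have equal length")
    if p.size and np.all(p == p[0]):
        logger.warning("all p-values equal; ranking is the stable gene order")
    order = np.argsort(p, kind="stable")
    hits = truth[order]
    tp = np.cumsum(hits)
    fp = np.cumsum(~hits)
    k = np.arange(1, p.size + 1)
    return k, tp, fp


def tpr_at_fpr(
    p: np.ndarray, truth: np.ndarray, fpr_target: float = 0.01
) -> float:
    """TPR at the largest cutoff whose FPR does not exceed the target."""
    truth = np.asarray(truth, dtype=bool)
    n_dag = int(truth.sum())
    n_non = int((~truth).sum())
    if n_dag == 0 or n_non == 0:
        raise ValueError("need at least one DAG and one non-DAG")
    _, tp, fp = rate_curve(p, truth)
    admissible = fp <= fpr_target * n_non
    if not admissible.any():
        return 0.0
    k = int(np.max(np.flatnonzero(admissible)))
    return float(tp[k]) / n_dag


def fpr_at_tpr(
    p: np.ndarray, truth: np.ndarray, tpr_target: float = 0.50
) -> float:
    """FPR at the smallest cutoff whose TPR reaches the target."""
    truth = np.asarray(truth, dtype=bool)
    n_dag = int(truth.sum())
    n_non = int((~truth).sum())
    if n_dag == 0 or n_non == 0:
        raise ValueError("need at least one DAG and one non-DAG")
    _, tp, fp = rate_curve(p, truth)
    reaching = tp >= tpr_target * n_dag
    if not reaching.any():
        logger.warning("TPR target %.2f unreachable; reporting FPR = 1", tpr_target)
        return 1.0
    k = int(np.min(np.flatnonzero(reaching)))
    return float(fp[k]) / n_non


def true_fdr_at_estimated(
    p_adj: np.ndarray, truth: np.ndarray, efdr_target: float = 0.05
) -> tuple[float, bool]:
    """True FDR of the selection {adjusted p <= target}.

    Returns ``(tFDR, empty)`` where ``empty`` marks the 0-by-convention
    case of an empty selection.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    selected = p_adj <= efdr_target
    n_sel = int(selected.sum())
    if n_sel == 0:
        logger.info("empty selection at eFDR %.2f; tFDR = 0 by convention", efdr_target)
        return 0.0, True
    fp = int((selected & ~truth).sum())
    return fp / n_sel, False


def pvalue_uniformity(p_non_dag: np.ndarray) -> dict:
    """QQ pairs against Uniform(0,1) and the Kolmogorov-Smirnov distance.

    Under correct normalization the non-DAG p-values are approximately
    uniform; a large KS distance flags the skew toward small p-values
    that improper normalization induces.
    """
    p = np.sort(np.asarray(p_non_dag, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    m = p.size
    uniform_q = (np.arange(1, m + 1) - 0.5) / m
    ks = float(stats.kstest(p, "uniform").statistic)
    return {"observed": p, "uniform": uniform_q, "ks_distance": ks}


def factor_diagnostics(
    results: dict[str, NormalizationResult], cm: CountMatrix
) -> dict:
    """Spearman agreement of scaling factors across methods and with depth.

    Factors are rescaled to geometric mean 1 before comparison (a global
    constant is meaningless for offsets).  Requires >= 3 samples and
    >= 2 scaling methods.
    """
    scaling = {
        name: rescale_to_geometric_mean(res.factors)
        for name, res in results.items()
        if res.transformed is None
    }
    if len(scaling) < 2:
        raise ValueError("need at least 2 scaling methods")
    if cm.n_samples < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    totals = cm.counts.sum(axis=0)
    names = sorted(scaling)
    vs_depth = {
        name: float(stats.spearmanr(scaling[name], totals).statistic)
        for name in names
    }
    pairwise = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rho = float(stats.spearmanr(scaling[a], scaling[b]).statistic)
            pairwise.loc[a, b] = pairwise.loc[b, a] = rho
    return {"factor_vs_depth": vs_depth, "factor_pairwise": pairwise}


def gene_correlation_change(
    raw: CountMatrix,
    norm: NormalizationResult,
    n_pairs: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mean pairwise gene-gene Spearman correlation before/after normalization.

    Improper normalization is known to introduce spurious gene-gene
    correlation; this reports the mean correlation over a random subset
    of gene pairs (all pairs when few genes) for the raw and the
    normalized data, and their difference.
    """
    if raw.n_samples < 3:
        raise ValueError("needs at least 3 samples")
    if norm.transformed is not None:
        after = norm.transformed.counts.astype(float)
    else:
        after = raw.counts / norm.factors
    before = raw.counts.astype(float)

    m = raw.n_genes
    all_pairs = m * (m - 1) // 2
    if all_pairs <= n_pairs:
        pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        seen = set()
        while len(seen) < n_pairs:
            a, b = rng.integers(0, m, size=2)
            if a != b:
                seen.add((min(a, b), max(a, b)))
        pairs = sorted(seen)

    def _mean_rho(mat: np.ndarray) -> float:
        ranks = stats.rankdata(mat, axis=1)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        rhos = []
        for a, b in pairs:
            denom = norms[a] * norms[b]
            if denom == 0:
                continue  # constant row: correlation undefined
            rhos.append(float(centered[a] @ centered[b] / denom))
        return float(np.mean(rhos)) if rhos else 0.0

    mean_before = _mean_rho(before)
    mean_after = _mean_rho(after)
    return {
        "mean_corr_before": mean_before,
        "mean_corr_after": mean_after,
        "delta": mean_after - mean_before,
    }


def aggregate(perf: list[PerfSummary] | pd.DataFrame) -> pd.DataFrame:
    """Mean, median and 2.5/97.5 percentiles of each measure per method.

    Accepts the per-iteration summaries (or an equivalent long-format
    DataFrame) and returns one row per (method, measure).
    """
    if isinstance(perf, pd.DataFrame):
        df = perf.copy()
    else:
        if not perf:
            raise ValueError("no iterations to aggregate")
        df = pd.DataFrame([vars(s) for s in perf])
    rows = []
    for method, sub in df.groupby("method", sort=True):
        for measure in MEASURES:
            vals = sub[measure].to_numpy(dtype=float)
            rows.append(
                {
                    "method": method,
                    "measure": measure,
                    "mean": float(np.mean(vals)),
                    "median": float(np.median(vals)),
                    "q025": float(np.percentile(vals, 2.5)),
                    "q975": float(np.percentile(vals, 97.5)),
                    "n_iterations": len(vals),
                }
            )
    return pd.DataFrame(rows)
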