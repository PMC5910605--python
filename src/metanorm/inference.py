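"""Overdispersed-Poisson differential-abundance testing.

Each gene *i* is modeled with the log-linear quasi-Poisson GLM

    log E[Y_ij | x_j] = alpha_i + beta_i * x_j + log N_j,

where ``x_j`` is the 0/1 condition indicator and ``N_j`` the normalization
factor (1 for count-replacing methods, whose transformed counts are
analyzed directly).  ``Var[Y_ij] = phi_i * E[Y_ij]`` with a gene-specific
dispersion ``phi_i`` estimated by the Pearson statistic of the full model
divided by its residual degrees of freedom ``n - 2``.

For a two-group design with offsets the Poisson maximum-likelihood
estimates are available in closed form — the fitted group means are the
offset-weighted group averages — so the fit is exact and needs no
iteration.  A gene is called differentially abundant with an F-test on
the scaled deviance drop,

    F = (D_null - D_full) / phi_hat ~ F(1, n - 2),

and p-values are adjusted for multiplicity with Benjamini-Hochberg
(default), Benjamini-Yekutieli, or Storey's q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .count_data import CountMatrix
from .effects import GroupDesign
from .normalization import NormalizationResult

__all__ = [
    "OGLMFit",
    "fit_oglm_gene",
    "test_dag",
    "run_inference",
    "adjust_pvalues",
]

_MIN_DISPERSION = 1e-12


@dataclass
class OGLMFit:
    """Per-gene fit of the overdispersed Poisson model."""

    alpha: float
    beta: float
    dispersion: float
    deviance_full: float
    deviance_null: float
    df_residual: int
    converged: bool = True
    flag: str = "ok"  # ok | degenerate


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[y log(y/mu) - (y - mu)], with the y = 0 terms equal to mu."""
    # xlogy handles y = 0; mu = 0 cells only occur with y = 0 (contribute 0).
    with np.errstate(divide="ignore", invalid="ignore"):
        term = special.xlogy(y, y) - special.xlogy(y, mu)
    term = np.where(y == 0, 0.0, term)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_oglm_gene(
    y: np.ndarray, x: np.ndarray, offsets: np.ndarray
) -> OGLMFit:
    """Fit one gene's two-group quasi-Poisson GLM with log offsets.

    The Poisson MLE is closed-form: with ``N_j = exp(offset_j)``,
    ``exp(alpha) = sum_{x=0} y / sum_{x=0} N`` and
    ``exp(alpha + beta) = sum_{x=1} y / sum_{x=1} N``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    offsets = np.asarray(offsets, dtype=float)
    if not (y.shape == x.shape == offsets.shape):
        raise ValueError("y, x and offsets must have equal length")
    n = y.size
    if n <= 2:
        raise ValueError("the F-test needs more than 2 samples (df = n - 2)")
    if np.all(y == 0):
        return OGLMFit(
            alpha=-np.inf,
            beta=0.0,
            dispersion=_MIN_DISPERSION,
            deviance_full=0.0,
            deviance_null=0.0,
            df_residual=n - 2,
            flag="degenerate",
        )

    N = np.exp(offsets)
    g1 = np.asarray(x, dtype=bool)
    g0 = ~g1
    s0, s1 = y[g0].sum(), y[g1].sum()
    N0, N1 = N[g0].sum(), N[g1].sum()

    flag = "ok"
    rate0, rate1 = s0 / N0, s1 / N1
    mu_full = np.where(g1, rate1, rate0) * N
    mu_null = (s0 + s1) / (N0 + N1) * N

    if s0 == 0 or s1 == 0:
        # one group entirely zero: report beta with a 0.5-count continuity
        # floor on the group total, but test with the actual deviances
        flag = "degenerate"
        alpha = float(np.log(max(s0, 0.5) / N0))
        beta = float(np.log(max(s1, 0.5) / N1) - alpha)
    else:
        alpha = float(np.log(rate0))
        beta = float(np.log(rate1) - alpha)

    dev_full = _poisson_deviance(y, mu_full)
    dev_null = _poisson_deviance(y, mu_null)
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.where(mu_full > 0, (y - mu_full) ** 2 / mu_full, 0.0)
    dispersion = max(float(pearson.sum()) / (n - 2), _MIN_DISPERSION)

    return OGLMFit(
        alpha=alpha,
        beta=beta,
        dispersion=dispersion,
        deviance_full=dev_full,
        deviance_null=dev_null,
        df_residual=n - 2,
        flag=flag,
    )


def test_dag(fit: OGLMFit) -> tuple[float, float]:
    """F-test of beta = 0 from a fitted gene.

    Returns ``(F, p)`` with ``F = (D_null - D_full) / phi_hat`` referred
    to an F(1, n - 2) distribution.  Degenerate all-zero genes get
    ``p = 1``.
    """
    if fit.df_residual <= 0:
        raise ValueError("F-test undefined for df_residual <= 0")
    if fit.flag == "degenerate" and fit.deviance_null == 0.0:
        return 0.0, 1.0
    drop = max(fit.deviance_null - fit.deviance_full, 0.0)
    f_stat = drop / fit.dispersion
    p = float(stats.f.sf(f_stat, 1, fit.df_residual))
    return float(f_stat), p


def _fit_all(
    Y: np.ndarray, x: np.ndarray, offsets: np.ndarray
) -> pd.DataFrame:
    """Vectorized closed-form fit of every gene (same math as
    :func:`fit_oglm_gene`)."""
    m, n = Y.shape
    N = np.exp(offsets)
    g1 = np.asarray(x, dtype=bool)
    g0 = ~g1
    s0 = Y[:, g0].sum(axis=1).astype(float)
    s1 = Y[:, g1].sum(axis=1).astype(float)
    N0, N1 = N[g0].sum(), N[g1].sum()
    s = s0 + s1

    rate0 = s0 / N0
    rate1 = s1 / N1
    mu_full = np.where(g1[None, :], rate1[:, None], rate0[:, None]) * N[None, :]
    mu_null = (s / (N0 + N1))[:, None] * N[None, :]

    Yf = Y.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_full = 2.0 * np.sum(
            np.where(Yf > 0, special.xlogy(Yf, Yf) - special.xlogy(Yf, mu_full), 0.0)
            - (Yf - mu_full),
            axis=1,
        )
        dev_null = 2.0 * np.sum(
            np.where(Yf > 0, special.xlogy(Yf, Yf) - special.xlogy(Yf, mu_null), 0.0)
            - (Yf - mu_null),
            axis=1,
        )
        pearson = np.where(mu_full > 0, (Yf - mu_full) ** 2 / mu_full, 0.0).sum(axis=1)

    dispersion = np.maximum(pearson / (n - 2), _MIN_DISPERSION)
    with np.errstate(divide="ignore"):
        alpha = np.log(np.maximum(s0, 0.5) / N0)
        beta = np.log(np.maximum(s1, 0.5) / N1) - alpha

    drop = np.maximum(dev_null - dev_full, 0.0)
    f_stat = drop / dispersion
    p = stats.f.sf(f_stat, 1, n - 2)

    all_zero = s == 0
    one_group_zero = (s0 == 0) | (s1 == 0)
    flag = np.where(all_zero | one_group_zero, "degenerate", "ok")
    p = np.where(all_zero, 1.0, p)
    f_stat = np.where(all_zero, 0.0, f_stat)

    return pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "dispersion": dispersion,
            "deviance_full": dev_full,
            "deviance_null": dev_null,
            "F": f_stat,
            "p_value": p,
            "flag": flag,
        }
    )


def run_inference(
    cm: CountMatrix,
    groups: GroupDesign,
    norm: NormalizationResult,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-gene differential-abundance table for one normalization.

    Count-replacing normalizations contribute their transformed counts
    and zero offsets; scaling normalizations contribute ``log N_j``
    offsets on the raw counts.  Returns a DataFrame indexed by gene id
    with columns alpha, beta, dispersion, F, p_value, p_adjusted, flag.
    """
    if groups.assignment.shape[0] != cm.n_samples:
        raise ValueError("group design does not match the sample count")
    if norm.factors.shape[0] != cm.n_samples:
        raise ValueError("normalization result does not match the sample count")
    analyzed = norm.counts_for_inference(cm)
    table = _fit_all(analyzed.counts, groups.assignment, norm.offsets)
    table.index = pd.Index(analyzed.gene_ids, name="gene_id")
    table["p_adjusted"] = adjust_pvalues(table["p_value"].to_numpy(), adjust)
    return table


def adjust_pvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: ``bh``, ``by`` or ``storey``.

    ``storey`` computes q-values with the fixed-lambda estimator
    ``pi0 = min(1, #\\{p > 0.5\\} / (0.5 m))``, a small-m-stable variant.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if method in ("bh", "by"):
        return multipletests(p, method={"bh": "fdr_bh", "by": "fdr_by"}[method])[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError("method must be one of {'bh', 'by', 'storey'}")


def _storey_qvalues(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    m = p.size
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
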