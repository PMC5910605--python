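"""Synthetic shotgun-metagenomic count matrices.

Real gene-abundance tables share a handful of marginal features: a
heavy-tailed distribution of gene baseline abundances (a few genes dominate
the library), order-of-magnitude differences in per-sample sequencing
depth, gene-specific overdispersion relative to the Poisson, and high
sparsity at low depth.  The generator here reproduces those features with
a hierarchical negative-binomial model:

    mu_i   ~ LogNormal(mean_log_mu, mean_log_sigma)        gene baseline
    d_j    ~ 10 ** Uniform(0, depth_log10_range)           depth factor,
                                                           rescaled to
                                                           geometric mean 1
    phi_i  ~ 1 + Gamma(dispersion_shape, dispersion_rate)  variance/mean
    Y_ij   ~ NB(mean = d_j * mu_i, variance = d_j * mu_i * phi_i)

Parameterizing the negative binomial by (mean, variance/mean ratio)
matches the quasi-Poisson variance assumption used by the inference
model, so parameter-recovery experiments are well-posed.  Sparsity is
emergent from low mu_i times low d_j rather than injected separately.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

from .count_data import CountMatrix

__all__ = ["SyntheticConfig", "PRESETS", "generate_counts", "estimate_profile"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the hierarchical count generator.

    Attributes
    ----------
    n_genes, n_samples
        Matrix dimensions.
    mean_log_mu
        Natural-log mean of the gene baseline abundance distribution.
    mean_log_sigma
        Natural-log standard deviation of baselines; controls how heavy
        the abundance tail is (``>= 0``).
    depth_log10_range
        Sample depth factors are drawn log-uniform over this many decades
        (``0`` means equal depths).
    dispersion_shape, dispersion_rate
        Shape and rate of the Gamma law for the overdispersion excess;
        the variance/mean ratio of gene *i* is ``1 + Gamma(shape, rate)``,
        so its mean is ``1 + shape / rate``.
    seed
        Seed for the generator; the seed fully determines the matrix.
    """

    n_genes: int
    n_samples: int
    mean_log_mu: float = 2.0
    mean_log_sigma: float = 1.5
    depth_log10_range: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("n_genes and n_samples must be >= 1")
        if self.mean_log_sigma < 0:
            raise ValueError("mean_log_sigma must be >= 0")
        if self.depth_log10_range < 0:
            raise ValueError("depth_log10_range must be >= 0")
        if self.dispersion_shape <= 0 or self.dispersion_rate <= 0:
            raise ValueError("dispersion shape and rate must be > 0")


#: Named generator profiles.  ``gut_like`` mimics a shallow, sparse dataset
#: (few reads per sample, many low-count genes); ``marine_like`` a deeply
#: sequenced one with a heavier abundance tail.  Values are this package's
#: own calibration of the qualitative features described above.
PRESETS: dict[str, SyntheticConfig] = {
    "gut_like": SyntheticConfig(
        n_genes=2000,
        n_samples=60,
        mean_log_mu=1.0,
        mean_log_sigma=1.2,
        depth_log10_range=1.0,
        dispersion_shape=2.0,
        dispersion_rate=1.0,
    ),
    "marine_like": SyntheticConfig(
        n_genes=4000,
        n_samples=45,
        mean_log_mu=3.0,
        mean_log_sigma=1.8,
        depth_log10_range=0.7,
        dispersion_shape=3.0,
        dispersion_rate=0.75,
    ),
}


def generate_counts(cfg: SyntheticConfig, seed: int | None = None) -> CountMatrix:
    """Draw a count matrix from the hierarchical model.

    ``seed`` overrides ``cfg.seed`` when given.  Identical configuration
    (and seed) yields a bitwise-identical matrix.
    """
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    rng = np.random.default_rng(cfg.seed)

    mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=cfg.n_genes)
    depth = 10.0 ** rng.uniform(0.0, cfg.depth_log10_range, size=cfg.n_samples)
    depth /= np.exp(np.mean(np.log(depth)))  # geometric mean 1
    phi = 1.0 + rng.gamma(cfg.dispersion_shape, 1.0 / cfg.dispersion_rate, size=cfg.n_genes)

    mean = np.outer(mu, depth)  # (m, n)
    phi_mat = np.broadcast_to(phi[:, None], mean.shape)

    counts = np.empty(mean.shape, dtype=np.int64)
    # NB with mean M and variance M*phi: size r = M/(phi-1), prob p = 1/phi.
    # phi ~ 1 degenerates to Poisson.
    poisson_like = phi_mat < 1.0 + 1e-9
    if poisson_like.any():
        counts[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if nb.any():
        r = mean[nb] / (phi_mat[nb] - 1.0)
        p = 1.0 / phi_mat[nb]
        counts[nb] = rng.negative_binomial(r, p)

    gene_ids = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"sample_{j:03d}" for j in range(cfg.n_samples)]
    return CountMatrix(counts, gene_ids, sample_ids)


def estimate_profile(cm: CountMatrix) -> SyntheticConfig:
    """Method-of-moments fit of a :class:`SyntheticConfig` to a matrix.

    The fit targets the marginal structure only: log-normal moments from
    the positive row means, depth range from the spread of log10 column
    totals, and the overdispersion Gamma from per-gene variance/mean
    ratios.  It is intended for mimicking a real dataset, not for
    statistically efficient estimation.
    """
    if cm.n_samples < 2:
        raise ValueError("profile estimation needs at least 2 samples")
    if not cm.counts.any():
        raise ValueError("cannot estimate a profile from an all-zero matrix")

    totals = cm.counts.sum(axis=0).astype(float)
    pos_totals = totals[totals > 0]
    depth_range = float(np.log10(pos_totals.max()) - np.log10(pos_totals.min()))

    # Depth-adjust before taking row means so mean_log_mu is depth-free.
    depth = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    adj = cm.counts / np.maximum(depth, 1e-12)
    row_means = adj.mean(axis=1)
    pos = row_means > 0
    log_means = np.log(row_means[pos])
    mean_log_mu = float(log_means.mean())
    mean_log_sigma = float(log_means.std(ddof=1)) if pos.sum() > 1 else 0.0

    row_var = adj.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(row_means > 0, row_var / row_means, np.nan)
    excess = ratio[np.isfinite(ratio)] - 1.0
    excess = excess[excess > 0]
    if excess.size >= 2 and excess.var(ddof=1) > 0:
        ex_mean = excess.mean()
        ex_var = excess.var(ddof=1)
        shape = float(ex_mean**2 / ex_var)
        rate = float(ex_mean / ex_var)
    else:  # near-Poisson data: a sharp Gamma with tiny mean excess
        shape, rate = 1.0, 100.0

    return SyntheticConfig(
        n_genes=cm.n_genes,
        n_samples=cm.n_samples,
        mean_log_mu=mean_log_mu,
        mean_log_sigma=mean_log_sigma,
        depth_log10_range=depth_range,
        dispersion_shape=shape,
        dispersion_rate=rate,
    )


def config_to_dict(cfg: SyntheticConfig) -> dict:
    """Plain-dict form for YAML serialization."""
    return asdict(cfg)
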