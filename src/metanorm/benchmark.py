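"""Benchmark orchestration: scenarios × methods × iterations.

One benchmark iteration draws a two-group dataset from the source matrix,
injects differentially abundant genes by binomial thinning, and then runs
*every* requested normalization method on the identical injected dataset
(a paired design, which removes the dataset draw from between-method
variance).  Per method, normalization feeds the quasi-Poisson inference
and the evaluation layer reports the three operating-point measures.

The seed schedule is hierarchical and stage-keyed: the master seed, the
scenario seed, the iteration index and a stage index together determine
each random stream.  Results are therefore bitwise reproducible and
independent of the order in which methods are listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .count_data import CountMatrix, filter_genes, read_counts
from .effects import ScenarioSpec, assign_effects, inject_effects, sample_groups
from .evaluation import PerfSummary, fpr_at_tpr, tpr_at_fpr, true_fdr_at_estimated
from .inference import run_inference
from .normalization import METHODS, normalize
from .synthetic import PRESETS, SyntheticConfig, generate_counts

__all__ = ["BenchmarkConfig", "run_iteration", "run_benchmark", "load_config", "default_grid"]

logger = logging.getLogger(__name__)

# stage indices of the seed schedule
_STAGE_SAMPLING = 0
_STAGE_ASSIGNMENT = 1
_STAGE_THINNING = 2
_STAGE_METHOD_BASE = 10  # + canonical method index


@dataclass
class BenchmarkConfig:
    """Full description of a benchmark run.

    ``source`` is either the name of a synthetic preset (``gut_like``,
    ``marine_like``), a path to a count TSV, or an explicit
    :class:`SyntheticConfig`.
    """

    source: str | SyntheticConfig = "gut_like"
    scenarios: list[ScenarioSpec] = field(default_factory=lambda: default_grid())
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    n_iterations: int = 100
    master_seed: int = 0
    output_dir: str | Path | None = None
    fdr_method: str = "bh"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; supported: {list(METHODS)}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def default_grid(
    fold_changes: tuple[float, ...] = (3.0,),
    group_sizes: tuple[int, ...] = (10, 3),
) -> list[ScenarioSpec]:
    """The study grid: every balance case at each group size and fold-change."""
    return [
        ScenarioSpec(samples_per_group=k, balance=b, fold_change=fc)
        for k in group_sizes
        for b in ("balanced", "lightly_unbalanced", "unbalanced", "heavily_unbalanced")
        for fc in fold_changes
    ]


def _stage_rng(
    master_seed: int, scenario_seed: int, iteration: int, stage: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, scenario_seed, iteration, stage])
    )


def run_iteration(
    cm: CountMatrix,
    spec: ScenarioSpec,
    methods: list[str],
    iteration: int = 0,
    master_seed: int = 0,
    fdr_method: str = "bh",
    collect_pvalues: bool = False,
) -> tuple[list[PerfSummary], dict]:
    """One resample-inject-normalize-test-evaluate cycle.

    All methods see the identical injected dataset.  ``extras`` carries
    the effect design, per-method median DAG effect estimates, and (when
    ``collect_pvalues``) the per-method non-DAG p-value vectors.
    """
    rng = lambda stage: _stage_rng(master_seed, spec.seed, iteration, stage)

    subset, groups = sample_groups(cm, spec.samples_per_group, rng(_STAGE_SAMPLING))
    effects = assign_effects(subset.n_genes, spec, rng(_STAGE_ASSIGNMENT))
    injected = inject_effects(subset, groups, effects, rng(_STAGE_THINNING))

    truth = effects.is_dag
    summaries: list[PerfSummary] = []
    extras: dict = {
        "effects": effects,
        "groups": groups,
        "beta_median_dag": {},
        "pvalues_non_dag": {},
    }
    for method in methods:
        stage = _STAGE_METHOD_BASE + METHODS.index(method)
        try:
            norm = normalize(injected, method, rng=rng(stage))
            table = run_inference(injected, groups, norm, adjust=fdr_method)
        except ValueError as exc:
            logger.warning(
                "iteration %d: method %s failed (%s); skipped", iteration, method, exc
            )
            continue
        p = table["p_value"].to_numpy()
        p_adj = table["p_adjusted"].to_numpy()
        if truth.any() and (~truth).any():
            tpr = tpr_at_fpr(p, truth)
            fpr = fpr_at_tpr(p, truth)
        else:
            tpr = fpr = float("nan")
        tfdr, empty = true_fdr_at_estimated(p_adj, truth)
        summaries.append(
            PerfSummary(
                method=method,
                iteration=iteration,
                tpr_at_fpr=tpr,
                fpr_at_tpr=fpr,
                tfdr_at_efdr=tfdr,
                n_dags=int(truth.sum()),
                n_non_dags=int((~truth).sum()),
                empty_selection=empty,
            )
        )
        if truth.any():
            # align the sign with the affected group: thinning group 1 gives
            # beta = log q, thinning group 0 gives -log q
            beta = table["beta"].to_numpy()
            aligned = np.where(effects.affected_group == 1, beta, -beta)
            extras["beta_median_dag"][method] = float(np.median(aligned[truth]))
        if collect_pvalues:
            extras["pvalues_non_dag"][method] = p[~truth]
    return summaries, extras


def _load_source(cfg: BenchmarkConfig) -> CountMatrix:
    if isinstance(cfg.source, SyntheticConfig):
        cm = generate_counts(cfg.source)
    elif cfg.source in PRESETS:
        # the dataset itself is part of the seeded experiment
        cm = generate_counts(PRESETS[cfg.source], seed=cfg.master_seed)
    else:
        cm = read_counts(cfg.source)
    return filter_genes(cm)


def run_benchmark(cfg: BenchmarkConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole grid and return (long table, aggregated table).

    When ``cfg.output_dir`` is set, writes ``results_long.tsv``,
    ``results_aggregated.tsv`` and a ``manifest.yaml`` echoing the
    configuration and seeds.
    """
    out_dir: Path | None = None
    if cfg.output_dir is not None:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        try:
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise OSError(f"output directory {out_dir} is not writable") from exc

    cm = _load_source(cfg)
    logger.info("source matrix after gene filter: %d genes × %d samples", *cm.shape)

    rows = []
    for spec in cfg.scenarios:
        for it in range(cfg.n_iterations):
            summaries, _ = run_iteration(
                cm,
                spec,
                cfg.methods,
                iteration=it,
                master_seed=cfg.master_seed,
                fdr_method=cfg.fdr_method,
            )
            for s in summaries:
                rows.append({"scenario": spec.label, **vars(s)})
        logger.info("scenario %s: %d iterations done", spec.label, cfg.n_iterations)

    long_df = pd.DataFrame(rows)
    agg_parts = []
    for scenario, sub in long_df.groupby("scenario", sort=True):
        from .evaluation import aggregate

        part = aggregate(sub)
        part.insert(0, "scenario", scenario)
        agg_parts.append(part)
    agg_df = pd.concat(agg_parts, ignore_index=True)

    if out_dir is not None:
        long_df.to_csv(out_dir / "results_long.tsv", sep="\t", index=False)
        agg_df.to_csv(out_dir / "results_aggregated.tsv", sep="\t", index=False)
        manifest = {
            "package_version": __version__,
            "master_seed": cfg.master_seed,
            "n_iterations": cfg.n_iterations,
            "fdr_method": cfg.fdr_method,
            "methods": list(cfg.methods),
            "source": (
                asdict(cfg.source)
                if isinstance(cfg.source, SyntheticConfig)
                else str(cfg.source)
            ),
            "scenarios": [asdict(s) for s in cfg.scenarios],
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return long_df, agg_df


def load_config(path: str | Path) -> BenchmarkConfig:
    """Build a :class:`BenchmarkConfig` from a YAML file.

    Schema: top-level keys mirror the dataclass fields; ``scenarios`` is
    a list of mappings with ScenarioSpec keys; ``source`` may also be a
    mapping of SyntheticConfig fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    kwargs = dict(raw)
    if isinstance(kwargs.get("source"), dict):
        kwargs["source"] = SyntheticConfig(**kwargs["source"])
    if "scenarios" in kwargs:
        kwargs["scenarios"] = [ScenarioSpec(**s) for s in kwargs["scenarios"]]
    return BenchmarkConfig(**kwargs)
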