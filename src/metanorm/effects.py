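"""Two-group resampling designs and binomial-thinning effect injection.

Artificial benchmark datasets are built from a source count matrix by
(1) drawing two groups of samples without replacement, (2) selecting a
set of genes to act as truly differentially abundant genes (DAGs), and
(3) thinning the counts of each selected gene in its affected group with
a ``Binomial(Y, q)`` draw, where ``q = 1 / fold_change``.  Thinning a
count by ``q`` reduces its expectation exactly ``fold_change``-fold while
keeping the data integer-valued and never increasing any count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from .count_data import CountMatrix

__all__ = [
    "GroupDesign",
    "EffectDesign",
    "ScenarioSpec",
    "BALANCE_PRESETS",
    "sample_groups",
    "assign_effects",
    "inject_effects",
]

#: balance name -> (default DAG fraction, share of DAGs affected in group 1).
BALANCE_PRESETS: dict[str, tuple[float, float]] = {
    "balanced": (0.10, 0.50),
    "lightly_unbalanced": (0.10, 0.75),
    "unbalanced": (0.10, 1.00),
    "heavily_unbalanced": (0.20, 1.00),
}


@dataclass
class GroupDesign:
    """Assignment of samples to the two experimental conditions."""

    assignment: np.ndarray  # per-sample label in {0, 1}
    group_sizes: tuple[int, int]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if not np.isin(self.assignment, (0, 1)).all():
            raise ValueError("group labels must be 0 or 1")
        n0 = int(np.sum(self.assignment == 0))
        n1 = int(np.sum(self.assignment == 1))
        if (n0, n1) != tuple(self.group_sizes):
            raise ValueError(
                f"label counts {(n0, n1)} do not match group_sizes {self.group_sizes}"
            )
        if min(n0, n1) < 1:
            raise ValueError("both groups must be non-empty")

    @property
    def indicator(self) -> np.ndarray:
        """x_j, the 0/1 condition indicator used by the inference model."""
        return self.assignment


@dataclass
class EffectDesign:
    """Which genes are DAGs, where the effect sits, and how strong it is."""

    is_dag: np.ndarray  # per-gene boolean
    affected_group: np.ndarray  # per-gene label in {0, 1}; -1 for non-DAGs
    q: float  # thinning probability, 1 / fold_change

    def __post_init__(self) -> None:
        self.is_dag = np.asarray(self.is_dag, dtype=bool)
        self.affected_group = np.asarray(self.affected_group, dtype=np.int64)
        if self.is_dag.shape != self.affected_group.shape:
            raise ValueError("is_dag and affected_group must have equal length")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must be in (0, 1]")
        if np.any(self.affected_group[self.is_dag] < 0):
            raise ValueError("every DAG needs an affected group")
        if np.any(self.affected_group[~self.is_dag] != -1):
            raise ValueError("non-DAG genes must have affected_group = -1")

    @property
    def n_dags(self) -> int:
        return int(self.is_dag.sum())


@dataclass(frozen=True)
class ScenarioSpec:
    """One benchmark scenario: group size, effect placement and size.

    ``balance`` selects the DAG fraction and the group split from
    :data:`BALANCE_PRESETS`; ``dag_fraction`` overrides the preset
    fraction when given.
    """

    samples_per_group: int
    balance: str = "balanced"
    fold_change: float = 3.0
    dag_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        if self.balance not in BALANCE_PRESETS:
            raise ValueError(
                f"balance must be one of {sorted(BALANCE_PRESETS)}, got {self.balance!r}"
            )
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if self.dag_fraction is not None and not 0.0 <= self.dag_fraction <= 1.0:
            raise ValueError("dag_fraction must be in [0, 1]")

    @property
    def effective_dag_fraction(self) -> float:
        preset_fraction, _ = BALANCE_PRESETS[self.balance]
        return preset_fraction if self.dag_fraction is None else self.dag_fraction

    @property
    def group1_share(self) -> float:
        return BALANCE_PRESETS[self.balance][1]

    @property
    def q(self) -> float:
        return 1.0 / self.fold_change

    @property
    def label(self) -> str:
        return f"{self.balance}_k{self.samples_per_group}_fc{self.fold_change:g}"


def sample_groups(
    cm: CountMatrix, samples_per_group: int, rng: np.random.Generator
) -> tuple[CountMatrix, GroupDesign]:
    """Draw ``2 * samples_per_group`` distinct samples and split them 50/50.

    Columns are selected uniformly without replacement; the first half of
    the draw is labeled group 0 and the second half group 1.  Counts are
    not modified.
    """
    k = int(samples_per_group)
    if cm.n_samples < 2 * k:
        raise ValueError(
            f"need at least {2 * k} samples, matrix has {cm.n_samples}"
        )
    chosen = rng.choice(cm.n_samples, size=2 * k, replace=False)
    subset = cm.subset_samples(chosen)
    assignment = np.repeat([0, 1], k)
    return subset, GroupDesign(assignment, (k, k))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def assign_effects(
    n_genes: int, spec: ScenarioSpec, rng: np.random.Generator
) -> EffectDesign:
    """Randomly select DAGs and distribute them between the groups.

    ``round(dag_fraction * n_genes)`` genes are flagged (half away from
    zero on ties).  Of those, ``group1_share`` are thinned in group 1 and
    the remainder in group 0; for fully unbalanced scenarios the affected
    group is always group 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    frac = spec.effective_dag_fraction
    n_dag = _round_half_away(frac * n_genes)
    n_dag = min(n_dag, n_genes)

    is_dag = np.zeros(n_genes, dtype=bool)
    affected = np.full(n_genes, -1, dtype=np.int64)
    if n_dag > 0:
        dag_idx = rng.choice(n_genes, size=n_dag, replace=False)
        is_dag[dag_idx] = True
        n_in_group1 = _round_half_away(spec.group1_share * n_dag)
        # dag_idx is in random order already; the first slice goes to group 1.
        affected[dag_idx[:n_in_group1]] = 1
        affected[dag_idx[n_in_group1:]] = 0
    return EffectDesign(is_dag, affected, spec.q)


def inject_effects(
    cm: CountMatrix,
    groups: GroupDesign,
    effects: EffectDesign,
    rng: np.random.Generator,
) -> CountMatrix:
    """Thin each DAG's counts in its affected group with Binomial(Y, q).

    Every affected cell is replaced independently; all other cells are
    returned unchanged.  Since a binomial draw never exceeds its size
    parameter, thinned counts never exceed the originals.
    """
    if effects.is_dag.shape[0] != cm.n_genes:
        raise ValueError("effect design length does not match gene count")
    if groups.assignment.shape[0] != cm.n_samples:
        raise ValueError("group design length does not match sample count")

    out = cm.counts.copy()
    if effects.q == 1.0 or effects.n_dags == 0:
        return cm.with_counts(out)
    for g in (0, 1):
        rows = np.flatnonzero(effects.is_dag & (effects.affected_group == g))
        cols = np.flatnonzero(groups.assignment == g)
        if rows.size and cols.size:
            block = out[np.ix_(rows, cols)]
            out[np.ix_(rows, cols)] = rng.binomial(block, effects.q)
    return cm.with_counts(out)
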