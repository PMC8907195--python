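"""Erdos-Renyi null ensembles and empirical-vs-null comparisons.

Null graphs are G(n, p) random graphs; by default they carry unit
weights (ER is a binary model) but weights may instead be bootstrapped
from an empirical non-zero weight pool for weighted-metric
comparability.  Null graphs pass through the identical density
thresholding as empirical matrices before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adjacency import WeightedAdjacency
from . import stats as gi


def default_ensemble_size(group_sizes) -> int:
    """Ensemble size rule: round of the mean group sample size."""
    sizes = [int(s) for s in group_sizes]
    if not sizes:
        raise ValueError("need at least one group size")
    return int(round(float(np.mean(sizes))))


def generate_er_graph(
    n: int,
    p_edge: float,
    weight_rule: str = "unit",
    seed=None,
    weight_pool=None,
    labels=None,
) -> WeightedAdjacency:
    """One G(n, p) graph: each unordered pair is an edge w.p. ``p_edge``.

    ``weight_rule``: 'unit' assigns weight 1 to every edge; 'empirical'
    samples weights with replacement from ``weight_pool``.
    """
    if not (0.0 <= p_edge <= 1.0):
        raise ValueError(f"p_edge must lie in [0, 1], got {p_edge}")
    if n < 2:
        raise ValueError("need n >= 2 nodes")
    if weight_rule not in ("unit", "empirical"):
        raise ValueError(f"unknown weight rule {weight_rule!r}")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"N{i:02d}" for i in range(n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < p_edge
    w = np.zeros((n, n))
    if weight_rule == "unit":
        vals = present.astype(float)
    else:
        pool = np.asarray(weight_pool, dtype=float)
        if pool.size == 0 or (pool <= 0).any():
            raise ValueError("empirical weight pool must be non-empty and positive")
        vals = np.where(present, rng.choice(pool, size=present.size), 0.0)
    w[iu] = vals
    w = w + w.T
    return WeightedAdjacency(tuple(labels), w)


@dataclass
class NullEnsemble:
    graphs: list
    n: int
    p_edge: float
    weight_rule: str
    seed: int
    child_seeds: list = field(default_factory=list, repr=False)

    @property
    def size(self) -> int:
        return len(self.graphs)


def build_null_ensemble(
    n_graphs: int,
    n: int,
    p_edge: float,
    weight_rule: str = "unit",
    seed: int = 0,
    weight_pool=None,
    labels=None,
) -> NullEnsemble:
    """Ensemble of independent ER graphs; child seeds are spawned
    deterministically from the master seed."""
    if n_graphs < 1:
        raise ValueError("need n_graphs >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_graphs)
    graphs = [
        generate_er_graph(n, p_edge, weight_rule, child, weight_pool, labels)
        for child in children
    ]
    return NullEnsemble(graphs, n, p_edge, weight_rule, seed, children)


@dataclass
class NullComparison:
    test: str
    statistic: float
    p: float
    direction: int  # sign of (empirical median - null median)
    n_empirical: int
    n_null: int
    degenerate: bool = False


def compare_to_null(empirical, null, alpha: float = gi.ALPHA) -> NullComparison:
    """Normality-gated two-sample test of empirical vs null metric values.

    Welch t when both samples pass Shapiro-Wilk, Mann-Whitney rank-sum
    otherwise.  Samples with zero variance in both arms are flagged
    degenerate (statistic 0, p 1).
    """
    emp = np.asarray(empirical, dtype=float)
    nul = np.asarray(null, dtype=float)
    emp, nul = emp[np.isfinite(emp)], nul[np.isfinite(nul)]
    if emp.size == 0 or nul.size == 0:
        raise ValueError("both samples must be non-empty")
    direction = int(np.sign(np.median(emp) - np.median(nul)))
    if np.ptp(emp) == 0 and np.ptp(nul) == 0:
        return NullComparison(
            "degenerate", 0.0, 1.0, direction, emp.size, nul.size, degenerate=True
        )
    try:
        parametric = gi.normality_gate([emp, nul], alpha)
    except ValueError:
        parametric = False
    if parametric:
        from scipy import stats as sps

        stat, p = sps.ttest_ind(emp, nul, equal_var=False)
        test = "welch-t"
    else:
        from scipy import stats as sps

        stat, p = sps.mannwhitneyu(emp, nul, alternative="two-sided")
        test = "ranksum"
    return NullComparison(test, float(stat), float(p), direction, emp.size, nul.size)
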