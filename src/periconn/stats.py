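"""Normality-gated group statistics and brain-behaviour correlations.

The battery used throughout the pipeline: Shapiro-Wilk normality gating,
one-way ANOVA or Kruskal-Wallis omnibus tests, Bonferroni-corrected
pairwise post-hocs (Welch t or Mann-Whitney rank-sum), Pearson
chi-squared for sex proportions, Pearson/Spearman correlations, Cohen's
d from summary statistics, and post-hoc power of the two-sample t test
via the noncentral t distribution.  Two-sided tests, alpha = 0.05
throughout unless overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def normality_gate(samples, alpha: float = ALPHA) -> bool:
    """True iff every group passes Shapiro-Wilk at ``alpha``.

    A single non-normal group routes the whole comparison to the
    nonparametric branch.  Constant-valued samples are treated as
    non-normal (gate False).  Groups smaller than 3 raise.
    """
    for x in samples:
        x = _clean(x)
        if x.size < 3:
            raise ValueError("Shapiro-Wilk requires n >= 3 per group")
        if np.ptp(x) == 0:
            return False
        with np.errstate(all="ignore"):
            _, p = sps.shapiro(x)
        if not np.isfinite(p) or p < alpha:
            return False
    return True


@dataclass
class OmnibusResult:
    test: str  # "ANOVA" | "Kruskal-Wallis"
    statistic: float
    p: float
    df: tuple  # ANOVA: (k-1, N-k); KW: (k-1,)
    n_total: int
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)


def omnibus_group_test(samples: dict, parametric: bool) -> OmnibusResult:
    """One-way ANOVA (parametric) or Kruskal-Wallis across >= 2 groups.

    ``samples`` maps group name to a value vector.  Degenerate input in
    which every observation is identical returns statistic 0, p = 1.
    """
    groups = {g: _clean(x) for g, x in samples.items()}
    if len(groups) < 2 or any(x.size == 0 for x in groups.values()):
        raise ValueError("omnibus test needs >= 2 non-empty groups")
    vals = list(groups.values())
    k = len(vals)
    N = sum(v.size for v in vals)
    means = {g: float(v.mean()) for g, v in groups.items()}
    sds = {g: float(v.std(ddof=1)) if v.size > 1 else 0.0 for g, v in groups.items()}
    pooled = np.concatenate(vals)
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
        test = "ANOVA" if parametric else "Kruskal-Wallis"
    elif parametric:
        stat, p = sps.f_oneway(*vals)
        test = "ANOVA"
    else:
        stat, p = sps.kruskal(*vals)
        test = "Kruskal-Wallis"
    df = (k - 1, N - k) if test == "ANOVA" else (k - 1,)
    return OmnibusResult(test, float(stat), float(p), df, N, means, sds)


def pairwise_posthoc(
    samples: dict, parametric: bool, family_size: int | None = None
) -> dict:
    """Bonferroni-corrected two-sample post-hocs for every group pair.

    Welch t tests on the parametric branch, Mann-Whitney rank-sum tests
    otherwise; raw p-values are multiplied by the family size (default:
    the number of pairs) and capped at 1.
    """
    groups = {g: _clean(x) for g, x in samples.items()}
    names = list(groups)
    pairs = [(a, b) for idx, a in enumerate(names) for b in names[idx + 1:]]
    family = family_size if family_size is not None else len(pairs)
    out = {}
    for a, b in pairs:
        x, y = groups[a], groups[b]
        if np.ptp(np.concatenate([x, y])) == 0:
            raw = 1.0
        elif parametric:
            _, raw = sps.ttest_ind(x, y, equal_var=False)
        else:
            _, raw = sps.mannwhitneyu(x, y, alternative="two-sided")
        out[(a, b)] = min(1.0, float(raw) * family)
    return out


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni correction: p times family size, capped at 1."""
    if not (0.0 <= p <= 1.0) or family_size < 1:
        raise ValueError("need p in [0,1] and family_size >= 1")
    return min(1.0, p * family_size)


def proportions_test(counts) -> tuple:
    """Pearson chi-squared on a contingency table (e.g. sex x group).

    Returns (statistic, df, p).  Zero marginals raise.
    """
    table = np.asarray(counts, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    coefficient: float
    p: float
    n: int


def correlate(x, y, parametric: bool) -> CorrelationResult:
    """Pearson r (parametric) or Spearman r_s with pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("correlation needs >= 3 complete pairs")
    if parametric:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(p), int(x.size))


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Effect size |mean1 - mean2| / sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)


def cohens_d_samples(x, y) -> float:
    x, y = _clean(x), _clean(y)
    return cohens_d(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))


def posthoc_power(
    alpha: float, d: float, n1: int, n2: int, two_sided: bool = True
) -> float:
    """Power of the two-sample t test at effect size d.

    Uses the noncentral t distribution with df = n1 + n2 - 2 and
    noncentrality d * sqrt(n1 n2 / (n1 + n2)).  At d = 0 the power
    equals alpha exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if d < 0:
        raise ValueError("effect size d must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    if two_sided:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        if not np.isfinite(power):  # nct is unstable at very large df
            power = sps.norm.sf(tcrit - ncp) + sps.norm.cdf(-tcrit - ncp)
    else:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        power = sps.nct.sf(tcrit, df, ncp)
        if not np.isfinite(power):
            power = sps.norm.sf(tcrit - ncp)
    return float(power)
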