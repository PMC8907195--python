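"""End-to-end orchestration: cohort -> threshold -> metrics -> nulls -> stats.

The pipeline consumes either a written cohort (manifest mode) or the
synthetic generator (simulate mode), applies the matrix preprocessing
path (hemisphere subsetting where needed, diagonal zeroing, density
thresholding), computes nodal and hemispheric metrics, builds an
Erdos-Renyi null ensemble pushed through the identical thresholding,
and runs the normality-gated statistical battery.  All randomness flows
from one master seed; outputs are deterministic CSVs plus a plain-text
summary and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjacency import WeightedAdjacency, density_threshold, subset_hemisphere, zero_diagonal
from .atlas import NodeAtlas, default_atlas, read_atlas
from .cohort import CohortConfig, generate_cohort, read_cohort
from .manifest import GROUPS, STROKE_GROUPS, SCORE_COLUMNS
from .metrics import (
    HEMI_METRICS,
    hierarchical_complexity,
    hemispheric_summary,
    nodal_metric_table,
    sensorimotor_slice,
)
from .nulls import build_null_ensemble, compare_to_null, default_ensemble_size
from . import stats as gi

log = logging.getLogger("periconn")

NODAL_COLUMNS = {
    "betweenness": "betweenness_raw",
    "clustering": "clustering",
    "neighbourhood_complexity": "neighbourhood_complexity",
}


@dataclass
class RunConfig:
    mode: str = "simulate"                 # "simulate" | "manifest"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None          # manifest mode input directory
    atlas_labels: str | None = None
    atlas_roles: str | None = None
    threshold: float = 0.25
    transform: str = "inverse"
    betweenness_normalized: bool = False
    null_n_graphs: int | None = None       # default: round(mean group size)
    null_p_edge: float | str = "auto"
    null_weight_rule: str = "unit"
    alpha: float = 0.05
    bonferroni_family: int = 3
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "manifest"):
            raise ValueError("mode must be 'simulate' or 'manifest'")
        if not (0.0 <= self.threshold < 1.0):
            raise ValueError("threshold must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def preprocess(A: WeightedAdjacency, atlas: NodeAtlas, threshold: float) -> WeightedAdjacency:
    """Subset to the atlas (when the matrix is larger), zero the
    diagonal and apply density thresholding."""
    if tuple(A.labels) != atlas.all_labels:
        A = subset_hemisphere(A, atlas.all_labels)
    A = zero_diagonal(A)
    return density_threshold(A, threshold)


def compute_metric_tables(matrices: dict, atlas: NodeAtlas, cfg: RunConfig):
    """Per-subject preprocessing plus nodal and hemispheric tables."""
    nodal_parts, hemi_rows = [], []
    for sid, A in matrices.items():
        thr = preprocess(A, atlas, cfg.threshold)
        table = nodal_metric_table(thr, sid, transform=cfg.transform)
        nodal_parts.append(table)
        summary = hemispheric_summary(table, hierarchical_complexity(thr))
        hemi_rows.append({"subject_id": sid, **summary})
    nodal = pd.concat(nodal_parts, ignore_index=True)
    hemispheric = pd.DataFrame(hemi_rows)
    return nodal, hemispheric


def _gate_and_compare(samples: dict, alpha: float, family: int) -> dict:
    """Normality gate -> omnibus -> Bonferroni pairwise, one comparison."""
    parametric = gi.normality_gate(samples.values(), alpha)
    omni = gi.omnibus_group_test(samples, parametric)
    pairwise = gi.pairwise_posthoc(samples, parametric, family)
    significant = omni.p < alpha and any(p < alpha for p in pairwise.values())
    row = {
        "parametric": parametric,
        "test": omni.test,
        "statistic": omni.statistic,
        "df1": omni.df[0],
        "df2": omni.df[1] if len(omni.df) > 1 else np.nan,
        "p": omni.p,
        "n_total": omni.n_total,
        "significant": significant,
    }
    for g in GROUPS:
        if g in omni.group_means:
            row[f"mean_{g}"] = omni.group_means[g]
            row[f"sd_{g}"] = omni.group_sds[g]
    for (a, b), p in pairwise.items():
        row[f"p_{a}_{b}"] = p
        try:
            row[f"d_{a}_{b}"] = gi.cohens_d_samples(samples[a], samples[b])
        except ValueError:
            row[f"d_{a}_{b}"] = np.nan
    return row


def nodal_comparisons(
    nodal: pd.DataFrame, manifest: pd.DataFrame, atlas: NodeAtlas, cfg: RunConfig
) -> pd.DataFrame:
    """Group tests for the 8 analysed nodes x 3 nodal metrics."""
    sub = sensorimotor_slice(nodal, atlas)
    merged = sub.merge(manifest[["id", "group"]], left_on="subject_id", right_on="id")
    rows = []
    for label in atlas.node_labels:
        at_node = merged[merged["node_label"] == label]
        for metric, col in NODAL_COLUMNS.items():
            samples = {
                g: at_node.loc[at_node["group"] == g, col].dropna().to_numpy()
                for g in GROUPS
            }
            samples = {g: v for g, v in samples.items() if v.size >= 3}
            if len(samples) < 2:
                continue
            row = _gate_and_compare(samples, cfg.alpha, cfg.bonferroni_family)
            rows.append({"node": atlas.role_of(label), "node_label": label,
                         "metric": metric, **row})
    return pd.DataFrame(rows)


def hemispheric_comparisons(
    hemispheric: pd.DataFrame, manifest: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    merged = hemispheric.merge(
        manifest[["id", "group"]], left_on="subject_id", right_on="id"
    )
    rows = []
    for metric in HEMI_METRICS:
        samples = {
            g: merged.loc[merged["group"] == g, metric].dropna().to_numpy()
            for g in GROUPS
        }
        samples = {g: v for g, v in samples.items() if v.size >= 3}
        if len(samples) < 2:
            continue
        row = _gate_and_compare(samples, cfg.alpha, cfg.bonferroni_family)
        rows.append({"node": "hemispheric", "metric": metric, **row})
    return pd.DataFrame(rows)


def _corr_row(x, y, alpha):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
        return None
    try:
        parametric = gi.normality_gate([x[keep], y[keep]], alpha)
    except ValueError:
        parametric = False
    res = gi.correlate(x, y, parametric)
    return {
        "method": res.method,
        "coefficient": res.coefficient,
        "p": res.p,
        "n": res.n,
    }


def correlation_report(
    nodal: pd.DataFrame,
    hemispheric: pd.DataFrame,
    manifest: pd.DataFrame,
    atlas: NodeAtlas,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Brain-behaviour correlations among stroke subjects.

    Nodal metrics are tested pooled across stroke groups; hemispheric
    metrics both pooled and per stroke group.
    """
    stroke = manifest[manifest["group"].isin(STROKE_GROUPS)]
    rows = []
    sub = sensorimotor_slice(nodal, atlas)
    for label in atlas.node_labels:
        at_node = sub[sub["node_label"] == label].set_index("subject_id")
        for metric, col in NODAL_COLUMNS.items():
            x = at_node.reindex(stroke["id"])[col].to_numpy()
            for score in SCORE_COLUMNS:
                y = stroke[score].to_numpy()
                row = _corr_row(x, y, cfg.alpha)
                if row:
                    rows.append(
                        {"node": atlas.role_of(label), "metric": metric,
                         "score": score, "pooling": "pooled", **row}
                    )
    hemi = hemispheric.set_index("subject_id")
    for metric in HEMI_METRICS:
        for pooling in ("pooled",) + STROKE_GROUPS:
            subjects = stroke if pooling == "pooled" else stroke[stroke["group"] == pooling]
            x = hemi.reindex(subjects["id"])[metric].to_numpy()
            for score in SCORE_COLUMNS:
                y = subjects[score].to_numpy()
                row = _corr_row(x, y, cfg.alpha)
                if row:
                    rows.append(
                        {"node": "hemispheric", "metric": metric, "score": score,
                         "pooling": pooling, **row}
                    )
    return pd.DataFrame(rows)


def null_comparison_report(
    matrices: dict,
    hemispheric: pd.DataFrame,
    manifest: pd.DataFrame,
    atlas: NodeAtlas,
    cfg: RunConfig,
):
    """ER null ensemble (identically thresholded) vs each group."""
    pre = {
        sid: zero_diagonal(
            subset_hemisphere(A, atlas.all_labels)
            if tuple(A.labels) != atlas.all_labels
            else A
        )
        for sid, A in matrices.items()
    }
    if cfg.null_p_edge == "auto":
        p_edge = float(np.mean([A.density() for A in pre.values()]))
    else:
        p_edge = float(cfg.null_p_edge)
    sizes = manifest["group"].value_counts()
    n_graphs = cfg.null_n_graphs or default_ensemble_size(sizes.to_list())
    pool = None
    if cfg.null_weight_rule == "empirical":
        pool = np.concatenate(
            [A.weights[np.triu_indices(A.n, 1)] for A in pre.values()]
        )
        pool = pool[pool > 0]
    ensemble = build_null_ensemble(
        n_graphs, atlas.n, p_edge, cfg.null_weight_rule,
        seed=cfg.seed + 1_000_003, weight_pool=pool, labels=atlas.all_labels,
    )
    null_rows = []
    for g_idx, G in enumerate(ensemble.graphs):
        thr = density_threshold(G, cfg.threshold)
        table = nodal_metric_table(thr, f"null{g_idx:03d}", transform=cfg.transform)
        null_rows.append(hemispheric_summary(table, hierarchical_complexity(thr)))
    null_values = pd.DataFrame(null_rows)
    merged = hemispheric.merge(
        manifest[["id", "group"]], left_on="subject_id", right_on="id"
    )
    rows = []
    for metric in HEMI_METRICS:
        for g in GROUPS:
            emp = merged.loc[merged["group"] == g, metric].dropna().to_numpy()
            if emp.size == 0:
                continue
            res = compare_to_null(emp, null_values[metric].to_numpy(), cfg.alpha)
            rows.append(
                {"metric": metric, "group": g, "test": res.test,
                 "statistic": res.statistic, "p": res.p,
                 "direction": res.direction, "n_empirical": res.n_empirical,
                 "n_null": res.n_null, "degenerate": res.degenerate}
            )
    meta = {"p_edge": p_edge, "n_graphs": n_graphs, "weight_rule": cfg.null_weight_rule}
    return pd.DataFrame(rows), null_values, meta


def demographics_report(manifest: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Age (Kruskal-Wallis) and sex proportion (chi-squared) tests."""
    rows = []
    ages = {
        g: manifest.loc[manifest["group"] == g, "age"].dropna().to_numpy()
        for g in GROUPS
        if (manifest["group"] == g).sum() >= 3
    }
    if len(ages) >= 2:
        omni = gi.omnibus_group_test(ages, parametric=False)
        rows.append(
            {"variable": "age", "test": omni.test, "statistic": omni.statistic,
             "df": omni.df[0], "p": omni.p}
        )
    table = pd.crosstab(manifest["sex"], manifest["group"])
    if table.shape[0] >= 2 and (table.to_numpy().sum(axis=0) > 0).all():
        stat, dof, p = gi.proportions_test(table.to_numpy())
        rows.append(
            {"variable": "sex", "test": "chi-squared", "statistic": stat,
             "df": dof, "p": p}
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    manifest: pd.DataFrame,
    matrices: dict,
    atlas: NodeAtlas,
    cfg: RunConfig,
    include_nulls: bool = True,
) -> dict:
    """Run every analysis stage on an in-memory cohort."""
    log.info("metrics: %d subjects, threshold %.2f", len(matrices), cfg.threshold)
    nodal, hemispheric = compute_metric_tables(matrices, atlas, cfg)
    bundle = {
        "nodal_metrics": nodal,
        "hemispheric_metrics": hemispheric,
        "nodal_comparisons": nodal_comparisons(nodal, manifest, atlas, cfg),
        "hemispheric_comparisons": hemispheric_comparisons(hemispheric, manifest, cfg),
        "correlations": correlation_report(nodal, hemispheric, manifest, atlas, cfg),
        "demographics": demographics_report(manifest, cfg),
        "manifest": manifest,
    }
    if include_nulls:
        null_df, null_values, null_meta = null_comparison_report(
            matrices, hemispheric, manifest, atlas, cfg
        )
        bundle["null_comparisons"] = null_df
        bundle["null_metrics"] = null_values
        bundle["null_meta"] = null_meta
    return bundle


REPORT_FILES = (
    "nodal_metrics",
    "hemispheric_metrics",
    "nodal_comparisons",
    "hemispheric_comparisons",
    "correlations",
    "null_comparisons",
    "null_metrics",
    "demographics",
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Load or simulate the cohort, run every stage, write reports.

    Returns the report bundle; when ``cfg.outdir`` is set, tidy CSVs, a
    plain-text summary and a JSON run log are written there.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if cfg.atlas_labels:
        atlas = read_atlas(cfg.atlas_labels, cfg.atlas_roles)
    else:
        atlas = default_atlas()
    if cfg.mode == "simulate":
        log.info("simulate: seed %d", cfg.seed)
        manifest, matrices, meta = generate_cohort(cfg.cohort, atlas, seed=cfg.seed)
    else:
        if not cfg.cohort_dir:
            raise ValueError("manifest mode requires cohort_dir")
        manifest, matrices, meta = read_cohort(cfg.cohort_dir)
    bundle = analyze_cohort(manifest, matrices, atlas, cfg, include_nulls=True)
    bundle["run_log"] = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_subjects": len(matrices),
        "cohort_meta": meta,
        "null_meta": bundle.get("null_meta"),
        "versions": {
            "periconn": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "gates": {
            "nodal_parametric": bundle["nodal_comparisons"]["parametric"].tolist(),
            "hemispheric_parametric": bundle["hemispheric_comparisons"][
                "parametric"
            ].tolist(),
        },
    }
    if cfg.outdir:
        write_reports(bundle, cfg.outdir)
    return bundle


def write_reports(bundle: dict, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in REPORT_FILES + ("manifest",):
        if name in bundle:
            bundle[name].to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    (outdir / "summary.txt").write_text(summarize_run(bundle))
    if "run_log" in bundle:
        (outdir / "run_log.json").write_text(
            json.dumps(bundle["run_log"], indent=2, default=str, sort_keys=True)
        )
    return outdir


def _fmt_mean_sd(row, g):
    m, s = row.get(f"mean_{g}"), row.get(f"sd_{g}")
    if m is None or (isinstance(m, float) and np.isnan(m)):
        return "--"
    return f"{m:.3g} ± {s:.3g}"


def summarize_run(bundle: dict) -> str:
    """Human-readable tables in 'mean +/- SD' style."""
    lines = []
    for section, key in (
        ("Nodal comparisons", "nodal_comparisons"),
        ("Hemispheric comparisons", "hemispheric_comparisons"),
    ):
        df = bundle.get(key)
        if df is None or df.empty:
            continue
        lines.append(section)
        lines.append("-" * len(section))
        for _, row in df.iterrows():
            cells = ", ".join(f"{g} {_fmt_mean_sd(row, g)}" for g in GROUPS)
            star = " *" if row.get("significant") else ""
            lines.append(
                f"{row['node']:<12} {row['metric']:<26} {row['test']:<14} "
                f"p={row['p']:.4g}{star}  [{cells}]"
            )
        lines.append("")
    corr = bundle.get("correlations")
    if corr is not None and not corr.empty:
        lines.append("Brain-behaviour correlations")
        lines.append("----------------------------")
        for _, row in corr.iterrows():
            lines.append(
                f"{row['node']:<12} {row['metric']:<26} {row['score']:<5} "
                f"{row['pooling']:<7} {row['method']:<8} "
                f"r={row['coefficient']:+.3f} p={row['p']:.4g} n={row['n']}"
            )
        lines.append("")
    nulls = bundle.get("null_comparisons")
    if nulls is not None and not nulls.empty:
        lines.append("Empirical vs Erdos-Renyi nulls")
        lines.append("------------------------------")
        for _, row in nulls.iterrows():
            lines.append(
                f"{row['group']:<4} {row['metric']:<26} {row['test']:<10} "
                f"p={row['p']:.4g} direction={row['direction']:+d}"
            )
        lines.append("")
    demo = bundle.get("demographics")
    if demo is not None and not demo.empty:
        lines.append("Demographics")
        lines.append("------------")
        for _, row in demo.iterrows():
            lines.append(
                f"{row['variable']:<6} {row['test']:<14} "
                f"stat={row['statistic']:.3f} df={row['df']} p={row['p']:.4g}"
            )
        lines.append("")
    return "\n".join(lines)
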