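"""Seeded synthetic three-group cohort generator.

Emulates the statistical structure the analysis assumes, so every
downstream stage is testable without real diffusion data:

* 47-region symmetric non-negative streamline-count matrices per
  subject, built from an Erdos-Renyi-like scaffold with log-normal
  weights;
* group-specific topology -- controls (TDC) carry M1/S1 as strongly
  weighted hubs with a spread degree profile (high betweenness, high
  degree diversity and hence high hierarchical/neighbourhood
  complexity); stroke groups (AIS, PVI) move the hubs onto background
  nodes with a uniform degree profile (more ordered network) and embed
  M1/S1/SMA in densely intra-connected strong-weight neighbourhoods
  (high closed-triplet mass, peripheral position);
* a thalamus effect (incident weights scaled up in controls, down in
  stroke) and an untouched negative-control node (IOG) whose own
  community -- an occipital block weakly coupled to the sensorimotor
  block -- keeps it clear of every group effect;
* clinical scores (AHA, MA on 0-100; BBT block counts) drawn so that
  AHA/MA carry a configured negative Spearman correlation with realized
  post-threshold M1 clustering across stroke subjects (Gaussian copula
  on ranks), while BBT scores are independent of all metrics.

A shared per-subject "reorganization severity" factor scales the
M1/S1/SMA clique strengths jointly, so the three sensorimotor
clustering values co-vary across subjects as the brain-behaviour
analysis assumes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .adjacency import WeightedAdjacency, density_threshold, write_adjacency
from .atlas import NodeAtlas, default_atlas
from .manifest import MANIFEST_COLUMNS, validate_manifest, write_manifest
from .metrics import clustering_coefficients

# Per-group clinical score models: (mean, sd) of the observed cohort.
DEFAULT_SCORES = {
    "AHA": {"AIS": (56.1, 18.7), "PVI": (68.4, 15.7)},
    "MA": {"AIS": (68.8, 22.4), "PVI": (88.0, 10.6)},
    "BBTA": {"AIS": (23.0, 16.6), "PVI": (36.3, 13.4)},
    "BBTU": {"AIS": (44.0, 14.5), "PVI": (49.0, 16.8)},
}
# Fraction of each stroke group completing each assessment.
DEFAULT_COMPLETION = {
    "AHA": {"AIS": 1.0, "PVI": 0.85},
    "MA": {"AIS": 0.77, "PVI": 0.52},
    "BBTA": {"AIS": 1.0, "PVI": 0.85},
    "BBTU": {"AIS": 1.0, "PVI": 0.85},
}
DEFAULT_AGE = {"AIS": (12.7, 4.0), "PVI": (11.5, 3.7), "TDC": (13.3, 3.6)}
DEFAULT_MALE_FRAC = {"AIS": 0.58, "PVI": 0.63, "TDC": 0.53}


@dataclass
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_ais: int = 26
    n_pvi: int = 27
    n_tdc: int = 32
    density: float = 0.35          # background edge density before thresholding
    block_within: float = 0.55     # edge density inside scaffold communities
    block_between: float = 0.10    # sensorimotor <-> occipital coupling
    weight_mu: float = 3.5         # log-normal log-mean of streamline counts
    weight_sigma: float = 0.9      # log-normal log-sd
    # hub mechanism (betweenness + degree diversity)
    hub_suppression: bool = True   # stroke groups lose M1/S1 hub status
    hub_degree: int = 28           # mean hub target degree
    hub_spread: int = 10           # controls' degree-profile half-range
    hub_spread_stroke: int = 0     # stroke groups' (more ordered) half-range
    hub_strength: float = 3.0      # weight multiplier on hub-incident edges
    n_hubs: int = 4
    background_keep_frac: float = 0.4  # stroke M1/S1 external edge survival
    background_weight_frac: float = 0.5
    # clique mechanism (clustering)
    local_clustering_boost: bool = True
    clique_strength: float = 6.0
    clique_sizes: dict = field(
        default_factory=lambda: {"M1": 7, "S1": 7, "SMA": 5}
    )
    clique_weight_sigma: float = 0.3  # log-sd of clique edge weights
    severity_sd: float = 0.8       # subject-level log-scale of clique strength
    # thalamus effect (weight scaling of thalamus-incident edges)
    thalamus_effect: bool = True
    thalamus_strength: float = 2.0   # controls
    thalamus_thin: float = 0.55      # stroke groups
    # hemispheric ordering (complexity): stroke hubs take a uniform
    # degree profile instead of the controls' spread profile
    hemispheric_order_increase: bool = True
    # subject-level noise
    subject_noise_sigma: float = 0.4
    edge_jitter: int = 16
    # clinical model
    rho: float = -0.5              # Spearman target, M1 clustering vs AHA/MA
    score_threshold: float = 0.25  # edge-removal fraction used when realizing
    scores: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCORES.items()})
    completion: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPLETION.items()})
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ais, self.n_pvi, self.n_tdc) < 2:
            raise ValueError("group sizes must be >= 2")
        if not (0.0 < self.density < 1.0):
            raise ValueError("density must lie in (0, 1)")
        if not (-1.0 < self.rho <= 0.0):
            raise ValueError("rho must lie in (-1, 0]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _symmetrize(w: np.ndarray) -> np.ndarray:
    return np.triu(w, k=1) + np.triu(w, k=1).T


def _set_edge(w, a, b, val):
    w[a, b] = val
    w[b, a] = val


def _lognormal(rng, cfg, size=None):
    return rng.lognormal(cfg.weight_mu, cfg.weight_sigma, size)


def _component_size(w: np.ndarray, start: int) -> int:
    adj = w > 0
    seen = np.zeros(w.shape[0], dtype=bool)
    stack = [start]
    seen[start] = True
    while stack:
        v = stack.pop()
        for u in np.flatnonzero(adj[v]):
            if not seen[u]:
                seen[u] = True
                stack.append(u)
    return int(seen.sum())


# Scaffold communities.  The occipital block holds the negative-control
# node and its natural visual-system neighbours; the sensorimotor block
# holds the seven analysed motor nodes plus adjacent areas.  Their weak
# coupling keeps group-specific sensorimotor effects out of the control
# node's neighbourhood, as in a real connectome.
OCCIPITAL_BLOCK = (
    "Calcarine_L",
    "Cuneus_L",
    "Lingual_L",
    "Occipital_Sup_L",
    "Occipital_Mid_L",
    "Occipital_Inf_L",
    "Fusiform_L",
)
SENSORIMOTOR_BLOCK_EXTRA = (
    "Paracentral_Lobule_L",
    "Rolandic_Oper_L",
    "Insula_L",
)


def _block_probability_matrix(cfg: CohortConfig, atlas: NodeAtlas) -> np.ndarray:
    """Per-pair edge probabilities of the stochastic block scaffold."""
    n = atlas.n
    labels = atlas.all_labels
    occ = {labels.index(x) for x in OCCIPITAL_BLOCK if x in labels}
    sm = {labels.index(x) for x in atlas.sensorimotor_labels}
    sm |= {labels.index(x) for x in SENSORIMOTOR_BLOCK_EXTRA if x in labels}
    p = np.full((n, n), cfg.density)
    for block in (occ, sm):
        b = sorted(block)
        p[np.ix_(b, b)] = cfg.block_within
    o, s = sorted(occ), sorted(sm)
    p[np.ix_(o, s)] = cfg.block_between
    p[np.ix_(s, o)] = cfg.block_between
    return p


def _generate_subject_matrix(rng, group: str, cfg: CohortConfig, atlas: NodeAtlas):
    """One subject's symmetric weight matrix plus the severity draw."""
    n = atlas.n
    idx = {role: atlas.all_labels.index(atlas.label_of(role)) for role in
           ("M1", "S1", "SMA", "thalamus", "IOG")}
    atlas_idx = {atlas.all_labels.index(lab) for lab in atlas.node_labels}
    occ_idx = {atlas.all_labels.index(x) for x in OCCIPITAL_BLOCK
               if x in atlas.all_labels}
    # nodes eligible to carry group-specific structure: outside the
    # analysed atlas set and outside the control node's community
    pool = np.array(sorted(set(range(n)) - atlas_idx - occ_idx))
    stroke = group in ("AIS", "PVI")
    severity = float(rng.standard_normal()) if stroke else 0.0

    # (i) scaffold: stochastic-block mask with log-normal weights
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    p_block = _block_probability_matrix(cfg, atlas)
    mask = rng.random(iu[0].size) < p_block[iu]
    vals = _lognormal(rng, cfg, iu[0].size) * mask
    w[iu] = vals
    w = _symmetrize(w)

    # (ii) hubs: strongly weighted high-degree nodes that attract
    # shortest paths.  Controls keep M1/S1 among the hubs; with
    # hub_suppression, stroke hubs are all drawn from the background.
    # Hub target degrees follow a spread profile in controls (high
    # degree diversity -> high hierarchical/neighbourhood complexity);
    # with hemispheric_order_increase, stroke hubs take a uniform
    # profile of the same mean (same edge mass, more ordered network).
    if stroke and cfg.hub_suppression:
        hubs = list(rng.choice(pool, size=cfg.n_hubs, replace=False))
    else:
        extra = rng.choice(pool, size=max(cfg.n_hubs - 2, 0), replace=False)
        hubs = [idx["M1"], idx["S1"], *extra.tolist()]
    spread = (
        cfg.hub_spread_stroke
        if (stroke and cfg.hemispheric_order_increase)
        else cfg.hub_spread
    )
    offsets = np.linspace(spread, -spread, num=len(hubs))
    targets = [int(round(cfg.hub_degree + o)) for o in offsets]
    for h, target in zip(hubs, targets):
        nbrs = set(np.flatnonzero(w[h] > 0))
        candidates = [v for v in range(n) if v != h and v not in nbrs]
        need = max(0, target - len(nbrs))
        if need and candidates:
            new = rng.choice(candidates, size=min(need, len(candidates)), replace=False)
            for v in new:
                _set_edge(w, h, v, _lognormal(rng, cfg))
        w[h, :] *= cfg.hub_strength
        w[:, h] = w[h, :]

    # stroke M1/S1: prune and weaken external edges (leaf-like
    # position); edges touching the negative-control node are exempt
    # from every group-specific effect
    if stroke and cfg.hub_suppression:
        for role in ("M1", "S1"):
            v = idx[role]
            nbrs = np.flatnonzero(w[v] > 0)
            keep = rng.random(nbrs.size) < cfg.background_keep_frac
            for u, kept in zip(nbrs, keep):
                if u == idx["IOG"]:
                    continue
                if kept:
                    _set_edge(w, v, u, w[v, u] * cfg.background_weight_frac)
                else:
                    _set_edge(w, v, u, 0.0)

    # (iii) dense strong-weight cliques.  Every subject carries the same
    # number of local communities so global path competition is matched
    # across groups; in stroke they are centred on M1/S1/SMA (strength
    # modulated by the shared severity factor), in controls on random
    # background nodes.
    if cfg.local_clustering_boost:
        strength = cfg.clique_strength * math.exp(cfg.severity_sd * severity)
        base = math.exp(cfg.weight_mu)
        if stroke:
            centres = [(idx[role], size) for role, size in cfg.clique_sizes.items()]
        else:
            # background centres are themselves pool nodes, so one fewer
            # partner keeps the count of strong pool-pool edges matched
            spots = rng.choice(pool, size=len(cfg.clique_sizes), replace=False)
            centres = [(v, s - 1) for v, s in zip(spots.tolist(), cfg.clique_sizes.values())]
        for v, size in centres:
            partners = rng.choice(pool[pool != v], size=size, replace=False)
            members = [v, *partners.tolist()]
            for a_i, a in enumerate(members):
                for b in members[a_i + 1:]:
                    jitter = rng.lognormal(0.0, cfg.clique_weight_sigma)
                    _set_edge(w, a, b, base * strength * jitter)

    # thalamus: incident weights scaled up in controls and down in
    # stroke (clustering scales as the 2/3 power of the factor, so the
    # leak onto other nodes' triangles stays small)
    if cfg.thalamus_effect:
        th = idx["thalamus"]
        factor = cfg.thalamus_thin if stroke else cfg.thalamus_strength
        iog_w = w[th, idx["IOG"]]
        w[th, :] *= factor
        w[th, idx["IOG"]] = iog_w  # control node untouched
        w[:, th] = w[th, :]

    # (iv) subject-level edge jitter and multiplicative weight noise
    present = np.flatnonzero(w[iu] > 0)
    absent = np.flatnonzero(w[iu] == 0)
    n_flip = min(cfg.edge_jitter, present.size, absent.size)
    if n_flip:
        add = rng.choice(absent, size=n_flip, replace=False)
        drop = rng.choice(present, size=n_flip, replace=False)
        for e in add:
            _set_edge(w, iu[0][e], iu[1][e], _lognormal(rng, cfg))
        for e in drop:
            _set_edge(w, iu[0][e], iu[1][e], 0.0)
    noise = np.zeros((n, n))
    noise[iu] = np.exp(cfg.subject_noise_sigma * rng.standard_normal(iu[0].size))
    noise = _symmetrize(noise)
    w = w * noise
    np.fill_diagonal(w, 0.0)
    return w, severity


def generate_subject(
    rng, group: str, cfg: CohortConfig, atlas: NodeAtlas, max_retries: int = 5
) -> tuple:
    """Generate one subject, retrying the random draw if the scaffold is
    disconnected at M1; raises if it stays disconnected."""
    m1 = atlas.all_labels.index(atlas.label_of("M1"))
    for _ in range(max_retries):
        w, severity = _generate_subject_matrix(rng, group, cfg, atlas)
        if _component_size(w, m1) >= int(0.9 * atlas.n):
            return WeightedAdjacency(atlas.all_labels, w), severity
    raise ValueError(
        "cohort configuration leaves the scaffold disconnected at M1; "
        "raise the density or reduce pruning"
    )


def _normal_scores(values: np.ndarray) -> np.ndarray:
    ranks = sps.rankdata(values)
    return sps.norm.ppf((ranks - 0.5) / values.size)


def generate_clinical_scores(
    metric_values: np.ndarray, groups, cfg: CohortConfig, rng
) -> pd.DataFrame:
    """Clinical scores for stroke subjects, coupled to a metric vector.

    ``metric_values``: realized post-threshold M1 clustering per stroke
    subject.  AHA and MA are drawn through a Gaussian copula on the
    metric's ranks so their Spearman correlation with it targets
    ``cfg.rho`` (Pearson copula parameter 2 sin(pi rho / 6)); BBT scores
    are independent.  AHA/MA are clipped to [0, 100]; BBT scores are
    non-negative integers.  Missingness follows the per-group
    completion fractions.
    """
    metric_values = np.asarray(metric_values, dtype=float)
    groups = list(groups)
    n = metric_values.size
    if n != len(groups):
        raise ValueError("one group label per metric value required")
    if not np.isfinite(metric_values).all():
        raise ValueError("metric values must be finite")
    z_x = _normal_scores(metric_values)
    rho_p = 2.0 * math.sin(math.pi * cfg.rho / 6.0)
    out = {}
    for score in ("AHA", "MA"):
        z = rho_p * z_x + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
        vals = np.empty(n)
        for i, g in enumerate(groups):
            mean, sd = cfg.scores[score][g]
            vals[i] = mean + sd * z[i]
        out[score] = np.clip(vals, 0.0, 100.0)
    for score in ("BBTA", "BBTU"):
        vals = np.empty(n)
        for i, g in enumerate(groups):
            mean, sd = cfg.scores[score][g]
            vals[i] = mean + sd * rng.standard_normal()
        out[score] = np.round(np.clip(vals, 0.0, None))
    df = pd.DataFrame(out)
    # missingness per assessment, per group
    for score in ("AHA", "MA", "BBTA", "BBTU"):
        for g in set(groups):
            members = [i for i, gg in enumerate(groups) if gg == g]
            frac = cfg.completion[score][g]
            n_missing = len(members) - int(round(frac * len(members)))
            if n_missing > 0:
                miss = rng.choice(members, size=n_missing, replace=False)
                df.loc[miss, score] = np.nan
    return df


def generate_cohort(cfg: CohortConfig, atlas: NodeAtlas | None = None, seed=None):
    """Full synthetic cohort: (manifest, matrices, metadata).

    ``matrices`` maps subject id to a :class:`WeightedAdjacency`;
    ``manifest`` is a validated cohort manifest (matrix_path holds the
    conventional relative path used by :func:`write_cohort`).
    """
    atlas = atlas or default_atlas()
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(master))
    plan = (
        [("AIS", i) for i in range(cfg.n_ais)]
        + [("PVI", i) for i in range(cfg.n_pvi)]
        + [("TDC", i) for i in range(cfg.n_tdc)]
    )
    rows, matrices = [], {}
    stroke_ids, stroke_groups, stroke_clust = [], [], []
    for group, i in plan:
        sid = f"{group}{i + 1:02d}"
        A, _ = generate_subject(rng, group, cfg, atlas)
        matrices[sid] = A
        age_mean, age_sd = DEFAULT_AGE[group]
        age = float(np.clip(age_mean + age_sd * rng.standard_normal(), 6.0, 19.9))
        sex = "M" if rng.random() < DEFAULT_MALE_FRAC[group] else "F"
        if group == "AIS":
            lesion = float(rng.lognormal(3.5, 1.0))
        elif group == "PVI":
            lesion = float(rng.lognormal(1.5, 0.8))
        else:
            lesion = np.nan
        rows.append(
            {
                "id": sid,
                "group": group,
                "age": round(age, 1),
                "sex": sex,
                "lesion_volume": round(lesion, 2) if np.isfinite(lesion) else np.nan,
                "AHA": np.nan,
                "MA": np.nan,
                "BBTA": np.nan,
                "BBTU": np.nan,
                "matrix_path": f"matrices/{sid}.csv",
            }
        )
        if group in ("AIS", "PVI"):
            thr = density_threshold(A, cfg.score_threshold)
            c, _ = clustering_coefficients(thr)
            stroke_ids.append(sid)
            stroke_groups.append(group)
            stroke_clust.append(c[atlas.all_labels.index(atlas.label_of("M1"))])
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    scores = generate_clinical_scores(
        np.array(stroke_clust), stroke_groups, cfg, rng
    )
    manifest = manifest.set_index("id")
    for col in ("AHA", "MA", "BBTA", "BBTU"):
        manifest.loc[stroke_ids, col] = scores[col].to_numpy()
    manifest = manifest.reset_index()
    manifest = validate_manifest(manifest)
    meta = {"seed": int(master), "config": cfg.to_dict(), "n_subjects": len(plan)}
    return manifest, matrices, meta


def write_cohort(manifest: pd.DataFrame, matrices: dict, outdir, meta: dict | None = None):
    """Write manifest.csv, matrices/<id>.csv and metadata.yaml."""
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    for sid, A in matrices.items():
        write_adjacency(A, outdir / "matrices" / f"{sid}.csv")
    write_manifest(manifest, outdir / "manifest.csv")
    if meta is not None:
        (outdir / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return outdir


def read_cohort(directory):
    """Load a cohort written by :func:`write_cohort`."""
    from .adjacency import read_adjacency
    from .manifest import read_manifest

    directory = Path(directory)
    manifest = read_manifest(directory / "manifest.csv")
    matrices = {
        row["id"]: read_adjacency(directory / row["matrix_path"])
        for _, row in manifest.iterrows()
    }
    meta = None
    meta_path = directory / "metadata.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
    return manifest, matrices, meta
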