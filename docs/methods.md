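# Methods

This note documents the analysis model, the numerical conventions, the
synthetic cohort generator, and the design choices that were genuinely
open. It states nothing the test suite or `scripts/acceptance.py` does
not itself compute.

## Analysis pipeline

The unit of analysis is a symmetric, non-negative, region-labelled
weight matrix — streamline counts between the 47 AAL2-style regions of
one hemisphere. Whole-brain (e.g. 120-region) matrices are first
reduced to the 47-region principal submatrix. Preprocessing per
subject: the diagonal is set to zero, then density thresholding removes
the `floor(0.25·m)` weakest of the `m` non-zero upper-triangle edges.
Zeros are treated as absent edges, not as candidate "bottom weights" —
otherwise the threshold would be a no-op on sparse matrices, and the
operation's purpose is pruning weak, likely spurious reconstructed
fibres. Ties at the cut weight are broken deterministically by
ascending (weight, row index, column index), a rule chosen only for
reproducibility. Thresholding is applied to the 47-region hemispheric
matrix (i.e. after subsetting).

### Metrics

*Shortest paths* use the length transform `length = 1/weight`:
streamline count is a connection strength, so heavier edges are
shorter. This is standard practice in structural connectivity but is a
convention, not a law; it is configurable (`transform="unit"` gives hop
counting). Unreachable pairs contribute zero to betweenness sums rather
than raising errors.

*Betweenness* is reported raw (ordered-pair sum) by default, with the
normalized variant (divided by `(n−1)(n−2)`) behind a flag. Group
averages of the raw variant on 47-node graphs are numbers of order
10–10³; normalized values lie in [0, 1]. Both variants are verified
against a brute-force simple-path enumeration oracle.

*Weighted clustering* uses geometric-mean triangle intensities on raw,
un-rescaled weights, so `c_i` carries the scale of the weights (it is
homogeneous of degree 1 in the weights — scaling all weights by κ
scales every `c_i` by κ). A `rescale=True` option divides weights by
the maximum weight first, matching the convention of common toolboxes
(and agreeing with networkx's weighted clustering, which is used as a
cross-check in the tests). Nodes of degree < 2 have no possible
triplets and get `c_i = 0`.

*Hierarchical complexity* `R` and its nodal decomposition
(neighbourhood complexity `nc_i`) are functions of integer degrees, so
they are evaluated on the binarized post-threshold graph. Per degree
class `K_p` with at least two members, member neighbour-degree
sequences are sorted ascending before the entrywise variance is taken
(unsorted sequences would make the entrywise mean meaningless). `D`
counts every distinct degree in the network, including singleton
classes and degree 0; classes with one member (or degree 0) contribute
no variance term. Nodes whose degree is unique have undefined `nc_i`
and are excluded from the hemispheric mean. Algebraically
`R = (Σ_i nc_i) / D` over defined nodes, which the tests assert.

### Statistics

Normality is assessed per group with Shapiro–Wilk at α = 0.05; a single
non-normal group routes the whole comparison to the nonparametric
branch (Kruskal–Wallis omnibus, Mann–Whitney rank-sum post-hocs).
Constant samples are treated as non-normal. Pairwise post-hoc p-values
are Bonferroni-multiplied by the family size — 3 (the group pairs)
within each metric × node; no correction is applied across nodes, since
the analysis reports per-node post-hocs. All tests are two-sided. A
comparison is declared significant when the omnibus p and at least one
corrected pairwise p fall below α.

Brain–behaviour correlations use pairwise deletion of missing scores
and the same normality gate to choose Pearson vs Spearman. Post-hoc
power of the two-sample t test uses the noncentral t distribution with
df = n₁+n₂−2 and noncentrality d·√(n₁n₂/(n₁+n₂)); at very large df,
where scipy's noncentral t loses stability, the normal approximation
(accurate to < 0.01 there) is substituted.

### Null models

Null graphs are Erdős–Rényi G(n, p) with p matched by default to the
mean pre-threshold density of the cohort (the generating study of this
kind typically leaves the ER parameter unstated, so matching the
empirical density is the least arbitrary choice; it is configurable).
Weights are unit by default — ER is a binary model — with an option to
bootstrap weights from the pooled empirical non-zero weight
distribution. Ensemble size defaults to the rounded mean group size
(28 for groups of 27/26/32). Null graphs pass through the identical
density-thresholding path before metrics are computed, and each group
is compared to the ensemble with the same normality-gated two-sample
machinery.

## Synthetic cohort generator

The generator's job is to emulate the statistical structure such a
study assumes, at the study's own scale (26 AIS / 27 PVI / 32 TDC, 47
regions), so the pipeline's inferential machinery can be exercised and
its direction-recovery measured. It is not a biophysical simulation.

**Scaffold.** A stochastic block model: background density 0.35 with
log-normal weights (log-mean 3.5, log-sd 0.9, i.e. median ≈ 33
streamlines, heavy right tail), a sensorimotor community (the seven
analysed motor regions plus paracentral lobule, rolandic operculum and
insula) and an occipital community (calcarine, cuneus, lingual,
superior/middle/inferior occipital, fusiform) each at density 0.55,
with weak (0.10) coupling between them. The occipital block matters:
it places the negative-control node (IOG) in its own community, so
group-specific sensorimotor effects do not reach its neighbourhood —
the property that makes a negative-control region meaningful in the
first place. The control node's incident edges are additionally exempt
from every group-specific operation.

**Group effects.** Four mechanisms, each an independent toggle:

1. *Hubs / hub suppression.* Every subject gets four strongly weighted
   (×3) high-degree hubs. In controls these are M1, S1 and two
   background nodes; with `hub_suppression` the stroke groups draw all
   four from the background, and M1/S1 instead lose 60% of their
   remaining external edges (the survivors halved in weight) — the
   "hub-to-leaf" shift. Hub target degrees average 28 in all groups,
   so total strong-edge mass, and hence global path competition, is
   matched across groups.
2. *Local clustering.* Every subject carries three dense cliques with
   strong (×6) weights. In stroke they are centred on M1, S1 (7
   partners each) and SMA (5); in controls on background nodes with one
   fewer partner, keeping the count of strong background-background
   edges matched. A per-subject "reorganization severity" factor
   (log-normal, log-sd 0.8) scales all three stroke clique strengths
   jointly, making the three sensorimotor clustering values co-vary
   across subjects — required for the brain–behaviour structure below.
3. *Thalamus.* Thalamus-incident weights are scaled ×2.0 in controls
   and ×0.55 in stroke; clustering at the thalamus scales as the 2/3
   power of the factor, so the contrast is ≈ 2.4× while the leak into
   other nodes' triangles (one scaled edge, 1/3 power) stays small.
4. *Hemispheric ordering.* Control hubs take a spread degree profile
   (28 ± 10 across the four hubs); with `hemispheric_order_increase`
   stroke hubs are uniform at 28. Degree diversity is what
   hierarchical and neighbourhood complexity measure, so controls score
   higher on both while edge counts stay matched.

Subject-level variability: multiplicative log-normal weight noise
(log-sd 0.4) and a 16-edge add/remove jitter. A draw whose graph is
disconnected at M1 is retried and eventually rejected with a message.

**Clinical scores.** AHA and MA are coupled to each stroke subject's
realized post-threshold M1 clustering through a Gaussian copula on
ranks (Pearson copula parameter 2·sin(πρ/6) for a Spearman target ρ,
default −0.5), then mapped to the per-group score means/SDs and clipped
to [0, 100]. Because S1 and SMA clustering co-vary with M1 through the
shared severity factor, their correlations with AHA/MA are negative as
well, at smaller magnitude — the intended cascade. BBT scores are
drawn independently of all metrics (block counts, non-negative
integers), and controls carry no scores. Per-assessment completion
fractions reproduce realistic missingness (e.g. only about half of the
PVI group has an MA score).

**What the generator does not emulate.** Real streamline matrices have
spatially structured weights (distance-dependent connectivity,
homotopic patterns), integer counts, subject-level global efficiency
differences, and measurement artifacts of tractography; none of these
are modelled. Passing tests therefore demonstrate that the pipeline
recovers group structure and score coupling *of the kind and size the
generator plants*, not that it would detect the (unknown) true effect
sizes in real diffusion data. Group-level dispersion parameters are
free choices, since subject-level dispersion of such matrices is not
publicly documented.

## Numerical conventions and degenerate inputs

- Symmetry tolerance on input matrices: 1e-9 absolute; matrices are
  exactly symmetrized internally after validation.
- Labels, not indices, are the public node identifiers; indexing is
  0-based internally.
- Omnibus tests on data where every observation is identical return
  statistic 0, p = 1 (scipy raises); empirical-vs-null comparisons
  where both samples are constant are flagged degenerate.
- Correlations require ≥ 3 complete pairs and a non-constant vector on
  each side; otherwise the pair is omitted from the report.
- CSV reports are written with `%.10g` floats, making byte-identical
  outputs for a fixed seed a testable contract.

## Problem sizes used by the tests

The oracle-equivalence suite sweeps 200 seeded random weighted graphs
with n ≤ 7 against brute-force path/triangle/variance enumerations;
the calibration tests run 1000 null replicates per omnibus branch; the
recovery suite generates 100 default-scale cohorts (85 subjects each)
and the acceptance script 50. These sizes give binomial confidence
intervals comfortably inside the asserted bounds while keeping the
whole suite in the tens of minutes on a single CPU.

## Known limitations

- The nodal neighbourhood-complexity formula is this package's
  documented decomposition of hierarchical complexity; other nodal
  definitions (e.g. unscaled per-node variances) exist.
- Which betweenness variant (raw vs normalized) and which
  weight-to-length transform best match any given external dataset is
  not decidable from the data model; both are exposed as options.
- The IOG negative-control guarantee is distributional: about 5–8% of
  seeded cohorts still show a nominally significant IOG comparison by
  type-I error alone, which is the expected behaviour of the test
  battery, not a generator defect.
- No covariate-adjusted (regression) models; correlation screening
  only. No edge-level statistics, no modularity/efficiency/rich-club
  metrics, no degree-preserving rewiring nulls.
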