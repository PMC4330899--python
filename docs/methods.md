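# Methods

## Scope and model of the data

`connrel` analyses test-retest (TRT) collections of weighted structural
brain networks: for each of *n* subjects and *m* scanning sessions, a
symmetric nonnegative matrix whose entry *w<sub>ij</sub>* is the number of
tractography streamlines (the fiber number, FN) with one endpoint in
cortical parcel *i* and the other in parcel *j*. Two parcels are connected
if at least one streamline ends in both; streamlines with both endpoints
in a single parcel form no edge (they are counted and logged). The package
quantifies how reproducible network properties are across sessions, at
four levels: global graph metrics, regional (nodal) metrics, individual
connections, and rich-club organization.

## Reliability estimator

The reliability index is the one-way random-effects intraclass correlation
ICC(1,1). For a balanced panel of n subjects × m sessions,

    MS_bs = m Σᵢ (ȳᵢ − ȳ)² / (n − 1)
    MS_ws = Σᵢⱼ (yᵢⱼ − ȳᵢ)² / (n (m − 1))
    ICC   = (MS_bs − MS_ws) / (MS_bs + (m − 1) MS_ws)

The between- and within-subject mean squares carry the roles of the
between- and within-subject variance components; this is the only reading
under which the estimator can go negative, which is why reported ICCs are
clamped at 0 (the raw value is kept for audit, and a constant panel is
reported as 0 with a degeneracy flag rather than a 0/0 failure). Values
are banded slight (0, 0.2], fair (0.2, 0.4], moderate (0.4, 0.6],
substantial (0.6, 0.8], almost perfect (0.8, 1], with ICC = 0 banded
slight. The estimator is affine-invariant and bounded above by 1; both
properties are tested, and the implementation is checked against an
independently coded loop-based ANOVA oracle and against
`pingouin.intraclass_corr`.

## Graph metrics and conventions

Edge length for shortest paths is the reciprocal weight 1/w — strong
fiber bundles are "short". The package computes network strength Sp
(mean nodal strength; a sum variant exists via `sp_mode`), global
efficiency E_glob (mean of 1/d over ordered pairs, 0 for disconnected
pairs), local efficiency E_loc (mean over nodes of the efficiency of the
neighbor-induced weighted subgraph), characteristic path length L_p
(mean distance over *connected* pairs, with a connectedness flag —
the convention for disconnected networks is not standardized, so it is
explicit here), Onnela-form weighted clustering C_p (geometric-mean
triangle intensity; weights divided by the network maximum by default,
with a raw-weight variant because fiber-count studies differ on this
point), and per-node strength and efficiency.

Second-order (normalized) metrics λ = L_p/⟨L_p,null⟩, γ = C_p/⟨C_p,null⟩
and σ = γ/λ are computed against an ensemble of degree-preserving
double-edge-swap nulls (default 100 nulls, 10·E attempted swaps each)
that carry each edge's weight with it, so every null preserves both the
binarized degree sequence and the weight multiset exactly. Nulls with
zero clustering are excluded with a warning. On graphs that admit no
valid swap (e.g. a triangle) the nulls equal the input and λ = γ = σ = 1
exactly.

## Rich-club organization and backbone

Hubs are nodes with strength > mean + 1 SD (population SD by default; a
sample-SD switch exists). Edges partition into rich-club (hub–hub),
feeder (hub–non-hub) and local (non-hub–non-hub). The weighted rich-club
coefficient at a strength cutoff is φ = W_R / (sum of the E_R strongest
weights in the network), evaluated at cutoffs mean + k·SD for
k ∈ {0, 0.5, 1, 1.5}; φ_norm divides by the null-ensemble mean, with each
null's cutoffs recomputed from its own strengths (rewiring changes
strengths; a fixed-threshold mode exists). A cutoff whose rich set
contains no edge is *flagged undefined*, never coerced to 0, so undefined
cells cannot silently enter averages.

The group backbone keeps edges that pass a one-tailed sign test of
"no connection exists" per session: subjects with zero count are ties and
are discarded, so k nonzero subjects give p = 0.5^k (p = 1 at k = 0).
With 11 subjects and α = 0.05 the survival boundary is exactly k ≥ 5.
An edge survives if significant in at least one session (`either`, the
default reading of a two-session design) or in all sessions (`both`, for
sensitivity analysis); surviving edges carry the mean weight over all
n × m observations, including zeros. No multiplicity correction is
applied by default; a Benjamini–Hochberg switch exists.

## Synthetic test-retest generator

No public per-edge variance components exist for scanned TRT connectome
data, so validation rests on a generator with *known* components.

**Template.** `make_template` draws a core–periphery graph: edge
probabilities in ratio 3:2:1 for core–core, core–periphery and
periphery–periphery pairs, water-filled to a target density (default 0.20,
matching typical low-resolution structural-connectome sparsity of
17–20%; the realized density must land within ±20% of target). Present
edges draw weights from a lognormal law with median `weight_scale`
(default 50 streamlines, σ_log = 1 — heavy-tailed, as fiber counts are),
doubled on core–core edges and rounded to integers ≥ 1 (fiber counts are
integers; integrality also makes the subdivision split exact). Nodes get
regional classes (association/primary/paralimbic at 50/30/20%) for
grouped reliability summaries. The default 80-node template emulates the
scale of a low-resolution cortical parcellation.

**Subdivision.** `subdivide_template` splits each node into `factor`
equal subnodes and partitions every edge weight across the factor²
subpairs with a multinomial draw whose cell probabilities are
Dirichlet-distributed (concentration 0.035 per cell). The small
concentration concentrates streamlines on few subpairs, which keeps the
high-resolution network sparse (≈1.7% at factor 13 from the default
template, the empirical range for ~1000-node parcellations); a uniform
split would give ≈5%. Totals are conserved exactly, so coarsening the
high-resolution template through the node map is the identity — a tested
invariant.

**Noise.** `simulate_trt` adds a per-subject random effect b (shared
across sessions) and a per-session residual ε to each present edge:
w = max(0, μ + b + ε), with b ~ N(0, σ²_bs·scale²) and
ε ~ N(0, σ²_ws·scale²). `variance_mode` sets the scale: `relative`
(scale = μ, noise proportional to bundle size; the default for the raw
API), `absolute` (scale = 1; the per-edge population ICC is then exactly
σ²_bs/(σ²_bs + σ²_ws), used by the recovery tests), and `mixed`
(between-subject relative, within-subject absolute — strong edges become
more reliable, reproducing the positive weight-vs-reliability relation
of real connectomes). A `lognormal_count` model yields rounded,
zero-truncated integer counts with log-scale components, for realism
rather than analytic checkability. Optional dropout zeroes a present edge
per subject-session. Clamping at zero induces a small downward ICC bias
for edges whose mean is within ~2 SD of zero; at the default weight scale
this is negligible and it is quantified nowhere else than here. All
randomness flows from one seed through named substreams (structure,
weights, classes, subjects, sessions, dropout), so identical seeds give
byte-identical datasets.

**Pipeline defaults.** The end-to-end scenario uses 11 subjects × 2
sessions (the canonical small TRT design), mixed variance mode with
σ²_bs = 0.04 (between-subject SD = 20% of the edge mean) and
σ²_ws = 100 (within-session SD = 10 streamlines), chosen once so the
median edge (≈50 streamlines) has population ICC ≈ 0.5 — the "fair to
good" regime reported for fiber-count networks. These components are
expressed on the low-resolution weight scale and are deliberately *not*
rescaled when the template is subdivided: subdivided edges are weaker, so
the high-resolution scenario is relatively noisier and its local ICCs
lower. Null ensembles in the reliability tables are seeded per subject
and shared across that subject's sessions, so the normalized metrics of
two identical sessions are identical — with zero within-subject variance
every defined ICC is exactly 1, a tested property.

## What the synthetic data does and does not show

The generator reproduces the qualitative facts that matter to the
analysis code — sparsity, heavy-tailed integer weights, a strength core
with rich-club organization, separable variance components, magnitude-
dependent reliability — and therefore validates estimators, invariants
and plumbing. It does not simulate image space: no susceptibility
artifacts, registration error, tractography false positives/negatives,
spatial autocorrelation between neighboring parcels, or subject-level
anatomical covariance. Passing tests demonstrate correctness of the
estimators and pipeline on data with known structure, not that any
specific empirical ICC value will be observed on scanner data.

## Numerical choices

- Problem sizes in the test suite: default end-to-end scenario 80 nodes /
  11 subjects / 100 nulls; high-resolution scenario 1040 nodes with the
  null ensemble scaled down to 20 and the binarized duplicate analysis
  disabled; ICC recovery at n = 200 subjects; oracle equivalence on all
  graphs with ≤ 5 nodes and 200 random graphs with ≤ 7 nodes at 1e−12.
- Shortest paths via Dijkstra on a sparse reciprocal-length graph;
  clustering via sparse triple products for large sparse matrices and
  dense `einsum` otherwise (identical results, one code path per regime).
- Tiny negative sums of squares from floating error are clipped at 0 with
  tolerance 1e−10 in the ANOVA decomposition; the highest-order within
  term's error is computed as the decomposition residual, which both
  equals its unit interaction in a balanced design and guarantees exact
  SS conservation.
- Rank-based Gaussianization uses Blom fractions (r − 3/8)/(n + 1/4) with
  average ranks on ties.
- TSV floats are written with `%.12g`; manifests hold SHA-256 content
  checksums and no timestamps, so reruns are byte-comparable.

## Known limitations

- Only ICC(1,1) is provided (no two-way or consistency variants, no
  confidence intervals) — it is the estimator the analysis is built
  around.
- `repeated_anova` handles balanced, fully crossed designs with ≤ 2
  within factors and ≤ 1 between factor, one observation per cell;
  unbalanced designs are rejected rather than approximated, and no
  sphericity correction is applied.
- The backbone's `either`/`both` session rule is exposed because the
  two-session design admits both readings; `either` is the default.
- Binary-network analysis binarizes at weight > 0 with no density
  matching across subjects.
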