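# Methods

## The diversity model

A sample's heterogeneity is summarised from its *cluster occupancy
distribution*: the vector `p` of fractions of cells assigned to each cluster
of a joint clustering of all samples under comparison. The generalized
diversity of order `q` is the Hill number

    qD = ( Σ_{i: p_i > 0} p_i^q )^(1/(1−q)),   q ≥ 0,
    1D = exp(−Σ p_i ln p_i)                      (continuous limit at q = 1),

an effective number of equally common clusters. The form is fixed uniquely
by requiring the classical special cases: richness at `q = 0`, exponential
Shannon at `q → 1`, inverse Simpson at `q = 2`, and Berger–Parker dominance
`1/max p` as `q → ∞`. Useful identities the test suite verifies:

* `qD` is non-increasing in `q` and bounded by `1 ≤ qD ≤ richness`;
* replication-invariant (doubling every count changes nothing) and
  doubling under equal-weight disjoint union of two copies;
* at finite large `q` the value exceeds `1/max p` by a relative
  `≈ ln(1/max p)/q`, so the `q → ∞` limit is approached only ~1/q fast.

Zero-count clusters are excluded from the sum at every order, including
`q = 0` (`0^0` is never evaluated): richness counts occupied clusters only.

### Numerical choices

* The generic branch is computed in log space,
  `log qD = logsumexp(q·log p) / (1−q)`, since `p^100` underflows double
  precision for `p < ~0.02`.
* `|q − 1| < 1e-9` switches to the exact exponential-Shannon branch; the
  generic branch suffers catastrophic cancellation there.
* `q = 0` returns the occupied-cluster count exactly (integer-derived), not
  the log-space expression.
* The default spectrum grid is 100 log-spaced points on `[1e-2, 1e2]`,
  always augmented with the exact anchors `{0.01, 0.1, 1, 2, 10, 100}` so
  the classical indices can be read off without interpolation.

## KS comparison of compositions

Two occupancy distributions aligned on the same ordered cluster space are
compared by `max_k |CDF_a(k) − CDF_b(k)|`, CDFs accumulating *proportions*
(not raw counts, so unequal sample sizes compare fairly) along the canonical
ascending cluster-id order. On categorical clusters the KS value depends on
that ordering; fixing it to the ascending joint-clustering order (the order
cluster exports use) is a deliberate reproducibility choice, stated
prominently here. The statistic is used purely as a distance — it satisfies
the metric axioms as a sup-norm of CDF differences — and no p-value is
attached. Pairwise matrices are computed on the full joint cluster space,
with zero padding for clusters a group never occupies (the distance is
invariant to such padding).

## Cluster expression profiles and network

Each cluster is summarised per gene by the geometric mean of UMI counts over
its cells, pooled across samples:

    profile_g = exp( mean_cells ln(count_g + c) ) − c,   c > 0.

The pseudocount `c` (default 1) makes zeros well defined; an all-zero gene
stays exactly 0 for any `c`, and `c → 0` recovers the plain geometric mean
on positive counts. No library-size normalisation is applied by default
(upstream pipelines normally normalise before clustering); an optional
median-library-size scaling flag is provided for raw inputs. Euclidean
distances between profile vectors define the cluster network; nodes carry
cell totals and condition composition (majority condition breaks exact ties
toward the lexicographically smallest label), edges carry the raw distance
plus a layout weight `1/(distance + 1e-6)` so force-directed layouts place
transcriptionally similar clusters near each other. The graph is emitted as
node/edge tables; rendering is presentation, not computation.

## Downsampling protocol

Stability of a score is established by subsampling `floor(f·n)` cells
uniformly without replacement (`f = 0.5` by default), recomputing occupancy
and `qD` at the six anchor orders, and repeating 1,000 times. Replicate `r`
draws its generator from `SeedSequence(entropy=master_seed, spawn_key=(r,))`
— a counter-based scheme making results bit-for-bit reproducible and
independent of execution order. `floor` keeps the subsample size
deterministic on odd counts. Reported per order: the replicate distribution
normalised by its mean (unit mean by construction), the standard deviation,
and the maximum absolute deviation from the full-data baseline in
effective-cluster units.

By default the joint cluster labels are held fixed under subsampling, which
isolates the sampling stability of the statistic itself from the stability
of the clustering algorithm. A `recluster_hook` lets callers re-derive
labels per replicate (e.g. with `quick_cluster`) when the combined
stability is wanted; the two modes answer different questions and outputs
are labelled by the caller accordingly.

## Synthetic cohorts

The generator emulates the structure of multi-sample droplet cohorts:
several samples per condition drawn on a shared cluster space, with
condition-specific occupancy vectors and per-cluster expression programs.
Cells are assigned clusters by multinomial draws from their sample's true
proportion vector; counts follow a negative binomial (gamma–Poisson) with a
log-normal baseline mean per gene (location 0.2 UMI, log-sd 0.5), a disjoint
block of 10 marker genes per cluster elevated to mean 8 UMI, and shared
dispersion α = 0.25 (variance = μ + αμ²) — desk-scale surrogates for UMI
data chosen for testability, not as biological claims. Defaults: 2,000
cells per sample, 300 genes.

Preset occupancy vectors encode the qualitative patterns the score should
rank, on a shared 14-cluster space where relevant:

* `healthy-like` — 8 occupied clusters, strongly skewed (max p = 0.40);
* `aml-like` — all 14 occupied, flat-ish (max p = 0.12); its spectrum
  strictly dominates the healthy-like one at *every* `q` by construction,
  since its `q → ∞` value (≈ 8.3) already exceeds healthy richness (8);
* `polyclonal-cd34-like` — uniform over 16 clusters (spectrum ≡ 16);
* `homogeneous-sorted-like` — one cluster holds 90% of cells.

These vectors are synthetic inventions; they are not estimates of any real
cohort. What passing tests show is that the pipeline recovers designed
composition structure through simulation, clustering and scoring; they say
nothing about batch effects, doublets, ambient RNA, clustering-resolution
choices or other properties of real droplet data, which the generator does
not model.

## Stand-in clustering

Cluster labels are a first-class *input* to every statistic here: in
practice they come from the platform that jointly processed the samples.
`quick_cluster` exists so end-to-end runs and tests need no external stack:
median-library-size scaling, `log1p`, truncated SVD to ≤ 20 components, and
k-means with 50 restarts. The generous restart count matters with strongly
imbalanced cluster sizes, where k-means++ occasionally seeds a dominant
cluster twice and merges two small clusters; 50 restarts makes that basin
escape reliable at the preset problem sizes. It is a plumbing partitioner,
not a proposed clustering method.

## Problem sizes and determinism

The shipped tests and the acceptance script run the identity suites on
1,000 random distributions, the arbitrary-precision cross-check (mpmath, 50
digits) on distributions of ≤ 6 clusters, the downsampling protocol at
10,000–20,000 cells × 1,000 replicates, and the full pipeline at 8,000
cells × 300 genes — sizes chosen so the whole analysis reruns from scratch
in a few minutes on one CPU while keeping every statistic comfortably out
of its small-sample regime. All entry points take explicit seeds; identical
seeds reproduce results bit for bit.

## Known limitations

* Diversity is computed on hard cluster assignments; soft/continuous
  embeddings, phylogenetic or functional diversity variants are out of
  scope.
* The KS distance's dependence on cluster ordering is inherited from the
  discrete formulation; alternative orderings would give different (equally
  deterministic) values.
* The expression network uses raw geometric-mean distances; whether a
  figure's layout uses distance or its inverse is a presentation choice,
  so both are emitted (raw distance + inverse layout weight).
* `quick_cluster` is deliberately simple and will not match platform
  clusterings on real data; real analyses should supply their own labels.
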