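# Methods

`grnfidelity` infers a gene regulatory network (GRN) from a short
developmental time course in two phases, and ships a synthetic-data
generator that makes every stage of the pipeline testable against a known
ground truth. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## Phase 1: ensemble inference and fidelity filtering

### Expression dynamics model

Each target gene *x* is modeled one gene at a time (the N-gene problem is
split into N one-dimensional problems). Production saturates and is
subject to competition between activators *A* and inhibitors *I*, with
first-order decay:

    dx/dt = v_max · (b + Σ_{j∈A} a_j u_j(t)^h) /
            (1 + b + Σ_{j∈A} a_j u_j(t)^h + Σ_{j∈I} c_j u_j(t)^h) − d·x

- `u_j(t)`: the regulator's observed, [0,1]-scaled profile, linearly
  interpolated between stages. Regulators enter as data, not as states —
  this is what makes the per-gene decomposition possible.
- `a_j, c_j ∈ [1e-3, 20]`: regulation weights. The upper bound is
  deliberately moderate: with the Hill exponent fixed at `h = 2`, very
  large weights turn any profile into a step function through
  saturation, which lets arbitrary regulators mimic each other.
- `b ∈ [1e-4, 0.5]`: basal drive; capped so that a regulator-free
  constant production cannot absorb strongly dynamic profiles.
- `v_max ∈ [1e-3, 2.5]`, `d ∈ [1e-3, 5]`: production scale and decay, in
  units of expression (scaled) per stage; stages sit at unit-spaced
  pseudo-times 0..T−1 because real stage timing is rarely quantified.
- `h = 2` fixed, not fitted: nine time points cannot constrain a
  per-edge exponent.
- Initial condition: the observed stage-0 value.

The right-hand side is linear in *x* given *t*, so a fixed-step RK4 on a
half-substep grid (4 substeps per stage interval by default) integrates
it accurately and deterministically; the single-activator case matches
the closed-form linear ODE solution to ~1e-6 at 8 substeps.

### Acceptance and the subnetwork ensemble

Fit quality is the variance-weighted mean squared error
`E = (1/T) Σ_t (x_sim − x_obs)² / σ_t²`; a simulation is data-consistent
when `E < 0.75`. Per-stage variances default to the floor
`(0.1 × dynamic range)²` (0.01 on scaled data) when no replicate
variances are available.

For each target the search repeatedly draws a regulator subset (size
1..K_max, `K_max = 3` by default, 2 in the recovery benchmarks), draws a
sign per regulator, and fits the weights/kinetics by a bounded
derivative-free local search in log-parameter space (3 random restarts,
120 shrinking-step coordinate moves, early stop at the acceptance
threshold; numba-compiled). Accepted members accumulate until an
ensemble cap or an attempt budget is reached. Defaults: cap 200, budget
1,000 attempts per gene; both configurable, and the full-scale analyses
in the literature run comparable ensembles of 50–2,000 members.

Accepted members are then reduced to a *necessary* regulator set: a
drawn regulator is removed when removing it keeps the member
data-consistent and costs almost nothing (error increase ≤ 0.05). This
strips the passengers that an under-determined subset draw inevitably
carries, without deleting co-regulators that genuinely improve the fit.

Whole putative networks are assembled by sampling one accepted member
per gene (1,000 networks by default) and pooled into per-directed-edge
statistics: the confidence metric (appearance frequency), activation /
inhibition fractions, and a sign call at a 2/3 majority ("unclear"
otherwise).

### Fidelity score

Confidence and term-overlap similarity are fused per edge as

    Z_k(w) = Zc_k + w · Zj_k

where `Zc` is the z-score of the natural-log confidence over the current
edge population and `Zj` the z-score of the Jaccard index
`|A∩B| / |A∪B|` of the genes' pre-propagated GO-style term sets. Only
nonzero Jaccard values are z-scored; zero-overlap edges receive the
sentinel `min(Zj) − 1`, which keeps `Zj` centred while still penalising
semantically dissimilar pairs. `w = 1` weights both sources equally and
is the default; `optimize_weight` grid-searches
{0, 0.25, 0.5, 1, 2, 5, 10} against a reference edge set by AUPR (ties
to the smallest weight). Z-scores are population statistics of the
network under analysis, so fidelity scores never compare across
networks; cross-network comparisons use the confidence metric, which is
absolute. Filtering keeps edges with `Z_k(w)` above a cutoff (defaults
2, 2.5, 3) and drops isolated nodes; the filtrations at rising cutoffs
are exactly nested.

The combination is the plain weighted sum of the two z-scores; no
normalising denominator is applied, and the default cutoffs should be
treated as formula-dependent.

## Phase 2: co-clustering and module expansion

Profile-driven inference cannot distinguish genes with near-identical
time courses, so Phase 2 first estimates profile-similarity clusters
stochastically: repeated self-organizing maps (batch algorithm, Gaussian
neighborhood shrinking linearly over 50 epochs, square grids drawn
uniformly per run) are trained on the profiles, and two genes'
*coincidence* is the fraction of runs mapping them to the same node.
The grid range is capped so genes outnumber map cells (side ≈
√(n_genes/2)), matching the regime of the full-scale setting (grids
3×3–50×50 against ~11k genes); with cells ≫ genes even near-identical
profiles split across neighboring nodes and coincidence loses meaning.
A dispersion pre-filter excludes stable genes (population SD over mean
< 20%, computed on the pre-scaling measurement scale — after min-max
scaling the ratio is meaningless). Clusters are connected components of
the coincidence graph at a 70% threshold; raising the threshold only
splits clusters.

Each scaffold edge A→B is expanded to all cross pairs of cluster(A) ×
cluster(B) (self-pairs removed; across parents an unordered duplicate
keeps the highest-confidence parent). Expanded pairs inherit the parent
confidence — re-running inference over the full gene set would be
prohibitive and adds no information for profile-identical genes — and
get their own Jaccard. The expanded population is re-z-scored and
filtered. The *cluster product* |cluster(src)|·|cluster(tgt)| is the
profile-uniqueness metric: predictions explainable by few
interchangeable genes rank first; the secondary filter keeps products ≤
30 by default (an arbitrary but documented choice).

## Benchmarking

Comparisons against a reference interaction set are undirected (curated
exports lack direction): per unordered pair the better-scoring direction
counts. The curve population is all unordered pairs among the evaluated
genes, with never-called pairs in a single trailing tie group — this
keeps the false-positive rate defined. AUCs are trapezoidal with grouped
tie thresholds. Network-level enrichment is the upper-tail
hypergeometric probability P(X ≥ x) for x reference edges among n called
out of N possible (the complement convention of a CDF routine, computed
in log space); it is verified against exhaustive draw enumeration for
all instances with N ≤ 12.

Topology reports: degree histogram with the Poisson estimate λ̂ = 2E/N;
a power-law exponent from least-squares regression of log count on log
degree over nonzero linear bins (γ = −slope, matching the evident
practice behind published γ ≈ 1 values; maximum-likelihood fitting is a
deliberate non-goal); and the hierarchy measure R² of an
origin-through fit of mean clustering coefficient C(k) against 1/k,
clipped at 0 for worse-than-mean fits. Both fits are flagged undefined
below 3 usable degree classes.

## Synthetic data: what it emulates, and what it does not

The generator plants every statistical structure the pipeline assumes:

- **Truth network**: a signed DAG grown gene-by-gene from a mixture of
  superlinear preferential attachment (70%, producing hubs; max degree
  exceeds 3× the median at n ≥ 40) and recency bias (30%, producing
  regulatory chains). The first ~15% of genes are root drivers with no
  regulators. Mean in-degree defaults to 2; values below 1 leave
  independent genes (used by the depleted preset).
- **Time course** (9 stages): generated in topological order with the
  *same* dynamics family and integrator the inference fits, so the
  noiseless case is exactly well-specified. Roots start high (0.8–1)
  and decay at log-spaced rates; each non-root gets a developmental
  event time propagated down the cascade (then spread over stages
  1.2–6.8 by a monotone blend of min-max and rank maps, so late genes do
  not pile into interchangeable end-window risers), and its kinetic
  parameters are chosen by fitting the true-regulator model to a pulse
  template at that time under transient-kinetics bounds (decay ≥ 0.3,
  basal ≤ 0.2). The gene's profile is the *integrated model trajectory*,
  never the template. Draws whose realized profile fails to express its
  event timing are retried. Gaussian noise (SD 0.05 by default,
  truncated at [0, 1.5]) is added before per-row min-max scaling.
- **Modules**: planted clone genes copy a template's noiseless profile
  plus fresh noise (pairwise Pearson r > 0.95 at noise ≤ 0.05) and
  inherit its annotations.
- **Annotations**: every gene carries a private term plus its cluster's
  term block; cross-cluster true pairs are forced to zero overlap with
  probability 0.37 (the roughly-one-third of known-true pairs that real
  propagated ontologies leave without common terms) and otherwise share
  a pair-specific term with probability `share_prob`. All non-shared
  terms are unique by construction, so the zero-overlap fraction is
  controlled, not accidental.
- **Reference database**: round(coverage × true edges) plus decoy
  non-edges, with exact bookkeeping of the true-positive count. The
  `enriched` preset (50 genes, mean in-degree ≈ 6.7, full coverage)
  lands near 283 known interactions; the `depleted` preset leaves ~3.

What passing these benchmarks shows: the search, scoring, clustering,
expansion and evaluation machinery behave as specified, and the
confidence/fidelity ranking genuinely separates signal from noise when
the data identify the regulators. What it does not show: performance on
real microarray data, whose noise is not i.i.d. Gaussian, whose dynamics
are not in the model family (a `misspecified` variant jitters the Hill
exponent for stress testing), and whose profile collinearity is
substantially worse than the generator's.

### A note on the recovery ceiling

On noiseless 20-gene benchmarks (K_max = 2, ensemble cap 100, budget
2,000 attempts/gene) the directed confidence AUROC averages ≈ 0.8 per
seed with the permutation null at 0.5. Two effects bound it there: with
two co-required regulators the exact pair with correct signs is drawn
only ~1–2 times per budget, so secondary co-regulators earn little
frequency; and saturating production lets similarly-timed candidate
profiles substitute for one another within the fixed acceptance band —
the same profile-interchangeability that motivates Phase 2's clustering
in the first place. Published full-scale applications of this method
class report undirected AUROC near 0.58 against curated references,
consistent with that regime.

## Reproducibility

Every stochastic stage derives its stream from a single master seed
(per-gene streams are spawned independently of execution order, so
parallel or reordered per-gene work merges deterministically). Pipeline
artifacts carry a SHA-256 hash of the full configuration, and Phase 2
refuses to consume artifacts written under a different configuration.
Default desk-scale sizes (200 SOM runs, 1,000 sampled networks, ensemble
cap 200) are package choices balancing statistical resolution against
interactive runtimes; the corresponding full-scale values used in the
literature (2,240 SOM runs, 1,000 networks, ensembles up to 2,000) are
reachable through configuration alone.
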