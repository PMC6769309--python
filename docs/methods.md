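# Methods

## Point clouds and dissimilarity

Samples (sample-level analysis) or genes (gene-level analysis) are
points; the dissimilarity is `1 − r` with `r` the Pearson correlation
of the two log2 expression vectors, giving values in [0, 2].  This is
deliberately `1 − r`, not `1 − |r|` or `(1 − r)/2`: anti-correlated
points are *far* apart.  `1 − r` is not a metric (the triangle
inequality can fail); none of the computations below require it, only
symmetry, a zero diagonal and finiteness.  Constant vectors make `r`
undefined and raise an error rather than being dropped silently — the
explicit `--drop-constant` pre-filter removes all-sample-constant genes
*before* group splitting so both groups keep identical gene universes.
Numerically, `r` is clipped so that `d` stays in [0, 2]; tie patterns
at the 1e−15 level may differ from other correlation implementations,
which can permute the order of equal-weight merges without changing any
invariant.

## Persistence computation

**Vietoris–Rips.** A k-simplex enters the filtration at the maximum
pairwise dissimilarity of its vertices; all simplices up to dimension
`max_dim + 1` are enumerated (guarded by a 10⁷ simplex ceiling), sorted
by (ε, dimension, lexicographic vertex tuple) — any valid order gives
the same diagram, but this fixed tie-break makes runs bit-reproducible
— and reduced by the standard Z/2 lowest-one column algorithm.
Coefficients are fixed to Z/2; no other field is offered.  The
filtration is truncated at ε_max, the largest pairwise dissimilarity,
where a Rips complex on a finite cloud is complete up to the enumerated
dimension, so the only essential (never-dying) class is the final
connected component.

**Essential classes and zero-length pairs.** Essential classes are
counted but excluded from all sums: assigning them an arbitrary finite
death would be undefined, and a connected cloud contributes exactly one
in dimension 0 for *both* groups, so group differences are unaffected.
Pairs with death == birth are dropped from diagrams (they contribute 0
to every invariant); an internal dimension-0 conservation check
(finite + essential == number of points) runs before dropping.

**Dimension-0 fast path.** Components are born at 0 and die at the
merge heights of Kruskal's algorithm, so the dimension-0 diagram is
computed exactly by union-find over ascending edges, and SDT₀ equals
the total minimum-spanning-tree weight.  This path is proven equal to
the full reduction in the test suite and is used automatically for
sample-level SDT₀ permutation runs, which makes very large permutation
counts cheap.

**Lazy-witness.** Gene clouds have thousands of points, so persistence
is computed on a landmark subset (default 20, chosen by maxmin;
`random` is available).  Maxmin starts from the point with the smallest
dissimilarity row-sum (lowest index on ties) and greedily adds the
point maximising its minimum dissimilarity to the chosen landmarks —
deterministic, well-spread.  Each non-landmark point acts as a witness:
with `m(w)` the dissimilarity from witness `w` to its ν-th nearest
landmark (default ν = 1), witness `w` inserts the landmark edge
`{a, b}` at `max(d(a,w), d(b,w)) − m(w)`, clipped at 0; in addition
every landmark pair witnesses its own edge at `d(a, b)`.  Higher
simplices fill in as soon as all their edges are present (lazy/flag
rule), and reduction proceeds exactly as for Rips.  The
landmark-self-witnessing term is this package's definition choice: it
bounds every edge's entry time by the plain Rips value, so with
landmarks = all points the construction degenerates *exactly* to
Vietoris–Rips for every ν — the correctness anchor the tests exploit —
while with sparse landmarks the witnesses dominate and the complex is
the usual sparse approximation.  Under the witness-only variant the
degeneracy holds in dimension 0 (any witness shortcut edge is subsumed
by the two direct edges through its witness) but not above it.

**Default homology caps.** max_dim = 2 at sample level and 3 at gene
level (both configurable).  χ always uses dimensions 0–2 even when
dimension-3 cycles are computed; those are still reported per
dimension.

## Invariants

SL_k, SBT_k, SDT_k per dimension over finite pairs, χ = SL₀ − SL₁ +
SL₂.  Accumulation is plain double precision in the diagram's canonical
(dim, birth, death) sort order, for bit-reproducibility.

## Permutation inference

D = invariant(case) − invariant(control); the case group defaults to
the second label in metadata order (the synthetic generator emits
controls first) and can be overridden.  Each permutation redraws a
uniformly random equal re-partition of the pooled samples — partitions,
not sign flips, matching a relabelling of samples — and recomputes both
groups' dissimilarities, landmark selections (with per-permutation
seeds derived from the master seed) and persistence from scratch.
"More extreme" defaults to the two-sided rule |D_perm| ≥ |D_obs|, which
is symmetric and conservative where the direction is not prespecified;
`sided="greater"` is available.  The reported quantity is called a
permutation FDR for continuity with the analysis this implements,
though it is an empirical permutation p-value; with n_perm = 99 and no
+1 correction, rejecting at FDR ≤ 0.05 has exact nominal level 0.05
for a continuous statistic.  Equal group sizes are enforced as an
error: dimension-0 topology scales with the number of points, so
unequal groups make D meaningless.

**Gene-set scan.** Sets are first filtered to those with at least half
their genes expressed (present in the matrix) and intersected with the
expressed universe; sets below 3 expressed genes are skipped with a
warning.  Per set, observed D on the sample cloud restricted to the
set's genes is compared against `n_random` (default 100) equal-size
gene sets drawn uniformly without replacement from the full expressed
universe — draws do *not* exclude the tested set's genes (the
unrestricted choice; with realistic set-to-universe ratios the overlap
bias is negligible).  No correction across sets is applied beyond the
per-set resampling; reports include the number of sets tested.

## Mahalanobis / SSMD comparison analysis

MD(x) = √((x − x̄_c)ᵀ Ψ⁺ (x − x̄_c)) with x̄_c the control mean and Ψ⁺
the Moore–Penrose pseudoinverse of the control sample covariance
(denominator n − 1, the standard unbiased estimator).  The
pseudoinverse uses an SVD with singular values below
`rank_tolerance × s_max` zeroed (default `eps × dim`, the conventional
cutoff, exposed as a parameter); the quadratic form is clipped at 0
before the square root.  Genes ≫ samples is the intended regime — the
covariance is singular by construction and the rank is logged.  SSMD is
the sum of squared MDs over case samples, tested one-sided (null ≥
observed): a dispersion excess is directional.  Each permutation refits
the model on the permuted control half — the only choice that respects
the null, since the covariance estimate itself depends on the labels.
The transcriptome-wide *gene-level* MD analysis is intentionally not
provided (cost scales with a genes × genes covariance); gene-set and
sample-level modes cover the practical use.

## Synthetic data generator

The generator emulates a normalised log2 expression matrix with two
equal groups: gene baselines ~ Normal(8, 1); genes assigned round-robin
to `n_modules` modules whose per-sample latent factors (Normal(0, 1),
weight `module_strength`) induce the modular gene–gene correlation of
real transcriptomes; independent residuals ~ Normal(0, `noise_sd`),
multiplied by `heterogeneity` in the case group (all genes, or a
`floor(affected_fraction × n_genes)` subset in restricted mode).
Heterogeneity is *residual-scale inflation, not mean shift*: it
enlarges inter-sample distances within the case group while keeping
group means equal, so the topological signal is not confounded with
differential expression.  Defaults — 200 genes, 20 per group, 5
modules, strength 0.5, noise 0.5, heterogeneity 1 — are a desk-scale
analogue of a quantile-normalised microarray matrix; the test and
acceptance runs use 60 genes × 15 samples per group so that hundreds of
datasets × ~100 permutations complete in seconds.  Three seeded
sub-streams (gene layout, factors, noise) keep gene baselines fixed
when the sample count changes.

What the generator does **not** emulate: count noise and library-size
effects (values are already log-scale), batch structure, outlier
samples, heavy-tailed expression, covariate-driven heterogeneity.
Passing tests therefore demonstrate that the machinery detects
dispersion differences of the modelled kind with calibrated type-I
error — not that any particular real dataset will show them.

## Numerical and design notes

* Single master seed per run; all stage seeds derived via
  `SeedSequence` spawning, so sub-analyses reproduce in isolation and a
  full pipeline run is a pure function of (inputs, config, seed).
* Diagram TSV export encodes essential deaths as the literal `inf`.
* Expression TSVs are written with `repr` floats: read/write round
  trips are bit-exact.
* Known limitations: full Rips enumeration is exponential in
  `max_dim` and intended for dozens of points (the ceiling errors out
  early); `1 − r` non-metricity means witness shortcuts can create
  higher-dimensional features earlier than a metric intuition suggests;
  the permutation FDR is a p-value, not a false-discovery *rate* across
  sets.
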