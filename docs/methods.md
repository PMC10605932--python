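# Methods

## The analysis

`gmnet` implements a subject-wise gray-matter (GM) morphometric network
analysis. For each subject, the voxel-wise GM volume (GMV) values of 90
cortical and subcortical atlas regions are summarized as normalized 25-bin
histograms, and every region pair receives an edge weight equal to the
histogram intersection

    s_ij = sum_k min(h_i(k), h_j(k)) / sum_k h_i(k),        k = 1..25,

which is 1 for identical distributions and 0 for disjoint ones. Because both
histograms are normalized first, the denominator is 1 and the similarity is
symmetric, yielding a symmetric 90x90 matrix with unit diagonal.

Each matrix is binarized over a sparsity sweep s = 0.10, 0.12, ..., 0.60
(26 levels): at sparsity s the `floor(s * 4005)` largest off-diagonal entries
become edges. The lower bound guards against network fragmentation, the upper
bound against increasingly random topology. Because the ranking is computed
once and each level keeps a prefix of it, the sweep graphs are nested, and
ties at the cutoff are broken by ascending region-pair order so thresholding
is deterministic.

Per thresholded graph the package computes the clustering coefficient Cp
(per-node transitivity, 0 for degree < 2), characteristic path length Lp
(mean shortest-path length over *connected* pairs only), global efficiency
Eglob (mean inverse shortest-path length over all ordered pairs, 1/inf = 0),
local efficiency Eloc (mean over all nodes of the Eglob of the
neighbor-induced subgraph; degree <= 1 contributes 0), unnormalized nodal
betweenness centrality BC, and the small-world indices gamma = Cp /
mean(Cp_null), lambda = Lp / mean(Lp_null), sigma = gamma / lambda against
degree-preserving double-edge-swap null networks. Metric curves over the
sweep are summarized by the trapezoidal area under the curve (AUC) in
sparsity units, removing single-threshold arbitrariness.

Hubs are regions whose group-mean BC AUC is at least one standard deviation
(sample SD across the 90 regions) above the regional mean. Group inference
uses ANCOVA (group indicators + age, sex, education, total intracranial
volume) with an omnibus partial F-test and LSD pairwise contrasts of
adjusted means on the pooled error term; brain-cognition associations are
Pearson and covariate-partial correlations with Benjamini-Hochberg FDR
control within each group's (metric x score) family.

## The synthetic cohort generator

No subject-level imaging data are redistributable, so the pipeline is driven
by a generator that emulates the *statistical structure* the analysis
assumes, not MRI images.

Region r of subject s draws voxels from a Beta distribution scaled by the
subject's TIV. The Beta mean is `profile_r + loading_r * z_s[factor(r)] +
eta_sr`: a fixed smooth per-region gradient (0.28-0.72, shared by left/right
homologues), 5 shared latent factors loading on contiguous blocks of
homologue pairs (between-region correlation), and idiosyncratic noise.
Nearby-profile regions overlap strongly, so the thresholded networks are
clustered and lattice-like with latent-factor modularity — a small-world
regime (gamma > 1, sigma > 1 across the sweep), which the acceptance checks
verify rather than assume.

The patient effect ("homogenization", e in [0, 1], 0 for controls) has two
coordinated components, both scaled by e:

* **module tightening** — region means shrink toward their latent-module
  mean by a factor `1 - 0.95 e`. Within-module GMV distributions converge,
  local neighborhoods densify (higher Eloc and Cp).
* **long-range co-alteration** — `round(22 e)` four-region cliques per
  subject (members drawn brain-wide; consecutive cliques share a member)
  replace 55% of their voxels with draws from a shared cluster-level Beta.
  Distant pairs acquire high histogram overlap, forming shortcut edges that
  span the network (higher Eglob, lower Lp).

A uniform shrinkage of all region means toward the subject grand mean cannot
produce these contrasts: sparsity thresholding keeps a fixed number of the
*largest* similarities, so any order-preserving transformation of the
similarity matrix leaves every thresholded graph unchanged. The group effect
has to reorder pair similarities, which is what the two components above do.
Both strictly raise mean pairwise similarity, so the generator's
monotonicity contract (more homogenization, more similarity) holds.

Each subject's random stream derives from the design seed through
`SeedSequence(seed, spawn_key=(group, subject, stream))`, so cohorts are
bit-identical across runs and independent of generation order. Covariates
are group-independent by default (age ~ N(62.5, 8.3) clipped to 45-80 y,
education ~ N(12, 3.3) clipped at >= 7 y, TIV ~ N(1.59, 0.15), 48% female),
matching a design in which demographics show no group differences. Cognitive
scores are Gaussian with the configured per-group means/SDs; MoCA is capped
at its 30-point ceiling (which pulls the realized mean ~0.3 below the
configured one) and timed scores are kept positive. The SDMT score can be
coupled to the subject's measured global-efficiency AUC (standardized within
group) with a configured correlation, negative in the patient groups and
absent in controls; the coupling is applied after the metrics stage so it
refers to the efficiency actually measured by the pipeline.

### What the generator does not emulate

Realistic anatomy, spatial smoothing, lesion burden, scanner effects, or
registration error. Passing tests show the *pipeline* recovers the
structure the generator encodes at realistic sizes and noise levels; they do
not validate the biological claims on real MRI. One known infidelity: the
co-alteration mechanism also raises patient Cp, whereas the motivating
finding reported no group difference in Cp; Cp group tests on synthetic
cohorts therefore tend to reject.

## Numerical and design choices

* **Binning policy.** The histogram range is not determined by the edge
  definition itself. Default: per-pair 25 equal-width bins over the pooled
  min-max of the two regions ("pair-pooled"), matching the pairwise
  histogram-distance framing; "subject-global" (one shared range) is
  selectable. Bins are right-open with the last bin closed (numpy
  convention), so mass always sums to 1. No outlier trimming by default; a
  percentile trim is available behind a flag.
* **Edge count rounding.** `floor(s * N(N-1)/2)`; ties at the cutoff broken
  lexicographically by (i, j) for determinism.
* **Disconnection conventions.** Eglob/Eloc use 1/inf = 0; Lp averages over
  connected pairs only; any fragmented threshold is flagged per subject in
  the run outputs, because the sparsity floor exists precisely to avoid
  fragmentation.
* **Null model.** Degree-preserving double-edge swap, 10 attempted swaps
  per edge, implemented as vectorized batches: each batch pairs edge slots
  through a random permutation (so proposals are slot-disjoint), rejects
  proposals that would create self-loops, multi-edges or duplicate new
  edges, and applies the rest simultaneously. Seeded through a
  `numpy.random.Generator`. `small_world_indices` defaults to 100 nulls per
  graph, while the pipeline configuration defaults to 20 per graph to keep
  full-cohort runs tractable on one core; null Cp/Lp are evaluated by a
  dense numpy routine verified to match the public metric conventions
  exactly.
* **BC normalization.** Unnormalized (pair-count units), mirroring how
  nodal betweenness magnitudes are conventionally tabulated; a normalized
  variant can be obtained by dividing by (N-1)(N-2)/2.
* **AUC convention.** Trapezoidal rule in sparsity units over [0.10, 0.60];
  a constant curve v integrates to 0.5 v. Published AUC magnitudes from
  other toolboxes can differ by an internal scaling constant, so only
  orderings and group contrasts of AUCs are comparable across
  implementations, not absolute values.
* **Hub criterion.** Inclusive boundary (>= mean + 1 SD), group-level mean
  BC AUC vector, sample SD across regions (not across subjects; the choice
  is recorded in the hub report metadata). A zero-SD vector yields an empty
  hub set: hubs must be exceptional by definition.
* **LSD post hocs** are unadjusted pairwise contrasts on the pooled error
  term — that is the definition of LSD — and are reported as such.
  Chi-square tests are Pearson without continuity correction (the tables
  compared are mostly 3x2). ANCOVA drops zero-variance covariates, making
  it collapse exactly onto one-way ANOVA in the degenerate case; sex enters
  as a binary numeric indicator.
* **Correlations.** Both plain Pearson and covariate-partial correlations
  are computed and labeled, because group analyses in this literature report
  either depending on context; the FDR family is all (metric x score) pairs
  within one group and one correlation kind.
* **Graph backends.** Betweenness centrality and connected-component
  detection go through python-igraph's C routines; Cp, Lp and Eglob come
  from a dense numpy reachability closure (exact integer distances on binary
  graphs, accumulated in float64), and local efficiency applies the same
  closure over neighbor subgraphs (float32 matrix products for
  reachability, float64 accumulation of 1/d; nodes of similar degree are
  batched with stacked products). All five metrics are verified exactly
  against a brute-force matrix-power oracle on every connected graph with
  <= 7 nodes, and the conventions above are pinned by hand-worked examples.

## Problem sizes used in the checks

The acceptance checks run the full pipeline at sizes chosen to exercise the
study conditions while remaining single-core desk-scale: the small-world
verification uses 30 subjects per group with 20 nulls per graph and the
default voxel counts (200-2000 per region); the type-I calibration uses 200
replicate null cohorts of 20 subjects per group with 50-90 voxels per region
(calibration does not depend on histogram noise level); the directional
recovery uses 50 replicate cohorts of 20 subjects per group with 200-600
voxels per region, the noise level at which the default effect sizes were
designed. The full default cohort (49/121/74 subjects, 200-2000 voxels per
region) runs through `gmnet all` in a few minutes.

## Known limitations

* The generator's group effects are mechanistic stand-ins chosen to produce
  the target contrast directions; effect magnitudes are in designed units,
  not calibrated to any empirical effect size.
* Regional betweenness effects (pulling designated regions toward or away
  from the subject's mean GMV level) perturb nodal BC in the intended
  regions but interact with the module structure, so per-region effect
  sizes are approximate.
* The optional NIfTI path extracts region values from a labeled volume on a
  congruent voxel grid only; no resampling or registration is performed.
* Weighted-graph variants, alternative edge metrics (e.g. divergence-based
  similarity), modularity optimization and rich-club analysis are out of
  scope.
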