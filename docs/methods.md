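# Methods

`ecoassembly` implements the analysis chain commonly applied to soil
amplicon (16S/ITS) surveys of vegetation-restoration gradients: alpha and
beta diversity with group contrasts, null-model quantification of
community assembly processes, and random-matrix-theory (RMT) thresholded
co-occurrence networks with topological role classification.  This note
records the models, the parameters that matter, the numerical choices,
and what the synthetic test bed does and does not establish.

## Data model

The central object is a taxa × samples count matrix of amplicon sequence
variants (ASVs) with a sample → group map (`CommunityTable`).  Counts are
accepted as non-negative reals so rarefied or otherwise normalised tables
pass validation.  Phylogenies are rooted newick trees with branch
lengths; missing lengths are set to 0 with a warning rather than
rejected, because several common exporters omit them on some edges.
Group labels are free strings; a control group (conventionally `CK`) is
designated by configuration only.

## Alpha and beta diversity

* **Sobs** — count of taxa with abundance > 0.
* **Shannon** — H = −Σ pᵢ ln pᵢ in nats (a log2 switch exists).  Natural
  log is the default because typical reported values for soils
  (≈ 6.5–6.8 at ≈ 1100–1500 ASVs) are only consistent with nats.
* **Faith PD** — total branch length of the minimal subtree connecting
  the observed tips *and the root* (rooted PD, the default of the
  mainstream implementations).  Implemented as a union of root-to-tip
  edge sets so multifurcating trees are handled; it is cross-checked
  against scikit-bio on bifurcating trees.
* **Group contrasts** — one-way ANOVA, then Fisher's LSD at α = 0.05
  using the pooled error term, summarised as a compact letter display
  (insert-and-absorb algorithm; two groups share a letter iff their LSD
  p ≥ α).  Percent change versus the control is 100·(x̄ₜ − x̄꜀)/x̄꜀,
  rounded half-up to two decimals for reporting.
* **Bray–Curtis / PCoA** — BC(x,y) = 1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ) via
  scipy; PCoA is the classical Gower double-centering eigen-decomposition.
  Negative eigenvalues are excluded from the explained-variance
  denominator and their axes dropped; no Lingoes/Cailliez correction is
  applied.  The implementation is cross-checked against scikit-bio's.
* **Per-taxon contrasts** — Kruskal–Wallis H with midranks and tie
  correction; stars *, **, *** at p < 0.05, 0.01, 0.001; unadjusted by
  default (the convention for per-taxon relative-abundance panels), with
  optional Benjamini–Hochberg adjustment.  An exact enumeration mode
  exists for tiny samples.

## Assembly null models

For every within-group sample pair (C(8,2) = 28 pairs per 8-replicate
group by default):

* **βMNTD / βNTI.**  βMNTD is the abundance-weighted mean distance from
  each taxon to its nearest relative in the other community.  The null
  shuffles taxon labels across all tips of the tree (regional-pool
  randomization), implemented as one permutation of the cophenetic
  matrix per replicate, shared by all pairs — so results cannot depend
  on pair evaluation order.  βNTI is the standardized effect size over
  999 replicates (199 in the test profile; the floor is 99).
  |βNTI| > 2 is deterministic turnover (heterogeneous selection above,
  homogeneous below); the boundary |βNTI| = 2 is assigned to the
  stochastic side because the source inequalities are strict on both
  sides and leave it open.  A degenerate null (sd = 0, e.g. a star
  phylogeny, or two samples containing every taxon) yields βNTI = 0
  with a warning.
* **RCbray.**  Null communities preserve each sample's richness and
  total abundance; taxa are drawn without replacement with probability
  proportional to occurrence frequency across samples, then filled
  multinomially with probability proportional to pool-wide relative
  abundance.  RCbray is the tie-adjusted percentile (ties weighted 0.5)
  of the observed Bray–Curtis within the null distribution, rescaled to
  [−1, 1].  Each pair's RNG is seeded from (master seed, pair indices),
  again order-independent.
* **Classification.**  Given |βNTI| ≤ 2: RCbray > 0.95 → dispersal
  limitation, < −0.95 → homogenizing dispersal, otherwise drift.  The
  stochastic contribution rate of a group is the percentage of its pairs
  with |βNTI| < 2.

## RMT co-occurrence networks

Per group (8 samples): taxa present in more than half the samples are
kept (the usual pre-network majority filter; configurable), abundances
are log10(x+1) transformed (the pseudocount handles zeros), and pairwise
Spearman ρ with midranks forms the similarity matrix.  Constant taxa get
ρ = 0 with a warning.

The threshold is chosen by the RMT transition: for each candidate t
(default scan 0.30–0.95, step 0.01) entries with |ρ| < t are zeroed and
the nearest-neighbor spacing distribution (NNSD) of the remaining
matrix's eigenvalues is tested against the Poisson form e^(−s).
Unfolding uses a monotone PCHIP fit of the cumulative spectral density
through at most 15 knots after collapsing duplicate eigenvalues (1e-8
relative tolerance); the goodness-of-fit statistic is a chi-square over
20 equal-probability bins (dof = bins − 2).  The chosen threshold is the
smallest t with p ≥ 0.05 that stays Poisson-consistent at the next step
(one step of stability suppresses isolated spikes); if none qualifies
the scan falls back to 0.6 — the conventional fixed cutoff for such
networks — with an explicit flag.  Matrices left with fewer than 50
connected taxa at a candidate t are skipped as untestable.

Edges use |ρ| ≥ t (inclusive; the measure-zero difference from a strict
inequality is immaterial), signed by the sign of ρ; isolated taxa are
dropped; an edgeless result is an explicit error.  Modules come from
greedy modularity agglomeration (deterministic given node order).
Topology metrics: mean local clustering coefficient (avgCC), mean
shortest-path distance (APD; per-component with a warning when
disconnected), graph density GD = 2E/(N(N−1)), and Newman modularity Q
of the stored partition.  Node roles use the within-module degree
z-score Zi (population sd; singleton or zero-variance modules give
Zi = 0) and the participation coefficient Pi = 1 − Σ(k_is/k_i)², with
the standard thresholds Zi = 2.5 and Pi = 0.62; boundary equality counts
as the non-hub/non-connector side because the source inequalities are
strict.  Networks export to GraphML (with module, Zi, Pi, role, degree,
sign) and edge-list CSV for external viewers such as Gephi.

With n = 8 samples per group, Spearman correlations take few distinct
values and the per-group networks are coarse; the implementation warns
but proceeds, since that is the design it mirrors.

## Synthetic test bed

The generators emulate the study design — 5 groups × 8 replicates,
depth 20 000, hundreds of taxa — under regimes with known ground truth:

* **Phylogeny** — ultrametric pure-birth (Yule) trees, unit speciation
  rate, tips extended to the present.
* **Selection** — niche optima evolve along the tree by a stationary
  Ornstein–Uhlenbeck process (mean 0, variance 1, reversion rate 0.1 per
  unit branch length, i.e. strongly conserved); expected abundance in a
  group with environment e is ∝ exp(−(e − optimum)²·s).  The default
  strength s = 2 corresponds to a Gaussian niche of width 0.5
  environment units against optima of sd 1 and group environments spread
  over [−2, 2]: strong selection by construction.  s → 0 recovers the
  neutral (uniform-expectation) limit.
* **Neutral** — every sample is one multinomial draw from a shared
  log-normal (σ = 1.5) metacommunity.
* **Dispersal limitation** — each taxon has a home group and is
  accessible to foreign groups independently with the dispersal
  probability; within pools sampling is neutral.  Dispersal 1 reduces to
  the neutral regime; 0 gives disjoint pools.
* **Module-structured counts** — one latent factor per module; loadings
  use the Gaussian-copula inversion 2·sin(π·r/6) so latent Spearman
  equals the requested within-module correlation; counts are multinomial
  at fixed depth.  Closing samples to a fixed depth adds a compositional
  common mode: realized between-module correlations are negative rather
  than zero and within-module correlations sit somewhat below the latent
  target, increasingly so for few modules.  Tests therefore treat the
  calibration as statistical (averaged over seeds).

All generators are pure functions of (scenario, seed) and reproduce
bit-identically; every sample's counts sum exactly to the stated depth.

**What passing does and does not show.**  Recovery tests show the
pipeline separates selection-driven from neutral regimes and finds
planted correlation modules under the study's sample sizes.  The
generators omit sequencing error, chimeras, compositional biases of
extraction/PCR, spatial autocorrelation between replicate plots, and
taxon-specific copy-number variation, so passing them does not certify
behaviour on real reads.  When depth far exceeds richness, samples
saturate (all taxa shared) and βNTI rests on a few unshared rare taxa,
making its null heavy-tailed; occasional |βNTI| > 2 pairs in neutral
simulations are that artifact.

## Problem sizes and reproducibility

Default analysis/test sizes — 200 taxa, 8 samples per group, 199 null
replicates, 5 seeds for recovery rates, 10 seeds for threshold recovery,
50 trials for NNSD calibration — were chosen as the smallest designs at
which the recovery properties are stable statistics rather than
single-draw anecdotes.  All stochastic stages derive their streams from
one master seed (numpy `SeedSequence` with fixed tags), so reruns with
equal configuration produce byte-identical outputs.

## Known limitations

* RCbray's null fixes richness and depth but not taxon-specific
  detectability.
* The NNSD chi-square test needs ≥ 50 distinct eigenvalues; very small
  or very sparse per-group matrices fall back to the fixed 0.6 cutoff.
* The compact letter display is exact for the LSD procedure but, like
  all letter displays, can require multiple letters per group when
  significance is non-transitive.
* BIOM input is not implemented (no biom parser dependency); TSV is the
  supported interchange format.
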