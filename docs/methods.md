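# Methods

`dilasm` re-implements, as a tested pipeline, the statistical core of a
dilution-to-extinction soil microcosm study: communities from two source
soils are serially diluted (10⁻¹, 10⁻⁴, 10⁻⁷, 10⁻¹⁰), inoculated into
sterile soil adjusted to five pH levels (4.5–8.5), regrown for weeks, and
sequenced. The analysis asks how the loss of rare taxa changes (i) community
composition, (ii) the balance of stochastic vs. deterministic assembly, and
(iii) the functional repertoire of the community. Because the package is
validated without any sequencing downloads, it ships a synthetic-experiment
generator whose statistical structure matches what the analysis assumes.

## The analysis

**Diversity.** OTU tables are rarefied to a common depth (one multivariate-
hypergeometric draw per sample, seed recorded; the study's depth of 11,020
reads is the default). α-diversity is the Shannon index in nats (natural
log, base configurable). Taxonomic β-diversity is Bray–Curtis on column-
normalized relative abundances; phylogenetic β-diversity is abundance-
weighted UniFrac, computed from a branch × tip incidence matrix as
Σ_b ℓ_b·|p_A(b) − p_B(b)|, optionally divided by the abundance-weighted
tip-depth sum so values lie in [0, 1] (the normalized form is the default
report). Ordination is non-metric MDS minimizing Kruskal stress-1 by
SMACOF majorization alternating with isotonic regression of configuration
distances on the observed dissimilarities. Ties share one fitted disparity
(the secondary approach); each start stops when stress improves by < 1e-7
or would increase, and the best of 50 random starts is returned.

**Assembly inference.** The observed statistic per sample pair is the
abundance-weighted between-community mean nearest taxon distance (βMNTD):
0.5·[Σᵢ xᵢ·minⱼ d(i,j) + Σⱼ yⱼ·minᵢ d(j,i)] on patristic distances, with
taxa shared by both communities contributing zero. The null model shuffles
taxon labels across the *full* patristic matrix of every taxon present in
the table (the "taxa.labels" scheme), with 999 permutations by default; one
permutation set is shared across all pairs of a run so pairwise z-scores
are comparable and the run is reproducible from one seed. βNTI is the
z-score of the observation; βNTI > +2 is read as variable selection,
< −2 as homogeneous selection, |βNTI| ≤ 2 (boundary inclusive) as
stochastic assembly. When the null SD is numerically zero (e.g. identical
membership, star phylogenies) βNTI is undefined and flagged. For the
diversity–assembly relationship each pair's |βNTI| is matched to the mean
Shannon index of its two samples; for the function–assembly grid |βNTI| is
propagated to samples as the median of the within-treatment pairwise
values. Within-treatment summaries exclude same-microcosm subsample pairs
(pseudo-replicates) by default.

**Multivariate statistics.** PERMANOVA computes the pseudo-F from squared
distances (single factor) or from the Gower-centered inner-product matrix
with a hat matrix (design-matrix form); p-values come from free label
permutation, with an exact enumeration mode for small n. The partial
Mantel test residualizes (rank-transformed) off-diagonal vectors against
the control matrix and permutes the first matrix's rows and columns
jointly. Variation partitioning is distance-based redundancy analysis:
principal coordinates of the distance matrix (negative-eigenvalue axes
dropped and counted) regressed on each of the seven combinations of the
ST / pH / CONC blocks; unique and shared Venn fractions follow by solving
the inclusion–exclusion system, so unadjusted fractions plus residual sum
to one exactly. The pH block enters as factor dummies because the
community response to pH is unimodal — a single linear pH column misses
most of the signal. BIOENV searches all covariate subsets exhaustively
(≤ 15) for the Euclidean covariate distance best rank-correlated with the
community distance, ties to the smaller subset. Group comparisons use
Tukey's HSD (studentized range); each pairwise distance is treated as one
observation, a convention inherited from the boxplot-style comparisons it
feeds, and acknowledged as ignoring pairwise non-independence.

**Functional analysis.** FG_RA is a category's share of a sample's reads;
FG_Div its detected-gene richness (reads ≥ 1 by default). Per-gene dilution
trends are Spearman correlations of within-sample relative abundance
against lg(dilution), two-sided, with Benjamini–Hochberg FDR by default.
IndVal uses the group-equalized statistic √(A·B) — specificity A is the
combination's group-equalized mean abundance over the summed base-group
means, fidelity B the occurrence fraction — with multipatt-style group
combinations (the trivial all-groups union excluded) and significance by
permuting sample group labels against the permuted best statistic. A
perfect indicator scores exactly 1.0; note the permutation p can only
reach 1/(n_perm+1) when no permuted grouping happens to reproduce a
perfect indicator, which is why calibration fixtures use six groups of
six samples.

## The generator

One pure-birth (Yule) ultrametric phylogeny underlies both soils; pools
are subsets of its tips, which is what makes cross-soil UniFrac possible.
Design choices, each with its default and rationale:

- **pH optima** evolve along the tree with Brownian increments whose rate
  decays toward the present (early burst, `bm_rate = 3.6`,
  `trait_rate_decay = 0.6`, root 6.5): trait divergence concentrates on
  deep branches, so pH guilds coincide with clades. Under time-homogeneous
  Brownian motion the clumpiness of a trait tail varies wildly between
  realizations and βNTI regime recovery is unstable; the early-burst
  variant makes "acid clade" / "alkaline clade" structure a reproducible
  property rather than a lucky draw. (`assign_ph_optima` with
  `rate_decay = 0` remains plain Brownian motion, and its variance contract
  Var(Δtrait) = rate × patristic distance is tested in that mode.)
- **Pools** (1200 taxa per soil on a 2000-tip tree, overlap 0.5): a
  soil-affinity trait (early-burst on the same tree) ranks tips; each
  soil's exclusive members come from opposite ends of the ranking, shared
  members from the middle. Endemics therefore form clades — without this,
  the two soils' endemic sets interleave phylogenetically and weighted
  UniFrac barely distinguishes soils. Exclusive members' abundances are
  scaled by `pool_exclusive_rarity = 0.05` (cosmopolitan taxa abundant,
  endemics rare), which is what makes the soil-type signal erode along the
  dilution gradient.
- **Inoculum densities** are lognormal(μ = 17.8, σ = 5 on the natural-log
  scale, arbitrary cells per unit volume; free parameters, not estimates
  of the study). With the inoculum volume factor of 100 the four dilution
  levels then retain roughly 100 / 95 / 85 / 45 % of a pool in
  expectation, so every level loses taxa, survival near the threshold is
  genuinely stochastic (replicates differ in membership — the raw material
  of the null-model analysis), and the most diluted communities remain
  large enough for βNTI to have power.
- **Dilution** is per-taxon Poisson sampling of the suspension; taxa
  drawing zero cells are extinct. Rare taxa are lost first by construction.
- **Regrowth** compresses surviving cell counts (`count^0.15`) — sixteen
  weeks at carrying capacity largely erases initial-density differences —
  and multiplies by a per-taxon, per-microcosm lognormal founder/drift
  factor (`growth_noise_sd = 0.8`), the demographic stochasticity that
  differentiates replicate microcosms.
- **Selection** is a Gaussian pH kernel (niche breadth 0.5 pH units)
  raised to an effective exponent that grows with dilution:
  `strength × (0.02 + 0.98·(lg_dil/10)^1.5)` with `strength = 6`.
  Rationale: regrowth from a 10⁻ᵈ inoculum takes ~d·log₂10 more
  generations and fitness compounds per generation. This single mechanism
  produces the study's central gradient — near-neutral composition at low
  dilution, strongly selected composition at high dilution — and with it
  the rising |βNTI| and rising pH fraction of explained variance.
- **Micro-environmental heterogeneity**: each microcosm draws one
  effective pH from Normal(target, microsite_sd), with microsite_sd a
  Gaussian bump in target pH (0.45 at pH 6.5 shrinking to 0.05 at the
  extremes). Large heterogeneity at neutral pH sends replicate microcosms
  toward different clades (variable selection, βNTI > 2); uniform strong
  filtering at extreme pH pulls them together (homogeneous selection,
  βNTI < −2). Truth labels follow this rule (`neutral` when selection is
  off, `variable` when microsite_sd ≥ 0.3, else `homogeneous`).
- **Gene content**: five specialized categories each live on one random
  monophyletic clade of ~5 % of tips; their members' inoculum abundances
  are scaled by 0.02 (specialized functions ride on rare taxa) and each
  carrier contributes a read weight of 5 (specialized pathways recruit
  more distinct mappable variants per genome), so the specialized share
  starts high and collapses as dilution removes the clades. Five broad
  categories scatter each gene over an independent random ~30 % of all
  tips, with per-gene host-range jitter; broad genes are lost only
  gradually, so their FG_Div declines with a smaller amplitude. Gene
  tables are multinomial draws (10,000 reads) from carrier-abundance-
  proportional gene shares.
- **Covariates** Ca/Fe/SO₄ are deterministic functions of target pH (CaO
  raises pH, FeSO₄ lowers it) plus small noise — they exist so the VPA has
  a CONC block with near-zero unique contribution by construction.
- **Seeding**: one master seed; `numpy.random.SeedSequence` children are
  spawned in a fixed order (tree, traits, pools, genes, covariates, then
  one child per microcosm, with sub-children for dilution, incubation,
  founder noise, and each subsample's reads), so every stage is
  independently reproducible and the whole experiment is bit-for-bit
  deterministic.

## What the generator does and does not emulate

It reproduces the *statistical* structure the analysis consumes: factorial
design arithmetic, richness and evenness gradients along dilution,
phylogenetically conserved pH filtering, replicate-level founder
stochasticity, partial pool overlap with clade-structured endemism, and
clade-bound vs. scattered gene content. It does not simulate sequences,
chimeras, OTU clustering, compositional artifacts of real library
preparation, soil chemistry dynamics, or interaction networks; passing
tests therefore demonstrate that the *pipeline* recovers planted structure
at desk scale, not that real soils behave like the generator.

## Problem sizes and numerical choices

Validation runs use desk-scale sizes chosen once: 2000-tip trees with
1500-taxon pools for regime recovery (supports of ~100–250 taxa per
sample; smaller pools cap |βNTI| well below 2 because the null SD of the
nearest-taxon statistic grows as supports shrink), 1600/800+800 for the
two-soil gradient analyses (rarefaction to 6000 reads), 500-tip even pools
at 600 reads for z-score calibration, and 999 null permutations where the
z-scores are the quantity of interest (199 or 99 where only medians or
signs are consumed). The βNTI null loop is chunk-vectorized over
permutations (≤ 4M matrix elements per chunk). The weighted βMNTD z-score
carries a small positive skew bias at very high sample-pair overlap
(shared taxa are inert under the joint tip shuffle); calibration fixtures
therefore use sampling depths that leave meaningful membership turnover
between samples. Variance-partitioning fractions are unadjusted R²;
negative adjusted fractions are not clipped. The pH fraction of explained
variance rises from 10⁻¹ through 10⁻⁷ and saturates at 10⁻¹⁰, where
founder effects add residual variance — the trend tests compare endpoint
medians and rank trends rather than asserting strict monotonicity at the
deepest level.

## Known limitations

- βNTI power depends on pool size and community evenness; at supports
  below ~50 taxa the statistic is shrunk toward zero and regime recovery
  degrades. This matches the method's behavior on real data with very
  shallow communities.
- The permutation p-value of a perfect indicator gene is exactly
  1/(n_perm+1) only while no label permutation reproduces the indicator;
  with few, small groups collisions are likely.
- Tukey HSD on pairwise-distance sets inherits the non-independence of
  distances sharing a sample; its p-values are descriptive, as in the
  boxplot comparisons it mirrors.
- The one-draw rarefaction is reproducible but adds sampling noise to
  every downstream statistic; a repeated-mean mode is available
  (`rarefy` with averaged draws left to the caller via seeds).
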