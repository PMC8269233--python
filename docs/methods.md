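# Methods

This document states the model behind each analysis stage, the numerical
conventions, the simulator's parameter defaults with their rationale, and the
known limitations. Nothing here asserts empirical results beyond what the
test suite and `scripts/acceptance.py` compute.

## Data model

A dataset is a `FeatureTable`: a samples × ASVs matrix of non-negative
integer read counts plus per-sample metadata with the factors
`compartment` (seed / soil / root / stem), `soil`, `genotype`, `year`,
`stage` and `replicate`, and optionally a taxonomy table and a newick
phylogeny. Validation is strict: duplicate ids, negative or non-integer
counts, samples missing from metadata, and unknown factor levels are hard
errors; metadata rows for unobserved samples are dropped with a logged
warning.

All randomness in the package derives from a single integer seed through
named streams: `rng_stream(seed, name)` builds a `numpy` generator from
`SeedSequence([seed, crc32(name)])`, so stages are reproducible
independently of each other and of call order, and every derived seed word
fits in 32 bits.

## Detection and origin assignment

Presence/absence is decided on **non-rarefied** counts: an ASV is present in
a sample group when it has at least `min_count` reads (default 1) in at
least `min_reps` samples (default 1) of the group. Rationale: detection asks
"was the taxon observed at all", so discarding reads by rarefying would only
add false absences; depth effects are instead acknowledged as a detection
bias (see Limitations).

Each seedling ASV is assigned exactly one origin by set algebra against the
sown seed lot's presence set and the pot soil's presence set: `both`,
`seed_only`, `soil_only`, or `unknown` (neither source). Aggregates
`soil_detected = soil_only + both` and `seed_detected = seed_only + both`
are reported alongside. Membership fractions divide by the seedling set
size; abundance fractions weight each ASV by its zero-inclusive mean
relative abundance in the seedling context (each sample normalised to 1,
then averaged with zeros kept, so the fractions are comparable across
contexts with different replicate counts).

Transmission success of a source pool is
`100 · |source ∩ seedling| / |source|`, computed per replicate and
summarised as mean ± SE (sample standard deviation with ddof = 1 over
√n), with the replicate-pooled union percentage reported alongside.
Abundance classes on mean relative abundance: rare < 1e-4,
abundant > 1e-2, boundaries inclusive to intermediate — so every ASV has
exactly one class and the two cut points are never ambiguous. Class-wise
transmission rates are undefined (reported as missing, never 0) for classes
with no source members.

## Diversity

Rarefaction subsamples each sample to a fixed depth **without replacement**
(`multivariate_hypergeometric`), the exact model of drawing reads from a
finite library; samples below the depth are dropped with a log message.
Chao1 uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, defined
for all inputs including F2 = 0. Faith's PD sums the branch lengths of the
union of tip-to-root paths of the present taxa; the stem to the root is
included by default (`include_root=True`), with the root-exclusive variant
(subtracting the MRCA-to-root path) available because both conventions
exist in the field. Group comparisons use one-way/sequential ANOVA, Welch's
t, or the Mann-Whitney rank-sum test.

## Community structure

Counts are transformed as log10(x+1) before Bray–Curtis, compressing the
dynamic range so abundant taxa do not dominate the dissimilarity. PCoA is
the eigendecomposition of the Gower-centered matrix −½ J D² J; negative
eigenvalues (possible because Bray–Curtis is non-Euclidean) are reported
signed, not corrected. Dispersion (betadisper) measures each sample's
distance to its group centroid in the full PCoA space, subtracting the
imaginary-axis contribution and clipping at zero; exactly two groups are
compared with a two-sided rank-sum test.

PERMANOVA is sequential (type-I, ordered terms, as in vegan's
`adonis2(..., by = "terms")`): each term's sum of squares is the increment
in explained trace from a progressively orthogonalised model matrix, with
factors coded as full one-hot blocks so that an interaction listed without
its main effects spans the full cell-means space. Per-term R² sums to 1
with the residual. p-values permute the distance matrix rows freely, with
the conservative tie rule `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, so
the smallest attainable p is `1/(1+n_perm)`. A consequence worth noting:
when permutations can exactly reproduce the observed partition (likely for
small balanced groups, probability `2·(n/2)!²/n!` per draw for two equal
groups), ties inflate p above the theoretical minimum — that is correct
behaviour of the ≥ rule, not an implementation artifact.

## Simulator

`generate_dataset` emulates a seed × soil transplant experiment:

1. **Source pools.** Lognormal species-abundance distributions
   (`sigma_pool = 1.5`, a typical soil SAD breadth) for one high-diversity
   soil (S1, 800 taxa) and four seed lots drawn from a 400-taxon seed
   metacommunity (100 taxa for year-1 lots, 250 for year-2), each sharing
   `seed_soil_overlap = 10` taxa with the soil. The low-diversity soil
   (S2) is produced from S1 by dilution-to-extinction: survivor counts are
   Poisson(inoculum · abundance · 10^−d) with `d = 6`, survivors
   renormalised ("regrowth to fixed biomass"); the inoculum is calibrated
   by bisection so the expected surviving richness equals the configured
   500.
2. **Seedling assembly.** Each source taxon transmits independently with a
   probability keyed by (source, compartment, abundance class of its true
   pool abundance). Defaults: soil → root 0.95 / 0.40 / 0.28 and
   soil → stem 0.86 / 0.40 / 0.29 for abundant / intermediate / rare, and
   seed → seedling 0.015 / 0.03 / 0.10 — weak overall and favouring rare
   taxa, the qualitative pattern the package is designed to detect. A
   transmitted taxon's seedling abundance blends its source abundance with
   a fresh lognormal draw in log space,
   `w = exp(ρ·ln(source) + (1−ρ)·N(0, σ_seedling))` with `ρ = 0.2`
   (assembly largely decouples seedling rank from source rank) and
   `σ_seedling = 1.0` (narrower than the source SAD: assembly into a
   constrained niche). An external pool of 300 unknown-origin taxa joins
   each seedling context with per-taxon inclusion probability 0.5 and a
   fixed community share of 0.2.
3. **Reads.** One composition is drawn per
   (soil, lot, stage, compartment) context; the three replicates differ
   only through multinomial read sampling at depth 30,000 (sources) or
   1,000 (seedlings). Everything is deterministic given the configuration
   seed.

The generator returns a `SimTruth` with every pool composition and the
exact per-context lists of truly transmitted taxa per channel, enabling
parameter-recovery tests without touching the estimators.

What the simulator does **not** emulate: taxonomic identity (no taxonomy or
phylogeny is generated), replicate-level biological variation (replicates
share one composition), PCR/chimera artifacts, compositional correlations
between taxa, temporal dynamics beyond the two discrete stages, and fungal
communities.

## Problem sizes and numerical choices

- Default depths 30,000 (sources) and 1,000 (seedlings); default 3
  replicates; factorial design 2 soils × 2 genotypes × 2 years × 2 stages
  × 2 seedling compartments — 96 seedling samples plus 18 source samples.
- Orthogonalisation tolerance 1e-9 (relative) for PERMANOVA model columns;
  PCoA eigenvalue threshold 1e-10 relative to the spectral radius;
  betadisper squared distances clipped at 0 after the imaginary
  correction.
- Result TSVs are written with `%.10g` floats so reruns are byte-identical.

## Limitations

- Class-wise transmission rates estimated from reads measure
  P(transmitted **and** detected). At seedling depth 1,000 × 3 replicates a
  small fraction of truly transmitted taxa falls below detection, and taxa
  near the 1e-4 class boundary can be classified from observed source
  profiles into a neighbouring class; both effects bias estimated rates
  slightly downward (on the order of one to a few percentage points of the
  true probability for non-abundant classes). This is a property of
  read-level estimation at realistic depth, not of the set algebra.
- The sequential PERMANOVA tests all terms with freely permuted rows; no
  restricted permutation schemes (strata) are implemented.
- Bray–Curtis between two all-zero samples is defined as 0 with a warning;
  it cannot occur after rarefaction.
- betadisper compares exactly two groups; multi-group designs require
  pairwise calls.
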