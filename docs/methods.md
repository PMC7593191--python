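# Methods

This note documents the statistical machinery in `bcpg`, the assumptions
behind it, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Estimators

### Jost's D (pairwise)

For each population pair and locus we use the unbiased two-deme estimator:
subpopulation heterozygosity `H_S` is corrected by `2ñ/(2ñ−1)` with `ñ`
the harmonic mean of the two per-locus sample sizes (individuals), and the
total-heterozygosity correction adds `Ĥ_S/(4ñ)`.  The bias correction can
push D slightly below zero for identical frequency distributions (for
p = (0.5, 0.5) and n = 10 per deme, D = −1/18); we deliberately do not
clamp, so averages over loci stay unbiased, and the d/(1−d) linearization
tolerates small negatives.  The multi-locus value is the arithmetic mean
over usable loci; a harmonic-mean option exists (`averaging="harmonic"`)
because tools in circulation disagree, but harmonic averaging is undefined
whenever a per-locus D is non-positive, in which case the pair falls back
to arithmetic with a warning.  Loci with no typed individual in either
member of a pair, or with `Ĥ_S = 1`, are skipped pairwise; a pair with no
usable locus at all is an error rather than a silent NaN.

### AMOVA

The three-level analysis treats each gene (two per typed individual per
locus) as a unit with 0/1 allele-identity distance.  For a stratum the sum
of squared deviations over n genes reduces to a count identity,
`SS = (n − Σ_a c_a²/n)/2` with `c_a` the allele counts, which is what makes
the permutation tests cheap.  SS and degrees of freedom are summed across
loci; the unequal-sample-size EMS coefficients (n′, n″, n‴) are pooled by
summing their per-locus numerators and dividing by the summed stratum df —
with complete typing this is exactly the single-locus textbook formula,
and with per-locus missingness it down-weights thin loci in proportion to
the information they carry.  Negative variance components are reported raw
so the three percentages always add to 100; a truncation option is not
provided because truncation silently breaks additivity.

The lowest stratum is "within populations" (gene-level AMOVA without a
within-individual stratum), so exactly three components are reported.
Permutation nulls follow the conventional strata: genes among all
populations for Φ_ST, genes among populations within their group for
Φ_SC, and whole populations among groups for Φ_CT, with
`p = (hits + 1)/(n_perm + 1)`.  With the default 1,000 permutations the
achievable floor is ≈ 0.001; the reported p never goes below the floor.
Monomorphic data yield zero total variance and an explicit "undefined"
flag instead of a Φ value.  Multilingual sites are grouped by the phylum
of their alphabetically first language — a deterministic rule chosen
because no principled primary-language marker exists in the data model;
sensitivity to it can be probed by editing the grouping mapping directly.

### Pairwise Φ_ST and migrants

Cluster-pair F_ST is the two-level specialization of the same AMOVA
(among-unit / within-unit on allele identity, loci pooled by summing SS
and df).  Migrant numbers use the finite-island closed form
`M = (1 − F_ST)/(2 F_ST)`; published "2Nm" values differ by a ploidy
constant depending on the computing tool, so a multiplier is exposed
(default 1).  Non-positive F_ST flags M as undefined rather than emitting
an infinity.

### Rarefied allelic richness

`Rs = Σ_a [1 − C(N−N_a, g)/C(N, g)]` is the expected number of distinct
alleles in g genes drawn without replacement.  Combinatorials are computed
with log-gamma and match exact big-integer ratios to 1e-10 for N ≤ 30
(tested).  The rarefaction base g defaults to the minimum typed gene count
over all populations and loci; a locus where any population falls below g
is dropped *for all* populations so every comparison shares one base —
dropping, not imputing, because imputation would manufacture alleles.

### Distance predictors

The linguistic index scores a language pair by the deepest shared level of
the 4-level classification.  Two open points were closed as follows:
languages attached directly at the family level (null subgroup) never
match at the subgroup level, so two such languages score 2 — the subgroup
tier is simply collapsed for them; and multilingual sites aggregate by
the *minimum* over cross-site language pairs (a shared language is a
communication channel), with `max` and `mean` available as sensitivity
options.  Geographic distance is the haversine great-circle on a
6371 km sphere — "straight-line km" at continental scale can only mean
arc length, and planar Euclidean on raw lat/lon would be dimensionally
meaningless.  The log transform floors distances at 1 km so co-located
sites do not produce −∞; diagonals never enter any regression.

IDW interpolation uses the GIS-conventional defaults p = 2 over the k = 12
nearest sites, takes a site's exact value within 1e-6 km, and is a convex
combination, so the surface is bounded by the input range (asserted
per-cell in tests).

### Matrix permutation tests

Mantel statistics correlate strict lower-triangle vectors.  The null
jointly permutes rows and columns of the first matrix; for the partial
test we permute the raw first matrix and recompute the first-order partial
correlation each time (the classic permute-raw scheme), not residual
permutation — the raw scheme is what the established toolchain uses, and
the known type-I inflation under strong spatial autocorrelation is exactly
why the MRM route is also reported.  When `n! ≤ n_perm` the tests switch
automatically to exact enumeration over all n! relabelings and report the
exact permutation p.  Sampled p-values use `(hits + 1)/(n_perm + 1)`, so
with 5,000 permutations no p can fall below 1/5001 ≈ 0.0002.  Upper-tail
p is the default because every working hypothesis here is directional.

MRM regresses the response triangle on predictor triangles with an
intercept; standardized betas come from z-scored vectors and are invariant
to affine predictor rescaling.  Coefficient p-values are two-sided on |b|
under response permutation; the model R² p is upper-tailed.  Predictor
condition numbers above 1e10 abort with a collinearity error.

Rank tests use the tie-corrected Kruskal–Wallis H (scipy) and a
hand-implemented Dunn post hoc,
`z_ij = (R̄_i − R̄_j)/√((N(N+1)/12 − T)(1/n_i + 1/n_j))` with tie term
`T = Σ(t³−t)/(12(N−1))`, unadjusted by default (Bonferroni and
Benjamini–Hochberg available).  When every value is identical the test
degenerates to H = 0, p = 1 by convention.

### Networks and cognate overlays

The population network is a true minimum spanning tree (Kruskal on edges
pre-sorted by weight then lexicographic label pair, so equal weights give
a deterministic tree).  Assortativity is the fraction of MST edges joining
same-phylum nodes, tested by permuting phylum labels over the fixed tree.

Cognate × cluster tables keep admixed categories (`admixed(a×b)`, the two
largest membership coefficients when no coefficient reaches the threshold)
as separate rows.  Two χ² formulations are always reported side by side:
a goodness-of-fit against prior presence probability ½ per cluster
(`Σ_r (O_r − n_r/2)²/(n_r/2)`, df = R−1) and a presence/absence ×
cluster independence test — published tables of this kind are ambiguous
about which was used, and no formulation we derived reproduces every
printed statistic, so the package shows both and the tests assert our
formulas only.  The admixture threshold defaults to 0.7; it is a free
parameter of the overlay, not an estimate.

## Synthetic data generator

The generator emulates a continental SSR sampling design: by default 91
populations of 20 diploid individuals at 14 loci with 10 alleles each,
spread over five language phyla (2 families per phylum, 2 languages per
family, ~8% of sites bilingual across a phylum boundary) on a
Eurasia-scale map (25–55°N, −10–110°E).  Phylum territories are Voronoi
cells of uniform seeds under great-circle distance; populations are split
evenly across phyla and placed uniformly within their territory.

Frequencies drift in two Balding–Nichols steps — Dirichlet with
concentration `(1−F)/F · base` — first phylum pools from a symmetric
Dirichlet(1) ancestral (F_phylum, default 0.05), then populations from
their phylum pool (F_pop, default 0.05).  Balding–Nichols was chosen
because it gives an analytic drift anchor: tests verify that within-phylum
population frequencies are statistically indistinguishable from a
single-level Balding–Nichols oracle simulation at the same F.  Isolation
by distance is injected afterwards as a Gaussian-kernel random field
(correlation length `ibd_range`, default 1,500 km) added on the logit
scale and renormalized; the field standard deviation (`ibd_strength`,
default 0.75) was set so that the simulated Mantel correlation between
genetic and geographic distance lands in the strong-IBD regime reported
for real continental SSR datasets (r ≈ 0.5–0.7).  This construction is
simpler than a stepping-stone model and suffices for Mantel-detectable
IBD, which is all the downstream tests require.  Genotypes are drawn under
Hardy–Weinberg within populations; calls are masked missing at 2% by
default.  Cognate sets are anchored one per phylum; a site carries a set
with probability `(1−leakage)·[member] + leakage/2`, so leakage 0 gives
perfect phylum alignment and leakage 1 a uniform coin flip (independence
χ² averaging its df).  All stages draw from per-stage seed streams, so a
bundle is byte-reproducible from its seed and stages can be re-run in
isolation.

**What the generator does not emulate:** mutation processes (stepwise or
otherwise), coalescent genealogies, selection, uneven sampling density,
genotyping artifacts beyond uniform missingness, linguistic borrowing
gradients, or real geography (coastlines, mountain barriers).  Passing
recovery tests therefore show that the estimators detect and quantify the
*kind* of structure the field model produces — hierarchical drift plus
spatially autocorrelated divergence plus culture-aligned overlays — not
that any particular real dataset will show those effect sizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default design
(91 × 20 × 14) for single analyses, 999 permutations inside the 20-seed
power and 50-seed type-I loops, and down-scaled designs (18–24 populations,
6–8 loci) for multi-seed recovery sweeps — sizes chosen so the whole suite
documents its claims in well under a minute while keeping the headline
runs at the realistic design.  Exact enumeration replaces sampling in the
Mantel tests whenever n! does not exceed the requested permutation count.
Permutation hit-counting uses a 1e-12 tolerance so ties at the observed
statistic are counted as hits on both sides of floating-point noise.
Degenerate inputs are flagged, not fudged: monomorphic AMOVA and
non-positive F_ST return explicit undefined markers, constant matrices
abort Mantel tests, and zero-variance rank tests return H = 0, p = 1.

## Known limitations

- The partial Mantel raw-permutation scheme inherits the documented type-I
  inflation under strong spatial autocorrelation; MRM output should be
  read alongside it (both are produced by `run_association`).
- Multi-locus EMS coefficient pooling is df-weighted rather than solved
  per locus; for heavily locus-specific missingness patterns per-locus
  AMOVA (available as the building block `_locus_terms`) is the safer
  cross-check.
- The island-model migrant number assumes equilibrium, equal-sized demes
  and one ploidy convention; it is an order-of-magnitude summary, hence
  the exposed multiplier.
- R_ST-type (stepwise-mutation) statistics, HWE tests, and Bayesian
  cluster inference are out of scope; cluster memberships are consumed as
  given.
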