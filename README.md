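# bcpg — biocultural population genetics of tree crops

`bcpg` asks a landscape-genetics question with a cultural twist: when tree
populations are genetically structured across a continent, how much of that
structure follows plain geography (isolation by distance) and how much
follows the *human* landscape — the boundaries between language communities
that traded, gifted, and carried seed for millennia?  It was built for
population geneticists and ethnobotanists working with codominant
microsatellite (SSR) data sampled across many sites, each annotated with
coordinates, the languages spoken there, and the local word forms for the
crop.

## What it computes

**Genetic differentiation.** Pairwise Jost's D between populations, per
locus for a pair of demes (k = 2):

    H_S = 1 − ½ Σ_a (p²_1a + p²_2a)          Ĥ_S = 2ñ/(2ñ−1) · H_S
    H_T = 1 − Σ_a ((p_1a + p_2a)/2)²          Ĥ_T = H_T + Ĥ_S/(4ñ)
    D   = 2 (Ĥ_T − Ĥ_S) / (1 − Ĥ_S)

with ñ the harmonic mean sample size, averaged over loci.  D = 0 under
panmixia, D = 1 when no alleles are shared.

**Explanatory distances.** d_GEO: great-circle km (log-transformed for
regressions); d_LAN: a 0–4 hierarchy distance between speech communities
(0 same language, 1 same subgroup, 2 same family, 3 same phylum,
4 different phyla).

**Inference.** Isolation by distance via the linearized regression of
D/(1−D) on ln(km); simple and partial Mantel tests and multiple regression
on distance matrices (MRM), all with seeded matrix-permutation nulls;
three-level AMOVA (among language phyla / among populations within phyla /
within populations) with Φ statistics and permutation tests; rarefied
allelic richness Rs with IDW interpolation onto a map grid; a
minimum-spanning-tree population network with a phylum-assortativity test;
island-model migrant numbers M = (1 − F_ST)/(2 F_ST) between genetic
clusters; and cognate-set × cluster contingency tables with χ² tests.

**Synthetic data.** A first-class generator builds SSR landscapes with
known truth: language phyla occupying contiguous Voronoi territories,
two-level Balding–Nichols drift (phylum then population), a spatially
autocorrelated drift field producing isolation by distance, missing calls,
bilingual sites, and phylum-anchored cognate sets.  Every statistical claim
in the test suite is checked against this ground truth or an independent
oracle.

## Worked example

```python
from bcpg import (SimulationConfig, simulate_bundle, jost_d_pairwise, linearize,
                  mantel, partial_mantel, greatcircle_matrix,
                  linguistic_distance_matrix, log_distance, amova_three_level)
from bcpg.simulate import primary_phylum

cfg = SimulationConfig(rng_seed=7)          # 91 populations, 14 SSR loci
genotypes, metadata, hierarchy, cognates, truth = simulate_bundle(cfg)

d_lin = linearize(jost_d_pairwise(genotypes))
d_geo = log_distance(greatcircle_matrix(metadata))
d_lan = linguistic_distance_matrix(metadata, hierarchy)

ibd  = mantel(d_lin, d_geo, n_perm=5000, seed=1)
lang = partial_mantel(d_lin, d_lan, d_geo, n_perm=5000, seed=1)
print(f"IBD:      r = {ibd.r:.3f}, p = {ibd.p:.4f}")
print(f"language: r = {lang.r:.3f}, p = {lang.p:.4f}")

grouping = {m.site: primary_phylum(m, hierarchy) for m in metadata}
res = amova_three_level(genotypes, grouping, n_perm=999, seed=1)
pct = res.percentages
print(f"AMOVA: {pct[0]:.2f}% among phyla, {pct[1]:.2f}% among populations, "
      f"{pct[2]:.2f}% within populations")
```

prints

```
IBD:      r = 0.530, p = 0.0002
language: r = 0.314, p = 0.0002
AMOVA: 5.21% among phyla, 6.88% among populations, 87.92% within populations
```

Geography explains most of the differentiation (r = 0.53), yet the
language signal survives the geographic control (partial r = 0.31 at the
permutation floor p = 1/5001 ≈ 0.0002) — exactly the biocultural pattern
the generator was configured to produce.  The AMOVA places most variance
within populations, with a real among-phylum component (Φ_CT ≈ 0.05
matching the configured phylum divergence).

## Command line

```sh
bcpg simulate --out bundle --seed 3          # write a synthetic dataset
bcpg gendist bundle/genotypes.gen --out d.csv
bcpg geodist bundle/metadata.csv bundle/hierarchy.csv --out geo.csv --log
bcpg mantel d.csv geo.csv --n-perm 5000 --seed 1
bcpg run-all config.yaml                     # full report bundle
```

`run-all` reads a YAML config (paths, estimator options, permutation
counts, seed) and writes the association, AMOVA, diversity and overlay
reports plus the IDW grid (`.asc`/CSV) and the MST (GraphML/CSV), with the
config hash and seed embedded for provenance.  Real datasets enter as
GenePop genotype files plus CSV metadata / language-classification /
Q-matrix tables.

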