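"""Synthetic SSR landscapes with known ethnolinguistic and spatial structure.

The generator emulates a continental sampling design: language phyla occupy
contiguous Voronoi territories, populations sit inside those territories and
speak a language of the local phylum, allele frequencies drift from a common
ancestral pool first at the phylum level then at the population level
(Balding-Nichols model at each step), a spatially autocorrelated
perturbation adds isolation by distance, and cognate sets are anchored to
phyla with a tunable leakage.  Every stage is deterministic under the
configured seed and the full ground truth is retained for recovery tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io import (
    write_cognates,
    write_genepop,
    write_hierarchy,
    write_metadata,
    write_yaml,
)
from .model import (
    ClusterAssignment,
    CognateCatalog,
    DataModelError,
    GenotypeDataset,
    LanguageHierarchy,
    PopulationMetadata,
    WordTerm,
)
from .predictors import haversine_km

import pandas as pd


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the walnut sampling design
    (91 populations x ~20 genotypes x 14 SSR loci across 5 phyla)."""

    n_phyla: int = 5
    families_per_phylum: int = 2
    languages_per_family: int = 2
    n_populations: int = 91
    individuals_per_population: int = 20
    n_loci: int = 14
    alleles_per_locus: int = 10
    f_phylum: float = 0.05  # phylum-level divergence from the ancestral pool
    f_pop: float = 0.05  # population-level divergence from the phylum pool
    ibd_range: float = 1500.0  # correlation length (km) of the drift field
    ibd_strength: float = 0.75  # s.d. of the spatial logit perturbation
    missing_rate: float = 0.02
    bilingual_fraction: float = 0.08
    cognate_leakage: float = 0.1
    lat_range: tuple[float, float] = (25.0, 55.0)
    lon_range: tuple[float, float] = (-10.0, 110.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_phylum", "f_pop", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise DataModelError(f"{name}={v} outside [0, 1)")
        if not 0.0 <= self.cognate_leakage <= 1.0:
            raise DataModelError("cognate_leakage outside [0, 1]")
        if self.ibd_range < 0:
            raise DataModelError("ibd_range must be >= 0")
        if self.n_populations < 2:
            raise DataModelError("need at least 2 populations")
        if self.n_populations < self.n_phyla:
            raise DataModelError("fewer populations than phyla")
        for name in (
            "n_phyla",
            "families_per_phylum",
            "languages_per_family",
            "individuals_per_population",
            "n_loci",
            "alleles_per_locus",
        ):
            if getattr(self, name) < 1:
                raise DataModelError(f"{name} must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth: frequencies per level, coordinates, assignments."""

    ancestral: list[np.ndarray]  # per locus: (alleles,)
    phylum_freqs: list[np.ndarray]  # per locus: (phyla, alleles)
    population_freqs: list[np.ndarray]  # per locus: (pops, alleles)
    phyla: list[str]
    phylum_of_population: list[str]
    coordinates: np.ndarray  # (pops, 2) lat, lon
    language_of_population: list[str]
    cognate_anchor: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for group in (self.ancestral, self.phylum_freqs, self.population_freqs):
            for arr in group:
                sums = np.atleast_2d(arr).sum(axis=-1)
                if np.abs(sums - 1.0).max() > 1e-9:
                    raise DataModelError("frequencies do not sum to 1 within 1e-9")


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    # independent per-stage streams so stages are reproducible in isolation
    return np.random.default_rng([cfg.rng_seed, stage])


def build_hierarchy(cfg: SimulationConfig) -> LanguageHierarchy:
    """Deterministic 4-level classification for the configured sizes.

    Families with more than one language split their languages into two
    subgroups; single-language families attach the language directly at the
    family level (null subgroup), exercising both coding paths of the
    linguistic dissimilarity index.
    """
    mapping: dict[str, tuple[str | None, str, str]] = {}
    for p in range(cfg.n_phyla):
        phylum = f"Phylum{p + 1}"
        for f in range(cfg.families_per_phylum):
            family = f"{phylum}-Fam{f + 1}"
            for l in range(cfg.languages_per_family):
                lang = f"{family}-Lang{l + 1}"
                if cfg.languages_per_family > 1:
                    sub = f"{family}-Sub{(l % 2) + 1}"
                else:
                    sub = None
                mapping[lang] = (sub, family, phylum)
    return LanguageHierarchy(mapping)


def simulate_landscape(
    cfg: SimulationConfig,
) -> tuple[list[PopulationMetadata], LanguageHierarchy]:
    """Place phylum territories and populations; assign languages and terms.

    Phylum seeds are uniform on the map; each territory is the seed's
    Voronoi cell under great-circle distance.  Populations are split as
    evenly as possible across phyla and placed uniformly inside their
    territory (rejection sampling).  A ``bilingual_fraction`` of sites
    additionally speaks a language of the nearest foreign phylum.
    """
    hierarchy = build_hierarchy(cfg)
    rng = _rng(cfg, stage=1)
    phyla = [f"Phylum{p + 1}" for p in range(cfg.n_phyla)]
    lang_by_phylum = {
        ph: [l for l in hierarchy.languages if hierarchy.phylum(l) == ph]
        for ph in phyla
    }
    seed_lat = rng.uniform(*cfg.lat_range, size=cfg.n_phyla)
    seed_lon = rng.uniform(*cfg.lon_range, size=cfg.n_phyla)

    def nearest_phylum(lat: float, lon: float) -> int:
        return int(np.argmin(haversine_km(lat, lon, seed_lat, seed_lon)))

    base, extra = divmod(cfg.n_populations, cfg.n_phyla)
    quota = np.full(cfg.n_phyla, base)
    quota[rng.permutation(cfg.n_phyla)[:extra]] += 1

    metadata: list[PopulationMetadata] = []
    idx = 0
    for p, phylum in enumerate(phyla):
        for _ in range(int(quota[p])):
            for _attempt in range(1000):
                lat = rng.uniform(*cfg.lat_range)
                lon = rng.uniform(*cfg.lon_range)
                if nearest_phylum(lat, lon) == p:
                    break
            else:  # degenerate tiny cell: jitter around the seed
                lat = float(np.clip(seed_lat[p] + rng.normal(0, 0.1), *cfg.lat_range))
                lon = float(np.clip(seed_lon[p] + rng.normal(0, 0.1), *cfg.lon_range))
            langs = {lang_by_phylum[phylum][rng.integers(len(lang_by_phylum[phylum]))]}
            if cfg.n_phyla > 1 and rng.random() < cfg.bilingual_fraction:
                d = haversine_km(lat, lon, seed_lat, seed_lon)
                d[p] = np.inf
                other = phyla[int(np.argmin(d))]
                langs.add(
                    lang_by_phylum[other][rng.integers(len(lang_by_phylum[other]))]
                )
            n_terms = 1 + rng.poisson(1.5)
            terms = tuple(
                WordTerm(
                    term=f"w{idx:03d}_{t}",
                    word_class=("inherited", "loanword", "compound")[
                        rng.integers(3)
                    ],
                    cognate_set=f"cs_{phylum}",
                )
                for t in range(n_terms)
            )
            metadata.append(
                PopulationMetadata(
                    site=f"pop{idx:03d}",
                    latitude=float(lat),
                    longitude=float(lon),
                    country=phylum,
                    languages=frozenset(langs),
                    word_terms=terms,
                )
            )
            idx += 1
    return metadata, hierarchy


def primary_phylum(meta: PopulationMetadata, hierarchy: LanguageHierarchy) -> str:
    """Phylum of the site's alphabetically first language."""
    return hierarchy.phylum(sorted(meta.languages)[0])


def _balding_nichols(
    rng: np.random.Generator, base: np.ndarray, f: float, size: int
) -> np.ndarray:
    """Draw ``size`` frequency vectors around ``base`` with divergence f.

    Dirichlet with concentration (1 - f)/f * base; f = 0 copies the base.
    """
    if f == 0.0:
        return np.tile(base, (size, 1))
    conc = np.maximum(base * (1.0 - f) / f, 1e-9)
    return rng.dirichlet(conc, size=size)


def simulate_frequencies(
    cfg: SimulationConfig,
    metadata: Sequence[PopulationMetadata],
    hierarchy: LanguageHierarchy,
) -> SimulatedTruth:
    """Two-level Balding-Nichols drift plus a spatially correlated field.

    Ancestral frequencies are symmetric Dirichlet(1); phylum pools drift
    with ``f_phylum``; population frequencies drift from their phylum pool
    with ``f_pop`` and then receive a Gaussian-kernel spatial perturbation
    (correlation length ``ibd_range`` km) applied on the logit scale and
    renormalized, so nearby populations share drift.
    """
    rng = _rng(cfg, stage=2)
    phyla = [f"Phylum{p + 1}" for p in range(cfg.n_phyla)]
    phylum_of = [primary_phylum(m, hierarchy) for m in metadata]
    p_idx = np.array([phyla.index(ph) for ph in phylum_of])
    coords = np.array([[m.latitude, m.longitude] for m in metadata])
    n_pops = len(metadata)

    spatial_l = None
    if cfg.ibd_range > 0 and cfg.ibd_strength > 0:
        d = haversine_km(
            coords[:, 0][:, None], coords[:, 1][:, None],
            coords[:, 0][None, :], coords[:, 1][None, :],
        )
        k = np.exp(-((d / cfg.ibd_range) ** 2))
        spatial_l = np.linalg.cholesky(k + 1e-8 * np.eye(n_pops))

    ancestral, phylum_freqs, pop_freqs = [], [], []
    for _l in range(cfg.n_loci):
        anc = rng.dirichlet(np.ones(cfg.alleles_per_locus))
        phy = _balding_nichols(rng, anc, cfg.f_phylum, cfg.n_phyla)
        pop = np.empty((n_pops, cfg.alleles_per_locus))
        for p in range(cfg.n_phyla):
            members = np.flatnonzero(p_idx == p)
            if members.size:
                pop[members] = _balding_nichols(rng, phy[p], cfg.f_pop, members.size)
        if spatial_l is not None:
            z = spatial_l @ rng.standard_normal((n_pops, cfg.alleles_per_locus))
            eps = 1e-9
            clipped = np.clip(pop, eps, 1 - eps)
            logit = np.log(clipped / (1 - clipped)) + cfg.ibd_strength * z
            pop = 1.0 / (1.0 + np.exp(-logit))
            pop /= pop.sum(axis=1, keepdims=True)
        ancestral.append(anc)
        phylum_freqs.append(phy)
        pop_freqs.append(pop)
    return SimulatedTruth(
        ancestral=ancestral,
        phylum_freqs=phylum_freqs,
        population_freqs=pop_freqs,
        phyla=phyla,
        phylum_of_population=phylum_of,
        coordinates=coords,
        language_of_population=[sorted(m.languages)[0] for m in metadata],
    )


def sample_genotypes(
    truth: SimulatedTruth,
    cfg: SimulationConfig,
    metadata: Sequence[PopulationMetadata],
) -> GenotypeDataset:
    """Draw diploid genotypes under Hardy-Weinberg within populations.

    Both alleles of an individual are independent draws from its
    population's locus frequencies; calls are masked missing at
    ``missing_rate``.  Allele tokens are zero-padded 3-digit codes.
    """
    rng = _rng(cfg, stage=3)
    n_ind = cfg.individuals_per_population
    n_pops = len(metadata)
    tokens = [f"{a + 1:03d}" for a in range(cfg.alleles_per_locus)]
    calls: dict[str, list[list[tuple[str, str] | None]]] = {}
    for p, meta in enumerate(metadata):
        pop_rows: list[list[tuple[str, str] | None]] = [[] for _ in range(n_ind)]
        for l in range(cfg.n_loci):
            freqs = truth.population_freqs[l][p]
            draws = rng.choice(cfg.alleles_per_locus, size=(n_ind, 2), p=freqs)
            miss = rng.random(n_ind) < cfg.missing_rate
            for i in range(n_ind):
                if miss[i]:
                    pop_rows[i].append(None)
                else:
                    pop_rows[i].append((tokens[draws[i, 0]], tokens[draws[i, 1]]))
        calls[meta.site] = pop_rows
    loci = [f"L{l + 1:02d}" for l in range(cfg.n_loci)]
    return GenotypeDataset.from_calls(loci, calls)


def simulate_cognates(
    truth: SimulatedTruth,
    cfg: SimulationConfig,
    metadata: Sequence[PopulationMetadata],
) -> CognateCatalog:
    """Phylum-anchored cognate sets with tunable leakage.

    Each phylum anchors one cognate set.  A site carries the set with
    probability ``(1 - leakage)`` when its phylum is the anchor (0
    otherwise) plus ``leakage * 0.5`` everywhere, so leakage 0 gives
    perfect phylum/cognate alignment and leakage 1 a uniform coin flip.
    """
    rng = _rng(cfg, stage=4)
    lam = cfg.cognate_leakage
    sites = [m.site for m in metadata]
    data = {}
    anchors = {}
    for phylum in truth.phyla:
        name = f"cs_{phylum}"
        anchors[name] = phylum
        member = np.array([ph == phylum for ph in truth.phylum_of_population])
        prob = member * (1.0 - lam) + 0.5 * lam
        data[name] = rng.random(len(sites)) < prob
    truth.cognate_anchor = anchors
    presence = pd.DataFrame(data, index=pd.Index(sites, name="site"))
    return CognateCatalog(presence)


def simulate_qmatrix(
    truth: SimulatedTruth, cfg: SimulationConfig, concentration: float = 0.9
) -> ClusterAssignment:
    """Synthetic membership coefficients tracking the true phylum clusters.

    Stands in for an external admixture clustering: each population loads
    ``concentration`` on its own phylum's cluster with the remainder spread
    evenly.  K equals the number of phyla (requires >= 2).
    """
    k = len(truth.phyla)
    if k < 2:
        raise DataModelError("Q-matrix needs K >= 2 (configure >= 2 phyla)")
    n = len(truth.phylum_of_population)
    q = np.full((n, k), (1.0 - concentration) / (k - 1))
    for i, ph in enumerate(truth.phylum_of_population):
        q[i, truth.phyla.index(ph)] = concentration
    sites = [f"pop{i:03d}" for i in range(n)]
    return ClusterAssignment(sites, q)


def simulate_bundle(
    cfg: SimulationConfig,
) -> tuple[
    GenotypeDataset,
    list[PopulationMetadata],
    LanguageHierarchy,
    CognateCatalog,
    SimulatedTruth,
]:
    """Run every stage under one seed and return the complete dataset."""
    metadata, hierarchy = simulate_landscape(cfg)
    truth = simulate_frequencies(cfg, metadata, hierarchy)
    genotypes = sample_genotypes(truth, cfg, metadata)
    cognates = simulate_cognates(truth, cfg, metadata)
    return genotypes, metadata, hierarchy, cognates, truth


def write_bundle(cfg: SimulationConfig, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write genotypes, metadata, hierarchy, cognates, Q-matrix and the
    truth ledger (YAML) into ``out_dir``; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    genotypes, metadata, hierarchy, cognates, truth = simulate_bundle(cfg)
    paths = {
        "genotypes": os.path.join(out_dir, "genotypes.gen"),
        "metadata": os.path.join(out_dir, "metadata.csv"),
        "hierarchy": os.path.join(out_dir, "hierarchy.csv"),
        "cognates": os.path.join(out_dir, "cognates.csv"),
        "qmatrix": os.path.join(out_dir, "qmatrix.csv"),
        "truth": os.path.join(out_dir, "truth.yaml"),
    }
    write_genepop(genotypes, paths["genotypes"])
    write_metadata(metadata, paths["metadata"])
    write_hierarchy(hierarchy, paths["hierarchy"])
    write_cognates(cognates, paths["cognates"])
    q = simulate_qmatrix(truth, cfg)
    frame = pd.DataFrame(q.q, columns=[f"Q{i + 1}" for i in range(q.k)])
    frame.insert(0, "site", q.labels)
    frame.to_csv(paths["qmatrix"], index=False)
    ledger = {
        "config": asdict(cfg),
        "phyla": truth.phyla,
        "phylum_of_population": truth.phylum_of_population,
        "language_of_population": truth.language_of_population,
        "cognate_anchor": truth.cognate_anchor,
    }
    ledger["config"]["lat_range"] = list(cfg.lat_range)
    ledger["config"]["lon_range"] = list(cfg.lon_range)
    write_yaml(ledger, paths["truth"])
    return paths
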