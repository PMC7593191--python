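"""Core data model: genotypes, metadata, language hierarchy, labeled matrices.

These containers are the substrate shared by every statistic in the package:
diploid SSR calls per population, site metadata with languages and word terms,
the 4-level language classification, symmetric labeled distance matrices,
STRUCTURE-style membership coefficients, and cognate-set presence tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # internal allele index for an untyped gene

WORD_CLASSES = ("inherited", "loanword", "compound")


class DataModelError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class WordTerm:
    term: str
    word_class: str  # inherited | loanword | compound
    cognate_set: str

    def __post_init__(self) -> None:
        if self.word_class not in WORD_CLASSES:
            raise DataModelError(
                f"word class {self.word_class!r} not in {WORD_CLASSES}"
            )


@dataclass(frozen=True)
class PopulationMetadata:
    """One sampling site: coordinates, country, spoken languages, word terms."""

    site: str
    latitude: float
    longitude: float
    country: str
    languages: frozenset[str]
    word_terms: tuple[WordTerm, ...] = ()

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise DataModelError(
                f"site {self.site!r}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise DataModelError(
                f"site {self.site!r}: longitude {self.longitude} outside [-180, 180]"
            )
        if not self.languages:
            raise DataModelError(f"site {self.site!r}: empty language set")

    @property
    def word_richness(self) -> int:
        return len(self.word_terms)


class LanguageHierarchy:
    """Map language -> (subgroup | None, family, phylum).

    The mapping is a tree: each language has exactly one path to a phylum.
    A null subgroup means the language attaches directly at the family level.
    """

    def __init__(self, mapping: Mapping[str, tuple[str | None, str, str]]):
        if not mapping:
            raise DataModelError("empty language hierarchy")
        self._map = dict(mapping)
        # tree invariant: a subgroup may not appear under two families, nor a
        # family under two phyla
        sub_parent: dict[str, str] = {}
        fam_parent: dict[str, str] = {}
        for lang, (sub, fam, phy) in self._map.items():
            if sub is not None and sub_parent.setdefault(sub, fam) != fam:
                raise DataModelError(f"subgroup {sub!r} appears under two families")
            if fam_parent.setdefault(fam, phy) != phy:
                raise DataModelError(f"family {fam!r} appears under two phyla")
            del lang

    def __contains__(self, language: str) -> bool:
        return language in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def languages(self) -> list[str]:
        return sorted(self._map)

    @property
    def phyla(self) -> list[str]:
        return sorted({v[2] for v in self._map.values()})

    def subgroup(self, language: str) -> str | None:
        return self._lookup(language)[0]

    def family(self, language: str) -> str:
        return self._lookup(language)[1]

    def phylum(self, language: str) -> str:
        return self._lookup(language)[2]

    def _lookup(self, language: str) -> tuple[str | None, str, str]:
        try:
            return self._map[language]
        except KeyError:
            raise DataModelError(f"unknown language {language!r}") from None

    def validate(self, metadata: Iterable[PopulationMetadata]) -> None:
        bad = [
            (m.site, lang)
            for m in metadata
            for lang in sorted(m.languages)
            if lang not in self
        ]
        if bad:
            rows = ", ".join(f"{site}:{lang}" for site, lang in bad)
            raise DataModelError(f"languages missing from hierarchy: {rows}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"language": lang, "subgroup": sub or "", "family": fam, "phylum": phy}
            for lang, (sub, fam, phy) in sorted(self._map.items())
        ]
        return pd.DataFrame(rows)


class GenotypeDataset:
    """Diploid SSR calls for individuals grouped into populations.

    Alleles are opaque tokens compared only for identity; internally each
    locus maps its tokens to integer codes, with ``MISSING`` for untyped
    genes.  An individual belongs to exactly one population.
    """

    def __init__(
        self,
        populations: Sequence[str],
        loci: Sequence[str],
        pop_index: np.ndarray,
        genotypes: np.ndarray,
        allele_names: Sequence[Sequence[str]],
    ):
        self.populations = list(populations)
        self.loci = list(loci)
        self.pop_index = np.asarray(pop_index, dtype=np.intp)
        self.genotypes = np.asarray(genotypes, dtype=np.int32)
        self.allele_names = [list(a) for a in allele_names]
        n_ind = self.pop_index.shape[0]
        if self.genotypes.shape != (n_ind, len(self.loci), 2):
            raise DataModelError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{n_ind} individuals x {len(self.loci)} loci x 2"
            )
        if len(set(self.populations)) != len(self.populations):
            raise DataModelError("duplicate population labels")
        if n_ind and (
            self.pop_index.min() < 0 or self.pop_index.max() >= len(self.populations)
        ):
            raise DataModelError("population index out of range")
        # a half-missing diploid call is not a valid SSR score
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            raise DataModelError("half-missing diploid calls are not allowed")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        loci: Sequence[str],
        calls: Mapping[str, Sequence[Sequence[tuple[str, str] | None]]],
    ) -> "GenotypeDataset":
        """Build from ``{population: [per-individual [call per locus]]}``.

        A call is an (allele, allele) token pair or None for missing.
        """
        populations = list(calls)
        alleles: list[dict[str, int]] = [dict() for _ in loci]
        pop_index: list[int] = []
        rows: list[list[tuple[int, int]]] = []
        for p, pop in enumerate(populations):
            for ind in calls[pop]:
                if len(ind) != len(loci):
                    raise DataModelError(
                        f"individual in {pop!r} has {len(ind)} calls, "
                        f"expected {len(loci)}"
                    )
                row = []
                for l, call in enumerate(ind):
                    if call is None:
                        row.append((MISSING, MISSING))
                    else:
                        a, b = call
                        table = alleles[l]
                        row.append(
                            (
                                table.setdefault(a, len(table)),
                                table.setdefault(b, len(table)),
                            )
                        )
                pop_index.append(p)
                rows.append(row)
        geno = np.array(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
        names = [sorted(t, key=t.get) for t in alleles]
        return cls(populations, loci, np.array(pop_index), geno, names)

    # -- accessors ------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.pop_index.shape[0]

    def population_sizes(self) -> np.ndarray:
        return np.bincount(self.pop_index, minlength=len(self.populations))

    def n_alleles(self, locus: int) -> int:
        return len(self.allele_names[locus])

    def sample_size(self, pop: str, locus: str) -> int:
        """Individuals of ``pop`` with a non-missing call at ``locus`` (n_i)."""
        p = self.populations.index(pop)
        l = self.loci.index(locus)
        mask = self.pop_index == p
        return int((self.genotypes[mask, l, 0] != MISSING).sum())

    def allele_counts(self, locus: int) -> np.ndarray:
        """(n_populations, n_alleles) gene counts at one locus."""
        k = self.n_alleles(locus)
        counts = np.zeros((len(self.populations), k), dtype=np.int64)
        g = self.genotypes[:, locus, :]
        typed = g[:, 0] != MISSING
        for gene in (0, 1):
            np.add.at(counts, (self.pop_index[typed], g[typed, gene]), 1)
        return counts

    def typed_genes(self, locus: int) -> tuple[np.ndarray, np.ndarray]:
        """Flat (pop_index, allele_index) arrays over typed genes at a locus."""
        g = self.genotypes[:, locus, :]
        typed = g[:, 0] != MISSING
        pops = np.repeat(self.pop_index[typed], 2)
        alleles = g[typed].reshape(-1)
        return pops, alleles

    def calls_for(self, pop: str) -> list[list[tuple[str, str] | None]]:
        """Token-level calls of every individual of one population."""
        p = self.populations.index(pop)
        out = []
        for row in self.genotypes[self.pop_index == p]:
            ind: list[tuple[str, str] | None] = []
            for l in range(len(self.loci)):
                a, b = int(row[l, 0]), int(row[l, 1])
                if a == MISSING:
                    ind.append(None)
                else:
                    names = self.allele_names[l]
                    ind.append((names[a], names[b]))
            out.append(ind)
        return out

    def subset_populations(self, keep: Sequence[str]) -> "GenotypeDataset":
        keep = list(keep)
        idx = {pop: i for i, pop in enumerate(self.populations)}
        missing = [p for p in keep if p not in idx]
        if missing:
            raise DataModelError(f"unknown populations: {missing}")
        order = {idx[p]: j for j, p in enumerate(keep)}
        mask = np.isin(self.pop_index, list(order))
        new_index = np.array([order[p] for p in self.pop_index[mask]], dtype=np.intp)
        return GenotypeDataset(
            keep, self.loci, new_index, self.genotypes[mask], self.allele_names
        )


class LabeledMatrix:
    """Square symmetric matrix with ordered row labels and zero diagonal."""

    KINDS = ("genetic", "linguistic", "geographic", "derived")

    def __init__(self, labels: Sequence[str], values: np.ndarray, kind: str = "derived"):
        if kind not in self.KINDS:
            raise DataModelError(f"kind {kind!r} not in {self.KINDS}")
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise DataModelError(f"matrix shape {values.shape} != ({n}, {n})")
        if len(set(labels)) != n:
            raise DataModelError("duplicate labels")
        if np.isnan(values).any():
            raise DataModelError("matrix contains NaN entries")
        if not np.allclose(values, values.T, atol=1e-12, rtol=0.0):
            raise DataModelError("matrix asymmetric beyond 1e-12")
        if np.abs(np.diag(values)).max(initial=0.0) > 0.0:
            raise DataModelError("matrix diagonal must be exactly zero")
        self.labels = labels
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self.kind = kind

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Strict lower-triangle values as a flat vector (pair order fixed)."""
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.values[iu]

    def subset(self, labels: Sequence[str]) -> "LabeledMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabeledMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def align(self, *others: "LabeledMatrix") -> list["LabeledMatrix"]:
        """Restrict self and others to their common labels, in self's order."""
        common = [l for l in self.labels if all(l in o.labels for o in others)]
        if len(common) < 2:
            raise DataModelError("fewer than 2 common labels after alignment")
        return [m.subset(common) for m in (self, *others)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


class ClusterAssignment:
    """Per-population membership coefficients from an admixture clustering.

    ``label(pop)`` is the argmax cluster (1-based) when its coefficient
    reaches the admixture threshold, else ``admixed(a×b)`` with a < b the two
    largest components.
    """

    def __init__(self, labels: Sequence[str], q: np.ndarray, threshold: float = 0.7):
        q = np.asarray(q, dtype=float)
        if not 0.5 < threshold <= 1.0:
            raise DataModelError(f"threshold {threshold} outside (0.5, 1]")
        if q.ndim != 2 or q.shape[0] != len(labels):
            raise DataModelError("Q matrix shape does not match labels")
        if q.shape[1] < 2:
            raise DataModelError("K must be >= 2")
        if ((q < -1e-9) | (q > 1 + 1e-9)).any():
            raise DataModelError("membership coefficients outside [0, 1]")
        sums = q.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
        if bad.size:
            raise DataModelError(
                f"Q rows not summing to 1 within 1e-6: rows {bad.tolist()}"
            )
        self.labels = list(labels)
        self.q = q / sums[:, None]
        self.threshold = threshold

    @property
    def k(self) -> int:
        return self.q.shape[1]

    def label(self, pop: str) -> str:
        i = self.labels.index(pop)
        row = self.q[i]
        order = np.argsort(-row, kind="stable")
        if row[order[0]] >= self.threshold:
            return str(order[0] + 1)
        a, b = sorted((int(order[0]) + 1, int(order[1]) + 1))
        return f"admixed({a}×{b})"

    def cluster_labels(self) -> dict[str, str]:
        return {pop: self.label(pop) for pop in self.labels}


class CognateCatalog:
    """Cognate sets (optionally with proto-words) and per-site presence."""

    def __init__(
        self,
        presence: pd.DataFrame,
        proto_words: Mapping[str, str] | None = None,
    ):
        if presence.empty:
            raise DataModelError("empty cognate presence table")
        self.presence = presence.astype(bool)
        self.proto_words = dict(proto_words or {})

    @property
    def sites(self) -> list[str]:
        return list(self.presence.index)

    @property
    def cognate_sets(self) -> list[str]:
        return list(self.presence.columns)

    def validate(self, metadata: Iterable[PopulationMetadata]) -> None:
        known = {m.site for m in metadata}
        unknown = [s for s in self.sites if s not in known]
        if unknown:
            raise DataModelError(f"cognate catalog references unknown sites: {unknown}")
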