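"""Three-level analysis of molecular variance on allele-identity distances.

Genes (two per typed individual, per locus) carry the 0/1 allele-identity
distance.  Sums of squares are decomposed into among-group, among-population
-within-group and within-population strata; variance components are solved
from the expected mean squares with unequal-sample-size coefficients, and
Phi statistics are tested by the standard permutation strata (genes among
populations for Phi_ST, genes within groups for Phi_SC, whole populations
among groups for Phi_CT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import GenotypeDataset


class AmovaError(ValueError):
    pass


@dataclass
class AmovaResult:
    groups: list[str]
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    ss: tuple[float, float, float]
    df: tuple[int, int, int]
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float | None
    p_phi_ct: float | None = None
    p_phi_sc: float | None = None
    p_phi_st: float | None = None
    n_perm: int = 0
    defined: bool = True

    @property
    def sigma_total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    @property
    def percentages(self) -> tuple[float, float, float]:
        """Percent of total variance per stratum, on raw components."""
        tot = self.sigma_total
        if tot == 0:
            raise AmovaError("zero total variance: percentages undefined")
        return (
            100.0 * self.sigma_a / tot,
            100.0 * self.sigma_b / tot,
            100.0 * self.sigma_c / tot,
        )


@dataclass
class _LocusData:
    """Typed genes of one locus: population index and allele index per gene."""

    pop: np.ndarray
    allele: np.ndarray
    n_alleles: int


def _gene_table(dataset: GenotypeDataset) -> list[_LocusData]:
    out = []
    for l in range(len(dataset.loci)):
        pops, alleles = dataset.typed_genes(l)
        out.append(_LocusData(pops, alleles, dataset.n_alleles(l)))
    return out


def _ss_within(counts: np.ndarray) -> np.ndarray:
    """Pairwise-mismatch SS per row of a unit x allele count table."""
    n = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss = (n - (counts**2).sum(axis=-1) / n) / 2.0
    return np.where(n > 0, ss, 0.0)


def _locus_terms(
    counts: np.ndarray, group_of_pop: np.ndarray, n_groups: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """SS, df and EMS-coefficient numerators for one locus.

    ``counts`` is populations x alleles (typed genes).  Returns None when
    the locus has genes in fewer than 2 groups (no information at the
    among-group stratum for this locus).
    """
    n_p = counts.sum(axis=1)
    present = n_p > 0
    gcounts = np.zeros((n_groups, counts.shape[1]))
    np.add.at(gcounts, group_of_pop, counts)
    n_g = gcounts.sum(axis=1)
    n_tot = n_p.sum()
    p_l = int(present.sum())
    g_l = int((n_g > 0).sum())
    if g_l < 2 or n_tot == 0:
        return None
    ss_wp = _ss_within(counts).sum()
    ss_wg = _ss_within(gcounts).sum()
    ss_tot = float(_ss_within(counts.sum(axis=0)[None, :])[0])
    ss = np.array([ss_tot - ss_wg, ss_wg - ss_wp, ss_wp])
    df = np.array([g_l - 1, p_l - g_l, int(n_tot) - p_l])
    with np.errstate(divide="ignore", invalid="ignore"):
        s_over_ng = np.where(
            n_g > 0, np.bincount(group_of_pop, n_p**2, minlength=n_groups) / n_g, 0.0
        ).sum()
    coef = np.array(
        [
            n_tot - (n_g**2).sum() / n_tot,  # n''' numerator (df_a stratum)
            s_over_ng - (n_p**2).sum() / n_tot,  # n'' numerator (df_a stratum)
            n_tot - s_over_ng,  # n' numerator (df_b stratum)
        ]
    )
    return ss, df, coef


def _solve_components(
    ss: np.ndarray, df: np.ndarray, coef: np.ndarray
) -> tuple[float, float, float] | None:
    """Solve the EMS equations for (sigma_a, sigma_b, sigma_c)."""
    if df[2] <= 0 or df[0] <= 0:
        return None
    ms_a = ss[0] / df[0]
    ms_c = ss[2] / df[2]
    n3 = coef[0] / df[0]
    n2 = coef[1] / df[0]
    sigma_c = ms_c
    if df[1] > 0:
        n1 = coef[2] / df[1]
        ms_b = ss[1] / df[1]
        sigma_b = (ms_b - sigma_c) / n1
    else:  # exactly one population per group: no within-group stratum
        sigma_b = 0.0
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


def _amova_components(
    loci: list[_LocusData],
    group_of_pop: np.ndarray,
    n_pops: int,
    n_groups: int,
) -> tuple[tuple[float, float, float] | None, np.ndarray, np.ndarray]:
    ss = np.zeros(3)
    df = np.zeros(3, dtype=int)
    coef = np.zeros(3)
    for ld in loci:
        counts = np.zeros((n_pops, ld.n_alleles))
        np.add.at(counts, (ld.pop, ld.allele), 1.0)
        terms = _locus_terms(counts, group_of_pop, n_groups)
        if terms is None:
            continue
        ss += terms[0]
        df += terms[1]
        coef += terms[2]
    return _solve_components(ss, df, coef), ss, df


def _phis(
    components: tuple[float, float, float]
) -> tuple[float, float | None, float] | None:
    a, b, c = components
    tot = a + b + c
    if tot == 0:
        return None
    phi_sc = b / (b + c) if (b + c) != 0 else None  # no within-group variance
    return a / tot, phi_sc, (a + b) / tot


def amova_three_level(
    dataset: GenotypeDataset,
    grouping: Mapping[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA: groups / populations within groups / within.

    ``grouping`` maps every population to its group (e.g. the language
    phylum spoken at the site).  SS and df are summed across loci and the
    EMS coefficients pooled per stratum (df-weighted), so per-locus missing
    genes reduce the degrees of freedom locally.  Negative components are
    reported raw so percentages stay additive.
    """
    missing = [p for p in dataset.populations if p not in grouping]
    if missing:
        raise AmovaError(f"populations without a group: {missing}")
    groups = sorted(set(grouping[p] for p in dataset.populations))
    if len(groups) < 2:
        raise AmovaError("AMOVA needs at least 2 groups")
    group_of_pop = np.array(
        [groups.index(grouping[p]) for p in dataset.populations], dtype=np.intp
    )
    n_pops = len(dataset.populations)
    n_groups = len(groups)
    loci = _gene_table(dataset)

    comps, ss, df = _amova_components(loci, group_of_pop, n_pops, n_groups)
    if comps is None:
        raise AmovaError("degenerate design: cannot solve variance components")
    phis = _phis(comps)
    if phis is None:  # monomorphic data: zero total variance
        return AmovaResult(
            groups=groups,
            sigma_a=comps[0],
            sigma_b=comps[1],
            sigma_c=comps[2],
            ss=tuple(ss),
            df=tuple(df),
            phi_ct=None,
            phi_sc=None,
            phi_st=None,
            defined=False,
        )
    phi_ct, phi_sc, phi_st = phis

    result = AmovaResult(
        groups=groups,
        sigma_a=comps[0],
        sigma_b=comps[1],
        sigma_c=comps[2],
        ss=tuple(ss),
        df=tuple(df),
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        n_perm=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        result.p_phi_st = _perm_phi_st(loci, group_of_pop, n_pops, n_groups, phi_st, n_perm, rng)
        if phi_sc is not None:
            result.p_phi_sc = _perm_phi_sc(loci, group_of_pop, n_pops, n_groups, phi_sc, n_perm, rng)
        result.p_phi_ct = _perm_phi_ct(loci, group_of_pop, n_pops, n_groups, phi_ct, n_perm, rng)
    return result


def _perm_phi_st(loci, group_of_pop, n_pops, n_groups, observed, n_perm, rng):
    """Null: permute genes among all populations (per locus)."""
    hits = 0
    for _ in range(n_perm):
        shuffled = [
            _LocusData(ld.pop, rng.permutation(ld.allele), ld.n_alleles) for ld in loci
        ]
        comps, _, _ = _amova_components(shuffled, group_of_pop, n_pops, n_groups)
        phis = _phis(comps) if comps else None
        if phis is not None and phis[2] >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_phi_sc(loci, group_of_pop, n_pops, n_groups, observed, n_perm, rng):
    """Null: permute genes among populations within their group."""
    group_of_gene = [group_of_pop[ld.pop] for ld in loci]
    hits = 0
    for _ in range(n_perm):
        shuffled = []
        for ld, gg in zip(loci, group_of_gene):
            allele = ld.allele.copy()
            for g in range(n_groups):
                mask = gg == g
                allele[mask] = rng.permutation(allele[mask])
            shuffled.append(_LocusData(ld.pop, allele, ld.n_alleles))
        comps, _, _ = _amova_components(shuffled, group_of_pop, n_pops, n_groups)
        phis = _phis(comps) if comps else None
        if phis is not None and phis[1] is not None and phis[1] >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_phi_ct(loci, group_of_pop, n_pops, n_groups, observed, n_perm, rng):
    """Null: permute whole populations among groups."""
    hits = 0
    for _ in range(n_perm):
        relabeled = rng.permutation(group_of_pop)
        comps, _, _ = _amova_components(loci, relabeled, n_pops, n_groups)
        phis = _phis(comps) if comps else None
        if phis is not None and phis[0] >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def amova_report(result: AmovaResult) -> pd.DataFrame:
    """Three-row AMOVA table: df, SS, component, % of total, Phi, p."""
    if result.defined:
        pct = result.percentages
    else:
        pct = (float("nan"),) * 3
    rows = [
        {
            "stratum": "among groups",
            "df": result.df[0],
            "SS": result.ss[0],
            "sigma2": result.sigma_a,
            "percent": pct[0],
            "phi": result.phi_ct,
            "phi_name": "Phi_CT",
            "p": result.p_phi_ct,
        },
        {
            "stratum": "among populations within groups",
            "df": result.df[1],
            "SS": result.ss[1],
            "sigma2": result.sigma_b,
            "percent": pct[1],
            "phi": result.phi_sc,
            "phi_name": "Phi_SC",
            "p": result.p_phi_sc,
        },
        {
            "stratum": "within populations",
            "df": result.df[2],
            "SS": result.ss[2],
            "sigma2": result.sigma_c,
            "percent": pct[2],
            "phi": result.phi_st,
            "phi_name": "Phi_ST",
            "p": result.p_phi_st,
        },
    ]
    return pd.DataFrame(rows)
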