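"""Population-genetic estimators for codominant SSR data.

Implements pairwise differentiation with Jost's D (unbiased two-population
estimator averaged over loci), AMOVA-based pairwise Phi_ST between arbitrary
units, the d/(1-d) linearization used for isolation-by-distance regressions,
hypergeometric rarefaction of allelic richness, and island-model migrant
numbers from FST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import DataModelError, GenotypeDataset, LabeledMatrix

D_AVERAGING = ("arithmetic", "harmonic")


class EstimatorError(ValueError):
    """Raised when a statistic is undefined for the given data."""


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def jost_d_pairwise(
    dataset: GenotypeDataset, averaging: str = "arithmetic"
) -> LabeledMatrix:
    """Pairwise Jost's D over all population pairs.

    Per locus, for the pair (k = 2 demes)::

        H_S   = 1 - 0.5 * sum_a (p1a^2 + p2a^2)
        n~    = harmonic mean of the two sample sizes (individuals)
        H_S^  = 2n~/(2n~ - 1) * H_S
        H_T   = 1 - sum_a ((p1a + p2a)/2)^2
        H_T^  = H_T + H_S^ / (4 n~)
        D_loc = 2 (H_T^ - H_S^) / (1 - H_S^)

    The multi-locus D is the arithmetic mean of per-locus values by
    default; ``averaging="harmonic"`` applies the harmonic mean over the
    loci with positive D (values <= 0 make a harmonic mean undefined and
    fall back to arithmetic for that pair, with a warning).

    Loci with no typed individual in either population of a pair, or with
    H_S^ = 1, are skipped for that pair; a pair with zero usable loci is an
    error.  The bias correction can make D slightly negative; no clamping.
    """
    if averaging not in D_AVERAGING:
        raise DataModelError(f"averaging {averaging!r} not in {D_AVERAGING}")
    npop = len(dataset.populations)
    if npop < 2:
        raise EstimatorError("pairwise D needs at least 2 populations")
    n_loci = len(dataset.loci)
    d_loc = np.full((n_loci, npop, npop), np.nan)
    for l in range(n_loci):
        counts = dataset.allele_counts(l).astype(float)
        genes = counts.sum(axis=1)
        n_ind = genes / 2.0
        with np.errstate(invalid="ignore"):
            p = counts / genes[:, None]
        s = np.nansum(p**2, axis=1)  # sum_a p^2 per population
        j = np.nan_to_num(p) @ np.nan_to_num(p).T
        hs = 1.0 - (s[:, None] + s[None, :]) / 2.0
        ht = 1.0 - (s[:, None] + s[None, :] + 2.0 * j) / 4.0
        with np.errstate(divide="ignore", invalid="ignore"):
            n_h = 2.0 * n_ind[:, None] * n_ind[None, :] / (
                n_ind[:, None] + n_ind[None, :]
            )
            hs_hat = (2.0 * n_h / (2.0 * n_h - 1.0)) * hs
            ht_hat = ht + hs_hat / (4.0 * n_h)
            d = 2.0 * (ht_hat - hs_hat) / (1.0 - hs_hat)
        usable = (n_ind[:, None] > 0) & (n_ind[None, :] > 0) & (hs_hat < 1.0)
        d_loc[l] = np.where(usable, d, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_usable = np.sum(~np.isnan(d_loc), axis=0)
        mean_d = np.nanmean(d_loc, axis=0)
    bad = [
        (dataset.populations[i], dataset.populations[j])
        for i in range(npop)
        for j in range(i + 1, npop)
        if n_usable[i, j] == 0
    ]
    if bad:
        raise EstimatorError(f"zero usable loci for pairs: {bad}")
    if averaging == "harmonic":
        mean_d = _harmonic_over_loci(d_loc, mean_d, dataset.populations)
    np.fill_diagonal(mean_d, 0.0)
    return LabeledMatrix(dataset.populations, mean_d, kind="genetic")


def _harmonic_over_loci(
    d_loc: np.ndarray, arithmetic: np.ndarray, populations: Sequence[str]
) -> np.ndarray:
    out = arithmetic.copy()
    npop = len(populations)
    for i in range(npop):
        for j in range(i + 1, npop):
            vals = d_loc[:, i, j]
            vals = vals[~np.isnan(vals)]
            if (vals <= 0).any():
                warnings.warn(
                    f"non-positive per-locus D for pair "
                    f"({populations[i]}, {populations[j]}); harmonic mean "
                    "undefined, using arithmetic",
                    RuntimeWarning,
                    stacklevel=3,
                )
                continue
            out[i, j] = out[j, i] = vals.size / np.sum(1.0 / vals)
    return out


# ---------------------------------------------------------------------------
# AMOVA-based pairwise Phi_ST
# ---------------------------------------------------------------------------

def _ss_from_counts(counts: np.ndarray) -> np.ndarray:
    """Within-unit sum of squared allele-identity deviations per row.

    For n genes with allele counts c_a the pairwise-mismatch SS is
    (n - sum_a c_a^2 / n) / 2; rows with no genes give 0.
    """
    n = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss = (n - (counts**2).sum(axis=-1) / n) / 2.0
    return np.where(n > 0, ss, 0.0)


def pairwise_fst(
    dataset: GenotypeDataset,
    grouping: Mapping[str, str] | None = None,
) -> tuple[LabeledMatrix, pd.DataFrame]:
    """AMOVA-based Phi_ST between all pairs of units.

    ``grouping`` maps population label to unit label; by default each
    population is its own unit.  Loci are pooled by summing sums of squares
    and degrees of freedom.  Returns the Phi_ST matrix plus a tidy frame
    with one row per pair (undefined pairs, e.g. jointly monomorphic data,
    are flagged and carry NaN in the matrix frame — the LabeledMatrix
    requires finite entries, so an undefined pair is an error there).
    """
    if grouping is None:
        grouping = {p: p for p in dataset.populations}
    units = sorted(set(grouping.values()))
    if len(units) < 2:
        raise EstimatorError("pairwise Phi_ST needs at least 2 units")
    unit_of = np.array(
        [units.index(grouping[p]) for p in dataset.populations], dtype=np.intp
    )
    # per-locus gene counts per unit x allele
    per_locus = []
    for l in range(len(dataset.loci)):
        counts = dataset.allele_counts(l)
        uc = np.zeros((len(units), counts.shape[1]), dtype=float)
        np.add.at(uc, unit_of, counts)
        per_locus.append(uc)
    rows = []
    n = len(units)
    values = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            phi = _phi_st_pair([uc[[i, j]] for uc in per_locus])
            rows.append(
                {
                    "unit_a": units[i],
                    "unit_b": units[j],
                    "phi_st": phi,
                    "defined": phi is not None,
                }
            )
            if phi is None:
                undefined.append((units[i], units[j]))
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = phi
    frame = pd.DataFrame(rows)
    if undefined:
        warnings.warn(
            f"Phi_ST undefined (no molecular variance) for pairs: {undefined}",
            RuntimeWarning,
            stacklevel=2,
        )
        return None, frame  # matrix not constructible with NaN cells
    return LabeledMatrix(units, values, kind="genetic"), frame


def _phi_st_pair(locus_counts: list[np.ndarray]) -> float | None:
    """Two-level AMOVA Phi_ST for one unit pair from per-locus gene counts."""
    ss_within = ss_total = 0.0
    df_within = df_among = 0
    nc_num = 0.0
    for uc in locus_counts:
        genes = uc.sum(axis=1)
        n_tot = genes.sum()
        present = genes > 0
        u = int(present.sum())
        if u < 2 or n_tot == 0:
            continue
        ss_within += _ss_from_counts(uc).sum()
        ss_total += float(_ss_from_counts(uc.sum(axis=0)[None, :])[0])
        df_within += int(n_tot) - u
        df_among += u - 1
        nc_num += n_tot - (genes**2).sum() / n_tot
    if df_among == 0 or df_within == 0:
        return None
    ms_within = ss_within / df_within
    ms_among = (ss_total - ss_within) / df_among
    n_c = nc_num / df_among
    sigma_a = (ms_among - ms_within) / n_c
    total = sigma_a + ms_within
    if total <= 0:
        return None
    return float(sigma_a / total)


# ---------------------------------------------------------------------------
# Linearization and migrants
# ---------------------------------------------------------------------------

def linearize(d: LabeledMatrix) -> LabeledMatrix:
    """Elementwise d/(1-d) off the diagonal, for IBD regressions.

    Slightly negative inputs (bias-corrected D) pass through; any value
    >= 1 is an error naming the pair.
    """
    vals = d.values
    over = np.argwhere(np.triu(vals >= 1.0, k=1))
    if over.size:
        pairs = [(d.labels[i], d.labels[j]) for i, j in over]
        raise EstimatorError(f"distance >= 1 cannot be linearized for pairs: {pairs}")
    out = vals / (1.0 - vals)
    np.fill_diagonal(out, 0.0)
    return LabeledMatrix(d.labels, out, kind="derived")


@dataclass(frozen=True)
class MigrationEstimate:
    """Island-model migrant number for one cluster pair."""

    unit_a: str
    unit_b: str
    fst: float
    migrants: float | None  # None when FST <= 0 leaves M undefined

    @property
    def defined(self) -> bool:
        return self.migrants is not None


def migrants_from_fst(
    fst: LabeledMatrix, multiplier: float = 1.0
) -> list[MigrationEstimate]:
    """M = multiplier * (1 - FST) / (2 FST) for every unit pair.

    The default multiplier 1 reports the classic finite-island number of
    migrants; the exact ploidy constant behind a published "2Nm" can vary
    by tool, hence the knob.  FST <= 0 flags M undefined; FST = 1 gives 0.
    """
    out = []
    n = len(fst.labels)
    for i in range(n):
        for j in range(i + 1, n):
            f = float(fst.values[i, j])
            m = multiplier * (1.0 - f) / (2.0 * f) if f > 0 else None
            out.append(MigrationEstimate(fst.labels[i], fst.labels[j], f, m))
    return out


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

@dataclass
class DiversityTable:
    """Rarefied allelic richness per population.

    ``per_locus`` is populations x kept loci; ``rs`` is the mean over kept
    loci; ``g_size`` the rarefaction depth in genes.
    """

    populations: list[str]
    loci: list[str]
    g_size: int
    per_locus: np.ndarray
    dropped_loci: list[str]

    @property
    def rs(self) -> np.ndarray:
        return self.per_locus.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_locus, index=self.populations, columns=self.loci)
        df.insert(0, "Rs", self.rs)
        return df.rename_axis("site")


def _log_choose(n: np.ndarray, k: int) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(
    dataset: GenotypeDataset, g_size: int | str = "auto"
) -> DiversityTable:
    """Rarefied allelic richness Rs per population (mean over loci).

    Per population and locus with N typed genes and N_a copies of allele a::

        Rs = sum_a [1 - C(N - N_a, g) / C(N, g)]

    i.e. the expected number of distinct alleles in a random subsample of
    g genes.  ``g_size="auto"`` uses the smallest typed gene count over all
    populations and loci, so every population is rarefied to a common base.
    A locus where any population has fewer than g typed genes is dropped
    for all populations (consistent base), with a warning.
    """
    n_loci = len(dataset.loci)
    counts = [dataset.allele_counts(l).astype(float) for l in range(n_loci)]
    genes = np.stack([c.sum(axis=1) for c in counts])  # loci x pops
    if isinstance(g_size, str):
        if g_size != "auto":
            raise DataModelError(f"g_size must be an int or 'auto', got {g_size!r}")
        g = int(genes.min())
        if g < 1:
            raise EstimatorError("a population has no typed genes at some locus")
    else:
        g = int(g_size)
        if g < 1:
            raise DataModelError("g_size must be >= 1")
    keep = np.flatnonzero((genes >= g).all(axis=1))
    dropped = [dataset.loci[l] for l in range(n_loci) if l not in keep]
    if dropped:
        warnings.warn(
            f"loci dropped from rarefaction at g={g}: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not keep.size:
        raise EstimatorError(f"no locus supports rarefaction at g={g}")
    npop = len(dataset.populations)
    per_locus = np.zeros((npop, keep.size))
    for col, l in enumerate(keep):
        c = counts[l]
        n = c.sum(axis=1, keepdims=True)
        remain = n - c
        with np.errstate(invalid="ignore"):
            ratio = np.exp(_log_choose(remain, g) - _log_choose(n, g))
        ratio = np.where(remain >= g, ratio, 0.0)  # allele certain to appear
        per_locus[:, col] = np.where(c > 0, 1.0 - ratio, 0.0).sum(axis=1)
    return DiversityTable(
        populations=list(dataset.populations),
        loci=[dataset.loci[l] for l in keep],
        g_size=g,
        per_locus=per_locus,
        dropped_loci=dropped,
    )
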