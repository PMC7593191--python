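"""Permutation inference on distance matrices.

Mantel and partial Mantel tests with matrix (row/column) permutation,
multiple regression on distance matrices (MRM) on vectorized lower
triangles, and rank tests (Kruskal-Wallis with Dunn's post hoc) comparing
distance values across categorical classes.

The null is built by jointly permuting rows and columns of the *first*
matrix; for small n the tests switch to exact enumeration over all n!
relabelings, in which case the reported p is the exact permutation p-value.
One-tailed (upper) p-values are the default because the working hypotheses
are directional (more distance, more differentiation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .model import DataModelError, LabeledMatrix

P_TAILS = ("upper", "two-sided")


class AssociationError(ValueError):
    pass


@dataclass
class MantelResult:
    r: float
    p: float
    n: int
    n_perm: int
    tail: str
    exact: bool = False
    partial: bool = False

    @property
    def r2(self) -> float:
        return self.r**2


@dataclass
class MrmResult:
    predictors: list[str]
    coefficients: np.ndarray  # raw, intercept first
    std_coefficients: np.ndarray  # standardized betas, no intercept
    r2: float
    p_coefficients: np.ndarray  # per non-intercept coefficient
    p_r2: float
    n: int
    n_perm: int


@dataclass
class RankTestResult:
    h: float
    df: int
    p: float
    class_summary: pd.DataFrame  # class, n, mean, se of values
    dunn: pd.DataFrame  # class_a, class_b, z, p (adjusted)
    adjustment: str


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.tril_indices(values.shape[0], k=-1)
    return values[iu]


def _check_pair(a: LabeledMatrix, b: LabeledMatrix) -> None:
    if a.labels != b.labels:
        raise AssociationError("matrices are not label-aligned; call align() first")
    if len(a.labels) < 4:
        raise AssociationError("Mantel-type tests need n >= 4")
    for name, m in (("first", a), ("second", b)):
        if np.ptp(_tri(m.values)) == 0:
            raise AssociationError(f"constant matrix ({name} argument)")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def _p_from_null(null: np.ndarray, observed: float, tail: str, exact: bool) -> float:
    """Permutation p; the identity permutation counts once in both modes."""
    if tail == "upper":
        hits = int((null >= observed - 1e-12).sum())
    else:
        hits = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    if exact:
        return hits / null.size
    return (hits + 1) / (null.size + 1)


def _permutation_orders(
    n: int, n_perm: int, rng: np.random.Generator, exact: bool
) -> tuple[np.ndarray, bool]:
    """Row orders for the null.  Exact mode enumerates all n! relabelings."""
    if exact:
        return np.array(list(iter_permutations(range(n))), dtype=np.intp), True
    return np.stack([rng.permutation(n) for _ in range(n_perm)]), False


def _should_enumerate(n: int, n_perm: int, exact: bool | None) -> bool:
    if exact is not None:
        return exact
    return math.factorial(n) <= n_perm


# ---------------------------------------------------------------------------
# Mantel family
# ---------------------------------------------------------------------------

def mantel(
    a: LabeledMatrix,
    b: LabeledMatrix,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    tail: str = "upper",
    exact: bool | None = None,
) -> MantelResult:
    """Mantel test: Pearson r of the lower-triangle vectors of A and B.

    The null permutes rows/columns of A jointly; ``exact=None`` switches to
    full enumeration automatically when n! <= n_perm, giving the exact
    permutation p for tiny matrices.
    """
    if tail not in P_TAILS:
        raise DataModelError(f"tail {tail!r} not in {P_TAILS}")
    _check_pair(a, b)
    n = len(a.labels)
    vb = _tri(b.values)
    r_obs = _pearson(_tri(a.values), vb)
    use_exact = _should_enumerate(n, n_perm, exact)
    orders, is_exact = _permutation_orders(
        n, n_perm, np.random.default_rng(seed), use_exact
    )
    null = np.array(
        [_pearson(_tri(a.values[np.ix_(o, o)]), vb) for o in orders]
    )
    p = _p_from_null(null, r_obs, tail, is_exact)
    return MantelResult(r=r_obs, p=p, n=n, n_perm=orders.shape[0], tail=tail, exact=is_exact)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    denom = (1.0 - rac**2) * (1.0 - rbc**2)
    return (rab - rac * rbc) / math.sqrt(denom)


def partial_mantel(
    a: LabeledMatrix,
    b: LabeledMatrix,
    c: LabeledMatrix,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    tail: str = "upper",
    exact: bool | None = None,
) -> MantelResult:
    """First-order partial Mantel correlation r_AB.C with permutation p.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)); the null
    permutes A (the permute-raw-matrix scheme of the classic Mantel
    toolchain) and recomputes the partial statistic each time.
    """
    if tail not in P_TAILS:
        raise DataModelError(f"tail {tail!r} not in {P_TAILS}")
    _check_pair(a, b)
    _check_pair(a, c)
    n = len(a.labels)
    va, vb, vc = _tri(a.values), _tri(b.values), _tri(c.values)
    r_bc = _pearson(vb, vc)
    r_ac = _pearson(va, vc)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise AssociationError("degenerate controlling matrix (|r| = 1)")
    r_obs = _partial_r(_pearson(va, vb), r_ac, r_bc)
    use_exact = _should_enumerate(n, n_perm, exact)
    orders, is_exact = _permutation_orders(
        n, n_perm, np.random.default_rng(seed), use_exact
    )
    null = []
    for o in orders:
        vp = _tri(a.values[np.ix_(o, o)])
        null.append(_partial_r(_pearson(vp, vb), _pearson(vp, vc), r_bc))
    p = _p_from_null(np.array(null), r_obs, tail, is_exact)
    return MantelResult(
        r=r_obs, p=p, n=n, n_perm=orders.shape[0], tail=tail, exact=is_exact,
        partial=True,
    )


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

def mrm(
    y: LabeledMatrix,
    xs: dict[str, LabeledMatrix],
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    standardize: bool = True,
) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS of Y's lower triangle on the predictors' triangles (plus
    intercept).  Coefficient p-values are two-sided on |b| and the model
    R^2 p is upper-tailed, both under joint row/column permutation of Y.
    Standardized betas come from z-scored triangle vectors and are
    invariant to affine rescaling of the predictors.
    """
    labels = y.labels
    for name, x in xs.items():
        if x.labels != labels:
            raise AssociationError(f"predictor {name!r} not label-aligned with Y")
    if not xs:
        raise AssociationError("MRM needs at least one predictor")
    vy = _tri(y.values)
    names = list(xs)
    vX = np.column_stack([_tri(xs[n].values) for n in names])
    if vX.shape[0] <= vX.shape[1]:
        raise AssociationError("more predictors than off-diagonal pairs")
    design = np.column_stack([np.ones(vX.shape[0]), vX])
    if np.linalg.cond(design) > 1e10:
        raise AssociationError("collinear predictors (condition number > 1e10)")

    def fit(target: np.ndarray) -> tuple[np.ndarray, float]:
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ beta
        tss = ((target - target.mean()) ** 2).sum()
        return beta, 1.0 - (resid @ resid) / tss

    beta_obs, r2_obs = fit(vy)
    zx = (vX - vX.mean(axis=0)) / vX.std(axis=0, ddof=1)
    zy = (vy - vy.mean()) / vy.std(ddof=1)
    std_beta, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(zx.shape[0]), zx]), zy, rcond=None
    )

    rng = np.random.default_rng(seed)
    n = len(labels)
    null_b = np.empty((n_perm, len(names)))
    null_r2 = np.empty(n_perm)
    for i in range(n_perm):
        o = rng.permutation(n)
        b, r2 = fit(_tri(y.values[np.ix_(o, o)]))
        null_b[i] = b[1:]
        null_r2[i] = r2
    p_coef = (np.sum(np.abs(null_b) >= np.abs(beta_obs[1:]) - 1e-12, axis=0) + 1) / (
        n_perm + 1
    )
    p_r2 = (np.sum(null_r2 >= r2_obs - 1e-12) + 1) / (n_perm + 1)
    return MrmResult(
        predictors=names,
        coefficients=beta_obs,
        std_coefficients=std_beta[1:] if standardize else np.full(len(names), np.nan),
        r2=float(r2_obs),
        p_coefficients=p_coef,
        p_r2=float(p_r2),
        n=n,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

ADJUSTMENTS = ("none", "bonferroni", "bh")


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    # Benjamini-Hochberg step-up
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(1.0, ranked)
    return out


def kruskal_dunn(
    values: np.ndarray,
    classes: np.ndarray,
    adjustment: str = "none",
) -> RankTestResult:
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise z tests.

    Dunn's statistic for classes i, j with mean ranks R_i, R_j::

        z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with tie term T = sum(t^3 - t) / (12 (N - 1)).  Two-sided normal p per
    pair, optionally Bonferroni or Benjamini-Hochberg adjusted.
    """
    if adjustment not in ADJUSTMENTS:
        raise DataModelError(f"adjustment {adjustment!r} not in {ADJUSTMENTS}")
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    levels = sorted(pd.unique(classes).tolist())
    if len(levels) < 2:
        raise AssociationError("rank test needs at least 2 classes")
    groups = [values[classes == lv] for lv in levels]
    summary = pd.DataFrame(
        {
            "class": levels,
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "se": [g.std(ddof=1) / math.sqrt(g.size) if g.size > 1 else np.nan
                   for g in groups],
        }
    )
    if np.ptp(values) == 0:  # all values equal: H = 0 by convention
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    n_total = values.size
    ranks = stats.rankdata(values)
    mean_rank = {lv: ranks[classes == lv].mean() for lv in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            na, nb = (classes == a).sum(), (classes == b).sum()
            var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
            if var <= 0:
                z, pz = 0.0, 1.0
            else:
                z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var)
                pz = 2.0 * stats.norm.sf(abs(z))
            rows.append({"class_a": a, "class_b": b, "z": z, "p": pz})
    dunn = pd.DataFrame(rows)
    dunn["p"] = _adjust(dunn["p"].to_numpy(), adjustment)
    return RankTestResult(
        h=float(h),
        df=len(levels) - 1,
        p=float(p),
        class_summary=summary,
        dunn=dunn,
        adjustment=adjustment,
    )


def rank_test_by_class(
    d: LabeledMatrix,
    classes: LabeledMatrix,
    adjustment: str = "none",
) -> RankTestResult:
    """Compare off-diagonal distance values across classes of pairs.

    ``classes`` carries an integer level per pair (e.g. the 0-4 linguistic
    dissimilarity); reports the tie-corrected Kruskal-Wallis H over pair
    values grouped by class, Dunn's pairwise comparisons, and per-class
    mean +/- standard error of the distances.
    """
    if d.labels != classes.labels:
        raise AssociationError("distance and class matrices are not label-aligned")
    values = _tri(d.values)
    levels = _tri(classes.values)
    rounded = np.rint(levels)
    if not np.allclose(levels, rounded, atol=1e-9):
        raise AssociationError("class matrix must carry integer levels")
    return kruskal_dunn(values, rounded.astype(int), adjustment)
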