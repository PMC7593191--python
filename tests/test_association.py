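"""Mantel family, MRM, and rank tests against independent oracles."""

from itertools import permutations

import numpy as np
import pytest

from bcpg.association import (
    AssociationError,
    kruskal_dunn,
    mantel,
    mrm,
    partial_mantel,
    rank_test_by_class,
)
from bcpg.model import LabeledMatrix
from conftest import random_labeled_values


def _labeled(rng_or_values, n=None, kind="derived"):
    if isinstance(rng_or_values, np.ndarray):
        vals = rng_or_values
        n = vals.shape[0]
    else:
        vals = random_labeled_values(rng_or_values, n)
    return LabeledMatrix([f"s{i}" for i in range(n)], vals, kind)


def _tri(values):
    iu = np.tril_indices(values.shape[0], k=-1)
    return values[iu]


def _oracle_mantel_exact(a, b):
    """Brute force: Pearson r over every relabeling of A; exact p."""
    n = a.shape[0]
    vb = _tri(b)
    r_obs = np.corrcoef(_tri(a), vb)[0, 1]
    hits = 0
    total = 0
    for order in permutations(range(n)):
        o = np.array(order)
        r = np.corrcoef(_tri(a[np.ix_(o, o)]), vb)[0, 1]
        total += 1
        if r >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / total


def _oracle_partial_exact(a, b, c):
    n = a.shape[0]
    vb, vc = _tri(b), _tri(c)

    def partial(va):
        rab = np.corrcoef(va, vb)[0, 1]
        rac = np.corrcoef(va, vc)[0, 1]
        rbc = np.corrcoef(vb, vc)[0, 1]
        return (rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2))

    r_obs = partial(_tri(a))
    hits = total = 0
    for order in permutations(range(n)):
        o = np.array(order)
        if partial(_tri(a[np.ix_(o, o)])) >= r_obs - 1e-12:
            hits += 1
        total += 1
    return r_obs, hits / total


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_identity_and_affine_invariance():
    rng = np.random.default_rng(0)
    a = _labeled(rng, 8)
    assert mantel(a, a, 99, seed=1).r == pytest.approx(1.0)
    shifted = 2.0 * a.values + 1.0
    np.fill_diagonal(shifted, 0.0)
    b = LabeledMatrix(a.labels, shifted)
    assert mantel(a, b, 99, seed=1).r == pytest.approx(1.0)


@pytest.mark.parametrize("n", [4, 5])
def test_mantel_exact_p_matches_enumeration(n):
    rng = np.random.default_rng(42 + n)
    a = _labeled(rng, n)
    b = _labeled(rng, n)
    res = mantel(a, b, n_perm=5000, seed=0)
    assert res.exact  # n! <= n_perm triggers full enumeration
    r_oracle, p_oracle = _oracle_mantel_exact(a.values, b.values)
    assert res.r == pytest.approx(r_oracle, abs=1e-12)
    assert res.p == pytest.approx(p_oracle, abs=1e-12)


def test_mantel_r_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    rng = np.random.default_rng(17)
    a = _labeled(rng, 12)
    b = _labeled(rng, 12)
    r_skbio, _, _ = skbio_mantel(
        DistanceMatrix(a.values, a.labels),
        DistanceMatrix(b.values, b.labels),
        permutations=0,
    )
    assert mantel(a, b, 99, seed=0).r == pytest.approx(r_skbio, abs=1e-12)


def test_mantel_constant_matrix_rejected():
    flat = np.ones((5, 5)) - np.eye(5)
    a = _labeled(np.random.default_rng(0), 5)
    with pytest.raises(AssociationError, match="constant"):
        mantel(a, LabeledMatrix(a.labels, flat), 99, seed=0)


def test_mantel_symmetry_in_r():
    rng = np.random.default_rng(3)
    a = _labeled(rng, 7)
    b = _labeled(rng, 7)
    assert mantel(a, b, 99, seed=0).r == pytest.approx(mantel(b, a, 99, seed=0).r)


def test_permutation_p_respects_floor():
    rng = np.random.default_rng(5)
    a = _labeled(rng, 10)
    res = mantel(a, a, n_perm=199, seed=0)
    assert res.p >= 1.0 / (199 + 1)


# ---------------------------------------------------------------------------
# Partial Mantel
# ---------------------------------------------------------------------------

def test_partial_mantel_identity():
    rng = np.random.default_rng(8)
    a = _labeled(rng, 8)
    c = _labeled(rng, 8)
    res = partial_mantel(a, a, c, 99, seed=0)
    assert res.r == pytest.approx(1.0)


def test_partial_mantel_zero_by_construction():
    # build B with r_AB = r_AC * r_BC via Gram-Schmidt on triangle vectors
    rng = np.random.default_rng(12)
    n = 10
    va = _tri(random_labeled_values(rng, n))
    vc = _tri(random_labeled_values(rng, n))
    noise = rng.random(va.size)
    za = (va - va.mean()) / va.std()
    zc = (vc - vc.mean()) / vc.std()
    rac = np.corrcoef(va, vc)[0, 1]
    # residual of noise orthogonal to both A and C triangle vectors
    resid = noise - np.polyval(np.polyfit(za, noise, 1), za)
    resid -= np.polyval(np.polyfit(zc, resid, 1), zc)
    resid -= np.polyval(np.polyfit(za, resid, 1), za)  # second sweep
    vb = zc + 0.5 * resid / resid.std()  # B correlates with C only
    mat = np.zeros((n, n))
    mat[np.tril_indices(n, k=-1)] = vb
    mat = mat + mat.T
    b = LabeledMatrix([f"s{i}" for i in range(n)], mat)
    a = LabeledMatrix(b.labels, _sym_from_tri(va, n))
    c = LabeledMatrix(b.labels, _sym_from_tri(vc, n))
    res = partial_mantel(a, b, c, 199, seed=0)
    assert abs(res.r) < 0.05


def _sym_from_tri(v, n):
    mat = np.zeros((n, n))
    mat[np.tril_indices(n, k=-1)] = v
    return mat + mat.T


def test_partial_mantel_exact_p_matches_enumeration():
    rng = np.random.default_rng(77)
    a = _labeled(rng, 5)
    b = _labeled(rng, 5)
    c = _labeled(rng, 5)
    res = partial_mantel(a, b, c, n_perm=5000, seed=0)
    assert res.exact
    r_oracle, p_oracle = _oracle_partial_exact(a.values, b.values, c.values)
    assert res.r == pytest.approx(r_oracle, abs=1e-12)
    assert res.p == pytest.approx(p_oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# MRM
# ---------------------------------------------------------------------------

def test_mrm_exact_linear_relation():
    rng = np.random.default_rng(2)
    x = _labeled(rng, 8)
    y = LabeledMatrix(x.labels, 2.0 * x.values)
    res = mrm(y, {"x": x}, 99, seed=0)
    assert res.r2 == pytest.approx(1.0)
    assert res.coefficients[1] == pytest.approx(2.0)


def test_mrm_single_predictor_r2_equals_mantel_r2():
    rng = np.random.default_rng(21)
    y = _labeled(rng, 9)
    x = _labeled(rng, 9)
    res = mrm(y, {"x": x}, 99, seed=0)
    assert res.r2 == pytest.approx(mantel(y, x, 99, seed=0).r2, abs=1e-12)


def test_mrm_matches_normal_equation_oracle():
    rng = np.random.default_rng(33)
    y = _labeled(rng, 5)
    x1 = _labeled(rng, 5)
    x2 = _labeled(rng, 5)
    res = mrm(y, {"x1": x1, "x2": x2}, 99, seed=0)
    design = np.column_stack(
        [np.ones(10), _tri(x1.values), _tri(x2.values)]
    )
    beta = np.linalg.solve(design.T @ design, design.T @ _tri(y.values))
    np.testing.assert_allclose(res.coefficients, beta, atol=1e-10)


def test_mrm_collinear_predictors_rejected():
    rng = np.random.default_rng(4)
    x = _labeled(rng, 6)
    x2 = LabeledMatrix(x.labels, 3.0 * x.values)
    with pytest.raises(AssociationError, match="collinear"):
        mrm(x, {"a": x, "b": x2}, 9, seed=0)


def test_mrm_standardized_beta_scale_invariant():
    rng = np.random.default_rng(6)
    y = _labeled(rng, 8)
    x1 = _labeled(rng, 8)
    x2 = _labeled(rng, 8)
    res1 = mrm(y, {"x1": x1, "x2": x2}, 9, seed=0)
    scaled = LabeledMatrix(x1.labels, 1000.0 * x1.values)
    res2 = mrm(y, {"x1": scaled, "x2": x2}, 9, seed=0)
    np.testing.assert_allclose(res1.std_coefficients, res2.std_coefficients, atol=1e-10)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def test_kruskal_all_equal_is_degenerate():
    res = kruskal_dunn(np.ones(10), np.array([0] * 5 + [1] * 5))
    assert res.h == 0.0
    assert res.p == 1.0


def test_kruskal_fully_separated_two_classes():
    # ranks 1-5 vs 6-10: H = 12/(10*11) * (15^2/5 + 40^2/5) - 3*11 = 6.8181...
    values = np.array([1, 2, 3, 4, 5, 10, 11, 12, 13, 14], dtype=float)
    classes = np.array([0] * 5 + [1] * 5)
    res = kruskal_dunn(values, classes)
    assert res.h == pytest.approx(12.0 / 110.0 * (45.0 + 320.0) - 33.0, abs=1e-10)
    assert res.h == pytest.approx(6.81818181, abs=1e-6)
    assert res.df == 1


def test_dunn_z_hand_computation():
    # no ties: T = 0; mean ranks 3 and 8, var = (10*11/12)(1/5+1/5)
    values = np.array([1, 2, 3, 4, 5, 10, 11, 12, 13, 14], dtype=float)
    classes = np.array([0] * 5 + [1] * 5)
    res = kruskal_dunn(values, classes)
    z = res.dunn.loc[0, "z"]
    expected = (3.0 - 8.0) / np.sqrt((10 * 11 / 12.0) * (2.0 / 5.0))
    assert z == pytest.approx(expected, abs=1e-10)


def test_rank_test_by_class_means_exact():
    d_vals = np.array(
        [
            [0.0, 0.1, 0.2, 0.3],
            [0.1, 0.0, 0.4, 0.5],
            [0.2, 0.4, 0.0, 0.6],
            [0.3, 0.5, 0.6, 0.0],
        ]
    )
    c_vals = np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ],
        dtype=float,
    )
    d = LabeledMatrix(list("abcd"), d_vals)
    c = LabeledMatrix(list("abcd"), c_vals)
    res = rank_test_by_class(d, c)
    means = dict(zip(res.class_summary["class"], res.class_summary["mean"]))
    # class 0 pairs: (b,a)=0.1, (d,c)=0.6; class 1: 0.2, 0.3, 0.4, 0.5
    assert means[0] == pytest.approx(0.35)
    assert means[1] == pytest.approx(0.35)


def test_rank_test_requires_two_classes():
    d = _labeled(np.random.default_rng(0), 4)
    c = LabeledMatrix(d.labels, np.zeros((4, 4)))
    with pytest.raises(AssociationError, match="2 classes"):
        rank_test_by_class(d, c)
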