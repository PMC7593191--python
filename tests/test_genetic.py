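"""Genetic estimators: Jost's D, Phi_ST, linearization, rarefaction, migrants."""

import math
from itertools import combinations

import numpy as np
import pytest

from bcpg.genetic import (
    EstimatorError,
    allelic_richness,
    jost_d_pairwise,
    linearize,
    migrants_from_fst,
    pairwise_fst,
)
from bcpg.model import GenotypeDataset, LabeledMatrix
from bcpg.simulate import SimulationConfig, simulate_bundle
from conftest import two_pop_dataset


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

def test_jost_d_shared_monomorphism_is_zero(shared_monomorphic):
    d = jost_d_pairwise(shared_monomorphic)
    assert d["A", "B"] == pytest.approx(0.0, abs=1e-12)


def test_jost_d_fixed_different_alleles_is_one(fixed_different):
    d = jost_d_pairwise(fixed_different)
    assert d["A", "B"] == pytest.approx(1.0, abs=1e-12)


def test_jost_d_identical_frequencies_small_negative_bias():
    # p = (0.5, 0.5) in both populations, n = 10 each; hand oracle:
    # H_S = 0.5, n~ = 10, H_S^ = (20/19)*0.5, H_T = 0.5,
    # H_T^ = H_T + H_S^/40, D = 2(H_T^ - H_S^)/(1 - H_S^) = -1/18
    # 10 individuals per population, allele 1 carried by 10 of 20 genes
    calls = [[("1", "2")]] * 4 + [[("1", "1")]] * 3 + [[("2", "2")]] * 3
    ds = two_pop_dataset(calls, list(calls))
    d = jost_d_pairwise(ds)
    assert d["A", "B"] == pytest.approx(-1.0 / 18.0, abs=1e-12)


def test_jost_d_invariant_under_relabeling(small_bundle):
    genotypes = small_bundle[0]
    d = jost_d_pairwise(genotypes)
    # permute population order: matrix permutes consistently
    perm = list(reversed(genotypes.populations))
    d_perm = jost_d_pairwise(genotypes.subset_populations(perm))
    for a, b in combinations(genotypes.populations[:6], 2):
        assert d[a, b] == pytest.approx(d_perm[a, b], abs=1e-12)


def test_jost_d_bounded_and_monotone_in_population_divergence():
    means = []
    for f_pop in (0.02, 0.08, 0.2):
        vals = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_phyla=2,
                n_populations=8,
                individuals_per_population=12,
                n_loci=8,
                alleles_per_locus=6,
                f_phylum=0.0,
                f_pop=f_pop,
                ibd_range=0.0,
                missing_rate=0.0,
                rng_seed=seed,
            )
            g = simulate_bundle(cfg)[0]
            d = jost_d_pairwise(g)
            assert d.condensed().max() <= 1.0 + 1e-12
            vals.append(d.condensed().mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_jost_d_zero_usable_loci_is_error():
    ds = two_pop_dataset([[None]], [[("1", "1")]])
    with pytest.raises(EstimatorError, match="zero usable loci"):
        jost_d_pairwise(ds)


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, expected", [(0.0, 0.0), (0.5, 1.0), (0.086, 0.086 / 0.914)])
def test_linearize_values(x, expected):
    vals = np.array([[0.0, x], [x, 0.0]])
    out = linearize(LabeledMatrix(["a", "b"], vals))
    assert out["a", "b"] == pytest.approx(expected, rel=1e-12)
    assert linearize(LabeledMatrix(["a", "b"], vals)).values[0, 0] == 0.0


def test_linearize_accepts_small_negative_and_rejects_one():
    neg = LabeledMatrix(["a", "b"], np.array([[0.0, -0.02], [-0.02, 0.0]]))
    assert linearize(neg)["a", "b"] == pytest.approx(-0.02 / 1.02)
    bad = LabeledMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(EstimatorError, match=r"\('a', 'b'\)"):
        linearize(bad)


# ---------------------------------------------------------------------------
# Rarefied allelic richness
# ---------------------------------------------------------------------------

def _exhaustive_rs(counts: list[int], g: int) -> float:
    """Oracle: mean distinct alleles over all C(N, g) gene subsets."""
    genes = [a for a, c in enumerate(counts) for _ in range(c)]
    subsets = list(combinations(range(len(genes)), g))
    return float(
        np.mean([len({genes[i] for i in sub}) for sub in subsets])
    )


def _one_pop(counts: list[int]) -> GenotypeDataset:
    genes = [str(a) for a, c in enumerate(counts) for _ in range(c)]
    assert len(genes) % 2 == 0
    calls = [[(genes[2 * i], genes[2 * i + 1])] for i in range(len(genes) // 2)]
    return GenotypeDataset.from_calls(["L1"], {"P": calls})


@pytest.mark.parametrize(
    "counts, g",
    [([2, 2], 2), ([4, 2], 3), ([3, 3, 2], 4), ([1, 1, 2], 2), ([6], 3)],
)
def test_rarefaction_matches_exhaustive_enumeration(counts, g):
    ds = _one_pop(counts)
    table = allelic_richness(ds, g)
    assert table.per_locus[0, 0] == pytest.approx(_exhaustive_rs(counts, g), abs=1e-10)


def test_rarefaction_exact_value_five_thirds():
    # N = 4 genes, counts {2, 2}, g = 2: all 6 subsets give (1+2+2+2+2+1)/6
    table = allelic_richness(_one_pop([2, 2]), 2)
    assert table.per_locus[0, 0] == pytest.approx(5.0 / 3.0, abs=1e-12)


def test_rarefaction_full_depth_counts_distinct_alleles():
    table = allelic_richness(_one_pop([3, 2, 1]), 6)
    assert table.per_locus[0, 0] == pytest.approx(3.0, abs=1e-12)


def test_rarefaction_monotone_in_subsample_size():
    ds = _one_pop([5, 3, 2])
    values = [allelic_richness(ds, g).per_locus[0, 0] for g in range(1, 11)]
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    assert values[0] == pytest.approx(1.0)  # one gene: one allele


def test_rarefaction_log_space_matches_big_integer_ratios():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n_alleles = int(rng.integers(1, 6))
        counts = rng.multinomial(2 * int(rng.integers(3, 15)), np.ones(n_alleles) / n_alleles)
        counts = [int(c) for c in counts if c > 0]
        n = sum(counts)
        g = int(rng.integers(1, n + 1))
        expected = sum(
            1.0 - math.comb(n - c, g) / math.comb(n, g) for c in counts
        )
        got = allelic_richness(_one_pop(counts), g).per_locus[0, 0]
        assert got == pytest.approx(expected, abs=1e-10)


def test_rarefaction_drops_shallow_locus_consistently():
    calls_a = [[("1", "2"), ("1", "1")], [("1", "1"), None]]
    calls_b = [[("2", "2"), None], [("1", "2"), None]]  # locus 2 untyped in B
    ds = two_pop_dataset(calls_a, calls_b)
    with pytest.warns(RuntimeWarning, match="dropped"):
        table = allelic_richness(ds, 2)
    assert table.loci == ["L1"]
    assert table.dropped_loci == ["L2"]


# ---------------------------------------------------------------------------
# Pairwise Phi_ST and migrants
# ---------------------------------------------------------------------------

def test_phi_st_fixed_different_alleles_is_one(fixed_different):
    m, frame = pairwise_fst(fixed_different)
    assert m["A", "B"] == pytest.approx(1.0, abs=1e-12)
    assert frame["defined"].all()


def test_phi_st_random_split_of_one_population_is_near_zero():
    cfg = SimulationConfig(
        n_phyla=1,
        n_populations=2,
        individuals_per_population=30,
        n_loci=200,
        alleles_per_locus=5,
        f_phylum=0.0,
        f_pop=0.0,
        ibd_range=0.0,
        missing_rate=0.0,
        rng_seed=3,
    )
    g = simulate_bundle(cfg)[0]  # both pops sample identical frequencies
    m, _ = pairwise_fst(g)
    assert abs(m.values[0, 1]) < 0.02


def test_phi_st_matches_brute_force_on_tiny_instance():
    # 3 populations, 1 locus, <= 12 genes: compare against explicit
    # pairwise-difference sums and the EMS solution computed by hand
    calls = {
        "P1": [[("1", "1")], [("1", "2")]],
        "P2": [[("2", "2")], [("2", "1")]],
        "P3": [[("1", "1")]],
    }
    ds = GenotypeDataset.from_calls(["L1"], calls)
    m, _ = pairwise_fst(ds)
    genes = {
        "P1": ["1", "1", "1", "2"],
        "P2": ["2", "2", "2", "1"],
        "P3": ["1", "1"],
    }
    for a, b in combinations(genes, 2):
        ga, gb = genes[a], genes[b]
        pooled = ga + gb
        ss_w = sum(
            sum(x != y for x, y in combinations(g, 2)) / len(g) for g in (ga, gb)
        )
        ss_t = sum(x != y for x, y in combinations(pooled, 2)) / len(pooled)
        n = len(pooled)
        ms_w = ss_w / (n - 2)
        ms_a = (ss_t - ss_w) / 1
        n_c = (n - (len(ga) ** 2 + len(gb) ** 2) / n) / 1
        sigma_a = (ms_a - ms_w) / n_c
        expected = sigma_a / (sigma_a + ms_w)
        assert m[a, b] == pytest.approx(expected, abs=1e-12)


def test_migrants_closed_forms():
    vals = np.array(
        [
            [0.0, 0.2, 1.0, 0.04],
            [0.2, 0.0, 0.5, 0.5],
            [1.0, 0.5, 0.0, 0.5],
            [0.04, 0.5, 0.5, 0.0],
        ]
    )
    m = LabeledMatrix(list("abcd"), vals)
    est = {(e.unit_a, e.unit_b): e for e in migrants_from_fst(m)}
    assert est[("a", "b")].migrants == pytest.approx(2.0)
    assert est[("a", "c")].migrants == pytest.approx(0.0)
    assert est[("a", "d")].migrants == pytest.approx(12.0)


def test_migrants_undefined_for_nonpositive_fst():
    vals = np.array([[0.0, -0.01], [-0.01, 0.0]])
    (est,) = migrants_from_fst(LabeledMatrix(["a", "b"], vals))
    assert not est.defined and est.migrants is None
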