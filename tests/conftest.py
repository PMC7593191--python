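import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bcpg.model import GenotypeDataset, LanguageHierarchy
from bcpg.simulate import SimulationConfig, simulate_bundle

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Down-scaled landscape for fast end-to-end tests."""
    return SimulationConfig(
        n_phyla=3,
        families_per_phylum=2,
        languages_per_family=2,
        n_populations=24,
        individuals_per_population=10,
        n_loci=6,
        alleles_per_locus=6,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return simulate_bundle(small_cfg)


@pytest.fixture(scope="session")
def toy_hierarchy() -> LanguageHierarchy:
    """Fragment of the Eurasian classification used in the examples."""
    return LanguageHierarchy(
        {
            "Hungarian": ("Finno-Ugric-core", "Finno-Ugric", "Uralic"),
            "Italian": (None, "Italic", "Indo-European"),
            "Spanish": (None, "Italic", "Indo-European"),
            "Russian": ("East-Slavic", "Balto-Slavic", "Indo-European"),
            "Slovak": ("Western-Slavic", "Balto-Slavic", "Indo-European"),
            "Kyrgyz": ("Western-Turkic", "Turkic", "Altaic"),
            "Turkish": ("Oghuz-Turkish", "Turkic", "Altaic"),
            "Georgian": (None, "Karto-Zan", "Kartvelian"),
        }
    )


def two_pop_dataset(calls_a, calls_b, loci=None) -> GenotypeDataset:
    loci = loci or [f"L{i + 1}" for i in range(len(calls_a[0]))]
    return GenotypeDataset.from_calls(loci, {"A": calls_a, "B": calls_b})


@pytest.fixture
def fixed_different() -> GenotypeDataset:
    """Two populations fixed for different alleles at one locus."""
    return two_pop_dataset(
        [[("1", "1")] for _ in range(5)], [[("2", "2")] for _ in range(5)]
    )


@pytest.fixture
def shared_monomorphic() -> GenotypeDataset:
    return two_pop_dataset(
        [[("1", "1")] for _ in range(5)], [[("1", "1")] for _ in range(5)]
    )


def random_labeled_values(rng: np.random.Generator, n: int) -> np.ndarray:
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
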