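import numpy as np
import pytest

from comorbnet import GeneratorConfig, default_catalog, simulate_cohort
from comorbnet.cohort import CatalogEntry, DiseaseCatalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_catalog():
    """Seven latent diseases plus the index entry: small enough for
    brute-force all-pairs oracles."""
    entries = [CatalogEntry("copd", "COPD", False, True, ("490-492", "494", "496"))] + [
        CatalogEntry(f"d{i}", f"Condition {i}", i % 3 == 0, False) for i in range(1, 8)
    ]
    return DiseaseCatalog(entries)


@pytest.fixture(scope="session")
def cohort_small(catalog):
    """2,000-per-group synthetic cohort on the default catalog."""
    records, _ = simulate_cohort(GeneratorConfig(n_per_group=2000, seed=42), catalog)
    return records


@pytest.fixture(scope="session")
def cohort_20k(catalog):
    """Study-scale synthetic cohort (20,000 per group) for the stratified
    and acceptance checks."""
    records, _ = simulate_cohort(GeneratorConfig(n_per_group=20000, seed=11), catalog)
    return records


def make_independent_matrix(rng, n_persons, n_diseases, p_low=0.2, p_high=0.8):
    """Binary matrix with mutually independent columns (null network)."""
    p = rng.uniform(p_low, p_high, size=n_diseases)
    return (rng.random((n_persons, n_diseases)) < p).astype(np.uint8)
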