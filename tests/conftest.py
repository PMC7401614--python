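import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import aridinet as an

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_counts():
    """4 OTUs x 4 samples, hand-sized."""
    return pd.DataFrame(
        {"s1": [5, 0, 3, 2], "s2": [1, 3, 0, 6], "s3": [0, 0, 4, 6], "s4": [2, 2, 2, 2]},
        index=["otu_a", "otu_b", "otu_c", "otu_d"],
    )


@pytest.fixture
def small_taxonomy():
    rows = {
        "otu_a": ["Bacteria", "Proteobacteria", "Alphaproteobacteria", None, None, None],
        "otu_b": ["Bacteria", "Cyanobacteria", "Chloroplast", None, None, None],
        "otu_c": ["Bacteria", "Actinobacteria", None, None, None, None],
        "otu_d": ["Bacteria", "Proteobacteria", "Epsilonproteobacteria", None, None, None],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(an.RANKS))


@pytest.fixture(scope="session")
def synthetic_default():
    """Default-condition synthetic dataset, shared across tests."""
    cfg = an.SyntheticConfig(seed=1)
    counts, meta, tax, soil, truth = an.generate_dataset(cfg)
    return cfg, counts, meta, tax, soil, truth


@pytest.fixture(scope="session")
def synthetic_trends(synthetic_default):
    """Trend classifications for both compartments on the default dataset."""
    _, counts, meta, tax, _, _ = synthetic_default
    rel = an.relative_abundance(an.filter_organelle_otus(counts, tax))
    return rel, meta, {c: an.classify_trend(rel, meta, c) for c in an.COMPARTMENTS}


def random_metadata(n_sites_per_zone=1, samples_per_site=2, compartment="rhizosphere"):
    rows = []
    for zone in an.ZONES:
        for i in range(n_sites_per_zone):
            site = f"{zone[:2]}{i}"
            for j in range(samples_per_site):
                rows.append((f"{site}_{j}", compartment, zone, site))
    meta = pd.DataFrame(rows, columns=["sample_id", "compartment", "zone", "site_id"])
    meta = meta.set_index("sample_id")
    meta["zone_rank"] = meta["zone"].map(an.ZONE_RANK)
    return meta


@pytest.fixture
def zone_metadata():
    return random_metadata()


def random_counts(rng, n_otus, samples, max_count=50):
    return pd.DataFrame(
        rng.integers(0, max_count, size=(n_otus, len(samples))),
        index=[f"o{i}" for i in range(n_otus)],
        columns=samples,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
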