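import numpy as np
import pandas as pd
import pytest

from miratlas.data import CountTable, rpmm_normalize
from miratlas.simulate import default_config, simulate_atlas


@pytest.fixture
def tiny_table():
    """3 features x 4 samples with two feature classes."""
    counts = pd.DataFrame(
        [[10, 0, 5, 3], [5, 15, 0, 7], [85, 85, 95, 90]],
        index=["mirA", "mirB", "trnX"],
        columns=["s1", "s2", "s3", "s4"],
    )
    fclass = pd.Series(["miRNA", "miRNA", "tRNA"], index=counts.index)
    return CountTable(counts, fclass)


@pytest.fixture
def tiny_meta():
    return pd.DataFrame({
        "region": ["pons", "pons", "medulla", "medulla"],
        "age_months": [3, 12, 3, 12],
        "sex": ["male", "female", "male", "female"],
        "cohort": ["aging"] * 4,
        "aligned_reads": [3_000_000, 2_500_000, 4_000_000, 2_000_001],
    }, index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))


@pytest.fixture(scope="session")
def sim_atlas():
    """One shrunk synthetic atlas shared across tests (seed 11)."""
    cfg = default_config(seed=11)
    table, meta, truth = simulate_atlas(cfg)
    return cfg, table, meta, truth


@pytest.fixture(scope="session")
def sim_expr(sim_atlas):
    _, table, _, _ = sim_atlas
    return rpmm_normalize(table)


def random_count_fixture(rng, n_features=10, n_samples=12, n_regions=3):
    """Small random count table + metadata for oracle equivalence tests."""
    counts = pd.DataFrame(
        rng.integers(0, 12, size=(n_features, n_samples)),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    table = CountTable(counts, pd.Series("miRNA", index=counts.index))
    meta = pd.DataFrame({
        "region": rng.choice([f"r{k}" for k in range(n_regions)], n_samples),
        "age_months": rng.choice([3, 12, 21], n_samples),
        "sex": rng.choice(["male", "female"], n_samples),
        "cohort": "aging",
        "aligned_reads": rng.integers(1_000_000, 5_000_000, n_samples),
    }, index=pd.Index(counts.columns, name="sample_id"))
    return table, meta
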