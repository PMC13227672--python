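import numpy as np
import pandas as pd
import pytest

from omicsblup.synthdata import SimulationConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """One-company, three-batch cohort used across the suite."""
    defaults = dict(
        n_companies=1,
        batches_per_company=[3],
        animals_per_batch=60,
        pens_per_batch=5,
        litters_per_batch=8,
        n_snps=400,
        maf_range=(0.1, 0.5),
        n_features_per_layer={"transcriptome": 200},
        genetic_anchor={"transcriptome": 0.7},
        true_varcomps={
            "growth": {"G": 0.25, "T": 0.15, "pen": 0.05, "litter": 0.05,
                       "residual": 0.50},
            "mortality": {"G": 0.10, "T": 0.30, "pen": 0.05, "litter": 0.05,
                          "residual": 0.50},
        },
        binary_traits={"mortality": 0.8},
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_design(n: int, n_batches: int = 3, pens_per_batch: int = 2,
               seed: int = 0) -> pd.DataFrame:
    """Minimal hand-rolled design table for unit tests."""
    rng = np.random.default_rng(seed)
    batches = [f"B{i % n_batches + 1}" for i in range(n)]
    return pd.DataFrame({
        "animal_id": [f"A{i + 1:03d}" for i in range(n)],
        "company": "A",
        "batch": batches,
        "pen": [f"P{i % pens_per_batch + 1}" for i in range(n)],
        "litter": [f"L{i % 4 + 1}" for i in range(n)],
        "entry_age": rng.integers(24, 31, size=n),
        "toy": rng.integers(0, 2, size=n).astype(str),
        "rin": np.round(rng.normal(8, 0.5, size=n), 2),
    })
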