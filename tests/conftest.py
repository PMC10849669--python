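import numpy as np
import pytest

from msigkit import (
    ChannelSchema,
    MutationalCatalog,
    SimulationSpec,
    generate_catalog,
)


@pytest.fixture(scope="session")
def toy_schema() -> ChannelSchema:
    """A 6-channel SBS-style schema, one channel per substitution class."""
    return ChannelSchema(
        "TOY6",
        (
            "A[C>A]A", "A[C>G]A", "A[C>T]A",
            "A[T>A]A", "A[T>C]A", "A[T>G]A",
        ),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated SBS96 catalog with ground truth (12 samples)."""
    spec = SimulationSpec(n_samples=12, seed=101)
    return generate_catalog(spec)


@pytest.fixture
def toy_catalog(toy_schema) -> MutationalCatalog:
    counts = np.array(
        [
            [5, 0, 3, 0, 2, 0],
            [0, 1, 0, 4, 0, 0],
            [2, 2, 2, 2, 2, 2],
        ]
    )
    return MutationalCatalog(
        toy_schema,
        ["s1", "s2", "s3"],
        counts,
        metadata={s: {"cancer_type": g} for s, g in
                  zip(["s1", "s2", "s3"], ["lung", "lung", "skin"])},
    )


def random_catalog(rng: np.random.Generator, schema: ChannelSchema,
                   n_samples: int = 5, max_count: int = 50) -> MutationalCatalog:
    counts = rng.integers(0, max_count, size=(n_samples, len(schema)))
    ids = [f"R{i}" for i in range(n_samples)]
    return MutationalCatalog(schema, ids, counts)
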