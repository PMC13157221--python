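from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nrsmeta import (
    FCMConfig,
    MixtureConfig,
    STMMConfig,
    SequenceRecord,
    build_bundle,
    simulate_genomes,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def record(seq: str, rec_id: str = "r") -> SequenceRecord:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return SequenceRecord(rec_id, "", np.array([lut[c] for c in seq], dtype=np.int8))


@pytest.fixture
def make_record():
    return record


@pytest.fixture(scope="session")
def small_mixture() -> MixtureConfig:
    """A cheap FCM+STMM ensemble (orders <= 3) for fast unit tests."""
    return MixtureConfig(
        models=(
            FCMConfig(order=1, alpha=1.0),
            FCMConfig(order=3, alpha=1.0 / 16.0),
            STMMConfig(order=3, alpha=1.0 / 16.0, max_substitutions=2, window=8,
                       share_counts_with=1),
        ),
        gamma=0.95,
    )


@pytest.fixture(scope="session")
def two_genomes() -> list[SequenceRecord]:
    return simulate_genomes(2, 4000, seed=101)


@pytest.fixture(scope="session")
def small_bundle(two_genomes, small_mixture):
    return build_bundle([two_genomes[0]], small_mixture, label="g1")
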