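from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridec import KmerIndex, KmerSpec, count_kmers

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_index(reads, k=5, solid_threshold=1, require_arcs=False) -> KmerIndex:
    return count_kmers(reads, KmerSpec(k=k, solid_threshold=solid_threshold,
                                       require_arcs=require_arcs))


def perfect_index(genome: str, k: int, solid_threshold: int = 1,
                  require_arcs: bool = False) -> KmerIndex:
    """Index in which every genome k-mer counts exactly ``solid_threshold``."""
    return make_index([genome] * solid_threshold, k=k,
                      solid_threshold=solid_threshold,
                      require_arcs=require_arcs)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    g = np.random.default_rng(42)
    return random_dna(g, 2_000)
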