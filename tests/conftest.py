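from __future__ import annotations

import numpy as np
import pytest

from mosaicscan import Genome, SimConfig, simulate_cohort
from mosaicscan.pipeline import RunConfig, run_scan

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution to a uniformly chosen different base."""
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, size=len(seq))
    codes = np.searchsorted(BASES, arr)
    arr[hit] = BASES[(codes[hit] + shift[hit]) % 4]
    return "".join(arr)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_pairs=3, genome_len=20_000, n_mosaics=2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scan(small_cohort):
    genomes, truth = small_cohort
    config = RunConfig(
        skip_ani=True,
        pairs=[(p.g1_id, p.g2_id) for p in truth.pairs],
        proximal_cols=250,
    )
    return run_scan(genomes, config)
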