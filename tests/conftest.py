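import numpy as np
import pytest
from hypothesis import settings

import diphase as dp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n: int) -> str:
    return "".join(np.frombuffer(b"ACGT", dtype="S1")[
        rng.integers(0, 4, size=n)].astype(str))


@pytest.fixture(scope="session")
def small_diploid():
    """A 30-kbp diploid at 1% heterozygosity with truth tracking."""
    spec = dp.DiploidGenomeSpec(length=30_000, snv_rate=0.01, seed=424242)
    return dp.simulate_diploid(spec)


@pytest.fixture(scope="session")
def small_libraries(small_diploid):
    haps = (small_diploid.hap_a, small_diploid.hap_b)
    pe = dp.simulate_reads(haps, dp.LibrarySpec(
        "paired-end", coverage=40, read_length=250, insert_mean=400,
        insert_sd=40, name="pe"), seed=7)
    mp = dp.simulate_reads(haps, dp.LibrarySpec(
        "mate-pair", coverage=40, read_length=100, insert_mean=3000,
        insert_sd=300, name="mp"), seed=8)
    return pe, mp


@pytest.fixture(scope="session")
def small_pipeline_result(small_diploid, small_libraries):
    """One full pipeline run on the 30-kbp diploid, shared across tests."""
    pe, mp = small_libraries
    return dp.run_pipeline([pe, mp], dp.PipelineConfig(genome_size=30_000))
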