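import numpy as np
import pandas as pd
import pytest

from dmrkit import SimConfig, simulate_genome, simulate_methylome


def small_config(**overrides) -> SimConfig:
    """A fast 200-kb study used by integration tests."""
    base = dict(
        chrom_lengths={"chr1": 200_000},
        control_length=20_000,
        n_dmrs_per_context={"CG": 5, "CHG": 5, "CHH": 5},
        n_hv=5,
        n_snps=20,
        n_clusters=40,
        n_background_reads=4_000,
        n_dsrs=4,
        seed=42,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_genome(small_config())


@pytest.fixture(scope="session")
def small_methylome(small_sim):
    return simulate_methylome(small_sim, "wt", 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


def make_methylome_frame(rows):
    """Helper: records frame from (chrom, pos, strand, context, a, b) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )
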