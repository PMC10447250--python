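import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epimemory.types import GenomeSpec, MethylomeTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_genome() -> GenomeSpec:
    return GenomeSpec(
        contigs=(("chr1", 500_000), ("chr2", 300_000), ("spike", 50_000)),
        spike_in_contig="spike",
    )


def make_table(rows, sample_id="s", nonconversion=None) -> MethylomeTable:
    """Rows of (chrom, pos, strand, context, dinucleotide, mc, cov)."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "dinucleotide", "mc", "cov"]
    )
    return MethylomeTable(df, sample_id=sample_id, nonconversion=nonconversion)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
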