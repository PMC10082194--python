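import numpy as np
import pandas as pd
import pytest

from hrdkit.genome import load_genome


@pytest.fixture(scope="session")
def toy_genome():
    return load_genome("toy3")


@pytest.fixture(scope="session")
def hg19():
    return load_genome("hg19")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230407)


def make_segments(rows):
    """Segment DataFrame from (chrom, start, end, level, n_bins) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "level", "n_bins"])
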