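import numpy as np
import pandas as pd
import pytest

from oriscan.intervals import GenomeLayout, IntervalSet, MappabilityMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout_1mb():
    return GenomeLayout.from_dict({"chr1": 1_000_000})


@pytest.fixture
def layout_two_chroms():
    return GenomeLayout.from_dict({"chr1": 500_000, "chr2": 300_000})


def random_intervals(rng, n, layout, max_len=5000, label="rand"):
    """Uniform random intervals on a layout (may overlap each other)."""
    chroms = rng.choice(layout.chrom_names, size=n)
    starts = np.empty(n, dtype=np.int64)
    lengths = rng.integers(1, max_len, size=n)
    for i, c in enumerate(chroms):
        starts[i] = rng.integers(0, layout.length(str(c)) - lengths[i])
    return IntervalSet(
        pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + lengths}
        ),
        label=label,
    )


@pytest.fixture
def whole_genome_mask(layout_1mb):
    return MappabilityMask.whole_genome(layout_1mb)
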