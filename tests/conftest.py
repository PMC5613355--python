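import numpy as np
import pandas as pd
import pytest

import duomark as dm


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """Compact genome for unit tests: same structure as the defaults but a
    single 1-Mb chromosome and fewer factor sites, so each test stays fast."""
    return dm.SimConfig(chrom_sizes={"chrS": 1_000_000}, n_factor_sites=50,
                        seed=42)


@pytest.fixture
def small_layout(small_config):
    return dm.build_layout(small_config)


def random_peakset(rng, n, chrom_sizes, max_len=5_000, label="rand"):
    """Random interval set over the given chromosomes (may self-overlap)."""
    chroms = sorted(chrom_sizes)
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
        rows.append((chrom, start, start + length))
    return dm.PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                      label=label)


def reads_from_positions(chrom, starts, length=147, label="test",
                         chrom_sizes=None):
    """Build a ReadSet from explicit start positions (truth channel unset)."""
    starts = np.asarray(starts, dtype=np.int64)
    df = pd.DataFrame({"chrom": chrom, "start": starts,
                       "end": starts + length,
                       "config": np.full(len(starts), -1, dtype=np.int8)})
    df = df.sort_values(["chrom", "start"], ignore_index=True)
    return dm.ReadSet(df, label, chrom_sizes)
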