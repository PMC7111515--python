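import numpy as np
import pandas as pd
import pytest

import creland
from creland.landscape import StateSegmentation


def random_segmentation(rng, chrom_lengths, n_states, bin_size=100, cell_type="x"):
    """A random bin-aligned segmentation (valid, tiling, adjacent runs merged)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        n = length // bin_size
        states = rng.integers(0, n_states, n)
        starts = np.arange(n) * bin_size
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": starts + bin_size, "state": states}))
    return StateSegmentation.from_dataframe(pd.concat(rows, ignore_index=True),
                                            cell_type, n_states)


def random_intervals(rng, chrom, length, n, max_len=2000):
    starts = rng.integers(0, length - max_len, n)
    ends = starts + rng.integers(1, max_len, n)
    return pd.DataFrame({"chrom": chrom, "start": np.sort(starts),
                         "end": ends[np.argsort(starts)]})


def base_cover(df, chrom, length):
    """Per-base boolean coverage oracle for one chromosome."""
    cov = np.zeros(length, dtype=bool)
    for _, row in df[df["chrom"] == chrom].iterrows():
        cov[row["start"]:row["end"]] = True
    return cov


def runs_from_cover(cov, chrom):
    """Maximal covered intervals from a per-base boolean array."""
    d = np.diff(cov.astype(np.int8), prepend=0, append=0)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


@pytest.fixture(scope="session")
def small_truth():
    """A small full synthetic dataset shared by read-only tests."""
    cfg = creland.SimConfig(seed=7, n_cell_types=6, n_genes=80,
                            chrom_lengths={"chr1": 800_000, "chr2": 600_000})
    return creland.simulate_dataset(cfg)
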