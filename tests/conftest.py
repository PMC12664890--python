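import numpy as np
import pandas as pd
import pytest

from diffloopkit import SimConfig, assemble_counts, simulate_loop_tables
from diffloopkit.background import CountMatrix


def make_count_matrix(counts, conditions=None, qvalues=None, binsize=5000,
                      start1=None, start2=None):
    """Small CountMatrix from an explicit loops x samples array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, s = counts.shape
    conditions = conditions or (["A"] * (s // 2) + ["B"] * (s - s // 2))
    if start1 is None:
        start1 = np.arange(n) * binsize * 10
    if start2 is None:
        start2 = np.asarray(start1) + binsize * 20
    keys = pd.DataFrame({"chrom": "chr1", "start1": start1, "start2": start2})
    q = np.zeros((n, s)) if qvalues is None else np.asarray(qvalues, dtype=float)
    return CountMatrix(
        keys=keys, counts=counts,
        sample_ids=[f"s{i}" for i in range(s)], conditions=list(conditions),
        qvalues=q, binsize=binsize,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but realistic 2v2 simulated experiment shared across tests."""
    cfg = SimConfig(chrom_length=4_000_000, n_peaks=40, depth=20_000,
                    n_reps=2, seed=11)
    tables, truth = simulate_loop_tables(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_cm(small_sim):
    _, tables, _ = small_sim
    return assemble_counts(tables)
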