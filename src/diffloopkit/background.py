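"""Cross-sample count matrix assembly and background-set selection.

The differential test operates on the union of locus pairs with a nonzero
contact count in at least one input sample. Two background modes exist:

* ``A`` (complete): the full union.
* ``F`` (filtered): pairs whose loop-caller FDR is below ``t_bg`` (default
  0.1) in at least one sample — the smaller, loop-enriched background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LoopTable

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Union-of-loops x samples integer counts with condition labels.

    Rows are loop keys (chrom, start1, start2) sorted lexicographically;
    ``qvalues`` carries the per-sample loop-caller FDR (1.0 where the pair
    was absent from that sample's table).
    """

    keys: pd.DataFrame  # chrom, start1, start2
    counts: np.ndarray  # (n_loops, n_samples) integer
    sample_ids: list[str]
    conditions: list[str]
    qvalues: np.ndarray  # (n_loops, n_samples)
    binsize: int
    kept_rows: np.ndarray | None = None  # indices into the pre-filter matrix

    @property
    def n_loops(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def distance(self) -> np.ndarray:
        return (self.keys["start2"] - self.keys["start1"]).to_numpy()

    @property
    def condition_levels(self) -> tuple[str, str]:
        levels = sorted(set(self.conditions))
        if len(levels) != 2:
            raise ValueError(f"expected exactly two condition levels, got {levels}")
        return levels[0], levels[1]

    def condition_mask(self, level: str) -> np.ndarray:
        return np.array([c == level for c in self.conditions])

    def subset(self, rows: np.ndarray) -> "CountMatrix":
        rows = np.asarray(rows)
        return CountMatrix(
            keys=self.keys.iloc[rows].reset_index(drop=True),
            counts=self.counts[rows],
            sample_ids=list(self.sample_ids),
            conditions=list(self.conditions),
            qvalues=self.qvalues[rows],
            binsize=self.binsize,
            kept_rows=rows,
        )

    def relabel(self, conditions: list[str]) -> "CountMatrix":
        """Same counts under a different condition assignment (type-I harness)."""
        if len(conditions) != self.n_samples:
            raise ValueError("condition labels must match sample count")
        return CountMatrix(
            keys=self.keys, counts=self.counts, sample_ids=list(self.sample_ids),
            conditions=list(conditions), qvalues=self.qvalues, binsize=self.binsize,
        )


@dataclass
class BackgroundConfig:
    """Background choice: mode 'A' (complete union) or 'F' (filtered)."""

    mode: str = "A"
    t_bg: float = 0.1

    def __post_init__(self):
        if self.mode not in ("A", "F"):
            raise ValueError(f"background mode must be 'A' or 'F', got {self.mode!r}")
        if not (0 < self.t_bg <= 1):
            raise ValueError(f"t_bg must be in (0, 1], got {self.t_bg}")


def assemble_counts(tables: list[LoopTable]) -> CountMatrix:
    """Build the union count matrix from per-sample loop tables.

    Missing (sample, loop) entries get count 0 and qvalue 1.0. Requires at
    least one table per condition and a shared binsize.
    """
    if not tables:
        raise ValueError("no loop tables provided")
    binsizes = {t.binsize for t in tables}
    if len(binsizes) != 1:
        raise ValueError(f"mismatched binsizes across samples: {sorted(binsizes)}")
    conditions = [t.condition for t in tables]
    levels = sorted(set(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition labels, got {levels}")
    # stable sample order: by (condition, sample_id) for permutation invariance
    order = sorted(range(len(tables)), key=lambda i: (tables[i].condition, tables[i].sample_id))
    tables = [tables[i] for i in order]

    frames = []
    for idx, t in enumerate(tables):
        f = t.df[["chrom", "start1", "start2", "count", "qvalue"]].copy()
        f["sample"] = idx
        frames.append(f)
    allrows = pd.concat(frames, ignore_index=True)
    keys = (
        allrows[["chrom", "start1", "start2"]]
        .drop_duplicates()
        .sort_values(["chrom", "start1", "start2"], kind="mergesort")
        .reset_index(drop=True)
    )
    n, s = len(keys), len(tables)
    key_index = pd.MultiIndex.from_frame(keys)
    row_of = pd.Series(np.arange(n), index=key_index)
    pos = row_of.loc[
        pd.MultiIndex.from_frame(allrows[["chrom", "start1", "start2"]])
    ].to_numpy()
    counts = np.zeros((n, s), dtype=np.int64)
    qvals = np.ones((n, s), dtype=float)
    counts[pos, allrows["sample"].to_numpy()] = allrows["count"].to_numpy()
    qvals[pos, allrows["sample"].to_numpy()] = allrows["qvalue"].to_numpy()
    return CountMatrix(
        keys=keys,
        counts=counts,
        sample_ids=[t.sample_id for t in tables],
        conditions=[t.condition for t in tables],
        qvalues=qvals,
        binsize=tables[0].binsize,
    )


def select_background(cm: CountMatrix, cfg: BackgroundConfig) -> CountMatrix:
    """Apply the background filter.

    Mode A returns the matrix unchanged; mode F keeps rows whose minimum
    per-sample q-value is strictly below ``t_bg``.
    """
    if cfg.mode == "A":
        return cm
    minq = cm.qvalues.min(axis=1)
    keep = np.flatnonzero(minq < cfg.t_bg)
    if keep.size == 0:
        raise ValueError(
            "filtered background is empty: no pair has loop-caller FDR < "
            f"{cfg.t_bg}. If the input tables lack a q-value column, use "
            "background mode 'A' instead."
        )
    logger.info("background F: kept %d / %d pairs at t_bg=%g", keep.size, cm.n_loops, cfg.t_bg)
    return cm.subset(keep)
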