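"""Readers and writers for every on-disk artifact.

Formats handled here:

* **Loop tables** — tab-delimited BEDPE-like files as produced by HiChIP
  loop callers such as FitHiChIP: one row per binned locus pair with a raw
  contact count and the caller's FDR (q-value).
* **Contact maps** — a BED file of fixed-size bins plus a sparse triplet
  matrix text file, the plain-text cousin of cooler/.hic dumps.
* **bedGraph** 1D coverage tracks, aggregated onto the looping resolution.
* **Result tables** — the tab-delimited differential output.

All coordinates are 0-based half-open (BED convention). Loop records are
canonicalized so that ``start1 < start2``; only intra-chromosomal pairs are
kept, since the differential model operates on the 10 kb – 3 Mb distance
range of a single chromosome arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOOP_COLUMNS = ["chr1", "start1", "end1", "chr2", "start2", "end2", "count", "qvalue"]


class LoopTableFormatError(ValueError):
    """Raised when a loop-table file violates the expected layout."""


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-size genomic bin, 0-based half-open."""

    chrom: str
    start: int
    binsize: int

    def __post_init__(self):
        if self.start < 0 or self.start % self.binsize != 0:
            raise ValueError(
                f"bin start {self.start} is not a non-negative multiple of {self.binsize}"
            )

    @property
    def end(self) -> int:
        return self.start + self.binsize


@dataclass
class LoopTable:
    """One sample's binned locus pairs with raw counts and caller q-values.

    ``df`` columns: chrom, start1, start2, count, qvalue. Anchors are
    canonical (start1 < start2) and keys (chrom, start1, start2) unique.
    """

    sample_id: str
    condition: str
    binsize: int
    df: pd.DataFrame
    n_dropped_interchrom: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def distance(self) -> np.ndarray:
        return (self.df["start2"] - self.df["start1"]).to_numpy()


@dataclass
class ContactMap:
    """Sparse symmetric binned contact matrix for one condition.

    Only the upper triangle (i <= j) is stored; :meth:`query` reflects
    lower-triangle lookups. ``bins`` is a DataFrame with chrom/start/end in
    bin-index order.
    """

    bins: pd.DataFrame
    binsize: int
    entries: dict = field(default_factory=dict)  # (i, j) i<=j -> value
    balanced: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def query(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.entries.get((i, j), 0.0)

    def set(self, i: int, j: int, value: float) -> None:
        if i > j:
            i, j = j, i
        self.entries[(i, j)] = value

    def bin_index(self, chrom: str, start: int) -> int:
        """Index of the bin containing genomic position (chrom, start)."""
        key = (chrom, start - start % self.binsize)
        try:
            return self._index[key]
        except AttributeError:
            self._index = {
                (c, s): i
                for i, (c, s) in enumerate(zip(self.bins["chrom"], self.bins["start"]))
            }
            return self._index[key]

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        for (i, j), v in self.entries.items():
            m[i, j] = v
            m[j, i] = v
        return m


def read_loop_table(
    path: str | Path,
    binsize: int,
    sample_id: str | None = None,
    condition: str = "",
) -> LoopTable:
    """Parse a FitHiChIP-style interaction table.

    Expects a header line and tab-delimited columns
    ``chr1 start1 end1 chr2 start2 end2 count qvalue``; the qvalue column may
    be absent (all q set to 0 with a warning, since the filtered background
    then degenerates). Extra columns are ignored. Anchors are swapped into
    canonical order, inter-chromosomal rows are dropped (count logged), and
    duplicate keys are rejected.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoopTableFormatError(f"{path}: cannot parse: {exc}") from exc
    if raw.shape[1] < 7:
        raise LoopTableFormatError(
            f"{path}: expected >= 7 tab-delimited columns, got {raw.shape[1]}"
        )
    has_q = raw.shape[1] >= 8
    if not has_q:
        logger.warning(
            "%s: no qvalue column; treating all loops as q=0 "
            "(filtered background will keep every pair)",
            path,
        )
    cols = raw.columns.tolist()
    out = pd.DataFrame()
    try:
        out["chr1"] = raw[cols[0]].astype(str)
        out["start1"] = raw[cols[1]].astype(np.int64)
        out["end1"] = raw[cols[2]].astype(np.int64)
        out["chr2"] = raw[cols[3]].astype(str)
        out["start2"] = raw[cols[4]].astype(np.int64)
        out["end2"] = raw[cols[5]].astype(np.int64)
        out["count"] = raw[cols[6]].astype(np.int64)
        out["qvalue"] = raw[cols[7]].astype(float) if has_q else 0.0
    except (ValueError, TypeError) as exc:
        # locate the first offending row for a useful message
        for lineno, (_, row) in enumerate(raw.iterrows(), start=2):
            try:
                int(row.iloc[1]), int(row.iloc[2]), int(row.iloc[4]), int(row.iloc[5])
                int(row.iloc[6])
                if has_q:
                    float(row.iloc[7])
            except (ValueError, TypeError):
                raise LoopTableFormatError(f"{path}: malformed row at line {lineno}") from exc
        raise LoopTableFormatError(f"{path}: malformed data: {exc}") from exc

    bad = (out["end1"] - out["start1"] != binsize) | (out["end2"] - out["start2"] != binsize)
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise LoopTableFormatError(
            f"{path}: line {lineno}: anchor width != binsize {binsize}"
        )
    if (out["count"] < 0).any():
        raise LoopTableFormatError(f"{path}: negative contact count")

    inter = out["chr1"] != out["chr2"]
    n_dropped = int(inter.sum())
    if n_dropped:
        logger.info("%s: dropped %d inter-chromosomal rows", path, n_dropped)
    out = out[~inter].copy()

    swap = out["start1"] > out["start2"]
    if swap.any():
        s1 = out["start1"].where(~swap, out["start2"])
        s2 = out["start2"].where(~swap, out["start1"])
        out["start1"], out["start2"] = s1, s2
    if (out["start1"] == out["start2"]).any():
        raise LoopTableFormatError(f"{path}: self-pair (distance 0) not allowed")

    df = pd.DataFrame(
        {
            "chrom": out["chr1"].to_numpy(),
            "start1": out["start1"].to_numpy(),
            "start2": out["start2"].to_numpy(),
            "count": out["count"].to_numpy(),
            "qvalue": np.asarray(out["qvalue"], dtype=float),
        }
    )
    dup = df.duplicated(subset=["chrom", "start1", "start2"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["chrom", "start1", "start2"]].tolist()
        raise LoopTableFormatError(f"{path}: duplicate loop key {tuple(key)}")
    df = df.sort_values(["chrom", "start1", "start2"], kind="mergesort").reset_index(drop=True)
    return LoopTable(
        sample_id=sample_id or path.stem,
        condition=condition,
        binsize=binsize,
        df=df,
        n_dropped_interchrom=n_dropped,
    )


def write_loop_table(table: LoopTable, path: str | Path) -> None:
    """Write a LoopTable back to the BEDPE-like input format."""
    df = table.df
    out = pd.DataFrame(
        {
            "chr1": df["chrom"],
            "start1": df["start1"],
            "end1": df["start1"] + table.binsize,
            "chr2": df["chrom"],
            "start2": df["start2"],
            "end2": df["start2"] + table.binsize,
            "count": df["count"],
            "qvalue": df["qvalue"].map(lambda q: format(q, ".6g")),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_contact_map(matrix_path: str | Path, bins_path: str | Path) -> ContactMap:
    """Load a contact map from a BED bins file plus a triplet matrix file.

    Bins file columns: chrom, start, end, index (tab-delimited, no header).
    Matrix file columns: index1, index2, value. Entries are stored
    upper-triangular; duplicate (i, j) triplets are an error.
    """
    bins = pd.read_csv(
        bins_path, sep="\t", header=None, names=["chrom", "start", "end", "index"]
    )
    bins = bins.sort_values("index").reset_index(drop=True)
    if not (bins["index"].to_numpy() == np.arange(len(bins))).all():
        raise ValueError(f"{bins_path}: bin indices must be 0..n-1")
    binsize = int((bins["end"] - bins["start"]).iloc[0]) if len(bins) else 0
    cmap = ContactMap(bins=bins[["chrom", "start", "end"]].copy(), binsize=binsize)
    try:
        trip = pd.read_csv(
            matrix_path, sep="\t", header=None, names=["i", "j", "value"]
        )
    except pd.errors.EmptyDataError:
        return cmap
    n = len(bins)
    for i, j, v in zip(trip["i"].astype(int), trip["j"].astype(int), trip["value"]):
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"{matrix_path}: bin index ({i},{j}) out of range 0..{n - 1}")
        key = (i, j) if i <= j else (j, i)
        if key in cmap.entries:
            raise ValueError(f"{matrix_path}: duplicate triplet for bins {key}")
        cmap.entries[key] = float(v)
    if any(v < 0 for v in cmap.entries.values()):
        raise ValueError(f"{matrix_path}: negative contact value")
    return cmap


def write_contact_map(cmap: ContactMap, matrix_path: str | Path, bins_path: str | Path) -> None:
    bins = cmap.bins.copy()
    bins["index"] = np.arange(len(bins))
    bins.to_csv(bins_path, sep="\t", index=False, header=False)
    with open(matrix_path, "w") as fh:
        for (i, j), v in sorted(cmap.entries.items()):
            fh.write(f"{i}\t{j}\t{format(v, '.8g')}\n")


def read_bedgraph(path: str | Path, binsize: int) -> pd.DataFrame:
    """Aggregate a 4-column bedGraph onto fixed-size bins.

    Returns a DataFrame (chrom, start, coverage) where coverage is the
    length-weighted sum of interval values over each bin: an interval of
    value v covering L bp of a bin contributes v*L. Overlapping intervals
    are summed; negative values are an error.
    """
    try:
        bg = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": [], "start": [], "coverage": []})
    bg = bg[~bg["chrom"].astype(str).str.startswith("track")]
    if bg.empty:
        return pd.DataFrame({"chrom": [], "start": [], "coverage": []})
    if (bg["value"] < 0).any():
        raise ValueError(f"{path}: negative bedGraph value")
    acc: dict[tuple[str, int], float] = {}
    for chrom, start, end, value in zip(
        bg["chrom"], bg["start"].astype(int), bg["end"].astype(int), bg["value"].astype(float)
    ):
        b0 = start // binsize
        b1 = (end - 1) // binsize
        for b in range(b0, b1 + 1):
            lo = max(start, b * binsize)
            hi = min(end, (b + 1) * binsize)
            if hi > lo:
                acc[(chrom, b * binsize)] = acc.get((chrom, b * binsize), 0.0) + value * (hi - lo)
    keys = sorted(acc)
    return pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "start": [k[1] for k in keys],
            "coverage": [acc[k] for k in keys],
        }
    )


RESULT_FLOATS = ("log2fc", "pvalue", "padj", "covariate")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a differential result table, floats at >= 6 significant digits."""
    out = results.copy()
    for col in out.columns:
        if col in RESULT_FLOATS or out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda x: "NA" if pd.isna(x) else format(float(x), ".8g")
            )
    out.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df
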