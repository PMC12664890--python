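"""Differential-loop categorization and 1D-anchor classification.

A loop is called differential when three conditions hold simultaneously:
its adjusted p-value is below ``f``, its absolute log2 fold change exceeds
``l``, and the loop was significant (loop-caller FDR < ``t_sig``) in at
least one input sample. Differential loops are then annotated by whether
their anchors themselves change in 1D ChIP-seq coverage: loops whose both
anchors are non-differential in 1D reflect genuine 3D-folding changes,
while loops with a differential anchor may simply track the 1D signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .background import CountMatrix
from . import nb_stats, significance

logger = logging.getLogger(__name__)


@dataclass
class DiffThresholds:
    """f: adjusted-p cut; l: |log2FC| cut; t_sig: caller-FDR cut (>=1 sample)."""

    f: float = 0.05
    l: float = 1.0
    t_sig: float = 0.01

    def __post_init__(self):
        if not (0 < self.f < 1) or not (0 < self.t_sig < 1) or self.l < 0:
            raise ValueError(
                f"invalid thresholds f={self.f}, l={self.l}, t_sig={self.t_sig}"
            )


def call_differential(results: pd.DataFrame, cm: CountMatrix,
                      thr: DiffThresholds | None = None) -> pd.DataFrame:
    """Categorize every tested loop.

    Categories: ``up-in-B`` / ``up-in-A`` (differential, by sign of log2fc,
    B over A) or ``not-differential``. All three rules use strict
    inequalities (padj < f, |log2fc| > l, min q < t_sig).
    """
    thr = thr or DiffThresholds()
    if len(results) != cm.n_loops:
        raise ValueError("results not aligned with count matrix rows")
    padj = results["padj"].to_numpy()
    lfc = results["log2fc"].to_numpy()
    minq = cm.qvalues.min(axis=1)
    sig = (padj < thr.f) & (np.abs(lfc) > thr.l) & (minq < thr.t_sig)
    out = results.copy()
    out["min_qvalue"] = minq
    out["category"] = np.where(
        sig, np.where(lfc > 0, "up-in-B", "up-in-A"), "not-differential"
    )
    out["anchor1_label"] = "unknown"
    out["anchor2_label"] = "unknown"
    out["origin_class"] = "unknown"
    return out


def classify_anchors_1d(coverage_a: pd.DataFrame, coverage_b: pd.DataFrame,
                        binsize: int,
                        fixed_dispersion: float = nb_stats.DEFAULT_FIXED_DISPERSION,
                        fdr: float = 0.05) -> pd.DataFrame:
    """Label genomic bins as 1D-differential from per-condition ChIP coverage.

    Coverage (from :func:`diffloopkit.io_formats.read_bedgraph`, in
    length-weighted value*bp units) is converted to the mean per-bp signal
    of each bin, integerized, and compared per bin with the
    single-replicate NB exact test at the given fixed dispersion; labels
    are assigned at 5% FDR (BH) by default. Returns (chrom, start, pvalue,
    padj, label).
    """
    merged = pd.merge(
        coverage_a, coverage_b, on=["chrom", "start"], how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0.0).sort_values(["chrom", "start"]).reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame({"chrom": [], "start": [], "pvalue": [], "padj": [],
                             "label": []})
    ca = np.round(merged["coverage_a"].to_numpy() / binsize).astype(np.int64)
    cb = np.round(merged["coverage_b"].to_numpy() / binsize).astype(np.int64)
    keep = (ca + cb) > 0
    merged = merged[keep].reset_index(drop=True)
    ca, cb = ca[keep], cb[keep]
    # reuse the count-matrix machinery: one pseudo-sample per condition
    keys = pd.DataFrame({"chrom": merged["chrom"], "start1": merged["start"],
                         "start2": merged["start"] + binsize})
    cm = CountMatrix(
        keys=keys, counts=np.stack([ca, cb], axis=1),
        sample_ids=["covA", "covB"], conditions=["A", "B"],
        qvalues=np.zeros((len(keys), 2)), binsize=binsize,
    )
    nf = nb_stats.norm_factors(cm, "libsize")
    res = nb_stats.exact_test(cm, nf, fixed_dispersion)
    padj = significance.bh_adjust(res["pvalue"].to_numpy())
    return pd.DataFrame({
        "chrom": merged["chrom"],
        "start": merged["start"],
        "pvalue": res["pvalue"],
        "padj": padj,
        "label": np.where(padj < fdr, "differential", "non-differential"),
    })


def annotate_origin(calls: pd.DataFrame, anchor_labels: pd.DataFrame | None,
                    binsize: int) -> pd.DataFrame:
    """Attach 1D anchor labels and the 3D-change / 1D-confounded class.

    A differential loop whose both anchors are 1D non-differential is
    classed ``3D-change``; any 1D-differential anchor makes it
    ``1D-confounded``; missing labels leave ``unknown``. Non-differential
    loops keep ``unknown``.
    """
    out = calls.copy()
    if anchor_labels is None or anchor_labels.empty:
        return out
    label_of = {(c, s): l for c, s, l in zip(
        anchor_labels["chrom"], anchor_labels["start"], anchor_labels["label"])}

    def look(chrom, start):
        return label_of.get((chrom, start), "unknown")

    a1 = [look(c, s) for c, s in zip(out["chrom"], out["start1"])]
    a2 = [look(c, s) for c, s in zip(out["chrom"], out["start2"])]
    out["anchor1_label"] = a1
    out["anchor2_label"] = a2
    diff = out["category"] != "not-differential"
    known = (out["anchor1_label"] != "unknown") & (out["anchor2_label"] != "unknown")
    both_nd = (out["anchor1_label"] == "non-differential") & (
        out["anchor2_label"] == "non-differential")
    out["origin_class"] = np.where(
        diff & known, np.where(both_nd, "3D-change", "1D-confounded"), "unknown"
    )
    return out
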