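"""Evaluation metrics: matrix balancing, APA, overlap/recovery, type-I harness.

Aggregate peak analysis (APA) summarizes the enrichment of a loop set on a
balanced contact map: the mean contact sub-matrix in a 100 kb x 100 kb
window (11 x 11 pixels at 10 kb) around each loop, scored as the center
pixel over the mean of a near-diagonal corner block. The differential APA
score d_AB = S_AA - S_AB measures whether loops called up in condition A
are indeed more enriched on A's map than on B's.

The type-I harness quantifies false discoveries by splitting replicates of
a single condition into two artificial groups and running the full
differential pipeline: every call is a false discovery by construction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ContactMap, LoopTable
from .background import BackgroundConfig, assemble_counts, select_background
from .diffcalls import DiffThresholds, call_differential
from . import nb_stats, significance

logger = logging.getLogger(__name__)

APA_HALF_WIDTH = 5          # 11x11 window at 10 kb = center +-50 kb
APA_MIN_DISTANCE = 130_000  # loops closer than this are excluded
# corner block: 20-30 kb downstream of anchor1, 20-30 kb upstream of anchor2
APA_CORNER_OFFSETS = (2, 3)


@dataclass
class APAStack:
    values: np.ndarray  # (2h+1, 2h+1) mean contact per pixel
    n_loops: int
    n_skipped_edge: int = 0


@dataclass
class APAResult:
    S_AA: float
    S_AB: float

    @property
    def d_AB(self) -> float:
        return self.S_AA - self.S_AB

    @property
    def ideal_direction(self) -> bool:
        return self.S_AA >= self.S_AB


def kr_balance(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 3000) -> ContactMap:
    """Knight-Ruiz diagonal balancing of a symmetric contact map.

    Finds x > 0 with x_i * sum_j M_ij x_j constant over rows that have any
    contact (all-zero rows are masked out). Uses the KR fixed-point
    iteration accelerated by a diagonal Newton step, with plain symmetric
    Sinkhorn scaling as a fallback; raises if neither converges.
    """
    m = cmap.to_dense()
    n = m.shape[0]
    mask = m.sum(axis=1) > 0
    sub = m[np.ix_(mask, mask)]
    k = sub.shape[0]
    if k == 0:
        raise ValueError("contact map has no nonzero rows")
    x = np.ones(k)

    def residual(x):
        rs = x * (sub @ x)
        return np.max(np.abs(rs - 1.0))

    converged = False
    for _ in range(max_iter):
        s = sub @ x
        bad = s <= 0
        if bad.any():
            break
        # damped Newton on f_i(x) = x_i (Sx)_i - 1 with diagonal Jacobian
        x_new = 0.5 * (x + 1.0 / s)
        if residual(x_new) < tol:
            x = x_new
            converged = True
            break
        x = x_new
    if not converged:
        x = np.ones(k)
        for _ in range(max_iter):
            s = sub @ x
            if (s <= 0).any():
                raise ValueError("KR balancing: zero row sum during scaling")
            x = np.sqrt(x / s)
            if residual(x) < tol:
                converged = True
                break
    if not converged:
        raise ValueError(
            f"KR balancing did not converge: residual {residual(x):.3g} > {tol}"
        )
    full_x = np.zeros(n)
    full_x[mask] = x
    balanced = m * np.outer(full_x, full_x)
    out = ContactMap(bins=cmap.bins.copy(), binsize=cmap.binsize, balanced=True)
    iu, ju = np.nonzero(np.triu(balanced))
    for i, j in zip(iu, ju):
        out.entries[(int(i), int(j))] = float(balanced[i, j])
    return out


def apa_stack(loops: pd.DataFrame, cmap: ContactMap,
              min_distance: int = APA_MIN_DISTANCE,
              half_width: int = APA_HALF_WIDTH) -> APAStack:
    """Mean contact window around each loop on a (balanced) 10 kb map.

    ``loops`` needs chrom/start1/start2 columns; loops at genomic distance
    <= ``min_distance`` are excluded, and windows clipped by the map edge
    are skipped with a logged count. Raises if no loop survives.
    """
    if not cmap.balanced:
        logger.warning("APA on an unbalanced map; scores reflect raw counts")
    dense = cmap.to_dense()
    n = dense.shape[0]
    w = 2 * half_width + 1
    acc = np.zeros((w, w))
    used = 0
    skipped = 0
    for chrom, s1, s2 in zip(loops["chrom"], loops["start1"], loops["start2"]):
        if s2 - s1 <= min_distance:
            continue
        i = cmap.bin_index(chrom, int(s1))
        j = cmap.bin_index(chrom, int(s2))
        if i - half_width < 0 or j + half_width >= n or i + half_width >= n or j - half_width < 0:
            skipped += 1
            continue
        acc += dense[i - half_width:i + half_width + 1, j - half_width:j + half_width + 1]
        used += 1
    if skipped:
        logger.info("APA: skipped %d edge-clipped windows", skipped)
    if used == 0:
        raise ValueError("no loop retained for APA (distance filter / map edges)")
    return APAStack(values=acc / used, n_loops=used, n_skipped_edge=skipped)


def apa_score(stack: APAStack) -> float:
    """Center pixel over the mean of the near-diagonal corner block.

    The corner block sits at row offsets +{2,3} and column offsets -{2,3}
    from the center (20-30 kb inward of each anchor at 10 kb pixels).
    """
    v = stack.values
    c = v.shape[0] // 2
    rows = [c + o for o in APA_CORNER_OFFSETS]
    cols = [c - o for o in APA_CORNER_OFFSETS]
    corner = v[np.ix_(rows, cols)].mean()
    if corner == 0:
        raise ZeroDivisionError("APA corner block mean is zero; score undefined")
    return float(v[c, c] / corner)


def differential_apa(loops_up_in_a: pd.DataFrame, map_a: ContactMap,
                     map_b: ContactMap,
                     min_distance: int = APA_MIN_DISTANCE) -> APAResult:
    """d_AB = S_AA - S_AB for loops upregulated in condition A."""
    s_aa = apa_score(apa_stack(loops_up_in_a, map_a, min_distance))
    s_ab = apa_score(apa_stack(loops_up_in_a, map_b, min_distance))
    return APAResult(S_AA=s_aa, S_AB=s_ab)


def slack_overlap(loop_x, loop_y, slack: int = 5000) -> bool:
    """Anchors-within-slack loop matching; slack 0 is exact anchor identity."""
    if loop_x[0] != loop_y[0]:
        return False
    return (abs(loop_x[1] - loop_y[1]) <= slack
            and abs(loop_x[2] - loop_y[2]) <= slack)


def reference_hic_loops(hic_cm, nf=None,
                        fixed_dispersion: float | None = None,
                        fdr: float = 0.05, min_abs_log2fc: float = 2.0) -> pd.DataFrame:
    """Reference differential loops from a (Hi-C derived) count matrix.

    Applies the exact test, BH adjustment, and keeps loops with padj < 0.05
    and |log2FC| > 2 (the stringent fold-change criterion used for
    orthogonal reference sets).
    """
    nf = nf or nb_stats.norm_factors(hic_cm, "median_of_ratios")
    la, lb = hic_cm.condition_levels
    na = int(hic_cm.condition_mask(la).sum())
    nb_ = int(hic_cm.condition_mask(lb).sum())
    if fixed_dispersion is not None:
        disp = fixed_dispersion
    elif na == 1 and nb_ == 1:
        disp = nb_stats.DEFAULT_FIXED_DISPERSION
    else:
        disp = nb_stats.estimate_dispersion(hic_cm, nf).tagwise
    res = nb_stats.exact_test(hic_cm, nf, disp)
    res["padj"] = significance.bh_adjust(res["pvalue"].to_numpy())
    keep = (res["padj"] < fdr) & (res["log2fc"].abs() > min_abs_log2fc)
    return res[keep].reset_index(drop=True)


def rank_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: ascending padj, then descending |log2fc|, then key."""
    out = calls.copy()
    out["_abs_lfc"] = out["log2fc"].abs()
    out = out.sort_values(
        by=["padj", "_abs_lfc", "chrom", "start1", "start2"],
        ascending=[True, False, True, True, True], kind="mergesort",
    ).drop(columns="_abs_lfc").reset_index(drop=True)
    return out


def recovery_curve(calls: pd.DataFrame, reference: pd.DataFrame,
                   ks: list[int], slack: int = 5000) -> pd.DataFrame:
    """Fraction of reference loops matched by the top-k ranked calls.

    ``calls`` must already be ranked (see :func:`rank_calls`). Returns a
    DataFrame (k, recovered, fraction); the fraction is non-decreasing in k.
    """
    if reference.empty:
        raise ValueError("reference loop set is empty")
    ref = list(zip(reference["chrom"], reference["start1"], reference["start2"]))
    call_keys = list(zip(calls["chrom"], calls["start1"], calls["start2"]))
    rows = []
    for k in sorted(ks):
        top = call_keys[:k]
        recovered = sum(
            1 for r in ref if any(slack_overlap(r, c, slack) for c in top)
        )
        rows.append({"k": k, "recovered": recovered,
                     "fraction": recovered / len(ref)})
    return pd.DataFrame(rows)


def _balanced_partitions(n: int):
    """All unordered balanced splits of range(n) into two halves."""
    half = n // 2
    first = 0  # fix element 0 in the first group to avoid mirrored duplicates
    rest = list(range(1, n))
    for combo in itertools.combinations(rest, half - 1):
        group_a = (first,) + combo
        group_b = tuple(i for i in range(n) if i not in group_a)
        yield group_a, group_b


def type1_harness(tables: list[LoopTable], n_iter: int = 60, seed: int = 0,
                  test: str = "exact", fdr_method: str = "bh",
                  alpha: float = 0.05, norm: str = "median_of_ratios",
                  thresholds: DiffThresholds | None = None,
                  background: BackgroundConfig | None = None,
                  prior_df: float = 40.0,
                  configs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Replicate-permutation null calibration of the differential caller.

    Takes >= 4 replicates of a single condition, repeatedly splits them
    into two balanced pseudo-conditions, runs the full pipeline (counts ->
    background -> normalization -> dispersion -> test -> FDR at ``alpha``
    -> thresholds) and records the discovery count per iteration. Every
    discovery is false by construction, so the per-iteration FDP is
    discoveries / max(1, discoveries). Partitions are sampled without
    replacement over distinct unordered balanced splits when there are at
    least ``n_iter`` of them, otherwise with replacement.

    ``configs`` (list of (test, fdr_method) pairs) evaluates several caller
    configurations on each partition while estimating normalization and
    dispersion once per partition; the returned frame then has one row per
    iteration x config with ``test`` and ``fdr_method`` columns.
    """
    n = len(tables)
    if n < 4:
        raise ValueError("type-I harness needs at least 4 replicates")
    if n % 2:
        raise ValueError("type-I harness needs an even number of replicates")
    thresholds = thresholds or DiffThresholds(f=alpha, l=1.0, t_sig=0.01)
    background = background or BackgroundConfig(mode="A")
    rng = np.random.default_rng(seed)
    parts = list(_balanced_partitions(n))
    if len(parts) >= n_iter:
        chosen = [parts[i] for i in rng.choice(len(parts), size=n_iter, replace=False)]
    else:
        chosen = [parts[i] for i in rng.choice(len(parts), size=n_iter, replace=True)]

    # counts depend only on the tables; relabel conditions per iteration
    base_tables = [
        LoopTable(t.sample_id, "grp", t.binsize, t.df) for t in tables
    ]
    for t in base_tables[: n // 2]:
        t.condition = "g1"
    for t in base_tables[n // 2:]:
        t.condition = "g2"
    cm0 = assemble_counts(base_tables)
    order = {sid: i for i, sid in enumerate(cm0.sample_ids)}
    tab_order = [order[t.sample_id] for t in base_tables]  # table idx -> column

    configs = configs or [(test, fdr_method)]
    records = []
    for it, (ga, gb) in enumerate(chosen):
        labels = [""] * n
        for t_idx in ga:
            labels[tab_order[t_idx]] = "g1"
        for t_idx in gb:
            labels[tab_order[t_idx]] = "g2"
        cm = cm0.relabel(labels)
        cm = select_background(cm, background)
        nf = nb_stats.norm_factors(cm, norm)
        est = nb_stats.estimate_dispersion(cm, nf, prior_df=prior_df)
        res_by_test = {}
        for tst, fdr in configs:
            if tst not in res_by_test:
                disp = nb_stats.dispersion_for_test(est, tst)
                res_by_test[tst] = nb_stats.run_test(cm, nf, disp, tst)
            res = res_by_test[tst].copy()
            ihw_cfg = significance.IHWConfig(alpha=alpha, seed=seed + it)
            res = significance.adjust(res, fdr, ihw_cfg)
            calls = call_differential(res, cm, thresholds)
            d = int((calls["category"] != "not-differential").sum())
            records.append({"iteration": it, "test": tst, "fdr_method": fdr,
                            "discoveries": d, "fdp": d / max(1, d),
                            "partition": (ga, gb)})
    return pd.DataFrame(records)
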