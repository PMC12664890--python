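"""End-to-end orchestration: read -> background -> test -> adjust -> call.

The functions here are the library face of the tool: they take in-memory
loop tables (or paths via the CLI), wire the stages together with the
mutual-exclusion rules (distance stratification replaces IHW, GLMs need
two replicates per condition, single-replicate designs route to the exact
test with a fixed dispersion) and record per-stage row counts in a
provenance log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__, nb_stats, significance
from .background import BackgroundConfig, CountMatrix, assemble_counts, select_background
from .diffcalls import DiffThresholds, annotate_origin, call_differential
from .io_formats import LoopTable, read_loop_table
from .significance import IHWConfig, StratificationConfig

logger = logging.getLogger(__name__)

FDR_METHODS = ("bh", "ihw", "strat")


@dataclass
class RunConfig:
    """Full configuration of a differential run (CLI/YAML mirror)."""

    samples: list = field(default_factory=list)  # dicts: path, sample_id, condition
    binsize: int = 5_000
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    test: str = "exact"
    norm: str = "median_of_ratios"
    fdr_method: str = "bh"
    thresholds: DiffThresholds = field(default_factory=DiffThresholds)
    strat: StratificationConfig = field(default_factory=StratificationConfig)
    ihw: IHWConfig | None = None
    fixed_dispersion: float | None = None
    prior_df: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.fdr_method not in FDR_METHODS:
            raise ValueError(f"fdr_method must be one of {FDR_METHODS}")
        if self.fdr_method == "strat" and self.ihw is not None:
            raise ValueError(
                "distance stratification already pools p-values into one BH "
                "pass; combining it with IHW would double-correct"
            )


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    return hashlib.sha256(
        json.dumps(asdict(cfg), default=enc, sort_keys=True).encode()
    ).hexdigest()[:16]


def _check_design(cm: CountMatrix, test: str) -> None:
    la, lb = cm.condition_levels
    na = int(cm.condition_mask(la).sum())
    nb = int(cm.condition_mask(lb).sum())
    if test in ("glm_lrt", "glm_qlf", "wald") and min(na, nb) < 2:
        raise ValueError(
            f"test {test!r} needs at least two replicates in both conditions "
            f"(got {la}:{na}, {lb}:{nb}); use the exact test, which supports "
            "single-replicate designs with a fixed dispersion"
        )


def run_diff_tables(
    tables: list[LoopTable],
    background: BackgroundConfig | None = None,
    test: str = "exact",
    norm: str = "median_of_ratios",
    fdr_method: str = "bh",
    thresholds: DiffThresholds | None = None,
    strat: StratificationConfig | None = None,
    ihw: IHWConfig | None = None,
    fixed_dispersion: float | None = None,
    prior_df: float = 40.0,
    anchor_labels: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Run the full differential pipeline on in-memory loop tables.

    Returns ``(calls, provenance)``: the per-loop call table (aligned to
    the selected background rows) and a provenance dict with per-stage row
    counts and the effective configuration.
    """
    background = background or BackgroundConfig()
    thresholds = thresholds or DiffThresholds()
    if fdr_method == "strat" and ihw is not None:
        raise ValueError("stratification and IHW are mutually exclusive")
    prov = {"version": __version__, "seed": seed, "stages": {}}
    cm = assemble_counts(tables)
    prov["stages"]["assembled"] = cm.n_loops
    cm = select_background(cm, background)
    prov["stages"]["background"] = cm.n_loops
    _check_design(cm, test)

    la, lb = cm.condition_levels
    single_rep = (int(cm.condition_mask(la).sum()) == 1
                  and int(cm.condition_mask(lb).sum()) == 1)
    if single_rep and fixed_dispersion is None:
        fixed_dispersion = nb_stats.DEFAULT_FIXED_DISPERSION
        logger.info("single replicate per condition: exact test with fixed "
                    "dispersion %.3g", fixed_dispersion)

    if fdr_method == "strat":
        strat = strat or StratificationConfig()
        counts_total = cm.counts.sum(axis=1)
        bins = significance.equal_occupancy_bins(cm.distance, counts_total, strat)
        inrange = np.flatnonzero(bins.membership >= 0)
        cm = cm.subset(inrange)
        bins.membership = bins.membership[inrange]
        prov["stages"]["in_distance_range"] = cm.n_loops
        res = significance.stratified_test(
            cm, bins, test=test, norm=norm,
            fixed_dispersion=fixed_dispersion, prior_df=prior_df,
        )
        res = res.drop(columns=["_row"])
    else:
        nf = nb_stats.norm_factors(cm, norm)
        if fixed_dispersion is not None:
            disp = fixed_dispersion
        else:
            est = nb_stats.estimate_dispersion(cm, nf, prior_df=prior_df)
            disp = nb_stats.dispersion_for_test(est, test)
        res = nb_stats.run_test(cm, nf, disp, test)
        if fdr_method == "ihw":
            ihw = ihw or IHWConfig(alpha=thresholds.f, seed=seed)
            res = significance.adjust(res, "ihw", ihw)
        else:
            res = significance.adjust(res, "bh")
    prov["stages"]["tested"] = len(res)

    calls = call_differential(res, cm, thresholds)
    calls = annotate_origin(calls, anchor_labels, cm.binsize)
    prov["stages"]["differential"] = int(
        (calls["category"] != "not-differential").sum()
    )
    prov["config"] = {
        "background": vars(background), "test": test, "norm": norm,
        "fdr_method": fdr_method, "thresholds": vars(thresholds),
        "fixed_dispersion": fixed_dispersion, "prior_df": prior_df,
    }
    return calls, prov


def run_diff(cfg: RunConfig, anchor_labels: pd.DataFrame | None = None):
    """File-based entry point: read sample tables per the manifest, then run."""
    if not cfg.samples:
        raise ValueError("no samples in config")
    tables = [
        read_loop_table(s["path"], cfg.binsize, sample_id=s.get("sample_id"),
                        condition=s["condition"])
        for s in cfg.samples
    ]
    calls, prov = run_diff_tables(
        tables, background=cfg.background, test=cfg.test, norm=cfg.norm,
        fdr_method=cfg.fdr_method, thresholds=cfg.thresholds, strat=cfg.strat,
        ihw=cfg.ihw, fixed_dispersion=cfg.fixed_dispersion,
        prior_df=cfg.prior_df, anchor_labels=anchor_labels, seed=cfg.seed,
    )
    prov["config_hash"] = _config_hash(cfg)
    return calls, prov


def run_glm_union(
    tables: list[LoopTable],
    thresholds: DiffThresholds | None = None,
    **kwargs,
):
    """Union of the GLM LRT and QLF differential sets on identical upstream state.

    Each loop keeps the smaller of the two adjusted p-values; the
    ``contrib`` column records which test(s) called it differential.
    """
    thresholds = thresholds or DiffThresholds()
    kwargs.pop("test", None)
    lrt, prov_l = run_diff_tables(tables, test="glm_lrt", thresholds=thresholds, **kwargs)
    qlf, prov_q = run_diff_tables(tables, test="glm_qlf", thresholds=thresholds, **kwargs)
    assert (lrt[["chrom", "start1", "start2"]].to_numpy()
            == qlf[["chrom", "start1", "start2"]].to_numpy()).all()
    take_lrt = lrt["padj"].to_numpy() <= qlf["padj"].to_numpy()
    out = lrt.where(pd.Series(take_lrt, index=lrt.index), qlf)
    out["test"] = np.where(take_lrt, "glm_lrt", "glm_qlf")
    d_l = (lrt["category"] != "not-differential").to_numpy()
    d_q = (qlf["category"] != "not-differential").to_numpy()
    out["category"] = np.where(
        d_l, lrt["category"], np.where(d_q, qlf["category"], "not-differential")
    )
    out["contrib"] = np.select(
        [d_l & d_q, d_l, d_q], ["lrt+qlf", "lrt", "qlf"], default=""
    )
    prov = {"lrt": prov_l, "qlf": prov_q,
            "union_differential": int((out["category"] != "not-differential").sum())}
    return out, prov
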