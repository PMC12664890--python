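"""Synthetic HiChIP data with the statistical structure the caller assumes.

The generator emulates what a FitHiChIP-style loop caller emits for a
peak-anchored HiChIP experiment on a single chromosome:

* a set of ChIP peak bins with elevated 1D signal (anchor bias),
* candidate locus pairs = peak-to-all bins within the 10 kb - 3 Mb range,
* a background expectation mu0 = depth-scaled x d^(-alpha) power-law
  distance decay x anchor biases,
* a subset of ``n_loops`` candidate pairs forming focal loops enriched
  ``loop_strength``-fold above that background (these are the pairs a
  loop caller would report as significant), optionally multiplied by
  2^log2fc for planted differential pairs in condition B,
* per-replicate NB(mu x library factor, phi) counts,
* per-sample q-values from an internal Poisson test of the observed count
  against the no-loop background expectation (BH-adjusted within sample),
* matched 10 kb contact maps and per-condition bedGraph coverage.

Everything is driven by one integer seed; the same seed reproduces the
same tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ContactMap, LoopTable

CHROM = "chrSim"


@dataclass
class SimConfig:
    """Study conditions for the simulated two-condition HiChIP experiment."""

    chrom_length: int = 20_000_000
    binsize: int = 5_000
    n_peaks: int = 200
    depth: float = 50_000.0          # expected background contacts per replicate
    decay_alpha: float = 1.0         # power-law distance-decay exponent
    dispersion: float = 0.2          # NB phi of replicate noise
    n_reps: int = 2                  # replicates per condition
    n_loops: int = 300               # focal loops enriched above the background
    loop_strength: float = 4.0       # fold enrichment of loop pairs over mu0
    planted: list = field(default_factory=list)  # (pair index, log2fc)
    n_planted: int = 0               # convenience: plant this many random loop pairs
    planted_log2fc: float = 2.0
    planted_min_mu: float = 5.0      # baseline intensity floor for planted pairs
    libsize_jitter: tuple = (0.7, 1.3)
    d_min: int = 10_000
    d_max: int = 3_000_000
    peak_bias: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.chrom_length, self.binsize, self.n_peaks, self.depth,
               self.n_reps) <= 0 or self.decay_alpha <= 0 or self.dispersion < 0:
            raise ValueError("all SimConfig sizes/rates must be positive")
        if not (0 < self.d_min < self.d_max):
            raise ValueError("need 0 < d_min < d_max")


@dataclass
class SyntheticTruth:
    """Planted per-pair effects aligned with the emitted loop keys."""

    keys: pd.DataFrame           # chrom, start1, start2 of every candidate pair
    log2fc: np.ndarray           # planted effect (0 for null pairs)
    baseline_mu: np.ndarray      # per-replicate expected count, condition A
    peak_bins: np.ndarray        # starts of peak bins
    bias: np.ndarray             # per-bin 1D bias
    is_loop: np.ndarray = None   # focal-loop pairs (enriched over background)

    @property
    def planted_mask(self) -> np.ndarray:
        return self.log2fc != 0


def _candidate_pairs(cfg: SimConfig, rng: np.random.Generator):
    n_bins = cfg.chrom_length // cfg.binsize
    peaks = np.sort(rng.choice(n_bins, size=min(cfg.n_peaks, n_bins), replace=False))
    bias = np.ones(n_bins)
    bias *= np.exp(rng.normal(0.0, 0.25, size=n_bins))  # mild per-bin wobble
    bias[peaks] *= cfg.peak_bias
    is_peak = np.zeros(n_bins, dtype=bool)
    is_peak[peaks] = True

    lo = cfg.d_min // cfg.binsize
    hi = cfg.d_max // cfg.binsize
    i_list, j_list = [], []
    for p in peaks:
        j = np.arange(p + lo, min(p + hi, n_bins - 1) + 1)
        i_list.append(np.full(j.size, p))
        j_list.append(j)
        i = np.arange(max(p - hi, 0), p - lo + 1)
        i = i[i >= 0]
        # avoid double-listing peak-peak pairs (kept once from the lower peak)
        i = i[~is_peak[i]]
        i_list.append(i)
        j_list.append(np.full(i.size, p))
    i = np.concatenate(i_list)
    j = np.concatenate(j_list)
    keep = j > i
    i, j = i[keep], j[keep]
    order = np.lexsort((j, i))
    i, j = i[order], j[order]
    pairs = np.unique(np.stack([i, j], axis=1), axis=0)
    return pairs[:, 0], pairs[:, 1], bias, peaks


def _universe(cfg: SimConfig, rng: np.random.Generator):
    """Candidate pairs, background expectation mu0, and loop assignment."""
    i, j, bias, peaks = _candidate_pairs(cfg, rng)
    d = (j - i) * cfg.binsize
    raw = d.astype(float) ** (-cfg.decay_alpha) * bias[i] * bias[j]
    mu0 = raw * (cfg.depth / raw.sum())
    is_loop = np.zeros(i.size, dtype=bool)
    n_loops = min(cfg.n_loops, i.size)
    if n_loops:
        # loops are detectable where contacts are: sample pairs with
        # probability proportional to the background intensity
        is_loop[rng.choice(i.size, size=n_loops, replace=False,
                           p=mu0 / mu0.sum())] = True
    mu_base = mu0 * np.where(is_loop, cfg.loop_strength, 1.0)
    return i, j, bias, peaks, d, mu0, mu_base, is_loop


def candidate_universe(cfg: SimConfig) -> pd.DataFrame:
    """Keys, distances, expectations and loop flags of every candidate pair.

    Deterministic for a given config (same seed as the simulation), so
    callers can pick planted-pair indices — e.g. stratified by distance —
    before generating the tables. ``mu0`` is the decay background, ``mu``
    the condition-A expectation including focal-loop enrichment.
    """
    rng = np.random.default_rng(cfg.seed)
    i, j, _, _, d, mu0, mu_base, is_loop = _universe(cfg, rng)
    return pd.DataFrame({
        "chrom": CHROM,
        "start1": i * cfg.binsize,
        "start2": j * cfg.binsize,
        "distance": d,
        "mu0": mu0,
        "mu": mu_base,
        "is_loop": is_loop,
    })


def simulate_loop_tables(cfg: SimConfig) -> tuple[list[LoopTable], SyntheticTruth]:
    """Generate per-replicate loop tables for two conditions plus the truth.

    Returns (tables, truth): ``2 * n_reps`` LoopTables with conditions "A"
    and "B", and the aligned SyntheticTruth. Pairs whose sampled count is
    zero are omitted from that sample's table (as a real caller's output
    would omit them).
    """
    rng = np.random.default_rng(cfg.seed)
    i, j, bias, peaks, d, mu0, mu_base, is_loop = _universe(cfg, rng)

    log2fc = np.zeros(i.size)
    planted = list(cfg.planted)
    if cfg.n_planted:
        # differential effects live on focal loops, as a caller would see them
        eligible = np.flatnonzero(is_loop & (mu_base >= cfg.planted_min_mu))
        if eligible.size < cfg.n_planted:
            eligible = np.flatnonzero(is_loop)[
                np.argsort(mu_base[is_loop])[-cfg.n_planted:]
            ]
        pick = rng.choice(eligible, size=min(cfg.n_planted, eligible.size),
                          replace=False)
        signs = rng.choice([-1.0, 1.0], size=pick.size)
        planted += [(int(p), s * cfg.planted_log2fc) for p, s in zip(pick, signs)]
    bad = [sel for sel, _ in planted if not (0 <= int(sel) < i.size)]
    if bad:
        raise ValueError(f"planted selectors out of range: {bad}")
    for sel, fc in planted:
        log2fc[int(sel)] = fc

    mu_a = mu_base
    mu_b = mu_base * 2.0 ** log2fc

    keys = pd.DataFrame({
        "chrom": CHROM,
        "start1": i * cfg.binsize,
        "start2": j * cfg.binsize,
    })
    truth = SyntheticTruth(keys=keys, log2fc=log2fc, baseline_mu=mu_a,
                           peak_bins=peaks * cfg.binsize, bias=bias,
                           is_loop=is_loop)

    tables = []
    for cond, mu in (("A", mu_a), ("B", mu_b)):
        for rep in range(cfg.n_reps):
            lf = rng.uniform(*cfg.libsize_jitter)
            mean = mu * lf
            if cfg.dispersion > 0:
                r = 1.0 / cfg.dispersion
                lam = rng.gamma(shape=r, scale=mean / r)
                counts = rng.poisson(lam)
            else:
                counts = rng.poisson(mean)
            nz = counts > 0
            # caller-style q-values: Poisson upper tail vs no-loop expectation
            pv = stats.poisson.sf(counts[nz] - 1, mu0[nz] * lf)
            from .significance import bh_adjust
            qv = bh_adjust(pv)
            df = pd.DataFrame({
                "chrom": CHROM,
                "start1": keys["start1"].to_numpy()[nz],
                "start2": keys["start2"].to_numpy()[nz],
                "count": counts[nz].astype(np.int64),
                "qvalue": qv,
            })
            tables.append(LoopTable(sample_id=f"{cond}{rep + 1}", condition=cond,
                                    binsize=cfg.binsize, df=df))
    return tables, truth


def simulate_contact_maps(cfg: SimConfig, truth: SyntheticTruth,
                          map_binsize: int = 10_000,
                          loop_boost: float = 3.0) -> dict[str, ContactMap]:
    """Matched per-condition contact maps at 10 kb, Poisson-sampled.

    The expected map combines the genome-wide power-law decay background
    with focal enrichment (``loop_boost`` x background) at every candidate
    pair, scaled by 2^log2fc in condition B for planted pairs; it is then
    aggregated to ``map_binsize`` and Poisson-sampled per condition.
    """
    rng = np.random.default_rng(cfg.seed + 104729)
    n_bins = cfg.chrom_length // map_binsize
    scale = map_binsize // cfg.binsize
    band = cfg.d_max // map_binsize

    # background decay over the whole band, on the coarse bins
    iu, ju = [], []
    for off in range(1, band + 1):
        idx = np.arange(0, n_bins - off)
        iu.append(idx)
        ju.append(idx + off)
    iu = np.concatenate(iu)
    ju = np.concatenate(ju)
    dist = (ju - iu) * map_binsize
    coarse_bias = truth.bias[: (n_bins * scale)].reshape(n_bins, scale).mean(axis=1)
    expected = {"A": dist.astype(float) ** (-cfg.decay_alpha)
                * coarse_bias[iu] * coarse_bias[ju]}
    expected["A"] *= (cfg.depth * scale**2) / expected["A"].sum()
    expected["B"] = expected["A"].copy()

    # focal loop enrichment on top of the background
    key = {}
    for idx, (a, b) in enumerate(zip(iu, ju)):
        key[(int(a), int(b))] = idx
    li = (truth.keys["start1"].to_numpy() // map_binsize)
    lj = (truth.keys["start2"].to_numpy() // map_binsize)
    mu = truth.baseline_mu
    for a, b, m, fc in zip(li, lj, mu, truth.log2fc):
        if a == b:
            continue
        idx = key.get((int(a), int(b)))
        if idx is None:
            continue
        expected["A"][idx] += loop_boost * m
        expected["B"][idx] += loop_boost * m * 2.0**fc

    bins = pd.DataFrame({
        "chrom": CHROM,
        "start": np.arange(n_bins) * map_binsize,
        "end": (np.arange(n_bins) + 1) * map_binsize,
    })
    maps = {}
    for cond in ("A", "B"):
        sampled = rng.poisson(expected[cond])
        cmap = ContactMap(bins=bins.copy(), binsize=map_binsize)
        nz = sampled > 0
        cmap.entries = {
            (int(a), int(b)): float(v)
            for a, b, v in zip(iu[nz], ju[nz], sampled[nz])
        }
        maps[cond] = cmap
    return maps


def simulate_coverage(cfg: SimConfig, truth: SyntheticTruth,
                      shift: dict[int, float] | None = None,
                      base_depth: float = 200.0) -> dict[str, pd.DataFrame]:
    """Per-condition 1D coverage (bedGraph rows) from the same bias model.

    ``shift`` maps peak-bin start coordinates to a condition-B fold change
    of the 1D signal; all other bins keep identical expectation in both
    conditions. Values are Poisson-sampled per bin.
    """
    shift = shift or {}
    bad = set(shift) - set(truth.peak_bins.tolist())
    if bad:
        raise ValueError(f"shift bins are not peak bins: {sorted(bad)}")
    rng = np.random.default_rng(cfg.seed + 15485863)
    n_bins = truth.bias.size
    starts = np.arange(n_bins) * cfg.binsize
    mu = truth.bias * base_depth
    mu_b = mu.copy()
    for s, fold in shift.items():
        mu_b[s // cfg.binsize] *= fold
    out = {}
    for cond, m in (("A", mu), ("B", mu_b)):
        vals = rng.poisson(m).astype(float)
        out[cond] = pd.DataFrame({
            "chrom": CHROM,
            "start": starts,
            "end": starts + cfg.binsize,
            "value": vals,
        })
    return out


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)
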