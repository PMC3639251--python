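"""Bulked-segregant mapping from pooled array intensities.

At each SFP the WE70-derived allele frequency of an aberrant F2 pool is read
off the pool's hybridization intensity by linear interpolation between the
two parental intensities, f = (I_pool - I_yw) / (I_WE70 - I_yw). Per-probe
frequencies (relative to the 0.5 Mendelian null, or as the difference between
two pools) are then averaged over sliding windows of consecutive probes, and
genome-wide significance thresholds come from permuting the pool arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .sfp import IntensityMatrix, SFPCallSet, call_sfps, sam_statistic

#: Probes whose parental log2 intensities differ by no more than this are
#: uninformative for frequency estimation and are dropped before windowing.
PARENT_CONTRAST_EPSILON = 0.2


# ---------------------------------------------------------------------------
# Window engine (shared with the RIL re-sequencing scan)
# ---------------------------------------------------------------------------


@dataclass
class WindowProfile:
    """Ordered genomic windows with a statistic value.

    ``windows`` columns: chrom, start, end (bp of the first/last member,
    1-based inclusive), n (member count), value. Windows never span
    chromosomes; a chromosome with fewer members than the window size yields
    a single truncated window (n < window size flags it).
    """

    windows: pd.DataFrame
    window: int
    step: int = 1
    thresholds: tuple[float, float] | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def values_for(self, chrom: str) -> np.ndarray:
        return self.windows.loc[self.windows["chrom"] == chrom, "value"].to_numpy()


def sliding_window(values, chroms, positions, window: int = 100, step: int = 1) -> WindowProfile:
    """Mean of ``values`` over windows of ``window`` consecutive members.

    Input must be sorted by (chromosome, position); windows are per
    chromosome, advancing by ``step`` members. NaN members are dropped before
    windowing (their positions do not count toward the member total).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    values = np.asarray(values, float)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    keep = ~np.isnan(values)
    values, chroms, positions = values[keep], chroms[keep], positions[keep]

    rows = []
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        v = values[mask]
        p = positions[mask]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions not sorted on {chrom}")
        n = v.size
        if n < window:
            rows.append((chrom, int(p[0]), int(p[-1]), n, float(v.mean())))
            continue
        cs = np.concatenate([[0.0], np.cumsum(v)])
        starts = np.arange(0, n - window + 1, step)
        means = (cs[starts + window] - cs[starts]) / window
        for i, m in zip(starts, means):
            rows.append((chrom, int(p[i]), int(p[i + window - 1]), window, float(m)))
    return WindowProfile(
        windows=pd.DataFrame(rows, columns=["chrom", "start", "end", "n", "value"]),
        window=window, step=step,
    )


def window_means_matrix(values: np.ndarray, window: int) -> np.ndarray:
    """Row-wise trailing-window means: (m, n) -> (m, n - window + 1).

    Vectorized core used by the permutation machinery (single chromosome,
    step 1)."""
    cs = np.cumsum(values, axis=1, dtype=np.float64)
    cs = np.concatenate([np.zeros((values.shape[0], 1)), cs], axis=1)
    return (cs[:, window:] - cs[:, :-window]) / window


# ---------------------------------------------------------------------------
# Allele-frequency estimation
# ---------------------------------------------------------------------------


def estimate_allele_frequency(pool_mean, we70_mean, yw_mean,
                              epsilon: float = PARENT_CONTRAST_EPSILON) -> np.ndarray:
    """WE70-derived allele frequency of a pool per probe:
    f = (I_pool - I_yw) / (I_WE70 - I_yw), clamped to [0, 1].

    Direction-aware (works when the WE70 intensity is below the yw one).
    Probes with parental contrast |I_WE70 - I_yw| <= epsilon are
    uninformative and returned as NaN.
    """
    pool_mean, we70_mean, yw_mean = np.broadcast_arrays(
        np.asarray(pool_mean, float), np.asarray(we70_mean, float),
        np.asarray(yw_mean, float))
    contrast = we70_mean - yw_mean
    informative = np.abs(contrast) > epsilon
    f = np.full(contrast.shape, np.nan)
    f[informative] = np.clip(
        (pool_mean[informative] - yw_mean[informative]) / contrast[informative], 0.0, 1.0)
    return f


def relative_frequency(f_pool_a, f_pool_b) -> np.ndarray:
    """Signed difference of two absolute pool allele frequencies, in [-1, 1]."""
    f_pool_a = np.asarray(f_pool_a, float)
    f_pool_b = np.asarray(f_pool_b, float)
    if np.any((f_pool_a < 0) | (f_pool_a > 1)) or np.any((f_pool_b < 0) | (f_pool_b > 1)):
        raise ValueError("pool frequencies must lie in [0, 1]")
    return f_pool_a - f_pool_b


# ---------------------------------------------------------------------------
# Permutation thresholds and the full scan
# ---------------------------------------------------------------------------


def _pool_statistic(im: IntensityMatrix, idx_a: np.ndarray, idx_b: np.ndarray,
                    we70_mean: np.ndarray, yw_mean: np.ndarray,
                    mode: str, epsilon: float) -> np.ndarray:
    """Per-probe contrast between two sets of pool arrays.

    ``frequency`` mode: difference of estimated pool allele frequencies;
    ``intensity`` mode: difference of mean log2 intensities.
    """
    mean_a = im.values[:, idx_a].mean(axis=1)
    mean_b = im.values[:, idx_b].mean(axis=1)
    if mode == "intensity":
        return mean_a - mean_b
    f_a = estimate_allele_frequency(mean_a, we70_mean, yw_mean, epsilon)
    f_b = estimate_allele_frequency(mean_b, we70_mean, yw_mean, epsilon)
    return f_a - f_b


def bsa_thresholds(im: IntensityMatrix, contrast: tuple[str, str],
                   window: int = 100, n_perm: int = 200, seed=None,
                   mode: str = "frequency",
                   epsilon: float = PARENT_CONTRAST_EPSILON,
                   parent_groups: tuple[str, str] = ("WE70", "yw"),
                   probe_mask: np.ndarray | None = None) -> tuple[float, float]:
    """(low, high) genome-wide significance thresholds for a two-pool contrast.

    Balanced reassignments of the contrast's arrays to pseudo-pools are
    enumerated exhaustively when there are at most 200, otherwise sampled with
    ``seed``. For each reassignment the full window profile is recomputed and
    its genome-wide extrema recorded; thresholds are the 2.5% quantile of the
    minima and the 97.5% quantile of the maxima (family-wise, per genome).
    """
    group_a, group_b = contrast
    idx_a = im.array_indices(group_a)
    idx_b = im.array_indices(group_b)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("need >= 2 arrays per side of the contrast")
    pooled = np.concatenate([idx_a, idx_b])
    we70_mean = im.group_values(parent_groups[0]).mean(axis=1)
    yw_mean = im.group_values(parent_groups[1]).mean(axis=1)
    probes = im.probes
    if probe_mask is not None:
        probe_mask = np.asarray(probe_mask, bool)
    n_a = idx_a.size

    total = comb(pooled.size, n_a)
    if total <= 200:
        assignments = [np.asarray(c, dtype=np.intp) for c in combinations(range(pooled.size), n_a)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [rng.permutation(pooled.size)[:n_a] for _ in range(n_perm)]

    lows, highs = [], []
    for assign in assignments:
        mask = np.zeros(pooled.size, dtype=bool)
        mask[assign] = True
        stat = _pool_statistic(im, pooled[mask], pooled[~mask], we70_mean, yw_mean,
                               mode, epsilon)
        if probe_mask is not None:
            stat = np.where(probe_mask, stat, np.nan)
        prof = sliding_window(stat, probes["chrom"], probes["pos"], window=window)
        vals = prof.windows["value"]
        lows.append(float(vals.min()))
        highs.append(float(vals.max()))
    return float(np.quantile(lows, 0.025)), float(np.quantile(highs, 0.975))


def _windows_to_regions(prof: WindowProfile, low: float, high: float) -> pd.DataFrame:
    """Merge consecutive above-threshold windows into regions (per direction)."""
    regions = []
    for chrom, sub in prof.windows.groupby("chrom", sort=False):
        for direction, mask in (("high", sub["value"].to_numpy() > high),
                                ("low", sub["value"].to_numpy() < low)):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                block = sub.iloc[run]
                extremum = block["value"].max() if direction == "high" else block["value"].min()
                regions.append((chrom, int(block["start"].iloc[0]),
                                int(block["end"].iloc[-1]), direction, float(extremum)))
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "direction", "value"])


@dataclass
class BsaResult:
    sfp: SFPCallSet
    profiles: dict[str, WindowProfile]
    regions: dict[str, pd.DataFrame]
    pool_frequencies: dict[str, np.ndarray] = field(default_factory=dict)


def bsa_scan(im: IntensityMatrix, pool_groups: tuple[str, str] = ("poolSD", "poolAI"),
             parent_groups: tuple[str, str] = ("WE70", "yw"),
             target_fdr: float = 0.11, window: int = 100, n_perm: int = 200,
             seed=None, mode: str = "frequency",
             epsilon: float = PARENT_CONTRAST_EPSILON) -> BsaResult:
    """Full bulked-segregant pipeline on a normalized intensity matrix.

    Stages: call SFPs between the parents; estimate each aberrant pool's
    WE70 allele frequency at the called SFPs; window the per-pool departure
    from the Mendelian 0.5 and the pool-vs-pool relative frequency; attach
    permutation thresholds; and report regions beyond them.
    """
    sfps = call_sfps(im, parent_groups[0], parent_groups[1], target_fdr=target_fdr)
    called = sfps.probes["call"].to_numpy()
    we70_mean = im.group_values(parent_groups[0]).mean(axis=1)
    yw_mean = im.group_values(parent_groups[1]).mean(axis=1)
    chroms = im.probes["chrom"]
    positions = im.probes["pos"]

    profiles: dict[str, WindowProfile] = {}
    regions: dict[str, pd.DataFrame] = {}
    frequencies: dict[str, np.ndarray] = {}
    pool_means = {}
    for pool in pool_groups:
        pool_means[pool] = im.group_values(pool).mean(axis=1)
        f = estimate_allele_frequency(pool_means[pool], we70_mean, yw_mean, epsilon)
        f = np.where(called, f, np.nan)
        frequencies[pool] = f
        stat = f - 0.5 if mode == "frequency" else np.where(
            called, pool_means[pool] - (we70_mean + yw_mean) / 2.0, np.nan)
        profiles[pool] = sliding_window(stat, chroms, positions, window=window)

    # pool A vs pool B relative profile with permutation thresholds
    fa, fb = frequencies[pool_groups[0]], frequencies[pool_groups[1]]
    rel = fa - fb if mode == "frequency" else np.where(
        called, pool_means[pool_groups[0]] - pool_means[pool_groups[1]], np.nan)
    rel_profile = sliding_window(rel, chroms, positions, window=window)
    low, high = bsa_thresholds(im, pool_groups, window=window, n_perm=n_perm,
                               seed=seed, mode=mode, epsilon=epsilon,
                               parent_groups=parent_groups, probe_mask=called)
    rel_profile.thresholds = (low, high)
    rel_profile.n_permutations = n_perm
    rel_profile.seed = seed
    key = f"{pool_groups[0]}-{pool_groups[1]}"
    profiles[key] = rel_profile
    regions[key] = _windows_to_regions(rel_profile, low, high)
    return BsaResult(sfp=sfps, profiles=profiles, regions=regions,
                     pool_frequencies=frequencies)
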