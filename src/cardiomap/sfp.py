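"""Single-feature-polymorphism calling between parental lines.

SFPs are probe-level hybridization differences between the genomic DNA of the
two parental strains on an expression array. Calling uses the SAM
(significance analysis of microarrays) moderated statistic: a per-probe
"relative difference" d_i = (mean_A - mean_B) / (s_i + s0), where s_i is the
pooled two-sample standard error of the mean difference and s0 is a small
positive constant (here the median of the s_i) that damps probes with tiny
variance. Significance is assessed against the exhaustive set of balanced
label permutations (20 assignments for 3 vs 3 arrays, including the true
labeling), and the false discovery rate at a cut |d| >= delta is the mean
permuted exceedance count divided by the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

#: Raw intensities are clipped here before the log2 transform.
INTENSITY_FLOOR = 1.0


@dataclass
class IntensityMatrix:
    """Probes x arrays hybridization values with group labels.

    ``probes`` has columns (probe, chrom, pos), sorted by genome position.
    ``values`` is (n_probes, n_arrays); ``groups`` labels each array (e.g.
    WE70, yw, poolSD, poolAI) and ``replicates`` numbers arrays within group.
    """

    probes: pd.DataFrame
    values: np.ndarray
    groups: np.ndarray
    replicates: np.ndarray
    is_log: bool = False

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.replicates = np.asarray(self.replicates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), self.groups.size):
            raise ValueError("values shape must be (n_probes, n_arrays)")
        if self.replicates.size != self.groups.size:
            raise ValueError("one replicate index per array required")

    def array_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def group_values(self, group: str) -> np.ndarray:
        return self.values[:, self.array_indices(group)]


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Reference-free quantile normalization (mean-of-sorted-columns reference).

    Afterwards every array's sorted value vector is identical. Ties within an
    array receive the mean reference value of their rank range.
    """
    ranks = np.argsort(np.argsort(values, axis=0), axis=0)
    reference = np.sort(values, axis=0).mean(axis=1)
    return reference[ranks]


def normalize(raw: IntensityMatrix, floor: float = INTENSITY_FLOOR) -> IntensityMatrix:
    """log2 transform (raw clipped at ``floor``) followed by quantile
    normalization so all arrays share one overall distribution."""
    values = raw.values if raw.is_log else np.log2(np.clip(raw.values, floor, None))
    values = quantile_normalize(values)
    return IntensityMatrix(probes=raw.probes, values=values, groups=raw.groups,
                           replicates=raw.replicates, is_log=True)


def sam_statistic(group_a: np.ndarray, group_b: np.ndarray,
                  s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe relative difference d and pooled standard error s.

    d_i = (mean_A,i - mean_B,i) / (s_i + s0) with
    s_i = sqrt(a * (SS_A,i + SS_B,i)), a = (1/n_A + 1/n_B) / (n_A + n_B - 2),
    where SS are the within-group sums of squared deviations.
    """
    group_a = np.asarray(group_a, float)
    group_b = np.asarray(group_b, float)
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    if n_a < 1 or n_b < 1:
        raise ValueError("each group needs at least one array")
    if n_a + n_b < 3:
        raise ValueError("pooled standard error needs n_A + n_B >= 3")
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    mean_a = group_a.mean(axis=1)
    mean_b = group_b.mean(axis=1)
    ss_a = ((group_a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((group_b - mean_b[:, None]) ** 2).sum(axis=1)
    a = (1.0 / n_a + 1.0 / n_b) / (n_a + n_b - 2)
    s = np.sqrt(a * (ss_a + ss_b))
    d = (mean_a - mean_b) / (s + s0)
    return d, s


def compute_s0(s: np.ndarray) -> float:
    """SAM damping constant: the median of the per-probe standard errors."""
    s = np.asarray(s, float)
    if s.size == 0:
        raise ValueError("empty standard-error vector")
    return float(np.median(s))


def balanced_permutations(n_a: int, n_b: int) -> list[np.ndarray]:
    """All C(n_a + n_b, n_a) assignments of array indices to pseudo-group A,
    in deterministic (lexicographic) order. Includes the true labeling
    (indices 0..n_a-1) as the first assignment."""
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one array")
    return [np.asarray(c, dtype=np.intp) for c in combinations(range(n_a + n_b), n_a)]


def permuted_statistics(values_a: np.ndarray, values_b: np.ndarray,
                        s0: float) -> np.ndarray:
    """d statistics for every balanced permutation of the pooled arrays.

    Returns an array of shape (n_permutations, n_probes). The null is the
    pooled distribution of these permuted d values.
    """
    pooled = np.concatenate([values_a, values_b], axis=1)
    n_a = values_a.shape[1]
    n = pooled.shape[1]
    out = []
    for assign in balanced_permutations(n_a, n - n_a):
        mask = np.zeros(n, dtype=bool)
        mask[assign] = True
        d, _ = sam_statistic(pooled[:, mask], pooled[:, ~mask], s0)
        out.append(d)
    return np.asarray(out)


@dataclass(frozen=True)
class FdrEstimate:
    delta: float
    n_called: int
    fdr: float  # NaN when nothing is called


def estimate_fdr(d_observed: np.ndarray, d_permuted: np.ndarray,
                 delta: float) -> FdrEstimate:
    """FDR at the symmetric two-sided cut |d| >= delta:
    mean permuted exceedance count across permutations / observed count,
    capped at 1. With zero observed calls the FDR is undefined (NaN)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if d_permuted.ndim != 2 or d_permuted.shape[0] < 1:
        raise ValueError("need at least one permutation")
    n_called = int((np.abs(d_observed) >= delta).sum())
    if n_called == 0:
        return FdrEstimate(delta=delta, n_called=0, fdr=float("nan"))
    mean_null = float((np.abs(d_permuted) >= delta).sum() / d_permuted.shape[0])
    return FdrEstimate(delta=delta, n_called=n_called, fdr=min(mean_null / n_called, 1.0))


@dataclass
class SFPCallSet:
    """Per-probe SAM results plus the global calling parameters."""

    probes: pd.DataFrame  # probe, chrom, pos, d, s, call, direction
    s0: float
    delta: float
    fdr: float
    n_permutations: int

    @property
    def n_called(self) -> int:
        return int(self.probes["call"].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.probes.copy()


def _fdr_curve(d_obs: np.ndarray, d_perm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw FDR over the grid of observed |d| thresholds (descending |d|).

    Returns (deltas_desc, n_called, fdr_raw) where deltas are the sorted
    unique observed |d| values, largest first.
    """
    abs_obs = np.sort(np.abs(d_obs))
    deltas = np.unique(abs_obs)[::-1]
    n_obs = abs_obs.size - np.searchsorted(abs_obs, deltas, side="left")
    abs_perm = np.sort(np.abs(d_perm).ravel())
    n_null = (abs_perm.size - np.searchsorted(abs_perm, deltas, side="left")) / d_perm.shape[0]
    fdr_raw = np.minimum(n_null / n_obs, 1.0)
    return deltas, n_obs, fdr_raw


def call_sfps(im: IntensityMatrix, group_a: str = "WE70", group_b: str = "yw",
              target_fdr: float = 0.11, probe_mask: np.ndarray | None = None) -> SFPCallSet:
    """Call SFPs between two parental groups at a target FDR.

    Sweeps the cut delta over the grid of observed |d| values and returns the
    largest call set whose (isotonically smoothed) estimated FDR does not
    exceed ``target_fdr``. The smoothed FDR at a cut is the minimum raw FDR
    over all cuts at or below it, which makes the estimate monotone
    non-increasing in delta and the sweep's solution unique; the selected
    cut's own raw FDR always meets the target. Direction is W-high (d > 0) or Y-high.

    ``probe_mask`` optionally restricts calling to a boolean subset of probes
    (e.g. an externally supplied present-call mask).
    """
    if not im.is_log:
        raise ValueError("call_sfps expects a normalized (log-scale) matrix")
    values_a = im.group_values(group_a)
    values_b = im.group_values(group_b)
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise ValueError("need >= 2 replicate arrays per group")
    probes = im.probes.copy()
    if probe_mask is not None:
        probe_mask = np.asarray(probe_mask, bool)
        values_a = values_a[probe_mask]
        values_b = values_b[probe_mask]
        probes = probes.loc[probe_mask].reset_index(drop=True)

    _, s = sam_statistic(values_a, values_b, s0=0.0)
    s0 = compute_s0(s)
    d_obs, s = sam_statistic(values_a, values_b, s0=s0)
    d_perm = permuted_statistics(values_a, values_b, s0)
    n_perm = d_perm.shape[0]

    deltas, n_obs, fdr_raw = _fdr_curve(d_obs, d_perm)
    fdr_smooth = np.minimum.accumulate(fdr_raw[::-1])[::-1]  # min raw FDR over cuts <= delta

    ok = fdr_smooth <= target_fdr
    probes = probes.assign(d=d_obs, s=s)
    probes["direction"] = np.where(d_obs > 0, "W-high", "Y-high")
    if not ok.any():
        probes["call"] = False
        return SFPCallSet(probes=probes, s0=s0, delta=float("inf"),
                          fdr=float("nan"), n_permutations=n_perm)
    # smallest delta (largest call set) still meeting the target
    i = int(np.flatnonzero(ok)[-1])
    delta = float(deltas[i])
    probes["call"] = np.abs(d_obs) >= delta
    return SFPCallSet(probes=probes, s0=s0, delta=delta,
                      fdr=float(fdr_smooth[i]), n_permutations=n_perm)
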