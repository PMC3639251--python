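"""RIL re-sequencing genome scan.

Low-pass pileups are reduced to per-line majority-allele genotype calls,
filtered so both genotypes are seen in a minimum number of lines, thinned to
an approximately even genomic grid, and oriented to the panel-wide major
allele. The scan statistic at each site is the difference in major-allele
carrier counts between two phenotype groups (e.g. six high- vs six
low-arrhythmia lines, bounded by +|g1| and -|g2|), averaged over sliding
windows of consecutive SNPs. Significance comes from random re-draws of the
line groups: the threshold is a high percentile of the largest window value
sustained across a minimum genomic span (peaks shorter than the span are
ignored, mirroring how only broad linkage signals are interpretable in a
panel of this size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsa import WindowProfile, sliding_window, window_means_matrix
from .simulate import SiteCounts

MISSING = -1
ALLELE_Y = 0
ALLELE_W = 1


@dataclass
class GenotypeMatrix:
    """Lines x sites parental-allele calls.

    ``calls`` is int8 with entries 1 (WE70), 0 (yw) and -1 (missing).
    ``sites`` has columns (chrom, pos), sorted by genome position.
    ``classes`` optionally assigns each line a phenotype class label
    (highAI / lowAI / wideSD / narrowSD).
    """

    line_ids: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.sites)):
            raise ValueError("calls shape must be (n_lines, n_sites)")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def line_index(self, ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        return np.asarray([lookup[i] for i in ids], dtype=np.intp)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.line_ids, self.sites.loc[mask].reset_index(drop=True),
                              self.calls[:, np.asarray(mask, bool)], dict(self.classes))


def call_genotype(count_w, count_y, min_depth: int = 2) -> np.ndarray:
    """Majority-allele genotype call per site.

    Returns 1 (WE70) / 0 (yw) / -1 (missing). Missing encodes ties and
    insufficient depth; residual heterozygosity in a line therefore surfaces
    as whichever allele dominates its pileup (or missing on an exact tie).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    count_w = np.asarray(count_w)
    count_y = np.asarray(count_y)
    calls = np.full(count_w.shape, MISSING, dtype=np.int8)
    depth = count_w + count_y
    ok = depth >= min_depth
    calls[ok & (count_w > count_y)] = ALLELE_W
    calls[ok & (count_y > count_w)] = ALLELE_Y
    return calls


def genotype_matrix_from_pileups(pileups: dict[str, SiteCounts],
                                 min_depth: int = 2,
                                 classes: dict[str, str] | None = None) -> GenotypeMatrix:
    """Stack per-line pileups (identical site frames) into a GenotypeMatrix."""
    line_ids = list(pileups)
    first = pileups[line_ids[0]].sites
    calls = np.stack([
        call_genotype(pileups[lid].count_w, pileups[lid].count_y, min_depth)
        for lid in line_ids
    ])
    return GenotypeMatrix(line_ids, first.reset_index(drop=True), calls,
                          dict(classes or {}))


def filter_sites(gm: GenotypeMatrix, min_lines: int = 3) -> GenotypeMatrix:
    """Keep sites where the WE70 and the yw genotype are each observed in at
    least ``min_lines`` lines. An empty result is legal (caller's problem)."""
    n_w = (gm.calls == ALLELE_W).sum(axis=0)
    n_y = (gm.calls == ALLELE_Y).sum(axis=0)
    return gm.subset_sites((n_w >= min_lines) & (n_y >= min_lines))


def thin_sites(gm: GenotypeMatrix, spacing: int = 10_000) -> GenotypeMatrix:
    """At most one site per ``spacing`` bin per chromosome (half-open bins on
    0-based coordinates); the first qualifying site of each bin is kept."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    chrom = gm.sites["chrom"].to_numpy()
    bins = (gm.sites["pos"].to_numpy() - 1) // spacing
    keep = np.ones(len(gm.sites), dtype=bool)
    keep[1:] = (chrom[1:] != chrom[:-1]) | (bins[1:] != bins[:-1])
    return gm.subset_sites(keep)


@dataclass
class OrientedMatrix:
    """Genotype matrix recoded against the per-site panel-major allele.

    ``carries`` is int8: 1 carries-major, 0 carries-minor, -1 missing.
    """

    line_ids: list[str]
    sites: pd.DataFrame
    carries: np.ndarray
    major_allele: np.ndarray  # per site, 1 = WE70, 0 = yw
    classes: dict[str, str] = field(default_factory=dict)

    def line_index(self, ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        return np.asarray([lookup[i] for i in ids], dtype=np.intp)

    def parental_calls(self) -> np.ndarray:
        """Undo the orientation: int8 calls in WE70/yw/missing coding."""
        flipped = np.where(self.carries == MISSING, MISSING, 1 - self.carries)
        return np.where(self.major_allele[None, :] == ALLELE_W,
                        self.carries, flipped).astype(np.int8)


def orient_major_allele(gm: GenotypeMatrix) -> OrientedMatrix:
    """Label each site's across-line modal allele 'major' and recode calls as
    carries-major / carries-minor / missing. Ties designate WE70 major."""
    n_w = (gm.calls == ALLELE_W).sum(axis=0)
    n_y = (gm.calls == ALLELE_Y).sum(axis=0)
    major = np.where(n_w >= n_y, ALLELE_W, ALLELE_Y).astype(np.int8)
    carries = np.full(gm.calls.shape, MISSING, dtype=np.int8)
    known = gm.calls != MISSING
    carries[known] = (gm.calls == major[None, :])[known]
    return OrientedMatrix(gm.line_ids, gm.sites, carries, major, dict(gm.classes))


def group_difference(om: OrientedMatrix, group1, group2) -> np.ndarray:
    """Per-site signed carrier-count difference:
    (# group1 lines carrying the major allele) - (# group2 lines carrying it).
    Missing entries contribute zero to either count; values lie in
    [-len(group2), +len(group1)].
    """
    idx1 = om.line_index(group1)
    idx2 = om.line_index(group2)
    if np.intersect1d(idx1, idx2).size:
        raise ValueError("groups must be disjoint")
    carries = om.carries == 1
    return carries[idx1].sum(axis=0).astype(np.int16) - carries[idx2].sum(axis=0).astype(np.int16)


def group_difference_parental(gm: GenotypeMatrix, group1, group2) -> np.ndarray:
    """Carrier-count difference oriented by the WE70 parental allele.

    Available when parental origin is known (simulated data, or a study that
    sequenced both parents); the major-allele orientation of
    :func:`group_difference` is the proxy a study without parental genotypes
    must use, and it is unstable wherever the panel allele frequency sits
    near 1/2 — which is exactly where a recessive causal locus puts it.
    """
    idx1 = gm.line_index(group1)
    idx2 = gm.line_index(group2)
    if np.intersect1d(idx1, idx2).size:
        raise ValueError("groups must be disjoint")
    calls = gm.parental_calls() if isinstance(gm, OrientedMatrix) else gm.calls
    carries = calls == ALLELE_W
    return carries[idx1].sum(axis=0).astype(np.int16) - carries[idx2].sum(axis=0).astype(np.int16)


def ril_window_profile(differences, sites: pd.DataFrame, window: int = 100,
                       step: int = 1) -> WindowProfile:
    """Window-averaged group-difference profile (shared window engine)."""
    return sliding_window(differences, sites["chrom"], sites["pos"],
                          window=window, step=step)


def sequence_panel(genomes: dict, marker_map, coverage: float = 8.0,
                   error_rate: float = 0.01,
                   residual_het: float | None = None,
                   min_depth: int = 2, min_lines: int = 3,
                   spacing: int = 10_000, seed=None,
                   classes: dict[str, str] | None = None) -> OrientedMatrix:
    """Low-pass re-sequencing observation pipeline for a panel of lines:
    pileups -> majority-allele calls -> both-genotypes-in->=min_lines filter ->
    one-site-per-spacing thinning -> major-allele orientation.

    ``residual_het`` designates the fraction of unfixed sites per line (see
    :func:`cardiomap.simulate.simulate_pileups`); pass
    ``cardiomap.simulate.RIL_RESIDUAL_HET`` to emulate the observed fixation
    level of re-sequenced lines, or None to use each genome's genuine
    heterozygosity. Per-line pileup seeds derive deterministically from
    ``seed``.
    """
    from .simulate import simulate_pileups

    line_ids = list(genomes)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(line_ids))
    pileups = {
        lid: simulate_pileups(genomes[lid], marker_map, coverage=coverage,
                              error_rate=error_rate, residual_het=residual_het,
                              rng=np.random.default_rng(child))
        for lid, child in zip(line_ids, children)
    }
    gm = genotype_matrix_from_pileups(pileups, min_depth=min_depth, classes=classes)
    gm = thin_sites(filter_sites(gm, min_lines=min_lines), spacing=spacing)
    return orient_major_allele(gm)


def ril_scan(om: OrientedMatrix, group1, group2, window: int = 100,
             threshold: float | None = None, min_span: float = 10_000_000.0,
             n_perm: int = 1000, percentile: float = 95.0, seed=None):
    """Group-difference window profile plus called peaks for one contrast.

    When ``threshold`` is None it is computed by :func:`ril_threshold` from
    random group draws of the same sizes. Returns (profile, peaks, threshold).
    """
    diffs = group_difference(om, group1, group2)
    profile = ril_window_profile(diffs, om.sites, window=window)
    if threshold is None:
        threshold = ril_threshold(om, (len(group1), len(group2)), n_perm=n_perm,
                                  window=window, min_span=min_span,
                                  percentile=percentile, seed=seed)
    profile.thresholds = (-threshold, threshold)
    peaks = call_peaks(profile, threshold, min_span=min_span)
    return profile, peaks, threshold


# ---------------------------------------------------------------------------
# Span-constrained permutation threshold
# ---------------------------------------------------------------------------


def _run_min_per_start(win_values: np.ndarray, run_len: np.ndarray) -> np.ndarray:
    """Minimum of the minimal qualifying run starting at each window.

    ``win_values`` is (m, n_windows); ``run_len[i]`` is the number of
    consecutive windows starting at i whose combined genomic span first
    reaches the minimum span (0 where unattainable). Returns an (m, n) array
    of min(win[i .. i+run_len[i]-1]) with -inf at unattainable starts. Uses a
    sparse table of power-of-two sliding minima, vectorized over rows.
    """
    m, n = win_values.shape
    out = np.full((m, n), -np.inf)
    valid = np.flatnonzero(run_len > 0)
    if valid.size == 0:
        return out
    kmax = int(run_len[valid].max())
    levels = [win_values]
    size = 1
    while size * 2 <= kmax:
        prev = levels[-1]
        levels.append(np.minimum(prev[:, :prev.shape[1] - size], prev[:, size:]))
        size *= 2
    k_of = (np.floor(np.log2(run_len[valid]))).astype(int)
    for k in np.unique(k_of):
        starts = valid[k_of == k]
        length = run_len[starts]
        tbl = levels[k]
        out[:, starts] = np.minimum(tbl[:, starts], tbl[:, starts + length - (1 << k)])
    return out


def _sustained_extremum(win_values: np.ndarray, run_len: np.ndarray) -> np.ndarray:
    """Largest value sustained over a qualifying run, per row: the highest
    level at which some >= min-span run stays entirely at or above it."""
    return _run_min_per_start(win_values, run_len).max(axis=1)


def _run_lengths(starts_bp: np.ndarray, ends_bp: np.ndarray, min_span: float) -> np.ndarray:
    """Per window start, the count of consecutive windows needed for the run
    start..end to span >= min_span bp (0 where no run fits)."""
    n = starts_bp.size
    j = np.searchsorted(ends_bp, starts_bp + min_span, side="left")
    run = np.where(j < n, j - np.arange(n) + 1, 0)
    return run.astype(np.int64)


def localize_peak(differences, sites: pd.DataFrame, window: int = 100,
                  min_span: float = 10_000_000.0) -> PeakCall | None:
    """Strongest span-sustained peak of a group-difference profile.

    For every candidate run of consecutive windows whose genomic span first
    reaches ``min_span``, the run is scored by the level it sustains (the
    minimum |window value| across it, sign-aware); the best-scoring run over
    the genome is returned. This is the scan's localization rule: isolated
    extreme windows are common under drift, but only linkage to a causal
    region sustains an extreme level across a long span.
    """
    differences = np.asarray(differences, float)
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(np.int64)
    best: PeakCall | None = None
    best_score = -np.inf
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < window:
            continue
        win = window_means_matrix(differences[None, idx[0]:idx[-1] + 1], window)
        starts = pos[idx[: idx.size - window + 1]].astype(float)
        ends = pos[idx[window - 1:]].astype(float)
        run = _run_lengths(starts, ends, min_span)
        for sign in (1.0, -1.0):
            mins = _run_min_per_start(sign * win, run)[0]
            i = int(np.argmax(mins))
            score = float(mins[i])  # level sustained in this direction
            if not np.isfinite(score):
                continue
            if best is None or score > best_score:
                # widen to the maximal run holding the sustained level
                held = sign * win[0] >= score
                lo = i
                while lo > 0 and held[lo - 1]:
                    lo -= 1
                hi = i + int(run[i]) - 1
                while hi + 1 < held.size and held[hi + 1]:
                    hi += 1
                best_score = score
                best = PeakCall(chrom=str(c), start=int(starts[lo]),
                                end=int(ends[hi]), value=sign * score,
                                direction="group1-excess" if sign > 0 else "group2-excess",
                                span=int(ends[hi] - starts[lo]))
    return best


def sustained_peak_height(profile_values: np.ndarray, starts_bp: np.ndarray,
                          ends_bp: np.ndarray, min_span: float) -> float:
    """Largest |value| sustained across a >= min_span run of one chromosome's
    windows, considering both signs. -inf when no run fits."""
    run = _run_lengths(np.asarray(starts_bp, float), np.asarray(ends_bp, float), min_span)
    v = np.asarray(profile_values, float)[None, :]
    return float(max(_sustained_extremum(v, run)[0], _sustained_extremum(-v, run)[0]))


def ril_threshold(om: OrientedMatrix, group_sizes: tuple[int, int] = (6, 6),
                  n_perm: int = 1000, window: int = 100,
                  min_span: float = 10_000_000.0, percentile: float = 95.0,
                  seed=None, return_maxima: bool = False):
    """Permutation threshold for sustained window peaks.

    Draws ``n_perm`` random disjoint line groups of the stated sizes from all
    lines (regardless of phenotype), recomputes the window profile for each,
    and records the largest |window value| sustained over a run of consecutive
    windows spanning at least ``min_span`` bp. The threshold (reported as a
    symmetric +/- bound) is the ``percentile`` quantile of those maxima.
    """
    n1, n2 = group_sizes
    n_lines = len(om.line_ids)
    if n1 + n2 > n_lines:
        raise ValueError("not enough lines to draw disjoint groups")
    if n_perm < 20:
        import warnings

        warnings.warn("fewer than 20 permutations gives a very coarse threshold")
    rng = np.random.default_rng(seed)
    draws = np.stack([rng.permutation(n_lines)[:n1 + n2] for _ in range(n_perm)])
    carries = (om.carries == 1).astype(np.int8)

    chrom = om.sites["chrom"].to_numpy()
    pos = om.sites["pos"].to_numpy(np.int64)
    chrom_slices = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < window:
            continue
        starts = pos[idx[: idx.size - window + 1]].astype(float)
        ends = pos[idx[window - 1:]].astype(float)
        run = _run_lengths(starts, ends, min_span)
        chrom_slices.append((idx[0], idx[-1] + 1, run))

    maxima = np.full(n_perm, -np.inf)
    chunk = max(1, 50_000_000 // max(om.carries.shape[1], 1))
    for lo in range(0, n_perm, chunk):
        sel = draws[lo:lo + chunk]
        g1 = carries[sel[:, :n1]].sum(axis=1).astype(np.float64)
        g2 = carries[sel[:, n1:]].sum(axis=1).astype(np.float64)
        diff = g1 - g2
        best = np.full(sel.shape[0], -np.inf)
        for a, b, run in chrom_slices:
            win = window_means_matrix(diff[:, a:b], window)
            best = np.maximum(best, _sustained_extremum(win, run))
            best = np.maximum(best, _sustained_extremum(-win, run))
        maxima[lo:lo + sel.shape[0]] = best
    threshold = float(np.percentile(maxima[np.isfinite(maxima)], percentile))
    if return_maxima:
        return threshold, maxima
    return threshold


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakCall:
    chrom: str
    start: int  # bp of the first window's first SNP (1-based inclusive)
    end: int    # bp of the last window's last SNP
    value: float  # signed extremum within the run
    direction: str  # "major-excess in group1" sign: W-excess/Y-excess semantics
    span: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("peak end before start")


def call_peaks(profile: WindowProfile, threshold: float,
               min_span: float = 10_000_000.0) -> list[PeakCall]:
    """Maximal runs of consecutive windows beyond +/- threshold whose genomic
    span (first to last SNP) is at least ``min_span``."""
    peaks: list[PeakCall] = []
    for chrom, sub in profile.windows.groupby("chrom", sort=False):
        values = sub["value"].to_numpy()
        for sign, direction in ((1.0, "group1-excess"), (-1.0, "group2-excess")):
            mask = sign * values >= threshold
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                block = sub.iloc[run]
                start = int(block["start"].iloc[0])
                end = int(block["end"].iloc[-1])
                if end - start < min_span:
                    continue
                ext = float(block["value"].max() if sign > 0 else block["value"].min())
                peaks.append(PeakCall(chrom=str(chrom), start=start, end=end,
                                      value=ext, direction=direction,
                                      span=end - start))
    return peaks
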