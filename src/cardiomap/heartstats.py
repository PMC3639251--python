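"""Heart-phenotype statistics: arrhythmia index, diameter summaries,
correlation tests, between-line variance partitioning, extreme-line selection.

A phenotype table is a pandas DataFrame with columns ``line`` (line id or
genotype group), ``fly``, and one column per trait (``sd``, ``dd``, ``ai``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default aberrant-classification cutoffs. The SD cutoff is the midpoint of
#: the parental means (20 and 37 um); the AI cutoff separates the wildtype
#: (0.06) from the aberrant (0.28) distributions.
SD_ABERRANT_CUTOFF = 27.0
AI_ABERRANT_CUTOFF = 0.17


class InsufficientDataError(ValueError):
    pass


def arrhythmia_index(periods) -> float:
    """Arrhythmia index: dispersion of heart-period durations normalized to
    the fly's median heart period.

    AI = sample standard deviation of the beat periods / median period. It is
    dimensionless, non-negative, and invariant under rescaling time (playing
    the same rhythm faster or slower) and under permuting the beats.
    """
    periods = np.asarray(periods, dtype=float)
    if periods.size < 3:
        raise InsufficientDataError("AI requires at least 3 beat periods")
    if np.any(periods <= 0):
        raise ValueError("beat periods must be positive")
    return float(np.std(periods, ddof=1) / np.median(periods))


def fractional_shortening(dd: float, sd: float) -> float:
    """(DD - SD) / DD, the fraction of the diastolic diameter lost in systole."""
    if dd <= 0:
        raise ValueError("diastolic diameter must be positive")
    if sd > dd or sd < 0:
        raise ValueError("require 0 <= SD <= DD")
    return (dd - sd) / dd


def group_summary(table: pd.DataFrame, trait: str, group_col: str = "line") -> pd.DataFrame:
    """Per-group n, mean, sd and SEM (= sd / sqrt(n)) of a trait."""
    if table.empty:
        raise ValueError("empty phenotype table")
    g = table.groupby(group_col)[trait]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
    if (out["n"] < 2).any():
        raise ValueError("every group needs at least 2 flies")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


@dataclass(frozen=True)
class CorrelationTest:
    r: float
    t: float
    p: float


def pearson_test(x, y) -> CorrelationTest:
    """Pearson correlation with the exact t test:
    t = r * sqrt(n - 2) / sqrt(1 - r^2), two-sided p from Student-t(n - 2).

    |r| = 1 is reported as t = +/-inf with p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    n = x.size
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if 1.0 - r * r < 1e-12:  # numerically perfect correlation
        return CorrelationTest(r=float(np.sign(r)), t=float(np.sign(r)) * np.inf, p=0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationTest(r=r, t=float(t), p=float(p))


@dataclass(frozen=True)
class RegressionTest:
    r2: float
    f: float
    p: float


def regression_r2_f(x, y) -> RegressionTest:
    """Simple linear regression R^2 with its F test:
    F = R^2 (n - 2) / (1 - R^2), p from F(1, n - 2). R^2 = 1 gives p = 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("regression undefined for a constant vector")
    n = x.size
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    r2 = r * r
    if 1.0 - r2 < 1e-12:
        return RegressionTest(r2=1.0, f=np.inf, p=0.0)
    f = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(f, 1, n - 2))
    return RegressionTest(r2=r2, f=float(f), p=p)


def variance_between_fraction(table: pd.DataFrame, trait: str,
                              group_col: str = "line") -> float:
    """Fraction of total variance lying between lines (one-way layout):
    between-line sum of squares / total sum of squares."""
    values = table[trait].to_numpy(float)
    groups = table[group_col]
    if groups.nunique() < 2:
        raise ValueError("between-line variance undefined for a single line")
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    if sst == 0:
        raise ValueError("zero total variance")
    means = table.groupby(group_col)[trait].transform("mean").to_numpy(float)
    ssb = float(((means - grand) ** 2).sum())
    return ssb / sst


@dataclass(frozen=True)
class ExtremeSelection:
    low: list
    high: list


def select_extremes(table: pd.DataFrame, trait: str, k: int,
                    group_col: str = "line") -> ExtremeSelection:
    """Line ids of the k smallest and k largest line means of ``trait``.

    Ties in the line mean are broken by line id (ascending), making the
    selection deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    means = table.groupby(group_col)[trait].mean()
    if 2 * k > means.size:
        raise ValueError("k per tail exceeds half the number of lines")
    order = means.reset_index().sort_values([trait, group_col])
    ids = order[group_col].tolist()
    return ExtremeSelection(low=ids[:k], high=ids[-k:])


def classify_aberrant(table: pd.DataFrame, sd_cutoff: float = SD_ABERRANT_CUTOFF,
                      ai_cutoff: float = AI_ABERRANT_CUTOFF) -> pd.DataFrame:
    """Add boolean ``aberrant_sd`` / ``aberrant_ai`` classification columns
    (constricted heart: SD below cutoff; arrhythmic: AI above cutoff)."""
    out = table.copy()
    if "sd" in out:
        out["aberrant_sd"] = out["sd"] < sd_cutoff
    if "ai" in out:
        out["aberrant_ai"] = out["ai"] > ai_cutoff
    return out


def validate_phenotype_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check table invariants: unique (line, fly) keys and DD >= SD."""
    if {"line", "fly"}.issubset(table.columns) and table.duplicated(["line", "fly"]).any():
        raise ValueError("duplicate (line, fly) keys")
    if {"sd", "dd"}.issubset(table.columns):
        both = table[["sd", "dd"]].dropna()
        if (both["dd"] < both["sd"]).any():
            raise ValueError("DD < SD in phenotype table")
    return table
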