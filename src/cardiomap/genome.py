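"""Genome coordinate frame shared by every scan: chromosome arms and marker grids.

The default map approximates the five major *D. melanogaster* chromosome arms
plus the X. Arms are modelled as independent linkage units (the centromere
suppresses crossing-over between arms strongly enough that, at the resolution
of these scans, treating 2L/2R and 3L/3R as separate units is adequate).
Positions are 1-based base pairs throughout the in-memory model; file writers
state their own convention in their headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Approximate euchromatic arm lengths (bp) of the D. melanogaster genome.
DEFAULT_ARMS: tuple[tuple[str, int], ...] = (
    ("X", 22_400_000),
    ("2L", 23_000_000),
    ("2R", 21_100_000),
    ("3L", 24_500_000),
    ("3R", 27_900_000),
)

#: Whole chromosomes as groups of arms (used by substitution lines).
CHROMOSOME_ARMS: dict[str, tuple[str, ...]] = {
    "X": ("X",),
    "2": ("2L", "2R"),
    "3": ("3L", "3R"),
}


class GenomeConfigError(ValueError):
    """Raised for an inconsistent genome configuration."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker grid over a set of chromosome arms.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs. Lengths must be positive.
    positions
        Mapping arm name -> strictly increasing 1-based marker positions.
    crossover_rate
        Expected crossovers per female meiosis per arm (Poisson mean).
        1.0 corresponds to a 50 cM arm, close to the observed female map.
    """

    chromosomes: tuple[tuple[str, int], ...]
    positions: dict[str, np.ndarray] = field(repr=False)
    crossover_rate: float = 1.0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeConfigError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeConfigError(f"chromosome {name!r} has non-positive length")
        if set(self.positions) != set(names):
            raise GenomeConfigError("positions must cover exactly the named chromosomes")
        lengths = dict(self.chromosomes)
        for name, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size == 0:
                raise GenomeConfigError(f"chromosome {name!r} carries no markers")
            if np.any(np.diff(pos) <= 0):
                raise GenomeConfigError(f"marker positions on {name!r} not strictly increasing")
            if pos[0] < 1 or pos[-1] > lengths[name]:
                raise GenomeConfigError(f"marker positions on {name!r} out of range")
            self.positions[name] = pos
        if self.crossover_rate < 0:
            raise GenomeConfigError("crossover rate must be >= 0")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(name for name in self.chrom_names if name != "X")

    def n_markers(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.positions[chrom].size)
        return int(sum(p.size for p in self.positions.values()))

    def marker_index(self, chrom: str, position: int) -> int:
        """Index of the marker nearest ``position`` on ``chrom``."""
        pos = self.positions[chrom]
        i = int(np.searchsorted(pos, position))
        if i == 0:
            return 0
        if i == pos.size:
            return int(pos.size - 1)
        return i if pos[i] - position < position - pos[i - 1] else i - 1

    def site_table(self):
        """Flat (chrom, pos) table over all markers, in map order."""
        import pandas as pd

        chroms = np.concatenate(
            [np.repeat(name, self.positions[name].size) for name in self.chrom_names]
        )
        pos = np.concatenate([self.positions[name] for name in self.chrom_names])
        return pd.DataFrame({"chrom": chroms, "pos": pos})


def make_marker_map(
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_ARMS,
    spacing: int = 10_000,
    crossover_rate: float = 1.0,
) -> MarkerMap:
    """Evenly spaced marker grid: markers at spacing, 2*spacing, ... <= length.

    A chromosome shorter than ``spacing`` still receives one marker (at its
    end) so every arm is scannable. Deterministic for a given configuration.
    """
    if spacing <= 0:
        raise GenomeConfigError("marker spacing must be positive")
    positions: dict[str, np.ndarray] = {}
    for name, length in chromosomes:
        if length <= 0:
            raise GenomeConfigError(f"chromosome {name!r} has non-positive length")
        grid = np.arange(spacing, length + 1, spacing, dtype=np.int64)
        if grid.size == 0:
            grid = np.array([length], dtype=np.int64)
        positions[name] = grid
    return MarkerMap(tuple(chromosomes), positions, crossover_rate)
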