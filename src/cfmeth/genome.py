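"""Genome-wide CpG coordinate system.

Fragment-level bisulfite data anchors every observation to a CpG dinucleotide
rather than to a base-pair coordinate.  :class:`GenomeCpGIndex` holds the
ordered CpG positions of every chromosome and provides the exact,
bidirectional mapping between genomic coordinates (1-based position of the C)
and the genome-wide 1-based CpG *serial index* used by PAT/BETA-style files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["GenomeCpGIndex"]


@dataclass(frozen=True)
class GenomeCpGIndex:
    """Ordered CpG positions per chromosome plus a global serial index.

    Parameters
    ----------
    chroms
        Chromosome labels in genome order.
    positions
        One int array per chromosome: strictly increasing 1-based genomic
        positions of the C of each CpG.

    Serial indices are 1-based, contiguous and unique genome-wide, assigned
    chromosome by chromosome in the order of ``chroms``.
    """

    chroms: tuple[str, ...]
    positions: tuple[np.ndarray, ...]
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.positions):
            raise ValueError("chroms and positions must have equal length")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome labels")
        pos = tuple(np.asarray(p, dtype=np.int64) for p in self.positions)
        for c, p in zip(self.chroms, pos):
            if p.ndim != 1 or p.size == 0:
                raise ValueError(f"{c}: positions must be a non-empty 1-d array")
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"{c}: CpG positions must be strictly increasing")
            if p[0] < 1:
                raise ValueError(f"{c}: positions are 1-based and must be >= 1")
        object.__setattr__(self, "positions", pos)
        counts = np.array([p.size for p in pos], dtype=np.int64)
        # _offsets[i] = serial index of the first CpG of chromosome i
        object.__setattr__(
            self, "_offsets", np.concatenate([[1], 1 + np.cumsum(counts)])
        )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dict(cls, positions: Mapping[str, Sequence[int]]) -> "GenomeCpGIndex":
        return cls(tuple(positions), tuple(np.asarray(v) for v in positions.values()))

    # -- basic properties --------------------------------------------------

    @property
    def n_cpgs(self) -> int:
        """Total CpG count genome-wide."""
        return int(self._offsets[-1] - 1)

    def n_cpgs_chrom(self, chrom: str) -> int:
        return self.positions[self._chrom_i(chrom)].size

    def _chrom_i(self, chrom: str) -> int:
        try:
            return self.chroms.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_serial_range(self, chrom: str) -> tuple[int, int]:
        """(first, last) serial index of a chromosome, both inclusive."""
        i = self._chrom_i(chrom)
        return int(self._offsets[i]), int(self._offsets[i + 1] - 1)

    # -- coordinate mapping ------------------------------------------------

    def serial_to_chrom(self, serial: int | np.ndarray) -> np.ndarray:
        """Chromosome array-index for each serial index."""
        s = np.asarray(serial)
        if np.any((s < 1) | (s > self.n_cpgs)):
            raise IndexError("serial index out of range")
        return np.searchsorted(self._offsets, s, side="right") - 1

    def serial_to_position(self, serial: int | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map serial index -> (chromosome array-index, genomic position)."""
        s = np.atleast_1d(np.asarray(serial, dtype=np.int64))
        ci = self.serial_to_chrom(s)
        pos = np.empty(s.size, dtype=np.int64)
        for i in np.unique(ci):
            m = ci == i
            pos[m] = self.positions[i][s[m] - self._offsets[i]]
        return ci, pos

    def position_to_serial(self, chrom: str, position: int) -> int:
        i = self._chrom_i(chrom)
        j = int(np.searchsorted(self.positions[i], position))
        if j >= self.positions[i].size or self.positions[i][j] != position:
            raise KeyError(f"no CpG at {chrom}:{position}")
        return int(self._offsets[i] + j)

    def serial_positions(self, first: int, last: int) -> np.ndarray:
        """Genomic positions of serials ``first..last`` (same chromosome)."""
        ci_a = int(self.serial_to_chrom(first))
        ci_b = int(self.serial_to_chrom(last))
        if ci_a != ci_b:
            raise ValueError("serial range crosses a chromosome boundary")
        off = self._offsets[ci_a]
        return self.positions[ci_a][first - off : last - off + 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeCpGIndex):
            return NotImplemented
        return self.chroms == other.chroms and all(
            np.array_equal(a, b) for a, b in zip(self.positions, other.positions)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: identity hash
        return id(self)
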