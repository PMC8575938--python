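"""Circular genome coordinate system and lysogen layout.

All coordinates are 0-based, intervals half-open, arithmetic modulo the
chromosome length.  A :class:`GenomeLayout` describes a circular bacterial
chromosome carrying one integrated *pac*-type prophage: the attL/attR hybrid
junctions, the packaging-initiation (*pac*) site inside the prophage, the
packaging direction, and the capsid headful capacity (~105 % of the phage
genome unit length).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularInterval",
    "GenomeLayout",
    "headful_capacity",
    "lt_reach",
    "circ_window_tile",
]


@dataclass(frozen=True)
class CircularInterval:
    """Half-open interval ``[start, end)`` on a circle of given length.

    ``end`` may be numerically smaller than ``start``, in which case the
    interval wraps the origin.  ``start == end`` denotes the full circle.
    """

    start: int
    end: int
    chromosome_length: int

    def __post_init__(self):
        L = self.chromosome_length
        if L <= 0:
            raise ValueError("chromosome_length must be positive")
        object.__setattr__(self, "start", int(self.start) % L)
        object.__setattr__(self, "end", int(self.end) % L)

    @classmethod
    def from_length(cls, start: int, length: int, chromosome_length: int) -> "CircularInterval":
        if not 0 < length <= chromosome_length:
            raise ValueError("interval length must be in (0, chromosome_length]")
        return cls(start, (start + length) % chromosome_length, chromosome_length)

    @property
    def length(self) -> int:
        d = (self.end - self.start) % self.chromosome_length
        return d if d != 0 else self.chromosome_length

    def contains_point(self, pos: int) -> bool:
        return (pos - self.start) % self.chromosome_length < self.length

    def contains_interval(self, other: "CircularInterval") -> bool:
        """True if ``other`` lies entirely inside this interval."""
        off = (other.start - self.start) % self.chromosome_length
        return off + other.length <= self.length

    def shift(self, offset: int) -> "CircularInterval":
        return CircularInterval.from_length(
            (self.start + offset) % self.chromosome_length, self.length, self.chromosome_length
        )

    def unwrap(self) -> list[tuple[int, int]]:
        """Decompose into 1-2 linear ``(start, end)`` pieces in [0, L]."""
        if self.start + self.length <= self.chromosome_length:
            return [(self.start, self.start + self.length)]
        return [(self.start, self.chromosome_length), (0, (self.start + self.length) % self.chromosome_length)]


@dataclass(frozen=True)
class GenomeLayout:
    """Circular chromosome with one integrated prophage.

    Parameters
    ----------
    chromosome_length:
        Length of the (circular) lysogen chromosome in bp.
    prophage_start:
        attL position: first bp of the integrated prophage.
    prophage_length:
        Phage genome unit length ``G`` in bp.
    attB_pos:
        Junction position on the non-lysogen chromosome.
    pac_offset:
        Offset in bp from ``prophage_start`` to the packaging-initiation site.
    packaging_direction:
        +1 for packaging toward increasing coordinates, -1 for the mirror.
    headful_capacity:
        Capsid headful in bp; defaults to ``round(1.05 * prophage_length)``.
    ori_offset:
        Offset from ``prophage_start`` to the theta-replication origin.
    """

    chromosome_length: int
    prophage_start: int
    prophage_length: int
    attB_pos: int
    pac_offset: int
    packaging_direction: int = 1
    headful_capacity: int | None = None
    ori_offset: int = 0

    def __post_init__(self):
        if self.chromosome_length <= 0 or self.prophage_length <= 0:
            raise ValueError("lengths must be positive")
        if self.prophage_length >= self.chromosome_length:
            raise ValueError("prophage must be shorter than the chromosome")
        if not 0 <= self.pac_offset < self.prophage_length:
            raise ValueError("pac_offset must lie within the prophage")
        if not 0 <= self.ori_offset < self.prophage_length:
            raise ValueError("ori_offset must lie within the prophage")
        if self.packaging_direction not in (-1, 1):
            raise ValueError("packaging_direction must be +1 or -1")
        if self.headful_capacity is None:
            object.__setattr__(self, "headful_capacity", headful_capacity(self.prophage_length))
        if self.headful_capacity <= self.prophage_length:
            raise ValueError("headful_capacity must exceed the phage genome unit length")

    # -- derived positions -------------------------------------------------
    @property
    def attL_pos(self) -> int:
        return self.prophage_start

    @property
    def attR_pos(self) -> int:
        return (self.prophage_start + self.prophage_length) % self.chromosome_length

    @property
    def pac_pos(self) -> int:
        if self.packaging_direction == 1:
            return (self.prophage_start + self.pac_offset) % self.chromosome_length
        return (self.prophage_start + self.prophage_length - 1 - self.pac_offset) % self.chromosome_length

    @property
    def pac_to_attR(self) -> int:
        """Phage bp packaged before the series crosses into the chromosome."""
        return self.prophage_length - self.pac_offset

    @property
    def prophage_interval(self) -> CircularInterval:
        return CircularInterval.from_length(self.prophage_start, self.prophage_length, self.chromosome_length)

    @property
    def downstream_edge(self) -> int:
        """First chromosomal bp past the prophage in the packaging direction."""
        if self.packaging_direction == 1:
            return self.attR_pos
        return (self.attL_pos - 1) % self.chromosome_length

    def forward_distance(self, pos) -> np.ndarray | int:
        """Distance from the downstream prophage edge along the packaging direction."""
        if self.packaging_direction == 1:
            return (np.asarray(pos) - self.attR_pos) % self.chromosome_length
        return (self.attL_pos - 1 - np.asarray(pos)) % self.chromosome_length

    def replace(self, **kw) -> "GenomeLayout":
        return dataclasses.replace(self, **kw)

    @classmethod
    def p22_default(cls) -> "GenomeLayout":
        """P22-like layout: LT2-sized chromosome, 41,724 bp phage unit, pac
        mid-terS (no published bp coordinate; centred by convention)."""
        G = 41_724
        return cls(
            chromosome_length=4_857_450,
            prophage_start=1_200_000,
            prophage_length=G,
            attB_pos=1_200_000,
            pac_offset=G // 2,
            packaging_direction=1,
            ori_offset=G // 2,
        )

    @classmethod
    def es18_default(cls) -> "GenomeLayout":
        """ES18-like layout: same attB, unrelated packaging module, ~46.9 kb unit."""
        G = 46_900
        return cls(
            chromosome_length=4_857_450,
            prophage_start=1_200_000,
            prophage_length=G,
            attB_pos=1_200_000,
            pac_offset=G // 2,
            packaging_direction=1,
            ori_offset=G // 2,
        )


def headful_capacity(genome_unit_length: int, factor: float = 1.05) -> int:
    """Capsid headful in bp: ``round(factor * G)``; P22's ~105 % of 41,724 bp
    gives 43,810 bp, i.e. the 'around 44 kb' capacity."""
    if genome_unit_length <= 0:
        raise ValueError("genome_unit_length must be positive")
    if factor < 1:
        raise ValueError("headful factor must be >= 1")
    return round(factor * genome_unit_length)


def lt_reach(n_headfuls: int, headful: int, pac_to_attR: int) -> int:
    """Chromosomal span reachable by ``n`` successive headfuls from pac.

    The first headful spends ``pac_to_attR`` bp on the phage segment, so the
    reach into the chromosome is ``n * headful - pac_to_attR``.
    """
    if n_headfuls < 1:
        raise ValueError("n_headfuls must be >= 1")
    if not 0 <= pac_to_attR <= headful:
        raise ValueError("pac_to_attR must be within one headful")
    return max(0, n_headfuls * headful - pac_to_attR)


def circ_window_tile(chromosome_length: int, window: int) -> list[CircularInterval]:
    """Non-overlapping tiles covering the chromosome exactly once; the last
    tile may be short."""
    if not 0 < window <= chromosome_length:
        raise ValueError("window must be in (0, chromosome_length]")
    tiles = []
    for s in range(0, chromosome_length, window):
        e = min(s + window, chromosome_length)
        tiles.append(CircularInterval.from_length(s, e - s, chromosome_length))
    return tiles


def n_windows(chromosome_length: int, window: int) -> int:
    return -(-chromosome_length // window)


def window_starts(chromosome_length: int, window: int) -> np.ndarray:
    return np.arange(0, chromosome_length, window)
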