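"""Circular-chromosome coordinate arithmetic and oriC-relative geometry.

Bacterial chromosomes are circles replicated bidirectionally from a single
origin (oriC) toward a terminus region (ter) roughly at the antipode.  All
spatial statistics in this package are expressed relative to the oriC-ter
axis: distances along the circle, oriC proximity (1 at oriC, 0 at ter), and
the assignment of loci to the two replichores (chromosome arms).

Coordinates are 0-based throughout; intervals are half-open.  All functions
accept scalars or numpy arrays for the position argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CoordinateError

__all__ = [
    "CircularChromosome",
    "GeneRecord",
    "circular_distance",
    "ori_proximity",
    "replichore_of",
]


@dataclass(frozen=True)
class CircularChromosome:
    """A circular chromosome with an oriC/ter axis.

    Parameters
    ----------
    name : str
        Chromosome (sequence) name.
    length : int
        Chromosome size L in bp; must be > 0.
    oriC : int
        Replication origin position in [0, L).
    ter : int, optional
        Terminus position in [0, L).  Defaults to the antipode of oriC.
    """

    name: str
    length: int
    oriC: int = 0
    ter: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise CoordinateError(f"chromosome length must be > 0, got {self.length}")
        if not 0 <= self.oriC < self.length:
            raise CoordinateError(f"oriC {self.oriC} outside [0, {self.length})")
        if self.ter is None:
            object.__setattr__(self, "ter", (self.oriC + self.length // 2) % self.length)
        if not 0 <= self.ter < self.length:
            raise CoordinateError(f"ter {self.ter} outside [0, {self.length})")
        if self.ter == self.oriC:
            raise CoordinateError("oriC and ter must differ")

    @property
    def half_length(self) -> float:
        return self.length / 2.0


@dataclass(frozen=True)
class GeneRecord:
    """A gene on a circular chromosome, reduced to what the analyses need.

    The gene's location is its midpoint (the convention used for every
    oriC-distance computation); strand and length are carried along for
    normalization and bookkeeping, ``category`` is an optional COG-style
    functional label.
    """

    gene_id: str
    midpoint: int
    strand: str = "+"
    length: int = 1
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise CoordinateError(f"gene {self.gene_id}: length must be >= 1")
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"gene {self.gene_id}: strand must be '+' or '-'")


def _check_coords(p, L: int):
    p = np.asarray(p)
    if np.any(p < 0) or np.any(p >= L):
        raise CoordinateError(f"coordinate outside [0, {L})")
    return p


def circular_distance(p, ref, chrom: CircularChromosome):
    """Shortest arc length between two positions on the circle.

    Result lies in [0, L/2].  Accepts scalars or arrays (broadcast).
    """
    L = chrom.length
    p = _check_coords(p, L)
    ref = _check_coords(ref, L)
    d = np.abs(np.asarray(p, dtype=float) - np.asarray(ref, dtype=float)) % L
    out = np.minimum(d, L - d)
    return out.item() if out.ndim == 0 else out


def ori_proximity(p, chrom: CircularChromosome):
    """Relative oriC proximity: 1 at oriC, 0 at the antipode.

    Defined as 1 - d(p, oriC)/(L/2), i.e. normalized by half the chromosome
    size regardless of where ter is annotated; values are clamped to [0, 1]
    so that real genomes with asymmetric replichores stay in range.
    """
    d = circular_distance(p, chrom.oriC, chrom)
    out = np.clip(1.0 - np.asarray(d) / chrom.half_length, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


def replichore_of(p, chrom: CircularChromosome):
    """Assign positions to the 'right' or 'left' replichore.

    'right' is the arc from oriC to ter in increasing-coordinate (clockwise)
    direction.  Tie-break: oriC itself is 'right', ter itself is 'left'.
    Accepts scalars (returns str) or arrays (returns object array).
    """
    L = chrom.length
    p = _check_coords(p, L)
    arc_right = (chrom.ter - chrom.oriC) % L
    t = (np.asarray(p, dtype=float) - chrom.oriC) % L
    is_right = t < arc_right
    if np.ndim(is_right) == 0:
        return "right" if bool(is_right) else "left"
    out = np.where(is_right, "right", "left")
    return out
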