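"""Core data containers for pooled bulked-segregant data.

A mapping-by-sequencing experiment sequences two pools of F2 plants —
one pool of recessive mutants and one pool of their phenotypically
wild-type siblings — and tabulates, for every biallelic SNP marker,
how many reads carry each allele in each pool.  Everything downstream
(allele-frequency tracks, Fisher's exact tests, candidate filtering)
works from these counts.

Containers are array-backed per chromosome so that genome-scale scans
stay vectorized; :class:`PooledMarker` gives a scalar row view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

VALID_BASES = frozenset("ACGT")


class BsamapError(Exception):
    """Base class for errors raised by this package."""


class DataError(BsamapError):
    """Input data violates a contract (bad counts, malformed rows...)."""


class SampleNotFoundError(DataError):
    """A requested sample name is absent from a VCF."""


class PooledMarker(NamedTuple):
    """One biallelic SNP with read counts in the two phenotype pools."""

    chrom: str
    pos: int
    ref: str
    alt: str
    wt_ref: int
    wt_alt: int
    mut_ref: int
    mut_alt: int

    @property
    def wt_depth(self) -> int:
        return self.wt_ref + self.wt_alt

    @property
    def mut_depth(self) -> int:
        return self.mut_ref + self.mut_alt

    def validate(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise DataError(f"ref/alt must be A/C/G/T, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if min(self.wt_ref, self.wt_alt, self.mut_ref, self.mut_alt) < 0:
            raise DataError(f"negative read count at {self.chrom}:{self.pos}")


@dataclass
class MarkerTrack:
    """Position-sorted biallelic markers for one chromosome.

    Columns are parallel numpy arrays; positions are 1-based and
    strictly increasing.
    """

    chrom: str
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    wt_ref: np.ndarray
    wt_alt: np.ndarray
    mut_ref: np.ndarray
    mut_alt: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        for name in ("wt_ref", "wt_alt", "mut_ref", "mut_alt"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
            if arr.shape != self.pos.shape:
                raise DataError(f"column {name} length mismatch on {self.chrom}")
            if arr.size and arr.min() < 0:
                raise DataError(f"negative read count in column {name} on {self.chrom}")
        if self.pos.size:
            if self.pos.min() < 1:
                raise DataError(f"positions must be >= 1 on {self.chrom}")
            if np.any(np.diff(self.pos) <= 0):
                raise DataError(f"positions not strictly increasing on {self.chrom}")
            if np.any(self.ref == self.alt):
                raise DataError(f"ref == alt marker on {self.chrom}")

    def __len__(self) -> int:
        return int(self.pos.size)

    def __iter__(self) -> Iterator[PooledMarker]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> PooledMarker:
        return PooledMarker(
            self.chrom,
            int(self.pos[i]),
            str(self.ref[i]),
            str(self.alt[i]),
            int(self.wt_ref[i]),
            int(self.wt_alt[i]),
            int(self.mut_ref[i]),
            int(self.mut_alt[i]),
        )

    @property
    def wt_depth(self) -> np.ndarray:
        return self.wt_ref + self.wt_alt

    @property
    def mut_depth(self) -> np.ndarray:
        return self.mut_ref + self.mut_alt

    def take(self, index: np.ndarray) -> "MarkerTrack":
        """New track restricted to ``index`` (boolean mask or indices)."""
        return MarkerTrack(
            self.chrom,
            self.pos[index],
            self.ref[index],
            self.alt[index],
            self.wt_ref[index],
            self.wt_alt[index],
            self.mut_ref[index],
            self.mut_alt[index],
        )

    @classmethod
    def from_markers(cls, chrom: str, markers: Sequence[PooledMarker]) -> "MarkerTrack":
        for m in markers:
            m.validate()
            if m.chrom != chrom:
                raise DataError(f"marker chrom {m.chrom} != track chrom {chrom}")
        cols = list(zip(*markers)) if markers else [[]] * 8
        return cls(chrom, cols[1], cols[2], cols[3], cols[4], cols[5], cols[6], cols[7])


@dataclass
class GeneModel:
    """Gene model for one mRNA: sorted, non-overlapping exon intervals.

    Coordinates are 1-based closed, as in GFF3.  Introns are the gaps
    between consecutive exons in genomic order, regardless of strand;
    the strand decides which end of an intron is the donor (5')
    and which the acceptor (3') splice site.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if a > b:
                raise DataError(f"exon interval [{a},{b}] inverted in {self.gene_id}")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 <= b1:
                raise DataError(f"overlapping/abutting exons in {self.gene_id}")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (b1 + 1, a2 - 1) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]
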