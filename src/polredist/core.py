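"""Core domain types: genes, annotations, read intervals, coverage tracks.

All coordinates are 0-based, half-open ([start, end)), BED-style. Strand is
explicit everywhere; the transcription start site (TSS) of a minus-strand
gene is ``end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "ReadInterval",
    "AlignedLibrary",
    "CoverageTrack",
    "build_coverage",
]


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with exon structure.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    start, end : int
        Gene span, 0-based half-open; ``start < end``.
    exons : tuple of (int, int)
        Sorted, pairwise-disjoint exon intervals contained in ``[start, end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid span [{self.start}, {self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s}, {e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping at ({s}, {e})")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (single base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (single base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene span minus the exon union (possibly empty)."""
        out = []
        cursor = self.start
        for s, e in self.exons:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.end:
            out.append((cursor, self.end))
        return tuple(out)


@dataclass
class GenomeAnnotation:
    """A set of genes plus chromosome sizes and an optional blacklist."""

    genes: dict[str, GeneModel]
    chrom_sizes: dict[str, int]
    blacklist: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes.values():
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chrom} ({g.end} > {size})")

    def lengths(self) -> dict[str, int]:
        return {gid: g.length for gid, g in self.genes.items()}


class ReadInterval(NamedTuple):
    """An aligned read reduced to its genomic interval.

    A NamedTuple rather than a validating dataclass: libraries hold millions
    of these, so construction must stay cheap. Parsers call ``validate``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def validate(self) -> "ReadInterval":
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        return self


@dataclass
class AlignedLibrary:
    """A collection of aligned reads from one genome of one sample."""

    sample_id: str
    genome_label: str  # "main" or "spike"
    reads: list[ReadInterval]

    @property
    def mapped_count(self) -> int:
        return len(self.reads)


class CoverageTrack:
    """Fixed-bin read density per chromosome.

    ``values[chrom][i]`` is the number of reads overlapping bin
    ``[i * bin_size, (i + 1) * bin_size)`` (after optional normalization).
    """

    def __init__(
        self,
        bin_size: int,
        chrom_sizes: dict[str, int],
        total_mapped: int = 0,
        normalization: str = "raw",
        dtype=np.float64,
    ) -> None:
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.bin_size = int(bin_size)
        self.chrom_sizes = dict(chrom_sizes)
        self.total_mapped = int(total_mapped)
        self.normalization = normalization
        self.values: dict[str, np.ndarray] = {
            c: np.zeros(math.ceil(size / bin_size), dtype=dtype)
            for c, size in chrom_sizes.items()
        }

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value at a single base."""
        return float(self.values[chrom][pos // self.bin_size])

    def base_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); out-of-bounds bases are NaN."""
        vals = self.values[chrom]
        n_bases = len(vals) * self.bin_size
        out = np.full(end - start, np.nan)
        lo, hi = max(start, 0), min(end, n_bases)
        if lo < hi:
            idx = np.arange(lo, hi) // self.bin_size
            out[lo - start : hi - start] = vals[idx]
        return out

    def to_cpm(self) -> "CoverageTrack":
        """Counts-per-million scaling: value * 1e6 / total_mapped."""
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive for CPM scaling")
        out = CoverageTrack(self.bin_size, self.chrom_sizes, self.total_mapped, "cpm")
        scale = 1e6 / self.total_mapped
        for c in self.values:
            out.values[c] = self.values[c] * scale
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        """Multiply all densities by a constant factor."""
        out = CoverageTrack(self.bin_size, self.chrom_sizes, self.total_mapped, "factor-scaled")
        for c in self.values:
            out.values[c] = self.values[c] * factor
        return out


def build_coverage(
    reads: list[ReadInterval] | "AlignedLibrary",
    chrom_sizes: dict[str, int],
    bin_size: int = 10,
) -> CoverageTrack:
    """Bin read coverage: each read adds 1 to every bin it overlaps (>=1 bp).

    Reads on unknown chromosomes or outside bounds raise ``ValueError``.
    """
    if hasattr(reads, "reads"):
        reads = reads.reads
    track = CoverageTrack(bin_size, chrom_sizes, total_mapped=len(reads))
    if not reads:
        return track
    chroms = np.asarray([r.chrom for r in reads])
    starts = np.asarray([r.start for r in reads], dtype=np.int64)
    ends = np.asarray([r.end for r in reads], dtype=np.int64)
    # difference-array trick per chromosome: +1 at first bin, -1 past last bin
    for chrom in np.unique(chroms):
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        m = chroms == chrom
        s, e = starts[m], ends[m]
        if e.max() > size:
            raise ValueError(f"read past end of {chrom} ({size})")
        nb = track.n_bins(chrom)
        b0 = s // bin_size
        b1 = (e - 1) // bin_size  # last overlapped bin
        delta = np.zeros(nb + 1, dtype=np.float64)
        np.add.at(delta, b0, 1.0)
        np.add.at(delta, b1 + 1, -1.0)
        track.values[chrom] = np.cumsum(delta[:-1])
    return track
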