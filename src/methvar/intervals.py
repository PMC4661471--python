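"""Genomic coordinate primitives.

All coordinates in this package are 0-based, half-open (BED convention).
1-based dialects (e.g. bisulfite-caller call files, GTF) are converted at
the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span ``[start, end)`` with optional strand.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        Exclusive end; must be > start.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Fragment:
    """An MspI-to-MspI restriction fragment with its CpG positions.

    ``cpg_positions`` holds the genomic position of the C of every CG
    dinucleotide on the forward strand that lies fully inside the fragment.
    Internal MspI fragments begin with CGG, so the first base always starts
    a CpG.
    """

    id: str
    interval: GenomicInterval
    cpg_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for p in self.cpg_positions:
            if not (self.interval.start <= p < self.interval.end):
                raise ValueError(
                    f"CpG position {p} outside fragment {self.interval}"
                )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)
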