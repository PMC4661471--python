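"""In silico MspI digestion of a genome into the reduced-representation
fragment universe.

MspI cuts at C^CGG. A cut is placed between offsets ``i`` and ``i + 1`` for
every occurrence of CCGG starting at ``i``; internal fragments span
successive cuts, so each begins with CGG and ends with C. Terminal
chromosome stubs (cut on one side only) are excluded, mirroring real RRBS
library chemistry. The reduced-representation (RR) genome is the subset of
internal fragments within a size-selection window (default 40-220 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import Fragment, GenomicInterval

_CCGG = re.compile("CCGG")
_VALID = re.compile(r"^[ACGTN]*$")

GenomeLike = Mapping[str, str]


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an in-memory ``{chrom: sequence}`` mapping."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def find_cut_positions(sequence: str) -> list[int]:
    """Return MspI cut positions (0-based offset of the first base after the
    cut) for every CCGG occurrence in ``sequence``. Case-insensitive; N runs
    never match."""
    seq = sequence.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return [m.start() + 1 for m in _CCGG.finditer(seq)]


def digest(sequence: str, chrom: str = "chr1") -> list[Fragment]:
    """Digest one chromosome sequence into internal MspI fragments.

    Returns fragments spanning successive cut positions, ordered and
    non-overlapping; chromosome ends (single-cut stubs) are excluded.
    An empty sequence or a sequence without CCGG yields no fragments.
    """
    cuts = find_cut_positions(sequence)
    frags: list[Fragment] = []
    for start, end in zip(cuts[:-1], cuts[1:]):
        cpgs = locate_cpgs_in_seq(sequence, start, end)
        frags.append(
            Fragment(
                id=f"{chrom}:{start}-{end}",
                interval=GenomicInterval(chrom, start, end),
                cpg_positions=tuple(cpgs),
            )
        )
    return frags


def locate_cpgs_in_seq(sequence: str, start: int, end: int) -> list[int]:
    """Positions of the C of every CG dyad fully inside ``[start, end)`` of
    ``sequence`` (forward strand)."""
    if start < 0 or end > len(sequence):
        raise ValueError(
            f"interval [{start}, {end}) out of bounds for sequence of "
            f"length {len(sequence)}"
        )
    window = sequence[start:end].upper()
    return [start + m.start() for m in re.finditer("(?=CG)", window) if m.start() + 1 < end - start]


def locate_cpgs(fragment: Fragment | GenomicInterval, genome: GenomeLike) -> list[int]:
    """CpG positions within a fragment, looked up from the genome."""
    iv = fragment.interval if isinstance(fragment, Fragment) else fragment
    if iv.chrom not in genome:
        raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    return locate_cpgs_in_seq(genome[iv.chrom], iv.start, iv.end)


def digest_genome(genome: GenomeLike) -> list[Fragment]:
    """Digest every chromosome; fragments are returned grouped by chromosome
    in genome order, positionally sorted within each."""
    frags: list[Fragment] = []
    for chrom, seq in genome.items():
        frags.extend(digest(seq, chrom=chrom))
    return frags


@dataclass(frozen=True)
class SizeSelectionSummary:
    n_total: int
    n_selected: int
    median_length: float
    mean_length: float


def select_rr_fragments(
    fragments: Iterable[Fragment],
    min_len: int = 40,
    max_len: int = 220,
) -> tuple[list[Fragment], SizeSelectionSummary]:
    """Size-select fragments into the RR genome (inclusive bounds).

    Returns the kept fragments plus count and length summary statistics.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) > max_len ({max_len})")
    fragments = list(fragments)
    kept = [f for f in fragments if min_len <= f.length <= max_len]
    lengths = np.array([f.length for f in kept], dtype=float)
    summary = SizeSelectionSummary(
        n_total=len(fragments),
        n_selected=len(kept),
        median_length=float(np.median(lengths)) if len(kept) else float("nan"),
        mean_length=float(lengths.mean()) if len(kept) else float("nan"),
    )
    return kept, summary


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Tabulate fragments as a DataFrame (one row per fragment)."""
    rows = [
        (f.id, f.chrom, f.start, f.end, f.length, f.n_cpgs)
        for f in fragments
    ]
    return pd.DataFrame(
        rows, columns=["fragment_id", "chrom", "start", "end", "length", "n_cpgs"]
    )


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as BED4 (chrom, start, end, fragment_id)."""
    df = fragments_to_frame(fragments)
    df[["chrom", "start", "end", "fragment_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_fragments_tsv(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write a fragments table with lengths and CpG counts."""
    fragments_to_frame(fragments).to_csv(path, sep="\t", index=False)


def read_fragments_bed(path: str | Path, genome: GenomeLike | None = None) -> list[Fragment]:
    """Read BED4 fragments; CpG positions are recomputed when a genome is
    supplied, otherwise left empty."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "fragment_id"],
        dtype={"chrom": str},
    )
    frags = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        cpgs = tuple(locate_cpgs(iv, genome)) if genome is not None else ()
        frags.append(Fragment(id=str(row.fragment_id), interval=iv, cpg_positions=cpgs))
    return frags
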