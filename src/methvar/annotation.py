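"""Gene and CpG-island context for fragments, per-feature variability
scores, and variably methylated gene (VMG) calling.

Context categories follow common promoter/gene-body conventions: a fragment
overlapping a protein-coding gene is classified as TSS overlap or by its
exon/intron overlap pattern; a non-genic fragment is assigned to the
nearest gene lying downstream of it (strand-aware) and binned by upstream
distance from the TSS — 0-2 kb and 2-5 kb (promoter), 5-10 kb (upstream),
>10 kb (distant). CpG-island context is core / shore (within 2 kb of a CGI
edge) / shelf (2-4 kb) / none, judged at the fragment midpoint.

A unit's variability score is n_iVMF / n_analysed for that unit; VMGs are
genes with >= 3 associated iVMFs and a score >= 0.5.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Fragment, GenomicInterval

logger = logging.getLogger(__name__)

GENE_CATEGORIES = (
    "tss_overlap", "promoter_0_2kb", "promoter_2_5kb", "upstream_5_10kb",
    "distant_gt10kb", "exon", "intron", "exon_intron_boundary",
    "intron_exon_boundary",
)
PROMOTER_CATEGORIES = frozenset({"tss_overlap", "promoter_0_2kb", "promoter_2_5kb"})
GENE_BODY_CATEGORIES = frozenset(
    {"exon", "intron", "exon_intron_boundary", "intron_exon_boundary"}
)
CGI_CLASSES = ("core", "shore", "shelf", "none")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene with its exon structure."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} must be stranded")
        for e in self.exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"exon outside gene {self.gene_id}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site: gene start on +, end - 1 on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def read_genes_gtf(path: str | Path, biotype: str | None = "protein_coding") -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="merge", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        bt = g.attributes.get("gene_biotype", ["protein_coding"])[0]
        if biotype is not None and bt != biotype:
            continue
        gid = g.attributes.get("gene_id", [g.id])[0]
        exons = tuple(sorted(
            (GenomicInterval(e.seqid, e.start - 1, e.end, g.strand)
             for e in db.children(g, featuretype="exon")),
            key=lambda iv: iv.start,
        ))
        genes.append(GeneModel(
            gene_id=gid,
            interval=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
            exons=exons,
            biotype=bt,
        ))
    return genes


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file (blocks = exons)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            genes.append(GeneModel(
                gene_id=name,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=exons,
            ))
    return genes


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain BED (>= 3 columns) intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


@dataclass(frozen=True)
class ContextAssignment:
    fragment_id: str
    gene_id: str | None
    category: str
    cgi_class: str = "none"
    distance_to_tss: int | None = None


class GeneIndex:
    """Per-chromosome sorted gene lookup for overlap and nearest-TSS
    queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.interval.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for chrom, gl in self._by_chrom.items():
            gl.sort(key=lambda g: (g.interval.start, g.gene_id))
            self._starts[chrom] = [g.interval.start for g in gl]

    def overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        gl = self._by_chrom.get(iv.chrom, [])
        starts = self._starts.get(iv.chrom, [])
        hi = bisect_right(starts, iv.end - 1)
        # genes are not guaranteed non-overlapping; scan back bounded by max gene span
        out = []
        for g in gl[:hi]:
            if g.interval.end > iv.start:
                out.append(g)
        return out

    def chrom_genes(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])


def _upstream_distance(gene: GeneModel, iv: GenomicInterval) -> int | None:
    """Distance from the TSS to the fragment's closest edge, when the
    fragment lies strictly on the gene's upstream side; None otherwise."""
    if gene.strand == "+":
        if iv.end <= gene.tss:
            return gene.tss - (iv.end - 1)
        return None
    if iv.start > gene.tss:
        return iv.start - gene.tss
    return None


def _exon_pattern_category(fragment_iv: GenomicInterval, gene: GeneModel) -> str:
    """Gene-body subcategory by exon overlap pattern (strand-aware
    boundaries: exon->intron in transcription order)."""
    overlapped = [e for e in gene.exons if e.overlaps(fragment_iv)]
    if not overlapped:
        return "intron"
    inside_one = any(
        e.start <= fragment_iv.start and fragment_iv.end <= e.end for e in overlapped
    )
    if inside_one:
        return "exon"
    # spans at least one exon edge; classify by which edge, in transcription order
    crosses_exon_end = any(
        e.start <= fragment_iv.start < e.end < fragment_iv.end for e in overlapped
    )
    crosses_exon_start = any(
        fragment_iv.start < e.start and e.start < fragment_iv.end <= e.end
        for e in overlapped
    )
    if gene.strand == "-":
        crosses_exon_end, crosses_exon_start = crosses_exon_start, crosses_exon_end
    if crosses_exon_end and not crosses_exon_start:
        return "exon_intron_boundary"
    if crosses_exon_start and not crosses_exon_end:
        return "intron_exon_boundary"
    # spans a whole exon (or both edges): call it exon_intron_boundary
    return "exon_intron_boundary"


def classify_gene_context(
    fragment: Fragment, index: GeneIndex
) -> ContextAssignment:
    """Assign a fragment to exactly one gene-context category.

    Overlapping fragments: ``tss_overlap`` when the fragment covers the TSS,
    else the exon/intron overlap pattern. Non-overlapping fragments: nearest
    gene with the fragment on its upstream side, binned by TSS distance;
    fragments with no upstream-side gene on the chromosome are ``distant``.
    Equidistant ties break lexicographically by gene_id (logged).
    """
    iv = fragment.interval
    hits = index.overlapping(iv)
    if hits:
        tss_hits = [g for g in hits if iv.contains(g.tss)]
        if tss_hits:
            tss_hits.sort(key=lambda g: g.gene_id)
            g = tss_hits[0]
            return ContextAssignment(fragment.id, g.gene_id, "tss_overlap",
                                     distance_to_tss=0)
        hits.sort(key=lambda g: (min(abs(g.tss - iv.start), abs(g.tss - (iv.end - 1))),
                                 g.gene_id))
        g = hits[0]
        cat = _exon_pattern_category(iv, g)
        return ContextAssignment(fragment.id, g.gene_id, cat, distance_to_tss=0)
    candidates = []
    for g in index.chrom_genes(iv.chrom):
        d = _upstream_distance(g, iv)
        if d is not None:
            candidates.append((d, g.gene_id, g))
    if not candidates:
        return ContextAssignment(fragment.id, None, "distant_gt10kb",
                                 distance_to_tss=None)
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        logger.warning(
            "fragment %s equidistant to genes %s and %s; keeping %s",
            fragment.id, candidates[0][1], candidates[1][1], candidates[0][1],
        )
    d, _, g = candidates[0]
    if d <= 2000:
        cat = "promoter_0_2kb"
    elif d <= 5000:
        cat = "promoter_2_5kb"
    elif d <= 10000:
        cat = "upstream_5_10kb"
    else:
        cat = "distant_gt10kb"
    return ContextAssignment(fragment.id, g.gene_id, cat, distance_to_tss=d)


def classify_cgi_context(
    fragment: Fragment | GenomicInterval,
    cgis: Sequence[GenomicInterval],
    shore_bp: int = 2000,
    shelf_bp: int = 2000,
) -> str:
    """CGI class at the fragment midpoint: core inside a CGI, shore within
    ``shore_bp`` of an edge, shelf within the next ``shelf_bp``, else none.
    The nearest CGI wins."""
    iv = fragment.interval if isinstance(fragment, Fragment) else fragment
    mid = iv.midpoint
    best = None
    for cgi in cgis:
        if cgi.chrom != iv.chrom:
            continue
        if cgi.start <= mid < cgi.end:
            return "core"
        d = cgi.start - mid if mid < cgi.start else mid - (cgi.end - 1)
        best = d if best is None else min(best, d)
    if best is None:
        return "none"
    if best <= shore_bp:
        return "shore"
    if best <= shore_bp + shelf_bp:
        return "shelf"
    return "none"


def annotate_fragments(
    fragments: Sequence[Fragment],
    genes: Sequence[GeneModel],
    cgis: Sequence[GenomicInterval] = (),
) -> pd.DataFrame:
    """Full context table: one row per fragment with gene category, gene id,
    TSS distance and CGI class."""
    coding = [g for g in genes if g.biotype == "protein_coding"]
    index = GeneIndex(coding)
    merged_cgis = merge_intervals(cgis) if cgis else []
    rows = []
    for f in fragments:
        if coding:
            a = classify_gene_context(f, index)
        else:
            a = ContextAssignment(f.id, None, "unassigned")
        rows.append({
            "fragment_id": f.id,
            "chrom": f.chrom,
            "gene_id": a.gene_id,
            "category": a.category,
            "distance_to_tss": a.distance_to_tss,
            "cgi_class": classify_cgi_context(f, merged_cgis),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VariabilityScore:
    unit_id: str
    n_analysed: int
    n_ivmf: int

    def __post_init__(self) -> None:
        if self.n_analysed < 1:
            raise ValueError("n_analysed must be >= 1")
        if self.n_ivmf > self.n_analysed:
            raise ValueError("n_ivmf cannot exceed n_analysed")

    @property
    def vs(self) -> float:
        return self.n_ivmf / self.n_analysed


def variability_scores(
    assignments: pd.DataFrame,
    ivmf_flags: Mapping[str, bool],
    by: str = "gene_id",
) -> pd.DataFrame:
    """Per-unit variability scores: n_iVMF / n_analysed grouped by
    ``by`` (gene_id or category). Units with no analysed fragments are
    skipped by construction."""
    df = assignments.copy()
    df["is_ivmf"] = df["fragment_id"].map(lambda x: bool(ivmf_flags.get(x, False)))
    g = df.dropna(subset=[by]).groupby(by)
    out = g.agg(n_analysed=("fragment_id", "size"), n_ivmf=("is_ivmf", "sum"))
    out["vs"] = out["n_ivmf"] / out["n_analysed"]
    return out.reset_index().rename(columns={by: "unit_id"})


def call_vmgs(
    scores: pd.DataFrame,
    min_ivmfs: int = 3,
    min_vs: float = 0.5,
) -> pd.DataFrame:
    """Variably methylated genes: units with >= ``min_ivmfs`` iVMFs and a
    variability score >= ``min_vs``. Units with fewer than ``min_ivmfs``
    iVMFs are not considered regardless of score."""
    eligible = scores[scores["n_ivmf"] >= min_ivmfs]
    return eligible[eligible["vs"] >= min_vs].sort_values(
        ["vs", "n_ivmf"], ascending=False, ignore_index=True
    )


def summarize_methylation_by_feature(
    methylation: Mapping[str, float],
    assignments: pd.DataFrame,
    by: str = "category",
) -> tuple[pd.DataFrame, float]:
    """Median fragment methylation per context category plus a one-way
    ANOVA p across categories (NaN sentinel when fewer than two non-empty
    categories or no variance)."""
    df = assignments.copy()
    df["meth"] = df["fragment_id"].map(methylation)
    df = df.dropna(subset=["meth"])
    med = df.groupby(by)["meth"].agg(["median", "count"]).reset_index()
    groups = [g["meth"].to_numpy() for _, g in df.groupby(by) if len(g) > 0]
    groups = [g for g in groups if len(g) > 0]
    p = float("nan")
    if len(groups) >= 2 and any(len(g) > 1 for g in groups):
        pooled = np.concatenate(groups)
        if np.ptp(pooled) > 0:
            _, p = stats.f_oneway(*groups)
            p = float(p)
    return med, p
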