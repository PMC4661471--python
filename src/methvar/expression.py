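"""Methylation-expression integration.

Links fragment methylation to gene- and exon-level expression: methylation
bins ([0,30], (30,70], (70,100]) versus log gene abundance with ANOVA and
Tukey HSD post-hoc; TSS-window association profiles; Pearson correlation of
exon methylation with log2(read count + 1); and the iVMF / exon-inclusion
analysis with adjacent-exon controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .intervals import Fragment

logger = logging.getLogger(__name__)

DEFAULT_BINS = ((0.0, 30.0), (30.0, 70.0), (70.0, 100.0))


def read_gene_abundance(path: str | Path) -> pd.DataFrame:
    """Gene-level abundance TSV: gene_id, individual_id, abundance."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "individual_id": str})
    if (df["abundance"] < 0).any():
        raise ValueError("negative abundance")
    return df


def read_exon_counts(path: str | Path) -> pd.DataFrame:
    """Exon-level count TSV: exon_id, gene_id, chrom, start, end,
    individual_id, read_count, is_differential."""
    df = pd.read_csv(path, sep="\t", dtype={"exon_id": str, "gene_id": str,
                                            "chrom": str})
    df["is_differential"] = df["is_differential"].astype(bool)
    if (df["read_count"] < 0).any():
        raise ValueError("negative read count")
    return df


def assign_bin(pct: float, bins: Sequence[tuple[float, float]] = DEFAULT_BINS) -> str | None:
    """Methylation bin label; the first bin is closed on both ends, later
    bins half-open on the left ((lo, hi]), so a boundary value (e.g. 30%)
    falls in the lower bin."""
    for i, (lo, hi) in enumerate(bins):
        if (lo <= pct <= hi) if i == 0 else (lo < pct <= hi):
            return f"{lo:g}-{hi:g}"
    return None


@dataclass
class BinComparison:
    summary: pd.DataFrame          # per-bin n, mean/median log abundance
    anova_F: float
    anova_p: float
    posthoc: pd.DataFrame          # Tukey HSD all-pairs table


def methylation_expression_bins(
    pairs: pd.DataFrame,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    abundance_offset: float = 0.1,
) -> BinComparison:
    """Compare log gene abundance across fragment-methylation bins.

    ``pairs`` holds one row per (fragment, individual) with columns
    ``methylation_pct`` and ``abundance``. Log-scale abundance
    (ln(abundance + offset)) is compared across bins with one-way ANOVA and
    a Tukey HSD all-pairs post-hoc; bins with < 2 observations are dropped
    from the post-hoc with a warning.
    """
    df = pairs.copy()
    df["bin"] = df["methylation_pct"].map(lambda x: assign_bin(x, bins))
    df = df.dropna(subset=["bin"])
    df["log_abundance"] = np.log(df["abundance"] + abundance_offset)
    summary = df.groupby("bin")["log_abundance"].agg(["size", "mean", "median"]).reset_index()
    groups = {b: g["log_abundance"].to_numpy() for b, g in df.groupby("bin")}
    usable = {b: v for b, v in groups.items() if len(v) >= 2}
    for b in set(groups) - set(usable):
        logger.warning("bin %s has < 2 observations; dropped from post-hoc", b)
    if len(usable) >= 2:
        F, p = stats.f_oneway(*usable.values())
        F, p = float(F), float(p)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        sub = df[df["bin"].isin(usable)]
        tk = pairwise_tukeyhsd(sub["log_abundance"].to_numpy(), sub["bin"].to_numpy())
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    else:
        F, p = math.nan, math.nan
        posthoc = pd.DataFrame()
    return BinComparison(summary=summary, anova_F=F, anova_p=p, posthoc=posthoc)


DEFAULT_WINDOWS = (
    ("down_0_500", -500, 0),
    ("up_0_500", 0, 500),
    ("up_500_1000", 500, 1000),
    ("up_1000_1500", 1000, 1500),
    ("up_1500_2000", 1500, 2000),
    ("up_2000_2500", 2000, 2500),
    ("up_2500_3000", 2500, 3000),
)


def tss_window_association(
    fragments: Sequence[Fragment],
    methylation: pd.DataFrame,
    genes: Sequence[GeneModel],
    abundance: pd.DataFrame,
    windows: Sequence[tuple[str, int, int]] = DEFAULT_WINDOWS,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Methylation-expression bin ANOVA per TSS-relative window.

    Windows are strand-aware upstream distances from the TSS to the
    fragment's nearest edge (negative = downstream of the TSS, i.e. into
    the gene). ``methylation`` has columns fragment_id, individual_id,
    methylation_pct; ``abundance`` has gene_id, individual_id, abundance.
    Windows without fragments are omitted.
    """
    frag_by_id = {f.id: f for f in fragments}
    rows = []
    for g in genes:
        for f in frag_by_id.values():
            if f.chrom != g.interval.chrom:
                continue
            if g.strand == "+":
                d = g.tss - (f.end - 1) if f.end - 1 < g.tss else -(f.start - g.tss)
            else:
                d = f.start - g.tss if f.start > g.tss else -(g.tss - (f.end - 1))
            rows.append({"fragment_id": f.id, "gene_id": g.gene_id, "dist": d})
    if not rows:
        return pd.DataFrame(columns=["window", "n_pairs", "anova_F", "anova_p"])
    dist = pd.DataFrame(rows)
    meth = methylation.merge(dist, on="fragment_id")
    merged = meth.merge(abundance, on=["gene_id", "individual_id"])
    out = []
    for name, lo, hi in windows:
        sel = merged[(merged["dist"] > lo) & (merged["dist"] <= hi)]
        if sel.empty:
            continue
        bc = methylation_expression_bins(sel, bins=bins)
        out.append({"window": name, "n_pairs": len(sel),
                    "anova_F": bc.anova_F, "anova_p": bc.anova_p})
    return pd.DataFrame(out)


def pearson_log2(meth_pct: Sequence[float], counts: Sequence[float]) -> tuple[float, float]:
    """Pearson r (and two-sided p from the t transform) between methylation
    % and log2(read count + 1). NaN sentinels when either variable has zero
    variance or fewer than 3 pairs."""
    x = np.asarray(meth_pct, dtype=float)
    y = np.log2(np.asarray(counts, dtype=float) + 1.0)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


def exon_methylation_correlation(
    pairs: pd.DataFrame,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Per-gene and pooled Pearson correlation of exon methylation with
    log2 exon read counts.

    ``pairs``: one row per (exon, individual) with columns gene_id,
    exon_id, individual_id, methylation_pct, read_count. Pairs are weighted
    equally in the pooled estimate.
    """
    per_gene = []
    for gid, g in pairs.groupby("gene_id"):
        r, p = pearson_log2(g["methylation_pct"], g["read_count"])
        per_gene.append({"gene_id": gid, "n_pairs": len(g), "r": r, "p": p})
    pooled = pearson_log2(pairs["methylation_pct"], pairs["read_count"])
    return pd.DataFrame(per_gene), pooled


def ivmf_exon_inclusion(
    ivmf_fragments: Sequence[Fragment],
    exon_records: pd.DataFrame,
    methylation: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate iVMF methylation with inclusion of the overlapped
    differential exon, against adjacent-exon controls.

    ``exon_records``: exon_id, gene_id, chrom, start, end, individual_id,
    read_count, is_differential (exons of a gene ordered by position).
    ``methylation``: fragment_id, individual_id, methylation_pct.
    Returns pooled r/p/n for roles overlapped, previous_exon, next_exon,
    over (iVMF, individual) pairs; first/last exons lack one control and
    are skipped for that control. No overlapping differential exon yields
    an empty frame.
    """
    exon_pos = (
        exon_records[["exon_id", "gene_id", "chrom", "start", "end"]]
        .drop_duplicates()
        .sort_values(["gene_id", "start"])
    )
    order: dict[str, list[str]] = {
        gid: g["exon_id"].tolist() for gid, g in exon_pos.groupby("gene_id")
    }
    exon_iv = {r.exon_id: (r.chrom, r.start, r.end) for r in exon_pos.itertuples()}
    diff_exons = set(exon_records.loc[exon_records["is_differential"], "exon_id"])
    counts = exon_records.set_index(["exon_id", "individual_id"])["read_count"]
    meth = methylation.set_index(["fragment_id", "individual_id"])["methylation_pct"]

    collected: dict[str, list[tuple[float, float]]] = {
        "overlapped": [], "previous_exon": [], "next_exon": []
    }
    for f in ivmf_fragments:
        hits = [
            eid for eid in diff_exons
            if exon_iv[eid][0] == f.chrom
            and f.start < exon_iv[eid][2] and exon_iv[eid][1] < f.end
        ]
        for eid in sorted(hits):
            gid = exon_pos.loc[exon_pos["exon_id"] == eid, "gene_id"].iloc[0]
            exons = order[gid]
            i = exons.index(eid)
            roles = {"overlapped": eid,
                     "previous_exon": exons[i - 1] if i > 0 else None,
                     "next_exon": exons[i + 1] if i + 1 < len(exons) else None}
            for (fid, ind), m in meth.items():
                if fid != f.id:
                    continue
                for role, target in roles.items():
                    if target is None:
                        continue
                    try:
                        c = counts.loc[(target, ind)]
                    except KeyError:
                        continue
                    collected[role].append((m, float(c)))
    rows = []
    for role, vals in collected.items():
        if vals:
            r, p = pearson_log2([v[0] for v in vals], [v[1] for v in vals])
        else:
            r, p = math.nan, math.nan
        rows.append({"role": role, "n_pairs": len(vals), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if not collected["overlapped"]:
        return out.iloc[0:0]
    return out


def cv_rank_differential_flagger(
    exon_records: pd.DataFrame, top_frac: float = 0.2
) -> pd.DataFrame:
    """Non-canonical fallback flagger for demo pipelines only: marks the
    top ``top_frac`` exons by coefficient of variation of read counts as
    differential. Real analyses should supply flags from a dedicated
    differential-exon-usage model."""
    cv = exon_records.groupby("exon_id")["read_count"].agg(
        lambda x: x.std(ddof=1) / x.mean() if x.mean() > 0 else 0.0
    )
    cut = cv.quantile(1 - top_frac)
    flags = cv >= cut
    out = exon_records.copy()
    out["is_differential"] = out["exon_id"].map(flags)
    return out
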