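"""Contingency-table statistics: Yates-corrected 2x2 chi-square for
feature enrichment and chromosome-wise iVMF distribution, the >= 50%
fragment-overlap rule, and hypergeometric gene-list overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import merge_intervals
from .intervals import Fragment, GenomicInterval

logger = logging.getLogger(__name__)


def yates_chi2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Yates-corrected chi-square on a 2x2 table.

    chi2 = N * (|ad - bc| - N/2)^2 / (r1 r2 c1 c2), clamped to 0 when the
    correction exceeds |ad - bc|; p from the df = 1 upper tail. Any zero
    margin returns (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative cell count")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if n < 1 or 0 in (r1, r2, c1, c2):
        return (0.0, 1.0)
    diff = abs(a * d - b * c)
    if diff <= n / 2:
        return (0.0, 1.0)
    chi2 = n * (diff - n / 2) ** 2 / (r1 * r2 * c1 * c2)
    return (float(chi2), float(stats.chi2.sf(chi2, 1)))


def overlap_bases(iv: GenomicInterval, merged: Sequence[GenomicInterval]) -> int:
    """Bases of ``iv`` covered by a merged interval set."""
    return sum(iv.overlap_bases(m) for m in merged if m.chrom == iv.chrom)


def feature_overlap_flag(
    fragment: Fragment | GenomicInterval,
    features: Sequence[GenomicInterval],
    min_frac: float = 0.5,
) -> bool:
    """True when >= ``min_frac`` of the fragment's bases overlap the
    feature track (inclusive threshold). ``features`` must be merged."""
    iv = fragment.interval if isinstance(fragment, Fragment) else fragment
    return overlap_bases(iv, features) / iv.length >= min_frac


@dataclass(frozen=True)
class EnrichmentResult:
    feature_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2_yates: float
    p: float
    direction: str  # enriched | depleted | none


def feature_enrichment(
    ivmf_fragments: Sequence[Fragment | GenomicInterval],
    nonvar_fragments: Sequence[Fragment | GenomicInterval],
    features: Iterable[GenomicInterval],
    feature_id: str = "feature",
    min_frac: float = 0.5,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Enrichment/depletion of iVMFs versus non-variable fragments in one
    feature track, by the >= ``min_frac`` strong-overlap rule and a
    Yates-corrected 2x2 chi-square."""
    merged = merge_intervals(features) if features else []
    k_i = sum(feature_overlap_flag(f, merged, min_frac) for f in ivmf_fragments)
    k_n = sum(feature_overlap_flag(f, merged, min_frac) for f in nonvar_fragments)
    n_i, n_n = len(ivmf_fragments), len(nonvar_fragments)
    table = ((k_i, n_i - k_i), (k_n, n_n - k_n))
    chi2, p = yates_chi2(table)
    direction = "none"
    if p < alpha and n_i > 0 and n_n > 0:
        pi, pn = k_i / n_i, k_n / n_n
        if pi > pn:
            direction = "enriched"
        elif pi < pn:
            direction = "depleted"
    return EnrichmentResult(feature_id, table, chi2, p, direction)


def chromosome_distribution_test(
    ivmf_counts: Mapping[str, int],
    rr_counts: Mapping[str, int],
    alpha: float = 1e-4,
) -> pd.DataFrame:
    """Per-chromosome iVMF share versus the RR-genome share.

    For each chromosome a 2x2 of (this chromosome vs all others) x (iVMF vs
    RR genome) is tested with the Yates chi-square; chromosomes at
    p < ``alpha`` are flagged. Chromosomes absent from the RR counts are
    skipped with a warning; a single-chromosome genome yields an empty
    result (the partition is degenerate)."""
    chroms = [c for c in rr_counts if rr_counts[c] > 0]
    for c in ivmf_counts:
        if c not in rr_counts:
            logger.warning("chromosome %s absent from RR counts; skipped", c)
    if len(chroms) < 2:
        return pd.DataFrame(
            columns=["chrom", "n_ivmf", "n_rr", "ivmf_pct", "rr_pct",
                     "chi2", "p", "direction", "significant"]
        )
    total_i = sum(ivmf_counts.get(c, 0) for c in chroms)
    total_r = sum(rr_counts[c] for c in chroms)
    rows = []
    for c in sorted(chroms):
        ki = ivmf_counts.get(c, 0)
        kr = rr_counts[c]
        table = ((ki, total_i - ki), (kr, total_r - kr))
        chi2, p = yates_chi2(table)
        share_i = ki / total_i if total_i else 0.0
        share_r = kr / total_r
        direction = "none"
        if p < alpha:
            direction = "enriched" if share_i > share_r else "depleted"
        rows.append({
            "chrom": c, "n_ivmf": ki, "n_rr": kr,
            "ivmf_pct": 100 * share_i, "rr_pct": 100 * share_r,
            "chi2": chi2, "p": p, "direction": direction,
            "significant": p < alpha,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapTest:
    universe_n: int
    list_a_size: int
    list_b_size: int
    overlap_k: int
    p: float


def hypergeometric_overlap(
    k: int, list_a: int, list_b: int, universe_n: int
) -> OverlapTest:
    """Upper-tail hypergeometric P(X >= k) for an observed overlap of ``k``
    genes between a list of ``list_a`` drawn from a universe of
    ``universe_n`` containing ``list_b`` successes."""
    if not (0 <= k <= min(list_a, list_b) <= max(list_a, list_b) <= universe_n):
        raise ValueError(
            f"inconsistent sizes: k={k}, a={list_a}, b={list_b}, N={universe_n}"
        )
    p = float(stats.hypergeom.sf(k - 1, universe_n, list_b, list_a))
    return OverlapTest(universe_n, list_a, list_b, k, min(p, 1.0))
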