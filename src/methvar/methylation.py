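"""Per-CpG methylation calls, fragment-level aggregation and the cohort
analysed-fragment matrix.

The unit of analysis is the MspI fragment: for each individual the
methylation proportion of a fragment is the total number of methylated CpG
observations over all reads divided by the total number of CpG observations.
A fragment *qualifies* in an individual when at least ``min_cpgs`` of its
CpGs are each covered by ``min_reads`` or more reads (default 2 CpGs at
>= 10 reads); the cohort's *analysed* set is the fragments qualifying in at
least ``min_individuals`` individuals (default 9 of 11).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Fragment

CALL_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


def read_cpg_calls(path: str | Path) -> pd.DataFrame:
    """Read a per-CpG call file (TSV: chrom, 1-based position, methylated
    count, unmethylated count; no header).

    Positions are converted to 0-based; duplicate positions (strand-split
    callers) are summed; output is sorted by (chrom, pos). An empty file
    yields an empty frame.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=CALL_COLUMNS,
            dtype={"chrom": str, "pos": np.int64, "meth": np.int64, "unmeth": np.int64},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS).astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed call file {path}: {exc}") from exc
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise ValueError(f"{path}: non-positive 1-based position at line {line}")
    if (df[["meth", "unmeth"]] < 0).any().any():
        bad = df.index[(df[["meth", "unmeth"]] < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count at line {int(bad) + 1}")
    df["pos"] -= 1
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
    )
    return df


def convert_coverage6(path: str | Path, out: str | Path) -> None:
    """Convert the common 6-column coverage dialect (chrom, start_1based,
    end, pct, meth, unmeth) into the 4-column call dialect used here."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "pct", "meth", "unmeth"],
        dtype={"chrom": str},
    )
    df[["chrom", "start", "meth", "unmeth"]].to_csv(
        out, sep="\t", header=False, index=False
    )


def assign_calls_to_fragments(
    calls: pd.DataFrame, fragments: Sequence[Fragment]
) -> pd.DataFrame:
    """Annotate each call with the fragment containing its position.

    Fragments on one chromosome are non-overlapping and ordered, so the
    containing fragment is found by binary search on starts. Calls outside
    every fragment are dropped.
    """
    if calls.empty or not fragments:
        return calls.iloc[0:0].assign(fragment_id=pd.Series(dtype=str))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, group in pd.DataFrame(
        [(f.chrom, f.start, f.end, f.id) for f in fragments],
        columns=["chrom", "start", "end", "fragment_id"],
    ).groupby("chrom", sort=False):
        g = group.sort_values("start")
        by_chrom[chrom] = (
            g["start"].to_numpy(), g["end"].to_numpy(), g["fragment_id"].to_numpy()
        )
    out = []
    for chrom, group in calls.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        starts, ends, ids = by_chrom[chrom]
        pos = group["pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        if inside.any():
            sub = group.loc[inside].copy()
            sub["fragment_id"] = ids[idx[inside]]
            out.append(sub)
    if not out:
        return calls.iloc[0:0].assign(fragment_id=pd.Series(dtype=str))
    return pd.concat(out, ignore_index=True)


def aggregate_to_fragments(
    calls: pd.DataFrame,
    fragments: Sequence[Fragment],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Aggregate per-CpG calls to fragment level for one individual.

    Returns one row per fragment with observed calls: summed methylated (m)
    and unmethylated (u) observations, the number of CpGs observed, the
    number of CpGs with coverage >= ``min_reads`` (for qualification), and
    the fragment methylation percentage 100*m/(m+u).
    """
    assigned = assign_calls_to_fragments(calls, fragments)
    if assigned.empty:
        return pd.DataFrame(
            columns=["fragment_id", "m", "u", "n_cpgs_observed",
                     "n_cpgs_covered", "methylation_pct"]
        )
    cov = assigned["meth"] + assigned["unmeth"]
    agg = assigned.assign(cov_ok=(cov >= min_reads).astype(int)).groupby(
        "fragment_id", sort=False, as_index=False
    ).agg(
        m=("meth", "sum"),
        u=("unmeth", "sum"),
        n_cpgs_observed=("pos", "size"),
        n_cpgs_covered=("cov_ok", "sum"),
    )
    total = agg["m"] + agg["u"]
    agg["methylation_pct"] = np.where(total > 0, 100.0 * agg["m"] / total, np.nan)
    return agg


def qualify_fragment(
    n_cpgs_covered: int,
    total_reads: int | None = None,
    min_cpgs: int = 2,
    min_reads: int = 10,
    mode: str = "per_cpg",
) -> bool:
    """Inclusion filter for one (fragment, individual) pair.

    ``per_cpg`` (default): at least ``min_cpgs`` CpGs each covered by
    ``min_reads`` or more reads. ``fragment_total``: an alternative reading
    for sensitivity analysis — at least ``min_cpgs`` CpGs observed and a
    fragment-total coverage of ``min_reads``.
    """
    if mode == "per_cpg":
        return n_cpgs_covered >= min_cpgs
    if mode == "fragment_total":
        if total_reads is None:
            raise ValueError("fragment_total mode requires total_reads")
        return n_cpgs_covered >= min_cpgs and total_reads >= min_reads
    raise ValueError(f"unknown qualification mode: {mode!r}")


def qualify_from_coverages(
    coverages: Sequence[int], min_cpgs: int = 2, min_reads: int = 10
) -> bool:
    """Per-CpG qualification from a list of per-CpG read coverages."""
    return sum(c >= min_reads for c in coverages) >= min_cpgs


@dataclass
class CohortMatrix:
    """Fragments x individuals methylation count matrix with qualification.

    ``m``/``u`` are (n_fragments, n_individuals) arrays of methylated and
    unmethylated CpG observations (0 where a fragment was not observed);
    ``qualified`` marks pairs passing the inclusion filter; ``analysed_ids``
    are the fragments qualifying in at least ``min_individuals`` individuals.
    """

    fragment_ids: list[str]
    individuals: list[str]
    m: np.ndarray
    u: np.ndarray
    qualified: np.ndarray
    min_individuals: int
    fragment_n_cpgs: dict[str, int] = field(default_factory=dict)
    chrom_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {fid: i for i, fid in enumerate(self.fragment_ids)}

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def qualifying_counts(self) -> np.ndarray:
        """Per-fragment number of qualifying individuals."""
        return self.qualified.sum(axis=1)

    @property
    def analysed_mask(self) -> np.ndarray:
        return self.qualifying_counts >= self.min_individuals

    @property
    def analysed_ids(self) -> list[str]:
        mask = self.analysed_mask
        return [fid for fid, keep in zip(self.fragment_ids, mask) if keep]

    @property
    def n_analysed(self) -> int:
        return int(self.analysed_mask.sum())

    def analysed_cpg_total(self) -> int:
        """Total CpG sites contained in the analysed fragments."""
        return int(sum(self.fragment_n_cpgs.get(fid, 0) for fid in self.analysed_ids))

    def per_individual_qualifying(self) -> pd.Series:
        return pd.Series(self.qualified.sum(axis=0), index=self.individuals)

    def methylation_pct(self) -> np.ndarray:
        """Per-(fragment, individual) methylation %, NaN where unobserved."""
        total = self.m + self.u
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, 100.0 * self.m / total, np.nan)

    def to_wide_frame(self, analysed_only: bool = True) -> pd.DataFrame:
        """Wide table: fragment_id then per-individual ``m:u`` pairs."""
        rows = np.arange(self.n_fragments)
        if analysed_only:
            rows = rows[self.analysed_mask]
        data = {"fragment_id": [self.fragment_ids[i] for i in rows]}
        for j, ind in enumerate(self.individuals):
            data[ind] = [
                f"{self.m[i, j]}:{self.u[i, j]}" if self.qualified[i, j] else "."
                for i in rows
            ]
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path, analysed_only: bool = True) -> None:
        self.to_wide_frame(analysed_only).to_csv(path, sep="\t", index=False)


def assemble_cohort(
    tables: Mapping[str, pd.DataFrame],
    fragments: Sequence[Fragment],
    min_individuals: int = 9,
    min_cpgs: int = 2,
) -> CohortMatrix:
    """Assemble per-individual aggregated tables into a CohortMatrix.

    ``tables`` maps individual id -> the output of
    :func:`aggregate_to_fragments` for that individual (whose
    ``n_cpgs_covered`` already encodes the per-CpG read threshold).
    """
    individuals = sorted(tables)
    if len(individuals) < 2:
        raise ValueError("cohort requires at least 2 individuals")
    if min_individuals > len(individuals):
        raise ValueError(
            f"min_individuals ({min_individuals}) exceeds cohort size "
            f"({len(individuals)})"
        )
    fragment_ids = [f.id for f in fragments]
    index = {fid: i for i, fid in enumerate(fragment_ids)}
    F, I = len(fragment_ids), len(individuals)
    m = np.zeros((F, I), dtype=np.int64)
    u = np.zeros((F, I), dtype=np.int64)
    qualified = np.zeros((F, I), dtype=bool)
    for j, ind in enumerate(individuals):
        t = tables[ind]
        rows = t["fragment_id"].map(index)
        keep = rows.notna()
        r = rows[keep].astype(int).to_numpy()
        m[r, j] = t.loc[keep, "m"].to_numpy()
        u[r, j] = t.loc[keep, "u"].to_numpy()
        qualified[r, j] = t.loc[keep, "n_cpgs_covered"].to_numpy() >= min_cpgs
    return CohortMatrix(
        fragment_ids=fragment_ids,
        individuals=individuals,
        m=m,
        u=u,
        qualified=qualified,
        min_individuals=min_individuals,
        fragment_n_cpgs={f.id: f.n_cpgs for f in fragments},
        chrom_of={f.id: f.chrom for f in fragments},
    )


def read_cohort_dir(
    calls_dir: str | Path,
    fragments: Sequence[Fragment],
    min_individuals: int = 9,
    min_cpgs: int = 2,
    min_reads: int = 10,
    pattern: str = "*.tsv",
) -> CohortMatrix:
    """Read every per-individual call file in a directory (individual id =
    file stem) and assemble the cohort matrix."""
    calls_dir = Path(calls_dir)
    tables = {}
    for path in sorted(calls_dir.glob(pattern)):
        calls = read_cpg_calls(path)
        tables[path.stem] = aggregate_to_fragments(calls, fragments, min_reads=min_reads)
    return assemble_cohort(tables, fragments, min_individuals=min_individuals,
                           min_cpgs=min_cpgs)
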