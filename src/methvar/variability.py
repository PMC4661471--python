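"""Inter-individual methylation variability statistics.

The core test is a chi-square homogeneity test on the k x 2 table of
(methylated, unmethylated) CpG observations across the k individuals in
which a fragment qualified, with k - 1 degrees of freedom. Fragments whose
Bonferroni-corrected p-value falls at or below the family-wise cutoff
(alpha / number of analysed fragments, alpha = 0.001) are called
inter-individual variably methylated fragments (iVMFs).

Diagnostics per fragment: mean and sample SD of per-individual methylation
percentages, the binomial-scaled ("modified") coefficient of variation
SD / sqrt(mean * (100 - mean) / k), and log / logit transforms. Natural
logarithms throughout.

`FragmentVariabilityModel` / `FragmentVariabilityResults` wrap the
per-fragment computations over a `CohortMatrix` in the usual
model-fit-results idiom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import CohortMatrix

DEFAULT_ALLOSOMES = frozenset({"chrX", "chrY", "X", "Y"})


def chi_square_homogeneity(
    counts: Sequence[tuple[int, int]]
) -> tuple[float, int, float]:
    """Chi-square homogeneity test on per-individual (m, u) count pairs.

    Individuals with zero total observations are excluded (reducing k). The
    statistic is the standard k x 2 Pearson chi-square with expected cell
    counts row_total * col_total / grand_total and k - 1 degrees of freedom.
    A degenerate table (either pooled column zero) carries no information
    about proportion differences and returns (0, k - 1, 1). Fewer than two
    usable individuals returns the untestable sentinel (nan, k - 1, nan).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("counts must be a sequence of (m, u) pairs")
    if (arr < 0).any():
        raise ValueError("negative counts")
    arr = arr[arr.sum(axis=1) > 0]
    k = arr.shape[0]
    df = k - 1
    if k < 2:
        return (math.nan, df, math.nan)
    col = arr.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        return (0.0, df, 1.0)
    n = arr.sum(axis=1)
    p = col[0] / col.sum()
    e1 = n * p
    e0 = n * (1 - p)
    chi2 = float(((arr[:, 0] - e1) ** 2 / e1 + (arr[:, 1] - e0) ** 2 / e0).sum())
    return (chi2, df, float(stats.chi2.sf(chi2, df)))


def chi_square_homogeneity_batch(
    m: np.ndarray, u: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised homogeneity test over a fragments x individuals matrix.

    ``mask`` selects the (fragment, individual) cells entering each
    fragment's table; cells with zero total are dropped per fragment.
    Returns (chi2, df, p) arrays of length n_fragments with the same
    degenerate-table conventions as :func:`chi_square_homogeneity`.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    use = np.asarray(mask, dtype=bool) & ((m + u) > 0)
    mm = np.where(use, m, 0.0)
    uu = np.where(use, u, 0.0)
    k = use.sum(axis=1)
    df = k - 1
    M = mm.sum(axis=1)
    U = uu.sum(axis=1)
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        p_pool = np.where(total > 0, M / np.where(total > 0, total, 1), np.nan)
        n = mm + uu
        e1 = n * p_pool[:, None]
        e0 = n * (1 - p_pool)[:, None]
        cells = np.where(use & (e1 > 0), (mm - e1) ** 2 / np.where(e1 > 0, e1, 1), 0.0) \
            + np.where(use & (e0 > 0), (uu - e0) ** 2 / np.where(e0 > 0, e0, 1), 0.0)
        chi2 = cells.sum(axis=1)
    pvals = stats.chi2.sf(chi2, np.maximum(df, 1))
    # degenerate pooled column -> no observable proportion variation
    degenerate = (M == 0) | (U == 0)
    chi2 = np.where(degenerate, 0.0, chi2)
    pvals = np.where(degenerate, 1.0, pvals)
    # untestable: fewer than two usable individuals
    untestable = k < 2
    chi2 = np.where(untestable, np.nan, chi2)
    pvals = np.where(untestable, np.nan, pvals)
    return chi2, df, pvals


def bonferroni_threshold(alpha: float = 0.001, m_tests: int = 1) -> float:
    """Family-wise cutoff alpha / m_tests."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m_tests


def dispersion_metrics(pcts: Sequence[float]) -> dict[str, float]:
    """Mean, sample SD, modified CV and log/logit diagnostics of
    per-individual fragment methylation percentages.

    mod_cv = SD / sqrt(mean * (100 - mean) / k); logit_mean =
    ln(mean / (100 - mean)). Values undefined at mean 0 or 100 (and logs of
    zero SD/CV) are returned as NaN sentinels.
    """
    x = np.asarray(pcts, dtype=float)
    x = x[~np.isnan(x)]
    k = len(x)
    if k < 2:
        raise ValueError("need at least 2 individuals")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if 0.0 < mean < 100.0:
        mod_cv = sd / math.sqrt(mean * (100.0 - mean) / k)
        logit_mean = math.log(mean / (100.0 - mean))
    else:
        mod_cv = math.nan
        logit_mean = math.nan
    log_sd = math.log(sd) if sd > 0 else math.nan
    log_cv = math.log(mod_cv) if mod_cv and mod_cv > 0 else math.nan
    return {
        "mean_pct": mean, "sd": sd, "mod_cv": mod_cv,
        "log_sd": log_sd, "log_cv": log_cv, "logit_mean": logit_mean,
    }


def call_ivmfs(
    results: pd.DataFrame,
    cutoff: float,
    allosomes: Iterable[str] = DEFAULT_ALLOSOMES,
) -> pd.DataFrame:
    """Flag iVMFs (p <= cutoff, inclusive) and their autosomal subset.

    ``results`` needs columns ``p`` and (for the autosomal flag) ``chrom``.
    Returns a copy with boolean ``is_ivmf`` and ``is_autosomal_ivmf``.
    """
    allosomes = set(allosomes)
    out = results.copy()
    out["is_ivmf"] = out["p"].le(cutoff).fillna(False)
    if "chrom" in out.columns:
        out["is_autosomal_ivmf"] = out["is_ivmf"] & ~out["chrom"].isin(allosomes)
    else:
        out["is_autosomal_ivmf"] = out["is_ivmf"]
    return out


@dataclass(frozen=True)
class GroupComparison:
    fragment_id: str
    group_means: dict[str, float]
    mean_diff: float
    F: float
    p: float
    passes_mean_diff: bool
    significant_after_bonferroni: bool


def group_anova(
    pcts: Sequence[float],
    labels: Sequence[str],
    min_mean_diff: float = 20.0,
    bonferroni_cutoff: float | None = None,
    fragment_id: str = "",
) -> GroupComparison:
    """One-way ANOVA of per-individual methylation % between two groups
    (e.g. male vs female), with the >= ``min_mean_diff`` percentage-point
    mean-difference filter applied irrespective of p."""
    x = np.asarray(pcts, dtype=float)
    lab = np.asarray(labels)
    keep = ~np.isnan(x)
    x, lab = x[keep], lab[keep]
    groups = sorted(set(lab.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    ga, gb = (x[lab == g] for g in groups)
    means = {g: float(v.mean()) if len(v) else math.nan for g, v in zip(groups, (ga, gb))}
    mean_diff = abs(means[groups[0]] - means[groups[1]])
    if len(ga) < 2 or len(gb) < 2:
        F, p = math.nan, math.nan
    else:
        F, p = stats.f_oneway(ga, gb)
        F, p = float(F), float(p)
    sig = bool(bonferroni_cutoff is not None and not math.isnan(p) and p <= bonferroni_cutoff)
    return GroupComparison(
        fragment_id=fragment_id,
        group_means=means,
        mean_diff=float(mean_diff),
        F=F,
        p=p,
        passes_mean_diff=bool(mean_diff >= min_mean_diff),
        significant_after_bonferroni=sig,
    )


def group_anova_table(
    cohort: CohortMatrix,
    labels: Mapping[str, str],
    min_mean_diff: float = 20.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group ANOVA across the fragments qualified in *all* cohort
    members, with Bonferroni correction at ``alpha`` over that family.

    Returns one row per tested fragment: group means, |mean difference|,
    F, p, the >= ``min_mean_diff`` flag and Bonferroni significance.
    """
    lab = np.asarray([labels[i] for i in cohort.individuals])
    groups = sorted(set(lab.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    pct = cohort.methylation_pct()
    tested = cohort.qualified.all(axis=1)
    rows = np.flatnonzero(tested)
    cutoff = bonferroni_threshold(alpha, max(len(rows), 1))
    recs = []
    for i in rows:
        gc = group_anova(pct[i], lab, min_mean_diff=min_mean_diff,
                         bonferroni_cutoff=cutoff,
                         fragment_id=cohort.fragment_ids[i])
        recs.append({
            "fragment_id": gc.fragment_id,
            "chrom": cohort.chrom_of.get(gc.fragment_id, ""),
            f"mean_{groups[0]}": gc.group_means[groups[0]],
            f"mean_{groups[1]}": gc.group_means[groups[1]],
            "mean_diff": gc.mean_diff,
            "F": gc.F,
            "p": gc.p,
            "passes_mean_diff": gc.passes_mean_diff,
            "significant_after_bonferroni": gc.significant_after_bonferroni,
        })
    return pd.DataFrame(recs)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Replicate agreement: bias (mean of a - b) and 95% limits of
    agreement bias +/- 1.96 * SD(differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired values of equal length")
    d = a - b
    bias = float(d.mean())
    spread = 1.96 * float(d.std(ddof=1))
    return (bias, bias - spread, bias + spread)


def proportion_pct(numerator: float, denominator: float, digits: int = 1) -> float:
    """Share of a total as a percentage, rounded for reporting."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, digits)


class FragmentVariabilityModel:
    """Chi-square inter-individual variability model over a cohort matrix.

    Parameters
    ----------
    cohort : CohortMatrix
        Assembled fragments x individuals count matrix.
    alpha : float
        Nominal significance level before Bonferroni correction.
    allosomes : iterable of str
        Chromosome names excluded from the autosomal iVMF subset.
    """

    def __init__(
        self,
        cohort: CohortMatrix,
        alpha: float = 0.001,
        allosomes: Iterable[str] = DEFAULT_ALLOSOMES,
    ) -> None:
        self.cohort = cohort
        self.alpha = alpha
        self.allosomes = frozenset(allosomes)

    def fit(self) -> "FragmentVariabilityResults":
        """Test every analysed fragment and call iVMFs at the
        Bonferroni-corrected cutoff alpha / n_analysed."""
        c = self.cohort
        rows = np.flatnonzero(c.analysed_mask)
        m = c.m[rows]
        u = c.u[rows]
        mask = c.qualified[rows]
        chi2, df, p = chi_square_homogeneity_batch(m, u, mask)
        pct = np.where(mask & ((m + u) > 0), 100.0 * m / np.maximum(m + u, 1), np.nan)
        frame = pd.DataFrame({
            "fragment_id": [c.fragment_ids[i] for i in rows],
            "chrom": [c.chrom_of.get(c.fragment_ids[i], "") for i in rows],
            "k": df + 1,
            "chi2": chi2,
            "df": df,
            "p": p,
        })
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(pct, axis=1) if len(rows) else np.array([])
            kk = np.maximum(frame["k"].to_numpy(), 1)
            sd = np.array([
                np.nanstd(row, ddof=1) if np.sum(~np.isnan(row)) >= 2 else np.nan
                for row in pct
            ])
            denom = np.sqrt(mean * (100.0 - mean) / kk)
            mod_cv = np.where((mean > 0) & (mean < 100), sd / np.where(denom > 0, denom, np.nan), np.nan)
            logit_mean = np.where((mean > 0) & (mean < 100),
                                  np.log(mean / (100.0 - mean)), np.nan)
            log_sd = np.where(sd > 0, np.log(np.where(sd > 0, sd, 1)), np.nan)
            log_cv = np.where(mod_cv > 0, np.log(np.where(mod_cv > 0, mod_cv, 1)), np.nan)
        frame["mean_pct"] = mean
        frame["sd"] = sd
        frame["mod_cv"] = mod_cv
        frame["log_sd"] = log_sd
        frame["log_cv"] = log_cv
        frame["logit_mean"] = logit_mean
        n_tests = len(frame)
        cutoff = bonferroni_threshold(self.alpha, max(n_tests, 1))
        frame = call_ivmfs(frame, cutoff, self.allosomes)
        return FragmentVariabilityResults(self, frame, cutoff)


class FragmentVariabilityResults:
    """Fitted per-fragment variability results.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per analysed fragment: fragment_id, chrom, k, chi2, df, p,
        mean_pct, sd, mod_cv, log_sd, log_cv, logit_mean, is_ivmf,
        is_autosomal_ivmf.
    bonferroni_cutoff : float
        The familywise p cutoff used for calling.
    """

    def __init__(
        self, model: FragmentVariabilityModel, frame: pd.DataFrame, cutoff: float
    ) -> None:
        self.model = model
        self.frame = frame
        self.bonferroni_cutoff = cutoff

    @property
    def n_analysed(self) -> int:
        return len(self.frame)

    @property
    def n_ivmf(self) -> int:
        return int(self.frame["is_ivmf"].sum())

    @property
    def n_autosomal_ivmf(self) -> int:
        return int(self.frame["is_autosomal_ivmf"].sum())

    @property
    def ivmf_ids(self) -> list[str]:
        return self.frame.loc[self.frame["is_ivmf"], "fragment_id"].tolist()

    @property
    def autosomal_ivmf_ids(self) -> list[str]:
        return self.frame.loc[self.frame["is_autosomal_ivmf"], "fragment_id"].tolist()

    def ivmf_share_pct(self, digits: int = 1) -> float:
        """iVMFs as a percentage of analysed fragments."""
        return proportion_pct(self.n_ivmf, max(self.n_analysed, 1), digits)

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Fragment variability (chi-square homogeneity across individuals)",
            "=" * 64,
            f"Analysed fragments:        {self.n_analysed}",
            f"Individuals:               {self.model.cohort.n_individuals}",
            f"Nominal alpha:             {self.model.alpha}",
            f"Bonferroni cutoff:         {self.bonferroni_cutoff:.3g}",
            f"iVMFs called:              {self.n_ivmf} "
            f"({self.ivmf_share_pct():.1f}% of analysed)",
            f"Autosomal iVMFs:           {self.n_autosomal_ivmf}",
        ]
        if self.n_analysed:
            lines += [
                f"Median methylation (%):    {f['mean_pct'].median():.1f}",
                f"Median per-fragment SD:    {f['sd'].median():.2f}",
            ]
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def write_ivmf_bed(self, path: str | Path,
                       coords: Mapping[str, tuple[str, int, int]]) -> None:
        """Write called iVMFs as BED4, given fragment_id -> (chrom, start,
        end) coordinates."""
        with open(path, "w") as fh:
            for fid in self.ivmf_ids:
                chrom, start, end = coords[fid]
                fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")
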