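"""Synthetic study generator with planted ground truth.

Emulates the structure of an RRBS cohort study of a homogeneous cell type:
a miniature genome with MspI (CCGG) sites at a configurable density, gene
models and CpG islands; per-individual per-CpG bisulfite call files drawn
from a beta-binomial model in which a planted subset of fragments carries
elevated inter-individual dispersion; optional X-linked sex-differential
fragments; and expression tables in which linked exons' counts correlate
with fragment methylation at a configurable coupling.

Generative model
----------------
Each RR fragment receives a true mean methylation mu: non-variable
fragments from a bimodal profile (low mode ~3%, high mode ~88%, as in
CpG-island-enriched methylomes), planted variable fragments from
Uniform(0.25, 0.75) (intermediate methylation, where inter-individual
variation is observable). Individual i's true fragment methylation is
p_i ~ Beta(mu * c, (1 - mu) * c) with concentration c set by the fragment's
dispersion class (``dispersion_null`` for stable fragments,
``dispersion_variable`` < ``dispersion_null`` for planted ones;
c = inf collapses the Beta to a point mass, giving exact binomial counts).
Per-CpG read coverage is negative binomial around ``coverage_mean`` and
methylated counts are Binomial(coverage, p_i).

Randomness is governed by a single seed; per-individual streams are spawned
from it, so adding individuals never changes the data of existing ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rr_digest import digest_genome, select_rr_fragments, write_fragments_bed
from .annotation import GeneModel
from .intervals import Fragment, GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    seed: int = 0
    n_individuals: int = 11
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    ccgg_density: float = 2.0          # CCGG sites per kb
    frac_variable: float = 0.10        # proportion of RR fragments planted variable
    base_meth_profile: tuple[float, float] = (0.6, 0.4)  # weights of low/high modes
    meth_modes: tuple[float, float] = (0.03, 0.88)
    dispersion_null: float = 200.0     # beta concentration, stable fragments
    dispersion_variable: float = 4.0   # beta concentration, planted fragments
    coverage_mean: float = 20.0        # reads per CpG
    coverage_shape: float = 5.0        # negative-binomial shape (overdispersion)
    expression_coupling: float = 0.7   # target |r| methylation vs linked exon counts
    sexes: tuple[str, ...] | None = None  # per-individual 'M'/'F'; adds a chrX
    min_fragment_len: int = 40
    max_fragment_len: int = 220

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if not 0 <= self.frac_variable <= 1:
            raise ValueError("frac_variable must be in [0, 1]")
        if abs(sum(self.base_meth_profile) - 1) > 1e-9:
            raise ValueError("base_meth_profile weights must sum to 1")
        if not all(0 <= w <= 1 for w in self.base_meth_profile):
            raise ValueError("base_meth_profile weights must be in [0, 1]")
        if not all(0 <= m <= 1 for m in self.meth_modes):
            raise ValueError("meth_modes must be proportions")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not self.dispersion_variable < self.dispersion_null:
            raise ValueError(
                "dispersion_variable must be < dispersion_null "
                "(variable fragments are more dispersed)"
            )
        if not -1 <= self.expression_coupling <= 1:
            raise ValueError("expression_coupling must be in [-1, 1]")
        if self.sexes is not None and len(self.sexes) != self.n_individuals:
            raise ValueError("sexes must have one entry per individual")

    @property
    def individual_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_individuals)]


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    cgis: list[GenomicInterval]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        write_gtf(self.genes, outdir / "genes.gtf")
        write_bed12(self.genes, outdir / "genes.bed12")
        with open(outdir / "cgi.bed", "w") as fh:
            for iv in self.cgis:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\tsynthetic\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(g.exons, 1):
                ea = attrs + f' transcript_id "{g.gene_id}.t1"; exon_number "{i}";'
                fh.write(
                    f"{e.chrom}\tsynthetic\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\t{ea}\n"
                )


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(e.length) for e in g.exons) + ","
            offsets = ",".join(str(e.start - iv.start) for e in g.exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def _scrub_ccgg(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every CCGG occurrence in-place by rewriting its second base.

    Replacement with A/T cannot create a new CCGG at the same spot, but a
    scan pass is repeated until clean to handle overlaps conservatively.
    """
    import re

    while True:
        s = "".join(seq.tolist())
        hits = [m.start() for m in re.finditer("(?=CCGG)", s)]
        if not hits:
            return
        for idx in hits:
            seq[idx + 1] = rng.choice(list("AT"))


def _random_sequence(n: int, rng: np.random.Generator,
                     p: Sequence[float] = (0.3, 0.2, 0.2, 0.3)) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=list(p))


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate chromosome sequences, gene models and CpG islands.

    CCGG sites are planted at approximately ``ccgg_density`` per kb on a
    background scrubbed of incidental CCGG (so density 0 yields a genome
    with no MspI site at all). Genes tile each chromosome with >= 2 exons
    and alternating strands; a CG-rich CpG island is planted at every other
    promoter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.sexes is not None:
        chrom_names.append("chrX")
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    cgis: list[GenomicInterval] = []
    for chrom in chrom_names:
        L = config.chrom_length
        seq = _random_sequence(L, rng)
        # gene layout: one gene every ~12 kb, 6 kb long, 3 exons
        gene_pitch, gene_len = 12_000, 6_000
        pos = 2_000
        g_index = 0
        while pos + gene_len + 2_000 < L:
            strand = "+" if g_index % 2 == 0 else "-"
            gid = f"{chrom}_g{g_index + 1}"
            exon_len = 400
            intron_len = (gene_len - 3 * exon_len) // 2
            exon_starts = [pos,
                           pos + exon_len + intron_len,
                           pos + 2 * (exon_len + intron_len)]
            exons = tuple(
                GenomicInterval(chrom, s, s + exon_len, strand)
                for s in exon_starts
            )
            genes.append(GeneModel(
                gene_id=gid,
                interval=GenomicInterval(chrom, pos, pos + gene_len, strand),
                exons=exons,
            ))
            if g_index % 2 == 0:
                # CG-rich island over the promoter-proximal end
                tss = pos if strand == "+" else pos + gene_len - 1
                c_start = max(0, tss - 500)
                c_end = min(L, tss + 500)
                island = rng.choice(
                    _BASES, size=c_end - c_start, p=[0.1, 0.4, 0.4, 0.1]
                )
                seq[c_start:c_end] = island
                cgis.append(GenomicInterval(chrom, c_start, c_end))
            pos += gene_pitch
            g_index += 1
        _scrub_ccgg(seq, rng)
        n_sites = rng.poisson(config.ccgg_density * L / 1000.0)
        if n_sites:
            placed = rng.choice(L - 4, size=min(n_sites, max(L // 8, 1)),
                                replace=False)
            for s in np.sort(placed):
                seq[s:s + 4] = list("CCGG")
            # planting can abut existing sites; keep whatever results
        sequences[chrom] = "".join(seq.tolist())
    return SyntheticGenome(sequences=sequences, genes=genes, cgis=cgis)


@dataclass
class TruthTable:
    """Planted ground truth: per-fragment dispersion class, true
    per-individual methylation (%), and optional linked exon."""

    frame: pd.DataFrame            # fragment_id, chrom, is_variable, is_sex_differential, linked_exon
    true_methylation: pd.DataFrame  # fragment_id x individual columns, in %

    @property
    def variable_ids(self) -> set[str]:
        return set(self.frame.loc[self.frame["is_variable"], "fragment_id"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.true_methylation.to_csv(outdir / "truth_methylation.tsv", sep="\t",
                                     index=False)


def _draw_beta(rng: np.random.Generator, mu: float, conc: float, size: int) -> np.ndarray:
    if math.isinf(conc):
        return np.full(size, mu)
    mu = min(max(mu, 1e-6), 1 - 1e-6)
    return rng.beta(mu * conc, (1 - mu) * conc, size=size)


def simulate_methylome(
    genome: SyntheticGenome,
    rr_fragments: Sequence[Fragment],
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Draw per-individual per-CpG call tables and the planted truth.

    Returns ``{individual_id: calls}`` with calls in the 1-based 4-column
    dialect of the call reader (chrom, pos, meth, unmeth) and the
    TruthTable. Fragments without CpGs are skipped with a warning.
    """
    root = np.random.SeedSequence(config.seed)
    _, frag_ss, *ind_ss = root.spawn(2 + config.n_individuals)
    frag_rng = np.random.default_rng(frag_ss)
    individuals = config.individual_ids

    usable = []
    for f in rr_fragments:
        if f.n_cpgs == 0:
            warnings.warn(f"fragment {f.id} has no CpGs; skipped")
            continue
        usable.append(f)

    autosomal = [f for f in usable if f.chrom != "chrX"]
    x_linked = [f for f in usable if f.chrom == "chrX"]

    # Location-dependent methylation: CGI-, promoter- and exon-associated
    # fragments occupy the low mode (as in real CpG-island-enriched
    # methylomes, where promoters/CGIs/exons are hypomethylated and introns
    # and intergenic regions methylated); the remaining low-mode mass needed
    # to hit the configured overall base_meth_profile weights is spread
    # uniformly over the other fragments.
    def _is_low_region(f: Fragment) -> bool:
        mid = f.interval.midpoint
        for cgi in genome.cgis:
            if cgi.chrom == f.chrom and cgi.start - 1000 <= mid < cgi.end + 1000:
                return True
        for g in genome.genes:
            if g.interval.chrom != f.chrom:
                continue
            if abs(g.tss - mid) <= 1000:
                return True
            for e in g.exons:
                if e.start <= mid < e.end:
                    return True
        return False

    low_region = {id(f): _is_low_region(f) for f in autosomal}
    f_regional = (sum(low_region.values()) / len(autosomal)) if autosomal else 0.0
    w_low = config.base_meth_profile[0]
    p_extra_low = max(0.0, (w_low - f_regional) / max(1.0 - f_regional, 1e-9))
    n_var = round(config.frac_variable * len(autosomal))
    # plant half the variable fragments on exons (where available) so the
    # exon-inclusion analyses have linked fragments to find
    exonic = [
        j for j, f in enumerate(autosomal)
        if any(
            e.overlaps(f.interval)
            for g in genome.genes if g.interval.chrom == f.chrom
            for e in g.exons
        )
    ]
    var_idx: set[int] = set()
    if n_var:
        n_exonic = min(len(exonic), n_var // 2 + n_var % 2)
        if n_exonic:
            var_idx |= set(
                frag_rng.choice(exonic, size=n_exonic, replace=False).tolist()
            )
        rest = [j for j in range(len(autosomal)) if j not in var_idx]
        n_rest = n_var - len(var_idx)
        if n_rest:
            var_idx |= set(
                frag_rng.choice(rest, size=n_rest, replace=False).tolist()
            )

    # fragment-level true means and dispersion class
    mu = np.empty(len(usable))
    conc = np.empty(len(usable))
    is_variable = np.zeros(len(usable), dtype=bool)
    is_sexdiff = np.zeros(len(usable), dtype=bool)
    pos_of = {id(f): i for i, f in enumerate(usable)}
    for j, f in enumerate(autosomal):
        i = pos_of[id(f)]
        if j in var_idx:
            is_variable[i] = True
            mu[i] = frag_rng.uniform(0.25, 0.75)
            conc[i] = config.dispersion_variable
        else:
            low = low_region[id(f)] or frag_rng.random() < p_extra_low
            mode = config.meth_modes[0] if low else config.meth_modes[1]
            mu[i] = float(np.clip(frag_rng.normal(mode, 0.01), 0.001, 0.999))
            conc[i] = config.dispersion_null
    for f in x_linked:
        i = pos_of[id(f)]
        is_sexdiff[i] = frag_rng.random() < 0.5
        mu[i] = 0.05
        conc[i] = config.dispersion_null

    # per-individual truth and observed counts, one spawned stream each
    true_pct = np.empty((len(usable), config.n_individuals))
    calls: dict[str, pd.DataFrame] = {}
    for j, (ind, ss) in enumerate(zip(individuals, ind_ss)):
        rng = np.random.default_rng(ss)
        rows = {"chrom": [], "pos": [], "meth": [], "unmeth": []}
        for i, f in enumerate(usable):
            m_i = mu[i]
            if is_sexdiff[i] and config.sexes is not None and config.sexes[j] == "F":
                m_i = 0.60   # X inactivation: heavy methylation in females
            p = float(_draw_beta(rng, m_i, conc[i], 1)[0])
            true_pct[i, j] = 100.0 * p
            ncpg = f.n_cpgs
            r = config.coverage_shape
            cov = rng.negative_binomial(r, r / (r + config.coverage_mean), size=ncpg)
            meth = rng.binomial(cov, p)
            rows["chrom"].extend([f.chrom] * ncpg)
            rows["pos"].extend(pp + 1 for pp in f.cpg_positions)  # 1-based dialect
            rows["meth"].extend(meth.tolist())
            rows["unmeth"].extend((cov - meth).tolist())
        calls[ind] = pd.DataFrame(rows)

    linked = _link_exons_to_fragments(genome, [usable[i] for i in range(len(usable))],
                                      is_variable)
    truth_frame = pd.DataFrame({
        "fragment_id": [f.id for f in usable],
        "chrom": [f.chrom for f in usable],
        "is_variable": is_variable,
        "is_sex_differential": is_sexdiff,
        "true_mean_pct": 100.0 * mu,
        "linked_exon": [linked.get(f.id) for f in usable],
    })
    tm = pd.DataFrame(true_pct, columns=individuals)
    tm.insert(0, "fragment_id", [f.id for f in usable])
    return calls, TruthTable(frame=truth_frame, true_methylation=tm)


def _link_exons_to_fragments(
    genome: SyntheticGenome, fragments: Sequence[Fragment], is_variable: np.ndarray
) -> dict[str, str]:
    """Map variable fragments overlapping exons to exon ids, one fragment
    per exon (an exon's counts can only track a single fragment)."""
    linked: dict[str, str] = {}
    used: set[str] = set()
    for i, f in enumerate(fragments):
        if not is_variable[i]:
            continue
        for g in genome.genes:
            if g.interval.chrom != f.chrom:
                continue
            for k, e in enumerate(g.exons, 1):
                eid = f"{g.gene_id}.e{k}"
                if eid not in used and e.overlaps(f.interval):
                    linked[f.id] = eid
                    used.add(eid)
                    break
            if f.id in linked:
                break
    return linked


def exon_id_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for g in genes:
        for k, e in enumerate(g.exons, 1):
            rows.append({"exon_id": f"{g.gene_id}.e{k}", "gene_id": g.gene_id,
                         "chrom": e.chrom, "start": e.start, "end": e.end})
    return pd.DataFrame(rows)


def simulate_expression(
    genome: SyntheticGenome,
    truth: TruthTable,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene abundance and exon count tables coupled to the planted truth.

    Exons linked to a variable fragment receive log2 counts correlated with
    that fragment's per-individual true methylation at approximately
    ``expression_coupling``; all other exons are independent noise. Genes
    whose promoter-most fragment is variable get abundance inversely
    related to its methylation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    individuals = config.individual_ids
    rho = config.expression_coupling
    tm = truth.true_methylation.set_index("fragment_id")

    exons = exon_id_table(genome.genes)
    link_of_exon = {
        r.linked_exon: r.fragment_id
        for r in truth.frame.itertuples()
        if r.linked_exon is not None and isinstance(r.linked_exon, str)
    }
    # Calibrate the linked-exon coupling so the correlation pooled over all
    # (linked exon, individual) pairs lands at expression_coupling: counts
    # follow one global linear map of methylation plus noise whose variance
    # is set from the pooled methylation spread.
    linked_meth = np.array([
        tm.loc[fid, individuals].to_numpy(float)
        for fid in link_of_exon.values()
    ]) if link_of_exon else np.empty((0, len(individuals)))
    pooled_sd = float(linked_meth.std()) if linked_meth.size else 0.0
    beta = 0.04 * np.sign(rho) if rho else 0.0   # log2 counts per % methylation
    if 0 < abs(rho) < 1 and pooled_sd > 0:
        noise_sd = abs(beta) * pooled_sd * math.sqrt(1.0 / rho ** 2 - 1.0)
    elif abs(rho) >= 1:
        noise_sd = 0.0
    else:
        noise_sd = 1.0
    exon_rows = []
    for r in exons.itertuples():
        if r.exon_id in link_of_exon:
            meth = tm.loc[link_of_exon[r.exon_id], individuals].to_numpy(float)
            log2c = 7.0 + beta * (meth - 50.0) \
                + noise_sd * rng.standard_normal(len(individuals))
            is_diff = True
        else:
            base = rng.uniform(5.0, 9.0)      # log2 scale baseline
            log2c = base + 1.5 * rng.standard_normal(len(individuals))
            is_diff = False
        counts = np.rint(np.exp2(log2c)).astype(int)
        for ind, c in zip(individuals, counts):
            exon_rows.append({
                "exon_id": r.exon_id, "gene_id": r.gene_id, "chrom": r.chrom,
                "start": r.start, "end": r.end, "individual_id": ind,
                "read_count": int(c), "is_differential": is_diff,
            })
    exon_table = pd.DataFrame(exon_rows)

    # gene abundance: inverse coupling to promoter-fragment methylation
    frame = truth.frame.set_index("fragment_id")
    promoter_frag: dict[str, str] = {}
    for g in genome.genes:
        tss = g.tss
        best, best_d = None, None
        for fid in frame.index:
            chrom, span = fid.split(":")
            if chrom != g.interval.chrom:
                continue
            s, e = (int(x) for x in span.split("-"))
            d = 0 if s <= tss < e else min(abs(tss - s), abs(tss - (e - 1)))
            if d <= 2000 and (best_d is None or d < best_d):
                best, best_d = fid, d
        if best is not None:
            promoter_frag[g.gene_id] = best
    gene_rows = []
    for g in genome.genes:
        base = rng.uniform(2.0, 5.0)       # ln scale
        fid = promoter_frag.get(g.gene_id)
        if fid is not None and bool(frame.loc[fid, "is_variable"]):
            meth = tm.loc[fid, individuals].to_numpy(float)
            z = (meth - meth.mean()) / (meth.std() or 1.0)
            noise = rng.standard_normal(len(individuals))
            ln_ab = base - (abs(rho) * z + math.sqrt(max(0.0, 1 - rho ** 2)) * noise)
        else:
            ln_ab = base + rng.standard_normal(len(individuals))
        for ind, v in zip(individuals, np.exp(ln_ab)):
            gene_rows.append({"gene_id": g.gene_id, "individual_id": ind,
                              "abundance": float(v)})
    return pd.DataFrame(gene_rows), exon_table


def simulate_count_tables(
    config: SimulationConfig,
    n_fragments: int,
    n_cpgs_range: tuple[int, int] = (2, 5),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw fragment x individual (m, u) count matrices directly, without a
    genome — the same beta-binomial generative model as
    :func:`simulate_methylome`, vectorised for statistical calibration and
    power studies at large fragment counts.

    Returns ``(m, u, is_variable)`` with shapes (n_fragments,
    n_individuals) for the count matrices. Set ``frac_variable=0`` and
    ``dispersion_null=inf`` in the config for an exact-binomial null.
    """
    root = np.random.SeedSequence(config.seed)
    _, frag_ss, *ind_ss = root.spawn(2 + config.n_individuals)
    frag_rng = np.random.default_rng(frag_ss)
    F, I = n_fragments, config.n_individuals

    n_var = round(config.frac_variable * F)
    is_variable = np.zeros(F, dtype=bool)
    if n_var:
        is_variable[frag_rng.choice(F, size=n_var, replace=False)] = True
    mu = np.empty(F)
    mu[is_variable] = frag_rng.uniform(0.25, 0.75, size=n_var)
    n_null = F - n_var
    low = frag_rng.random(n_null) < config.base_meth_profile[0]
    modes = np.where(low, config.meth_modes[0], config.meth_modes[1])
    mu[~is_variable] = np.clip(
        frag_rng.normal(modes, 0.01), 0.001, 0.999
    )
    conc = np.where(is_variable, config.dispersion_variable, config.dispersion_null)
    ncpg = frag_rng.integers(n_cpgs_range[0], n_cpgs_range[1] + 1, size=F)

    m = np.empty((F, I), dtype=np.int64)
    u = np.empty((F, I), dtype=np.int64)
    r = config.coverage_shape
    for j, ss in enumerate(ind_ss):
        rng = np.random.default_rng(ss)
        if np.isinf(conc).all():
            p = mu
        else:
            finite = np.isfinite(conc)
            p = np.where(finite, 0.0, mu)
            cm = np.clip(mu, 1e-6, 1 - 1e-6)
            draws = rng.beta(cm * np.where(finite, conc, 1.0),
                             (1 - cm) * np.where(finite, conc, 1.0))
            p = np.where(finite, draws, mu)
        # total fragment coverage: sum of per-CpG negative binomials
        cov = rng.negative_binomial(r * ncpg, r / (r + config.coverage_mean))
        meth = rng.binomial(cov, p)
        m[:, j] = meth
        u[:, j] = cov - meth
    return m, u, is_variable


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: SyntheticGenome
    rr_fragments: list[Fragment]
    calls: dict[str, pd.DataFrame]
    truth: TruthTable
    gene_abundance: pd.DataFrame
    exon_counts: pd.DataFrame

    def to_cohort(self, min_individuals: int = 9, min_cpgs: int = 2,
                  min_reads: int = 10):
        """Aggregate the in-memory call tables into a CohortMatrix, applying
        the same dialect conversion as the file reader (positions 1-based
        on disk, 0-based in memory)."""
        from .methylation import aggregate_to_fragments, assemble_cohort

        tables = {}
        for ind, df in self.calls.items():
            calls = df[["chrom", "pos", "meth", "unmeth"]].copy()
            calls["pos"] = calls["pos"] - 1
            tables[ind] = aggregate_to_fragments(
                calls, self.rr_fragments, min_reads=min_reads
            )
        return assemble_cohort(
            tables, self.rr_fragments,
            min_individuals=min_individuals, min_cpgs=min_cpgs,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write(outdir)
        write_fragments_bed(self.rr_fragments, outdir / "rr_fragments.bed")
        calls_dir = outdir / "calls"
        calls_dir.mkdir(exist_ok=True)
        for ind, df in self.calls.items():
            df.to_csv(calls_dir / f"{ind}.tsv", sep="\t", header=False, index=False)
        self.truth.write(outdir)
        self.gene_abundance.to_csv(outdir / "gene_abundance.tsv", sep="\t", index=False)
        self.exon_counts.to_csv(outdir / "exon_counts.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """End-to-end generation: genome -> RR fragments -> methylomes ->
    expression, with planted truth."""
    genome = generate_genome(config)
    frags = digest_genome(genome.sequences)
    rr, _ = select_rr_fragments(
        frags, config.min_fragment_len, config.max_fragment_len
    )
    calls, truth = simulate_methylome(genome, rr, config)
    gene_ab, exon_counts = simulate_expression(genome, truth, config)
    return SimulatedStudy(
        config=config, genome=genome, rr_fragments=rr, calls=calls,
        truth=truth, gene_abundance=gene_ab, exon_counts=exon_counts,
    )
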