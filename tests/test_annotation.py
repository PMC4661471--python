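"""Gene/CGI context assignment, variability scores and VMG calling."""

import math

import pandas as pd
import pytest

from methvar.annotation import (
    GeneIndex,
    GeneModel,
    VariabilityScore,
    annotate_fragments,
    call_vmgs,
    classify_cgi_context,
    classify_gene_context,
    merge_intervals,
    read_genes_bed12,
    read_genes_gtf,
    summarize_methylation_by_feature,
    variability_scores,
)
from methvar.intervals import Fragment, GenomicInterval


def frag(fid, chrom, start, end):
    return Fragment(id=fid, interval=GenomicInterval(chrom, start, end))


def gene(gid, chrom, start, end, strand, exon_spans):
    return GeneModel(
        gene_id=gid,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans),
    )


# + strand gene: TSS 20000; exons [20000,20400), [22000,22400), [25600,26000)
PLUS = gene("gplus", "chr1", 20_000, 26_000, "+",
            [(20_000, 20_400), (22_000, 22_400), (25_600, 26_000)])
# - strand gene far away: TSS 59999
MINUS = gene("gminus", "chr1", 54_000, 60_000, "-",
             [(54_000, 54_400), (56_800, 57_200), (59_600, 60_000)])
INDEX = GeneIndex([PLUS, MINUS])


class TestGeneContext:
    @pytest.mark.parametrize("start,end,expected,gene_id", [
        (18_950, 19_050, "promoter_0_2kb", "gplus"),   # ~1 kb upstream of + TSS
        (7_900, 8_000, "distant_gt10kb", "gplus"),     # 12 kb upstream
        (17_400, 17_500, "promoter_2_5kb", "gplus"),
        (12_000, 12_100, "upstream_5_10kb", "gplus"),
        (19_990, 20_050, "tss_overlap", "gplus"),      # covers the TSS
        (20_100, 20_200, "exon", "gplus"),             # inside exon 1
        (21_000, 21_100, "intron", "gplus"),
        (20_300, 20_500, "exon_intron_boundary", "gplus"),
        (21_900, 22_100, "intron_exon_boundary", "gplus"),
    ])
    def test_plus_strand_categories(self, start, end, expected, gene_id):
        a = classify_gene_context(frag("f", "chr1", start, end), INDEX)
        assert a.category == expected
        assert a.gene_id == gene_id

    @pytest.mark.parametrize("start,end,expected", [
        (60_900, 61_000, "promoter_0_2kb"),   # upstream of - TSS = higher coords
        (63_000, 63_100, "promoter_2_5kb"),
        (59_950, 60_050, "tss_overlap"),
        (59_700, 59_800, "exon"),
        # crossing the exon's genomic start on a - strand gene is where
        # transcription leaves the exon for the intron
        (59_500, 59_700, "exon_intron_boundary"),
    ])
    def test_minus_strand_categories(self, start, end, expected):
        a = classify_gene_context(frag("f", "chr1", start, end), INDEX)
        assert a.category == expected

    def test_strand_symmetry(self):
        """Mirroring the genome and flipping strands preserves categories."""
        L = 100_000
        g_fw = gene("g", "chr1", 20_000, 26_000, "+",
                    [(20_000, 20_400), (22_000, 22_400), (25_600, 26_000)])
        g_rv = gene("g", "chr1", L - 26_000, L - 20_000, "-",
                    [(L - 26_000, L - 25_600), (L - 22_400, L - 22_000),
                     (L - 20_400, L - 20_000)])
        ix_fw, ix_rv = GeneIndex([g_fw]), GeneIndex([g_rv])
        cases = [(18_950, 19_050), (12_000, 12_100), (20_100, 20_200),
                 (21_000, 21_100), (20_300, 20_500), (19_990, 20_050)]
        for s, e in cases:
            a = classify_gene_context(frag("f", "chr1", s, e), ix_fw)
            b = classify_gene_context(frag("f", "chr1", L - e, L - s), ix_rv)
            assert a.category == b.category, (s, e)

    def test_empty_gene_set_sentinel(self):
        df = annotate_fragments([frag("f", "chr1", 0, 100)], genes=[])
        assert df.loc[0, "category"] == "unassigned"

    def test_partition_property(self, study):
        """Every fragment gets exactly one category; counts sum to total."""
        df = annotate_fragments(study.rr_fragments, study.genome.genes,
                                study.genome.cgis)
        assert len(df) == len(study.rr_fragments)
        assert df["category"].notna().all()
        assert df["category"].value_counts().sum() == len(df)


class TestCgiContext:
    CGIS = [GenomicInterval("chr1", 10_000, 11_000)]

    @pytest.mark.parametrize("start,end,expected", [
        (10_400, 10_500, "core"),        # midpoint inside
        (11_950, 12_050, "shore"),       # midpoint 1 kb from edge
        (13_950, 14_050, "shelf"),       # 3 kb from edge
        (15_950, 16_050, "none"),        # 5 kb out
        (7_950, 8_050, "shore"),         # left flank
    ])
    def test_band_arithmetic(self, start, end, expected):
        assert classify_cgi_context(frag("f", "chr1", start, end), self.CGIS) \
            == expected

    def test_other_chromosome(self):
        assert classify_cgi_context(frag("f", "chr2", 10_400, 10_500), self.CGIS) \
            == "none"

    def test_nearest_cgi_wins(self):
        cgis = [GenomicInterval("chr1", 0, 1_000),
                GenomicInterval("chr1", 6_000, 7_000)]
        # midpoint 5,050: 4,051 bp right of first CGI edge, 950 bp left of second
        assert classify_cgi_context(frag("f", "chr1", 5_000, 5_100), cgis) == "shore"


class TestVariabilityScore:
    @pytest.mark.parametrize("n_ivmf,n_analysed,expected", [
        (5, 5, 1.00),
        (0, 7, 0.0),
        (9, 13, 9 / 13),   # ~0.69
    ])
    def test_score(self, n_ivmf, n_analysed, expected):
        assert VariabilityScore("u", n_analysed, n_ivmf).vs == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            VariabilityScore("u", 0, 0)
        with pytest.raises(ValueError):
            VariabilityScore("u", 2, 3)

    def test_scale_free(self):
        assert VariabilityScore("u", 13, 9).vs == \
            pytest.approx(VariabilityScore("u", 26, 18).vs)


class TestVmgCalling:
    def _scores(self, rows):
        df = pd.DataFrame(rows, columns=["unit_id", "n_analysed", "n_ivmf"])
        df["vs"] = df["n_ivmf"] / df["n_analysed"]
        return df

    def test_threshold_rules(self):
        scores = self._scores([
            ("gA", 6, 3),    # vs 0.5, 3 iVMFs -> VMG
            ("gB", 2, 2),    # vs 1.0 but only 2 iVMFs -> no
            ("gC", 22, 9),   # 9 iVMFs, vs 0.41 -> no (score rule)
            ("gD", 5, 5),    # vs 1.0 -> VMG
        ])
        vmgs = call_vmgs(scores)
        assert set(vmgs["unit_id"]) == {"gA", "gD"}

    def test_scores_from_assignments(self):
        assignments = pd.DataFrame({
            "fragment_id": [f"f{i}" for i in range(6)],
            "gene_id": ["g1"] * 4 + ["g2"] * 2,
        })
        flags = {"f0": True, "f1": True, "f2": False, "f3": False, "f4": True,
                 "f5": False}
        scores = variability_scores(assignments, flags).set_index("unit_id")
        assert scores.loc["g1", "n_analysed"] == 4
        assert scores.loc["g1", "n_ivmf"] == 2
        assert scores.loc["g1", "vs"] == pytest.approx(0.5)
        assert scores.loc["g2", "vs"] == pytest.approx(0.5)


class TestFeatureMethylationSummary:
    def _assign(self, cats):
        return pd.DataFrame({
            "fragment_id": [f"f{i}" for i in range(len(cats))],
            "category": cats,
        })

    def test_constant_input(self):
        a = self._assign(["exon", "exon", "intron", "intron"])
        meth = {f"f{i}": 50.0 for i in range(4)}
        med, p = summarize_methylation_by_feature(meth, a)
        assert (med["median"] == 50.0).all()
        assert math.isnan(p)   # no variance anywhere: sentinel

    def test_disjoint_separation(self):
        a = self._assign(["exon"] * 4 + ["intron"] * 4)
        meth = {f"f{i}": (0.0 if i < 4 else 100.0) for i in range(8)}
        med, p = summarize_methylation_by_feature(meth, a)
        med = med.set_index("category")
        assert med.loc["exon", "median"] == 0.0
        assert med.loc["intron", "median"] == 100.0
        assert p < 1e-10

    def test_generator_promoter_below_gene_body(self, study):
        """The bimodal generator plants CGI-promoter fragments in the low
        mode, so promoter methylation sits below gene-body methylation."""
        df = annotate_fragments(study.rr_fragments, study.genome.genes,
                                study.genome.cgis)
        truth = study.truth.frame.set_index("fragment_id")["true_mean_pct"]
        stable = set(study.truth.frame.loc[~study.truth.frame["is_variable"],
                                           "fragment_id"])
        meth = {fid: truth[fid] for fid in truth.index if fid in stable}
        med, _ = summarize_methylation_by_feature(meth, df)
        med = med.set_index("category")
        promoter = med.loc["tss_overlap":"tss_overlap", "median"].min() \
            if "tss_overlap" in med.index else math.inf
        promoter = min(promoter, *(med.loc[c, "median"]
                                   for c in ("promoter_0_2kb",)
                                   if c in med.index))
        body = max(med.loc[c, "median"] for c in ("intron", "exon")
                   if c in med.index)
        assert promoter < body


class TestReaders:
    def test_gtf_roundtrip(self, tmp_path, study):
        from methvar.simulate import write_gtf

        path = tmp_path / "genes.gtf"
        write_gtf(study.genome.genes, path)
        back = read_genes_gtf(path)
        orig = sorted(study.genome.genes, key=lambda g: g.gene_id)
        back = sorted(back, key=lambda g: g.gene_id)
        assert [g.gene_id for g in back] == [g.gene_id for g in orig]
        for a, b in zip(back, orig):
            assert a.interval == b.interval
            assert a.exons == b.exons
            assert a.tss == b.tss

    def test_bed12_roundtrip(self, tmp_path, study):
        from methvar.simulate import write_bed12

        path = tmp_path / "genes.bed12"
        write_bed12(study.genome.genes, path)
        back = {g.gene_id: g for g in read_genes_bed12(path)}
        for g in study.genome.genes:
            assert back[g.gene_id].interval == g.interval
            assert back[g.gene_id].exons == g.exons

    def test_merge_intervals(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20),
               GenomicInterval("chr1", 30, 40), GenomicInterval("chr2", 0, 5)]
        merged = merge_intervals(ivs)
        assert [(m.chrom, m.start, m.end) for m in merged] == [
            ("chr1", 0, 20), ("chr1", 30, 40), ("chr2", 0, 5)
        ]
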