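"""Synthetic-data generator: determinism, planted structure, limits."""

import math

import numpy as np
import pandas as pd
import pytest

from methvar.rr_digest import digest_genome, select_rr_fragments
from methvar.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_count_tables,
    simulate_expression,
    simulate_methylome,
    simulate_study,
)
from methvar.variability import chi_square_homogeneity_batch


class TestConfigValidation:
    def test_zero_chromosome_length(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=0)

    def test_dispersion_ordering(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion_variable=200.0, dispersion_null=200.0)

    def test_coverage_floor(self):
        with pytest.raises(ValueError):
            SimulationConfig(coverage_mean=0.5)

    def test_profile_weights(self):
        with pytest.raises(ValueError):
            SimulationConfig(base_meth_profile=(0.7, 0.7))

    def test_sex_vector_length(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=3, sexes=("M", "F"))


class TestGenerateGenome:
    def test_zero_density_yields_no_fragments(self):
        cfg = SimulationConfig(seed=1, ccgg_density=0.0, n_chromosomes=1,
                               chrom_length=30_000)
        genome = generate_genome(cfg)
        for seq in genome.sequences.values():
            assert "CCGG" not in seq
        assert digest_genome(genome.sequences) == []

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_chromosomes=1, chrom_length=40_000)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_study(cfg).write(a)
        simulate_study(cfg).write(b)
        for name in ("genome.fa", "genes.gtf", "cgi.bed", "rr_fragments.bed",
                     "calls/S01.tsv", "truth.tsv", "gene_abundance.tsv",
                     "exon_counts.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_requested_density_approximately_met(self):
        cfg = SimulationConfig(seed=2, n_chromosomes=1, chrom_length=100_000,
                               ccgg_density=2.0)
        genome = generate_genome(cfg)
        seq = genome.sequences["chr1"]
        n_sites = seq.count("CCGG")
        # Poisson(200): 3 sigma is about 42
        assert 150 <= n_sites <= 250
        internal = digest_genome({"chr1": seq})
        assert len(internal) == n_sites - 1

    def test_gene_models_well_formed(self):
        genome = generate_genome(SimulationConfig(seed=3))
        assert genome.genes
        for g in genome.genes:
            assert len(g.exons) >= 2
            assert g.strand in "+-"
            assert g.interval.start <= g.tss < g.interval.end

    def test_cgis_are_cg_rich(self):
        genome = generate_genome(SimulationConfig(seed=4))
        for cgi in genome.cgis[:5]:
            s = genome.sequences[cgi.chrom][cgi.start:cgi.end]
            gc = (s.count("C") + s.count("G")) / len(s)
            assert gc > 0.6


class TestSimulateMethylome:
    def test_truth_table_invariants(self, study):
        t = study.truth.frame
        autosomal = t[t["chrom"] != "chrX"]
        expected = round(study.config.frac_variable * len(autosomal))
        assert int(t["is_variable"].sum()) == expected
        tm = study.truth.true_methylation
        vals = tm.drop(columns="fragment_id").to_numpy()
        assert ((vals >= 0) & (vals <= 100)).all()

    def test_individual_streams_stable_under_extension(self):
        """Adding individuals must not perturb existing individuals' data."""
        cfg5 = SimulationConfig(seed=9, n_individuals=5, n_chromosomes=1,
                                chrom_length=50_000)
        cfg8 = SimulationConfig(seed=9, n_individuals=8, n_chromosomes=1,
                                chrom_length=50_000)
        genome = generate_genome(cfg5)
        rr, _ = select_rr_fragments(digest_genome(genome.sequences))
        calls5, _ = simulate_methylome(genome, rr, cfg5)
        calls8, _ = simulate_methylome(genome, rr, cfg8)
        for ind in calls5:
            pd.testing.assert_frame_equal(calls5[ind], calls8[ind])

    def test_zero_cpg_fragment_skipped_with_warning(self, study):
        from methvar.intervals import Fragment, GenomicInterval

        bogus = Fragment(id="no_cpg", interval=GenomicInterval("chr1", 10, 20))
        with pytest.warns(UserWarning, match="no CpGs"):
            calls, truth = simulate_methylome(
                study.genome, [bogus] + study.rr_fragments[:3], study.config
            )
        assert "no_cpg" not in set(truth.frame["fragment_id"])

    def test_low_coverage_fails_qualification(self):
        cfg = SimulationConfig(seed=10, coverage_mean=2.0, n_chromosomes=1,
                               chrom_length=60_000)
        cohort = simulate_study(cfg).to_cohort()
        assert cohort.n_analysed <= 0.05 * cohort.n_fragments

    def test_sex_differential_fragments_on_x(self):
        sexes = ("M",) * 5 + ("F",) * 6
        cfg = SimulationConfig(seed=11, sexes=sexes, n_chromosomes=1,
                               chrom_length=80_000)
        study = simulate_study(cfg)
        assert "chrX" in study.genome.sequences
        t = study.truth.frame
        sd = t[t["is_sex_differential"]]
        assert len(sd) > 0 and (sd["chrom"] == "chrX").all()
        tm = study.truth.true_methylation.set_index("fragment_id")
        males = [f"S{i+1:02d}" for i in range(5)]
        females = [f"S{i+1:02d}" for i in range(5, 11)]
        diffs = tm.loc[sd["fragment_id"], females].mean(axis=1) - \
            tm.loc[sd["fragment_id"], males].mean(axis=1)
        assert (diffs > 20).all()


class TestCountTables:
    def test_near_null_limit_recall_matches_false_positive_rate(self):
        """When the two dispersion classes nearly coincide, planted
        fragments are statistically indistinguishable from the rest."""
        cfg = SimulationConfig(seed=12, frac_variable=0.5,
                               dispersion_variable=199.9,
                               dispersion_null=200.0)
        m, u, is_var = simulate_count_tables(cfg, 4000)
        mask = np.ones_like(m, dtype=bool)
        _, _, p = chi_square_homogeneity_batch(m, u, mask)
        alpha = 0.001
        recall = (p[is_var] <= alpha).mean()
        fpr = (p[~is_var] <= alpha).mean()
        assert abs(recall - fpr) < 0.01

    def test_separated_classes_are_recovered(self):
        cfg = SimulationConfig(seed=13)
        m, u, is_var = simulate_count_tables(cfg, 2000)
        mask = np.ones_like(m, dtype=bool)
        _, _, p = chi_square_homogeneity_batch(m, u, mask)
        cutoff = 0.001 / len(p)
        called = p <= cutoff
        assert called[is_var].mean() >= 0.9
        fdr = (called & ~is_var).sum() / max(called.sum(), 1)
        assert fdr <= 0.1

    def test_determinism(self):
        cfg = SimulationConfig(seed=14)
        a = simulate_count_tables(cfg, 500)
        b = simulate_count_tables(cfg, 500)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestSimulateExpression:
    def test_linked_exon_correlation_near_target(self, study):
        tm = study.truth.true_methylation.set_index("fragment_id")
        links = study.truth.frame.dropna(subset=["linked_exon"])
        assert len(links) > 0
        ec = study.exon_counts.set_index(["exon_id", "individual_id"])["read_count"]
        ms, cs = [], []
        for row in links.itertuples():
            for ind in study.config.individual_ids:
                ms.append(tm.loc[row.fragment_id, ind])
                cs.append(ec.loc[(row.linked_exon, ind)])
        r = np.corrcoef(ms, np.log2(np.asarray(cs) + 1))[0, 1]
        assert 0.5 <= r <= 0.85   # coupling target 0.7

    def test_decoupled_limit(self):
        cfg = SimulationConfig(seed=15, expression_coupling=0.0,
                               n_chromosomes=1, chrom_length=80_000)
        study = simulate_study(cfg)
        tm = study.truth.true_methylation.set_index("fragment_id")
        links = study.truth.frame.dropna(subset=["linked_exon"])
        ec = study.exon_counts.set_index(["exon_id", "individual_id"])["read_count"]
        ms, cs = [], []
        for row in links.itertuples():
            for ind in study.config.individual_ids:
                ms.append(tm.loc[row.fragment_id, ind])
                cs.append(ec.loc[(row.linked_exon, ind)])
        if len(ms) >= 20:
            r = np.corrcoef(ms, np.log2(np.asarray(cs) + 1))[0, 1]
            assert abs(r) < 3 / math.sqrt(len(ms))

    def test_pooled_r_tracks_coupling_target(self):
        """At coupling 0.9 with ~500 linked (exon, individual) pairs the
        recovered pooled Pearson r sits in the sampling band around 0.9."""
        cfg = SimulationConfig(seed=16, expression_coupling=0.9,
                               n_chromosomes=3, chrom_length=500_000)
        study = simulate_study(cfg)
        tm = study.truth.true_methylation.set_index("fragment_id")
        links = study.truth.frame.dropna(subset=["linked_exon"])
        ec = study.exon_counts.set_index(["exon_id", "individual_id"])["read_count"]
        ms, cs = [], []
        for row in links.itertuples():
            for ind in study.config.individual_ids:
                ms.append(tm.loc[row.fragment_id, ind])
                cs.append(ec.loc[(row.linked_exon, ind)])
        assert len(ms) >= 300
        r = np.corrcoef(ms, np.log2(np.asarray(cs) + 1))[0, 1]
        assert 0.8 <= r <= 0.95

    def test_differential_flags_mark_linked_exons(self, study):
        linked = set(study.truth.frame["linked_exon"].dropna())
        flagged = set(
            study.exon_counts.loc[study.exon_counts["is_differential"], "exon_id"]
        )
        assert linked == flagged
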