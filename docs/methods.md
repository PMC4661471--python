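# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical conventions, and the design decisions behind `methvar`.

## The variability model

The unit of analysis is the internal MspI fragment: a span between two
successive C^CGG cut sites, both ends cut, within the 40–220 bp
size-selection window ("RR genome"). Working at fragment rather than CpG
resolution pools the sparse per-CpG read counts of RRBS into one
(methylated, unmethylated) observation pair per individual, at the cost of
assuming CpGs within a fragment share a methylation state.

**Qualification.** A fragment qualifies in an individual when at least
`min_cpgs = 2` of its CpGs each carry `min_reads = 10` or more reads. The
threshold is applied per CpG; an alternative fragment-total reading is
available behind `qualify_fragment(mode="fragment_total")` for sensitivity
analysis, because the per-CpG and per-fragment interpretations of a
"10 reads at ≥ 2 CpGs" filter genuinely differ on uneven coverage. The
cohort's analysed set is the fragments qualifying in `min_individuals = 9`
of the cohort (11 by default).

**Test.** Per analysed fragment, the k×2 contingency table of per-individual
(m, u) counts is tested with the Pearson chi-square, df = k − 1, expected
counts from the pooled proportion. Individuals with zero observations are
excluded (reducing k); a fragment left with fewer than two testable
individuals returns a NaN sentinel; a table whose pooled methylated or
unmethylated column is zero carries no information about proportion
differences and returns (X² = 0, p = 1) rather than an error. No continuity
correction is applied in the k×2 test — Yates is reserved for the 2×2
enrichment tables. The test treats every CpG read observation as
independent; correlation between neighbouring CpGs within a fragment will
overstate significance, which is the motivation for the stringent α below.
No correction for that correlation is implemented.

**Calling.** iVMF ⇔ p ≤ α/M with α = 0.001 and M the number of analysed
fragments in the current run (never a hard-coded constant). The boundary is
inclusive. Allosomal fragments (default `chrX`, `chrY`) are excluded from
the autosomal subset used for annotation summaries, since X inactivation in
mixed-sex cohorts produces expected, sex-driven variability.

**Diagnostics.** Per fragment: mean and sample (n−1) SD of per-individual
methylation percentages; the binomial-scaled coefficient of variation
SD/√(mean·(100−mean)/k), which removes the mean-dependence a raw SD or CV
has on bounded percentages; and ln(mean/(100−mean)). All logarithms are
natural; values undefined at mean 0 or 100 (or log of 0) are NaN
sentinels, not errors.

**Group comparison.** The male/female path tests fragments qualified in
*all* cohort members with one-way ANOVA, Bonferroni-corrected at 0.05 over
that family, and separately flags fragments with ≥ 20 percentage-point
group mean difference irrespective of p. Replicate agreement uses
Bland–Altman limits: bias ± 1.96·SD of paired differences.

## Annotation conventions

Coordinates are 0-based half-open throughout; 1-based dialects (call files,
GTF) are converted at the readers. CpGs are indexed by the forward-strand C
of the dyad; strand-split caller output is collapsed by position summing in
the reader.

Gene context is a partition over nine categories. A fragment overlapping a
protein-coding gene is `tss_overlap` when it covers the TSS, otherwise
classified by exon-overlap pattern: wholly inside an exon → `exon`, wholly
inside an intron → `intron`, spanning a junction → `exon_intron_boundary`
or `intron_exon_boundary` in transcription order (strand-aware). A
non-genic fragment is assigned to the nearest gene having the fragment on
its upstream side, by TSS-to-nearest-edge distance, binned 0–2 kb and
2–5 kb (promoter), 5–10 kb (upstream), > 10 kb (distant). A fragment with
no upstream-side gene on its chromosome (i.e. downstream of every gene) is
classified `distant_gt10kb`; this closes the partition while honouring the
invariant that promoter bins contain only upstream fragments. Equidistant
ties break lexicographically by gene id, with a logged warning.

CGI context is judged at the fragment midpoint (avoids double-counting at
band edges): core inside a merged CGI, shore within 2 kb of an edge, shelf
within the next 2 kb, nearest CGI winning.

Variability scores are n_iVMF/n_analysed per gene or feature class. VMGs
require ≥ 3 iVMFs and VS ≥ 0.5; units with < 3 iVMFs are not considered
regardless of score. Gene-level scoring imposes no upstream distance limit;
region-class scoring uses the ≤ 5 kb promoter definition.

Enrichment uses the ≥ 50 % fragment-overlap ("strong overlap") rule against
merged feature tracks and a Yates-corrected 2×2 chi-square
N(|ad−bc|−N/2)²/(r₁r₂c₁c₂), clamped to 0 when the correction exceeds
|ad−bc| and returning (0, 1) on any zero margin. Enrichment p-values are
reported unadjusted at α = 0.05 (the CLI notes the multiplicity caveat).
Chromosome-wise distribution tests each chromosome against the rest
(iVMF vs RR-genome counts), flagging p < 10⁻⁴ — the simplest construction
consistent with per-chromosome significance calls. Gene-list overlap is the
upper-tail hypergeometric; the universe defaults to the protein-coding gene
count of the supplied annotation and is overridable, since no canonical
universe exists.

Expression integration bins fragment methylation as [0, 30], (30, 70],
(70, 100] (boundary values fall into the lower bin), compares
ln(abundance + 0.1) across bins with ANOVA plus Tukey HSD, and correlates
exon methylation with log2(read count + 1). Pooled exon correlations weight
every (exon, individual) pair equally. Differential-exon flags are inputs
from an external differential-usage model; the built-in
coefficient-of-variation flagger is a labelled non-canonical fallback for
demo pipelines only.

## The synthetic-data generator

The generator emulates the structure of an RRBS cohort study: ~11
individuals, bimodal fragment methylation, beta-binomial read sampling,
a planted variable subset, optional X-linked sex-differential fragments,
and expression coupled to exon methylation.

*Genome.* Chromosomes (default 2 × 150 kb) carry genes every 12 kb (6 kb
long, 3 exons of 400 bp, alternating strands) with CG-rich 1 kb islands at
every other promoter. The background sequence is scrubbed of incidental
CCGG and sites are planted at the requested density (default 2/kb), so
density 0 yields a genome with no MspI site.

*Methylation.* Each RR fragment gets a true mean: planted variable
fragments (default 10 %, half of them placed on exons so the
exon-inclusion analyses have linked fragments) draw Uniform(0.25, 0.75) —
intermediate methylation, where inter-individual variation is observable;
stable fragments take the low (~3 %) or high (~88 %) mode, with CGI-,
TSS- and exon-associated fragments always low (as in real
CpG-island-enriched methylomes) and the residual low-mode mass spread over
the rest so the overall mix matches `base_meth_profile` (default
0.6/0.4). Individual i's fragment methylation is
Beta(μc, (1−μ)c): c = 200 for stable fragments (SD ≈ 3.5 points at
mid-range means — realistic biological noise) and c = 4 for variable ones
(SD ≈ 19–22 points at the planted means, comfortably above the ≥ 15-point
separation the recovery analyses assume). Setting c = ∞ collapses the Beta
to a point mass, giving exact binomial counts — the configuration used for
type-I calibration. Per-CpG coverage is negative binomial
(mean 20, shape 5; over-dispersed, as in real RRBS, so the qualification
filter is exercised non-trivially). With a configured sex vector, a pseudo-X
chromosome is added whose sex-differential fragments are ~5 % methylated in
males and ~60 % in females.

*Expression.* Linked exons' log2 counts follow one global linear map of the
fragment's true methylation plus Gaussian noise whose variance is
calibrated from the pooled methylation spread, so the correlation pooled
over all (linked exon, individual) pairs lands at `expression_coupling`
(default 0.7) by construction; each exon tracks at most one fragment.
Unlinked exons are independent noise with random baselines. Genes whose
promoter-proximal fragment is variable receive abundance inversely coupled
to its methylation.

*Randomness.* One seed governs everything; per-individual streams are
spawned from it, so extending the cohort never changes existing
individuals' data. `simulate_count_tables` draws the same generative model
directly at the count level (no genome) for calibration and power studies
at large fragment counts.

**What the generator does not emulate.** Read-level artefacts (no FASTQ,
no alignment or bisulfite-conversion error), allele-specific methylation,
SNPs, spatial correlation of methylation along a fragment beyond the shared
fragment-level p, realistic gene/CGI geometry, and any empirically
calibrated effect-size distribution for real variable fragments — none is
published, so defaults are chosen for testability. Passing tests therefore
demonstrate correctness of the pipeline's statistics and plumbing under a
known generative model, not sensitivity or specificity on real cohorts.

## Problem sizes and numerical choices

The test suite runs the pipeline end to end on ~160-fragment genomes and
the statistical checks on 2,000–10,000 direct-count fragments; the
acceptance script uses 10,000 null fragments for calibration, 5,000 (10 %
planted) for recovery, 100 random chromosomes for the digestion oracle and
20 seeded cohort simulations for the local exon effect. These sizes give
Monte-Carlo error comfortably inside the asserted bounds while keeping a
full run in the tens of seconds.

Ties, degenerate inputs and sentinels are handled as described above rather
than raising, except where an input is structurally invalid (negative
counts, inverted intervals, inconsistent list sizes), which raises
`ValueError`. The chi-square and Yates statistics are validated against
scipy's generic contingency implementation to 10⁻⁹ relative error; they are
implemented directly (vectorised across fragments) because the per-fragment
batch path is the package's hot loop.

## Known limitations

- The homogeneity test inherits the chi-square approximation; at very low
  coverage or extreme means its tail is only approximate (the calibration
  suite bounds the error at the sizes used).
- Neighbouring-CpG correlation within fragments is not modelled or
  corrected; the stringent α = 0.001 is a blunt instrument against it.
- Nearest-gene assignment uses a single TSS per gene (no isoform-aware
  promoters).
- Enrichment p-values are unadjusted, matching the per-feature reporting
  convention; treat multi-track scans accordingly.
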