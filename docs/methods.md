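# Methods

This note records the models, defaults and design choices behind `txsnp`,
and what the synthetic-data tests do and do not demonstrate.

## Dual-evidence SNP calling

Variants are called per site from pileups of duplicate-free alignments to
the transcriptome. A base is *high quality* (HQ) at PHRED ≥ 20
(`hq_threshold`, configurable; echoed in summaries). The threshold is a
judgement call — "high quality" has no universal definition — and Q20
(1% error) is the customary floor for counting variant support.

Filters per evidence source:

| source | min depth | max depth | min HQ alt bases |
|--------|-----------|-----------|------------------|
| T2T (transcriptome reads) | 8× | 200× | 2 |
| G2T (genomic reads) | 20× | 200× | 3 |

The depth window is interpreted **per site**, not as a transcript-mean:
per-site is the stricter and more standard reading, and it is what the
implementation's depth arrays naturally provide. (`PileupColumn` carries
all the information needed to apply a mean-based variant if a user wants
one.) The 200× ceiling suppresses collapsed repeats and spurious local
alignments; the alt-count floors force higher MAFs where coverage is low.
Only biallelic substitutions are considered: the alternative allele is the
modal non-reference HQ base with alphabetical tie-break, and indels are
ignored — the genotyping assays this pipeline feeds score substitutions
only. A putative SNP must appear in **both** sources with identical
(transcript, position, ref, alt).

Duplicate removal groups alignments by (transcript, start, reference
span, mate, orientation) and keeps the highest-mapq member, emulating
standard rmdup behaviour on single-end-coordinate evidence.

## Intron–exon boundary (IEB) prediction

A genomic read crossing an exon junction cannot align through its whole
length against the spliced transcript; the alignment is soft-clipped at
the junction. Per transcript position we count *change points*: alignment
starts with a leading clip ≥ `min_clip` and ends with a trailing clip ≥
`min_clip` (both pooled into one count — a junction produces starts on one
side and ends on the other). The null model is a per-position binomial:
with n reads covering the position and pooled background clipping rate p₀
(change points per read-touch event over all interior positions), the
p-value is P[X ≥ k], X ~ Bin(n, p₀). Positions pass at Bonferroni-corrected
p ≤ α within each transcript, and surviving positions within
`merge_window` collapse to the one with most change points (ties:
leftmost).

Defaults and why:

- `min_clip = 5` bp — shorter clips are adapter/quality trimming noise;
- `end_margin = read length` — alignments flush with a transcript end are
  expected to clip (the read simply runs off the reference) and are never
  counted, nor are end-margin positions used for p₀ or testing;
- `α = 0.01` per transcript after Bonferroni; `merge_window = 5` bp
  (a junction's starts and ends sit on adjacent positions).

The binomial upper tail is this package's own definition of "surprisingly
many change points"; it is deliberately simple and is validated against an
exact-summation oracle and on simulations with planted junctions.

## Assay design and panel QC

One SNP per contig. A candidate is rejected if its contig received any
multimapped read, if its ±`flank_len` (default 60 bp) flanks do not fit
inside the transcript, or if a predicted IEB falls within the flanks.
Secondary putative SNPs inside flanks are masked to N. Ranking —
(distance to nearest IEB, descending; supporting depth, descending;
|MAF − 0.5|, ascending; position) — is a deterministic convention of this
package; the flank length of 60 bp matches typical SNP-type assay
requirements.

Panel QC classifies loci in a fixed order (no_signal → disperse at call
rate < 0.80 → monomorphic at MAF < 0.01 among called individuals → psv
when every called individual is heterozygous → polymorphic). The
**conversion rate** excludes only technical failures,
100·(n − no_signal − disperse)/n; the **validation rate** counts only truly
polymorphic loci, 100·polymorphic/n. The two definitions coincide on a
panel with no monomorphic/psv loci but differ in general; both are always
reported. MAF is computed over called individuals only.

## Population genetics

- **Diversity**: H_o is the heterozygote fraction; H_e is the unbiased
  estimator (2n/(2n−1))·2p(1−p).
- **Exact HWE**: full enumeration of the heterozygote count conditional on
  allele counts (the Levene distribution); the two-sided p-value sums the
  probabilities of all outcomes no more likely than the observed one.
  Enumeration is exact and cheap for biallelic loci at panel scale
  (n = 140), so no Markov-chain approximation is used.
- **F_ST**: Weir–Cockerham (1984) θ as the ratio of summed variance
  components a/(a+b+c) across loci, overall and for each pair of groups.
  Missing genotypes are excluded pairwise per locus; loci monomorphic
  within a comparison contribute zero components. **F_IS** within a group
  is 1 − Σc/Σ(b+c) from the single-population components. Significance by
  permutation (default 1,000): group labels are permuted for θ (one-sided,
  θ_perm ≥ θ_obs); alleles are re-dealt among a group's individuals for
  F_IS (two-sided on |f|); p = (1 + hits)/(1 + permutations). Sequential
  Bonferroni (Holm) is applied across the pairwise tests. Other estimators
  (e.g. distance-based pairwise F_ST) will differ from θ in the third
  decimal; comparisons to numbers produced with other software should
  allow for that.
- **Outlier scan**: per-locus θ compared to a pooled null distribution.
  The default null is *drift-calibrated*: every locus is resimulated under
  the Balding–Nichols model at the estimated genome-wide θ, keeping its
  pooled allele frequency and per-group called sample sizes, so that an
  outlier means "more differentiated than genome-wide drift explains" —
  the semantics of a selection scan. A label-permutation null (appropriate
  only when genome-wide θ ≈ 0, since it destroys all baseline
  differentiation) is available as `null_model="permutation"`.
  Benjamini–Hochberg q-values; outliers at q < 0.1. This scan is a
  frequentist stand-in for Bayesian selection scans: it targets the same
  neutral/outlier partition, not a posterior.
- **Admixture**: EM on the no-LD admixture likelihood — each of an
  individual's two allele copies at a locus comes from cluster k with
  probability Q[i,k] and is the reference allele with probability P[k,l].
  The EM log-likelihood is non-decreasing (asserted in tests); K = 1 is
  closed-form. This is a maximum-likelihood stand-in for MCMC clustering:
  ancestry estimates are comparable, but the maximized log-likelihood is
  *not* the posterior-predictive LnP(D) such programs report. Consequence:
  the plateau (Pritchard-style) rule, which expects a quantity that
  saturates, tends to report the largest K tried, while Evanno's ΔK —
  mean over paired runs of |L(K+1) − 2L(K) + L(K−1)| divided by the
  across-run sd of L(K) — remains informative and is the primary
  criterion. Published K choices made with MCMC log-probabilities are not
  expected to reproduce numerically.

## Genome-size decomposition

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; k-mers containing N skipped), default k = 25. The estimator is
peak-based: multiplicities ≤ `noise_cutoff` (default 3) are treated as
sequencing-error k-mers; the coverage peak is the modal remaining
multiplicity; haploid length = (k-mer instances above cutoff)/peak; unique
length applies the same ratio to multiplicities in [peak/2, 2·peak]. This
is a documented simplification — no mixture model is fitted and no
heterozygosity rate is estimated — but the *reporting arithmetic*
(unique fraction = 100·unique/haploid) is exact.

## The simulator

`txsnp.simulate` generates: a genome of `n_genes` multi-exon genes
(uppercase exons, lowercase introns, random intergenic spacers); spliced
transcripts that are exactly the exon concatenations (so truth junctions
are known); planted biallelic SNPs at `snp_rate` per transcript bp with
Balding–Nichols per-population frequencies around a uniform ancestral
frequency; paired DNA reads from the genome and RNA reads from the
transcripts; and two-population genotype panels. Every planted SNP
segregates at dosage 0.5 in the sequenced pool. Alignments are produced
from the known layout (a local-alignment emulation: a genomic read aligns
by its longest single-exon run, remainder soft-clipped, minimum 20 aligned
bases), so the pipeline's input is controlled exactly.

Default conditions mirror the scale of the validation study: two
populations of 70 individuals, 92 loci, target F_ST 0.05; 50×/50× dual
sequencing with 101-bp-class reads (100 bp), 0.5% uniform substitution
error, constant Q30 qualities. Sizes used in tests and the acceptance
script (20 three-exon genes, ≈ 13 kb of transcriptome) are chosen so a
full pipeline run takes seconds; recovery metrics were checked to be
stable across seeds at this size.

What the simulator does **not** model: indel errors, quality-score
variation, coverage bias (GC, mappability), paralogy/multimapping, allele
dosage other than 0.5, linkage disequilibrium, and genotyping-intensity
noise. Passing tests therefore demonstrate the *logic* of the filters and
estimators under clean assumptions, not robustness to every artefact of
real libraries.

A single seed governs each generator function with a documented draw
order (genome → SNP planting → DNA reads → RNA reads; genotype panels use
an offset stream), so outputs are byte-reproducible.

## Numerical conventions

Coordinates are 1-based fully-closed on transcripts everywhere (SAM/VCF
convention); BED export converts to 0-based half-open. Genotypes are
two-character allele strings, missing `--`; Genepop export codes
A,C,G,T → 01..04. Ties break deterministically and are documented at each
site (alphabetical alt allele; leftmost merged IEB; frame order then
leftmost ORF). Degenerate inputs raise informative errors rather than
returning silent defaults (empty references, zero coverage, groups with
fewer than two individuals, K exceeding the number of individuals).

## Known limitations

- The coding filter is ORF-length-only (≥ 100 aa); no homology evidence.
- The expression fallback counter is zero/nonzero-accurate only; it is not
  an EM abundance estimator.
- The caller emits at most one alternative allele per site; triallelic
  sites lose their minor alternative.
- IEB detection requires genomic coverage; junctions in low-coverage
  transcripts are undetectable, and assays near them cannot be warned
  about.
- F_IS permutation p-values are two-sided on |f|; software testing only
  heterozygote deficit will report roughly half the p-value.
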