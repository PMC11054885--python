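# Methods

This note documents the models, procedures and numerical choices behind
`miredit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic data does and does not emulate.

## Problem setting

miRNA editing — predominantly A-to-I (read as A-to-G) and C-to-U
deamination — appears in small RNA-seq as a systematic mismatch between
reads and the pre-miRNA (hairpin) reference. Edits inside the seed region
(mature positions 2–8 from the 5′ end) can redirect a miRNA to a different
target-gene repertoire, which is why the pipeline ends in wild-type (WT)
versus edited-type (ET) target comparison and pathway enrichment. The
package reproduces this analysis chain on data with known planted truth:
a 4-stage × 3-replicate developmental design (stage labels
N30D/N90D/N150D/N210D, replicates F1–F3, as in porcine subcutaneous
adipose development).

## Read filtering and alignment

Reads are kept when ≥ 95 % of bases have phred ≥ 30, the 3′ adapter (if
configured) has been removed by an exact-prefix match of ≥ 8 nt, and the
trimmed length is 15–28 nt. Alignment to the hairpins is ungapped,
sense-strand and unique: the last 2 nt of each read are excluded from the
aligned span (they absorb non-templated 3′ A/U additions), at most one
mismatch is allowed over the span, and a read is dropped when its best
mismatch stratum holds zero or more than one location. "One mismatch" is
total Hamming distance, not a quality-weighted budget: aligner-specific
budget arithmetic is not part of the contract being implemented. The
aligner indexes all reference 6-mers and seeds each read with its first
two non-overlapping 6-mers; with ≤ 1 mismatch on a ≥ 12-nt span at least
one seed is exact (pigeonhole), so seeding loses nothing at this budget.
Correctness is property-tested against an exhaustive all-positions
Hamming scan.

## Site calling

Per sample, quality-passing bases (phred ≥ 30) are piled up per hairpin
position. For each position and alternative base, the edited count k out
of coverage n is tested against a binomial null with per-substitution
error probability p_err = 10^(−Q/10)/3 at Q = 30 (≈ 3.33 × 10⁻⁴): the
probability that a base survives the quality filter yet is a specific
miscall. One-sided tails P(X ≥ k) are Bonferroni-corrected with family
size T = 3 × (number of positions at pooled coverage ≥ 10). A site is
called when (1) its corrected p ≤ 0.05 in ≥ 3 samples ("individuals",
counted dataset-wide by default; per-stage counting is available),
(2) exactly one alternative base is supported (a second per-sample- or
pooled-significant alt voids the position), (3) pooled coverage is ≥ 10
(per-sample mode available), and (4) the position is not a known SNP
(VCF or BED input). The editing level is k/n per sample; stage levels
average the replicates with coverage > 0. Genomic coordinates are
attached only when a hairpin→genome liftover table is supplied; the
internal frame is always hairpin-1-based. Editing types are written on
the sense mature strand with U for T (A-to-G, C-to-U, U-to-C, G-to-U).

## Characterization

*Flank preferences.* For each editing type, the ±5 nt context of called
sites is compared to a background of tested-but-uncalled positions with
the same reference base, one Fisher exact test per (offset, base) with
Bonferroni correction over the 40 tests. Fisher's exact test is used
because the edited set is small (tens of sites); sites with fewer than
10 real flank bases (hairpin boundary) are skipped. The procedure is
symmetric: swapping the two sets swaps enriched/depleted labels and
leaves p-values unchanged.

*Trajectory clustering.* Stage-mean levels are z-standardized per site
and soft-clustered with fuzzy c-means (c = 4 clusters by default,
fuzzifier m = 1.25, random Dirichlet initialization from a fixed seed,
stop when the objective changes by < 10⁻⁹ or after 300 iterations).
m = 1.25 is a fixed, reproducible default in the range typical for
short, well-separated trajectories; dataset-adaptive fuzzifier estimates
exist but make runs depend on the site count, so they are left to the
caller. Zero-variance trajectories cannot be standardized and are
dropped with a warning. Hard labels are argmax memberships.

*Conservation.* The ≤ 51-nt flank (site ± 25 nt, truncated at hairpin
boundaries) of each site is locally aligned (match +1, mismatch −2,
linear gap −2) against a database of editing-site flanks from another
species. A site is conserved when its best hit has e-value < 0.001 and
identity > 85 % — both strict, so a hit at exactly 85.0 % is not
conserved. Identity is computed over the aligned span (the full 51-mer
alternative penalizes boundary-truncated flanks). E-values use ungapped
Karlin–Altschul statistics for the +1/−2 scheme (λ solved numerically,
≈ 1.28 for uniform base composition; K = 0.621 from the standard
nucleotide table) on a search space of query length × total database
length. This is a threshold-level stand-in for a full BLASTN search: the
conserved/not decision is driven by the thresholds, not by score
precision, and bit-score-exact reproduction is out of scope.

## Differential editing

Edited counts are over-dispersed relative to a binomial because
replicate animals differ biologically. Counts are modeled per site as
beta-binomial with mean μ and intra-class dispersion ρ
(α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ); ρ → 0 recovers the binomial. For a
stage pair, the null fits a common μ jointly with ρ (L-BFGS-B on
logit-transformed parameters, three dispersion starts, Nelder-Mead
polish); the alternative then fits one μ per stage at that fixed ρ, and
2·(llf_alt − llf_null) is referred to χ²(1).

Why ρ is estimated under the null and then shared: the two candidate
schemes were measured on null simulations (3 vs 3 samples, totals
10–200, μ = 0.2, ρ = 0.05, 2000 sites). Estimating ρ under the
alternative lets the group difference leak into a smaller dispersion and
deflate the null likelihood — empirical type-I error 0.20 at nominal
0.05. Free (α, β) per group with df = 2 measured 0.21. The null-ρ
scheme measures 0.051–0.060 across seeds: at, or within ~1 Monte-Carlo
standard error above, the nominal level, which is the behavior the
calibration suite asserts. The cost is mild conservatism under strong
alternatives (ρ̂ absorbs part of the group difference), which the power
tests show is immaterial at the effect sizes of interest.

Degenerate inputs: when every group's observed proportions are constant
the dispersion carries no information, and a free ρ would absorb the
between-group difference being tested; the fit then uses the
parsimonious binomial limit ρ = 0 (so complete separation such as
0/30 ×3 vs 30/30 ×3 is decisively significant). Means are clamped to
(10⁻⁶, 1 − 10⁻⁶) for likelihood evaluation at the k = 0 / k = n
boundaries. Fits that still fail both optimizers report a missing
p-value rather than a number.

All C(S, 2) unordered stage pairs are tested per site (6 pairs for 4
stages). Significance for site selection is raw p < 0.05 — matching the
selection rule this pipeline mirrors — with Benjamini-Hochberg q-values
reported per pair for transparency but not used to select. The
seed-region selection keeps sites significant in ≥ 1 pair, drops sex
chromosomes (X/Y) when chromosome labels exist, keeps seed-region sites,
and tabulates per-site significant-pair counts (the upset-plot logic).

## Retargeting and enrichment

`apply_edit` substitutes the edited base (A-to-G edits substitute G,
since inosine pairs like G) and tags the variant `<miRNA>_<position>`.
The default target scan is seed-based: a gene is a target when any of
its 3′UTRs contains a canonical site — 6mer (perfect complement of
positions 2–7), 7mer-m8 (adds position 8), 7mer-A1 (adds an A opposite
position 1), or 8mer (both). Note the geometry: an edit at position 8
changes only the m8-anchored classes and leaves the 6mer intact, so a
position-8 edit does not change the gene-level seed target set; edits at
positions 2–7 rewrite all classes. The alternative "score" mode scans
with a Smith-Waterman complementarity alignment of the full miRNA
(match +5, G:U wobble +1, mismatch −3, gap −9, positions 2–8 weighted
×4) and reports hits at score ≥ 140 with an energy proxy ≤ −10, where
the proxy is a stacking sum of −2 per Watson-Crick and −1 per wobble
pair. Seed mode is the default because it has exact, reproducible
semantics; score mode exposes the published thresholds over a documented
scoring scheme rather than imitating any particular binary. U/T are
normalized to one alphabet before matching.

Gain/loss is set algebra on gene sets computed against the same UTR
universe: lost = WT∖ET, gained = ET∖WT. Enrichment is the one-sided
hypergeometric tail P(X ≥ k) per pathway with BH correction; the
universe defaults to the genes whose UTRs were scanned (targets can only
come from there), not the union of pathway members. WT-vs-ET pathway
comparison is the same set algebra on the enriched pathway sets.

## Synthetic data

The generator emulates the study design, not the organism: 12 samples
(4 stages × 3 replicates), hairpins of 70–110 nt with one annotated
mature arm of 20–24 nt, i.i.d. uniform bases with the constraint that no
mature 13-mer recurs elsewhere in the reference (so unique mapping is
achievable by construction). Editing is an independent Bernoulli draw
per read at the site's stage-specific level — exactly the binomial
sampling model the caller assumes. Per-base sequencing errors occur at
10⁻³ with qualities drawn from a profile placing 10 % of mass below
Q30 (so quality filters have work to do); correct bases draw from the
Q ≥ 30 part of the profile, which keeps pileup-level editing levels
unbiased. A configurable fraction of reads (10 % by default) gains a
1–2 nt non-templated A/U tail, which the 3′ trim neutralizes. SNP decoys
are planted at a stage-constant level of 0.5 (heterozygote-like) and
listed in the generated VCF. Default depth is 300 reads per mature arm
(~9 × 10³ reads per sample across 30 hairpins): per-arm coverage is far
above every caller threshold while keeping a full pipeline run in
seconds. Downstream fixtures carry designed truth: UTRs with planted
8mer complements of a focal seed edit's WT and ET seeds (the focal edit
is chosen at positions 2–7, where the edit rewrites every match class),
one pathway stacked with ET-only genes (a designed gain) and one with
WT-only genes (a designed loss), and a conservation database of ~6 %
diverged copies of each real site's flanks plus random decoys.

What the simulation does **not** emulate: RNA secondary structure and
Drosha/Dicer processing heterogeneity, 5′ isomiRs, genome-scale
multimapping, ADAR/APOBEC sequence context, and realistic UTR base
composition. Passing tests therefore demonstrate that the statistics and
bookkeeping are correct under the stated sampling model — not that the
pipeline's sensitivity/specificity transfer to any real library.

## Problem sizes and determinism

Test-suite and acceptance runs use scaled-down instances chosen for
desk-scale reproduction: 6–15 hairpins and 80–200 reads per arm for
caller calibration and end-to-end runs, 2000 sites for differential
calibration, 20 replicates for the family-wise false-call check. Every
random draw flows from a single integer seed (simulator, clustering
initialization, calibration harness), and a fixed seed reproduces every
output byte-for-byte.

## Known limitations

- The LRT's small-sample type-I error sits ~0.2–1 percentage point above
  nominal in the worst seeds (χ² asymptotics at n = 6); the calibration
  suite bounds it within Monte-Carlo error of 5 %.
- The caller's Bonferroni family is recomputed per run, so adding
  samples changes T and thus per-site corrected p-values.
- The e-value model is ungapped while the alignment permits gaps; for
  the near-identical-flank decisions it gates, this inconsistency is
  immaterial, but absolute e-values should not be compared to BLASTN's.
- Score-mode target scanning is O(|miRNA| × |UTR|) per gene in pure
  Python; it is meant for worked examples, not transcriptome sweeps.
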