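# Methods

## Cohort model and data contracts

The analysis consumes four artifacts: per-sample fusion-call tables in
a deFuse-style TSV dialect (the column mapping is configuration — the
default targets deFuse 0.6.1-like headers — because caller versions
rename columns); a sample manifest carrying condition (tumor/benign),
pairing and library size (fusion-call tables do not carry total mapped
reads, which breakpoint RPKM needs); an Ensembl-dialect GTF with
gene/transcript/exon/CDS features and `gene_biotype` attributes; and
gene-/exon-level expression matrices (FPKM or counts). All coordinates
are 1-based inclusive (GTF convention) throughout the package; no
0-based conversion layer exists, because every junction computation is
coordinate equality or ordering, and a single convention removes a
class of off-by-one errors. Chromosome names are normalised by
stripping any `chr` prefix by default. Gene-pair identity is the
ordered (5′, 3′) pair; reciprocal orientations are distinct events.

Per-sample parsing never silently drops rows: every input row is
either accepted as a validated call (nonnegative read counts,
multimapping ≤ total spanning reads, probability in [0,1]) or rejected
with a row-number diagnostic.

## Filter cascade

Stage order and defaults (all configurable via `FilterThresholds`):

| stage | rule | default |
|---|---|---|
| call screen | discordant pairs ≥ t, split reads ≥ t, probability ≥ t | 5, 1, 0.05 (inclusive) |
| recurrence | tumor-positive samples ≥ t | 5 (inclusive) |
| enrichment | one-sided Fisher exact p < α on the paired 2×2 table | α = 0.05 |
| overexpression | paired signed-rank p < α, only if benign-positive > t | t = 2 |
| homology | pooled multimap/total spanning ratio; removed if strictly > t | 0.6 |
| annotation | biotypes ⊆ {protein_coding, lincRNA, miRNA}; overlapping spans dropped | — |

Design choices that were genuinely open:

* **Fisher sidedness.** One-sided, greater positivity in tumors. This
  is the variant that reproduces the reference table's printed values
  (17 of 21 rows exactly at 2 significant figures); two-sided
  reproduces none of them.
* **Multimap boundary.** At exactly 0.6 the "less than 0.6 passes" and
  "greater than 0.6 removed" phrasings conflict; removal is strictly
  > 0.6 here, covered by a dedicated boundary test and a config knob.
* **Pooled vs per-sample multimap ratio.** The ratio is computed from
  support summed over positive samples — the stabler estimator when
  single samples have few spanning reads.
* **Enrichment margins.** The 2×2 table is restricted to the paired
  cohort (44 vs 44); unpaired validation tumors contribute to
  recurrence counting and association analyses but not to the paired
  enrichment or signed-rank tests.
* **Conditional gating.** The overexpression test runs only for pairs
  detected in more than two benign samples: tumor-exclusive fusions
  need no expression contrast to be tumor-associated.
* **No multiple-testing correction** is applied in the cascade; a
  Benjamini–Hochberg q column is emitted in the report for
  transparency but never used for filtering.
* **Support aggregation.** A sample's support for a pair comes from
  its call with the most split reads; aggregation is idempotent.

Breakpoint expression is RPKM over a junction *region*, the window in
which a read can align across the breakpoint. The region length is
2 × read length (default read length 100 bp → 200 bp region); this is a
scale choice only — it never changes test ranks, because the paired
test compares matched samples under the same region length.

### Statistical primitives

The Fisher tail is computed in exact rational arithmetic
(`fractions.Fraction` over binomial coefficients) and converted to
float only at the end; display rounding (2 significant figures,
scientific notation) happens exclusively at the report layer. The
paired signed-rank test drops zero differences (classic Wilcoxon
rather than Pratt), uses midranks for ties, and evaluates the null
exactly by dynamic programming over doubled ranks when ≤25 nonzero
pairs remain; beyond that a tie-corrected normal approximation with
continuity correction is used. scipy's exact mode rejects ties, which
is why the exact null is implemented here; both routes are
cross-checked in tests against full 2ⁿ sign enumeration and against
scipy's approximation. The unpaired contrast is scipy's Mann–Whitney
U (one-sided, tie-corrected, no continuity correction, so identical
groups give p = 0.5). Spearman correlations use scipy, except that for
≤7 tie-free observations the one-sided p is replaced by the exact n!
permutation tail.

**Known conservatism.** On discrete 44 vs 44 tables the exact Fisher
test's Type-I error at α = 0.05 is well below nominal: 0.0089 at
detection rate 0.05, at most ≈0.035 even at rate 0.5 (computed by
summing binomial-weighted rejection probabilities). A calibration
check that expects the null rejection rate to sit in a symmetric band
around α will therefore read low. This is the usual conservatism of
exact tests on discrete data — protective for nomination (the cascade
over-filters rather than under-filters at this stage) — and is left
as-is rather than "fixed" with mid-p values, which would change the
published-value reproduction.

### Reference-table reproduction

The packaged table `data/published_cohort_counts.tsv` carries the
published detection counts and printed enrichment p-values for 21
recurrent fusion transcripts in a 44-pair prostate cohort. Seventeen
rows are reproduced exactly by the one-sided Fisher p at 2 significant
figures. Four are not, under any standard one- or two-sided variant of
the test applied to the printed counts:

| row | printed | computed (one-sided) |
|---|---|---|
| TMPRSS2-ERG | 1.6E-06 | 1.6E-07 (a factor-10 difference; likely a typo) |
| FAM83H-RP11_429J17.6 | 1.4E-04 | 7.2E-06 |
| TMEM219-TAOK2 | 2.5E-02 | 1.3E-02 (printed value equals the two-sided p) |
| ZNF551-ZNF776 | 7.4E-03 | 7.5E-03 (exact tail 0.0074605; rounding inconsistency) |

These rows are flagged `reproducible = N` in the packaged table and
excluded from exact-match assertions.

## Junction annotation

Partner geometry: inner distance is the gap between gene spans (0 when
abutting or overlapping; undefined across chromosomes). Distances are
annotation-release-dependent, so they are reported but never asserted
against reference values. A pair is a read-through candidate iff the
genes share chromosome and strand, the 5′ gene is transcriptionally
upstream, and the gap is ≤60 kb (configurable).

Splice-site concordance is existential over transcripts: the 5′
breakpoint must equal some exon's transcription-wise 3′ end and the 3′
breakpoint some exon's 5′ start, strand-aware. Frame prediction picks
the transcript pair maximising total CDS coverage (canonical-like,
deterministic tie-break by transcript id), carries the 5′ CDS phase
(coding bases through the breakpoint mod 3) across the junction, and
calls the fusion in-frame iff that phase plus the 3′ CDS segment's GTF
frame is a whole codon. Junctions off annotated splice sites are never
called in-frame, matching the observation that in-frame calls coincide
with annotated boundaries; a 3′ junction exon whose CDS does not begin
exactly at the junction (5′ UTR or noncoding exon) also yields
not-in-frame, since phase continuation is undefined there. Peptides
are translated with the standard nuclear code (no selenocysteine) to
the first stop when contig sequence is available.

Domain retention is computed only against user-supplied protein-
coordinate intervals (no external domain-database search): a domain is
retained iff its interval lies entirely within its source partner's
translated portion; straddling intervals are truncated.

## Partner association

The read-through signature: (i) 3′-partner expression higher in
fusion-positive than fusion-negative tumors and than benign samples
(one-sided rank-sum — one-sided for consistency with the cascade);
(ii) positive Spearman correlation between fusion breakpoint RPKM
(0 in fusion-negative samples) and partner FPKM, after a rank-
preserving log2(x+1) transform kept for consistency with plotted
values; (iii) exons downstream of the junction elevated in positive
samples while the most-upstream exon is not. The exon contrast is a
per-exon one-sided rank-sum on library-size-normalised counts — a
deliberate simplification of dispersion-modelling differential-exon-
usage machinery, chosen because the confirmatory logic (first exon
unchanged, downstream exons up) is exactly this contrast; the
signature rule requires at least half of downstream exons significant
at α with the most-upstream exon not significant.

Expression profiling normalises each fusion's tumor-minus-benign
differences by the row's maximum absolute difference, so profiles lie
in [−1, 1] with at least one entry at ±1 (all-zero rows stay zero),
and clusters profiles under distance 1 − Pearson r with average
linkage (a common default for correlation distances; configurable).
Zero-variance profiles are excluded with a warning since Pearson r is
undefined for them.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not real
transcriptomes. Per pair and sample, detection is Bernoulli at the
planted condition rate (only marginal counts are specified by the
design, so independent Bernoulli is the minimal model); split reads
are 1 + Poisson (mean 6 for plantings), discordant pairs are
max(5, split + Poisson(2)) so that planted detections pass the call
screen, total spanning equals discordant pairs, and multimapping
spanning reads are Binomial(total, planted fraction). Library sizes
are uniform on 30–60 million reads. Additional junk calls with
sub-threshold support exercise the call screen. Background pairs run
at rate 0.05 in both conditions — so on a 44-pair cohort roughly α of
them clear the enrichment test by chance, which is the expected
false-positive behaviour, not a defect.

The toy genome uses short contigs with explicit sequence. Genes are
'+'-strand, fully coding (ATG + non-stop codons + TAA laid across
90-bp, codon-aligned exons), so frame arithmetic is exact by
construction: a frame-incompatible planting lengthens the donor exon
by 1 nt and shortens the final exon to keep the native ORF intact.
Expression coupling multiplies the 3′ partner's FPKM, and its
downstream-of-junction exon counts, by 2^coupling in fusion-positive
samples (default planted coupling: 2 log2 units).

What passing tests on these cohorts do **not** show: robustness to
correlated detection across samples, to expression covariance
structure, to annotation errors, to minus-strand or multi-isoform
frame edge cases beyond those constructed, or to real callers' column
quirks beyond the default dialect. Identical seeds give byte-identical
bundles; tests and the acceptance script regenerate cohorts at run
time (a 44-pair cohort generates in well under a second).

## Problem sizes and numerics

The default study configuration is 44 tumor/benign pairs plus 50
unpaired tumors, 3 enriched plantings (rates 0.6/0.02), 1 homology
artifact (multimap 0.9) and 200 background pairs; oracle-equivalence
checks cover all 2×2 tables with group sizes ≤20 and signed-rank
enumeration up to n = 10; null calibration uses 2,000 simulated pairs.
Ties in ranks use midranks everywhere; p-values are reported in (0, 1]
and compared in full precision, with 2-significant-figure scientific
notation only in reports; unavailable report cells (e.g. variance over
fewer than two positive samples) render as `*`.
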