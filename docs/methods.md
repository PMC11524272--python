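# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
and design choices made where the design was genuinely open.

## Synthetic diploid generator

Haplotype A is drawn i.i.d. per base with P(G) = P(C) = gc/2 (default GC
0.34, typical of poplar-like dicot genomes). Genes are placed uniformly
without overlap, each with 1–5 exons (150–600 bp; 400–1,600 bp when
single-exon), introns of 60–800 bp, fixed 90 bp UTRs, and a valid ORF
written into the sequence (ATG start, TAA stop, no internal stops,
strand-aware). Gene geometry is a free choice of the generator and is not
calibrated to any particular species' feature-length tables.

Haplotype B is A plus planted events, all recorded in a truth object:

- SNPs at `snp_rate` (default 2 %, the regime of a highly heterozygous
  outbred tree) and small indels (< 50 bp) at `small_indel_rate` (default
  0.4 %), geometrically spread with a minimum spacing of
  2 × `indel_length_max` + 20 bp between indels so truth positions stay
  unambiguous after left-alignment. Small indels avoid coding exons (± a
  3 bp splice margin): purifying selection keeps frameshifts out of real
  coding sequence, and lifted B gene models therefore translate to the same
  protein as their A alleles. SNPs are planted everywhere, including CDS.
- Structural events of the five classes. Placement is a pure function of
  the config (its own RNG stream), drawn with a 1 kb guard zone around
  every event and bounded retries; infeasible requests raise. Because the
  plan is config-deterministic, `generate_haplotype_a` can embed the tandem
  unit pair that a contraction later collapses in B, with no state shared
  between the two steps. Translocations excise a segment (default 20 kb,
  block scale) and reinsert it at a distant, possibly inter-chromosomal,
  position.
- Annotation lifting goes through an explicit A→B offset map built from the
  edit list. Genes overlapped by an SV-scale removal are dropped (not
  truncated) and become haplotype-specific truth; a configurable extra
  fraction of genes (default 5 %) is additionally dropped from the B
  annotation to emulate one-sided annotation.

Expression: negative-binomial counts per allele copy and replicate
(default mean 200, dispersion 0.1, 4 experiments × 3 replicates), with a
log-normal library-size factor (sd 0.1) shared by all genes of a replicate
so normalisation is exercised. Non-ASE pairs share one mean; ASE pairs
split it by ±log₂FC/2 (default 2.0). A configurable fraction of ASE pairs
(default 60 %) is common to all experiments; planted ASE blocks (runs of
≥ 4 neighbouring pairs, one direction) are shared by construction and
their members are floored at the configured mean expression so that block
recovery tests exercise the run rule rather than detection power at trace
expression levels. Haplotype-specific genes get independent, lower means
(0.35×) with higher dispersion (3×), reproducing the lower average RPKM and
higher RPKM CV that distinguishes such genes in real data.

The k-mer histogram simulator draws, for every distinct canonical genomic
k-mer with diploid multiplicity m, a Poisson(m · coverage · (1−e)^k)
observation count (coverage = per-haplotype k-mer depth), and adds the
corrupted occurrences as multiplicity-1 error k-mers. This is the
uniform-coverage read model marginalised to k-mer space; it does not model
read-edge effects, quality-dependent errors, error k-mer collisions, or
GC-coverage bias, so passing recovery tests says nothing about those
biases in real sequencing data. Whole-read FASTQ simulation is out of
scope.

## k-mer spectrum fit

Error cutoff = first local minimum of the multiplicity histogram. Above
it, EM fits w₁·Pois(λ) + w₂·Pois(2λ) (tied means; 200 iterations max,
1e-8 relative log-likelihood tolerance). λ is initialised at mode/2 and
additionally at the mode itself, keeping the higher-likelihood fit — at
percent-scale heterozygosity the het peak can dominate the histogram mode
and the mode/2 start alone locks onto the wrong optimum. Spectra with
fewer than two local maxima above 5 % of the peak height (a prominence
guard against tail ripples) are flagged unimodal and returned with
het = 0 rather than failing. Genome size = (k-mer mass above cutoff)/(2λ);
heterozygosity = 1 − (1 − a)^(1/k) as in the README. The Poisson (not
negative-binomial) components match the uniform-coverage simulator;
repeat-aware corrections and ploidy > 2 are out of scope.

## Collinearity blocks

Anchors are maximal exact matches seeded by 21-mers unique in at least one
sequence (seeds occurring > 10 times in either sequence are dropped as
repeats), merged along diagonals and extended, both strands. Chaining is a
sparse DP over A-sorted anchors with per-strand B-monotonicity, score =
anchored length − 0.05·|gapA − gapB| − 0.01·min(gapA, gapB), chains broken
at gaps > 100 kb; a predecessor window of 80 keeps the DP near-linear (with
window ≥ n it is exact, which the oracle tests use). Maximal matches
flanking an insertion can overlap by a few chance-matching bases; overlaps
up to 50 bp are accepted and trimmed at block construction, which keeps
the trimmed anchors exact. Block identity comes from affine-gap alignment
of inter-anchor gaps (match +1, mismatch −2, gap open −4, extend −1) via
the Biopython pairwise aligner, switching to edlib edit-distance alignment
(extended CIGAR) above 4 kb per side where the affine DP is no longer
worth its memory; gaps > 100 kb per side are excluded from identity and
left to the SV caller. Filtering keeps blocks with A-span ≥ 15 kb and
identity ≥ 80 %, then enforces one-to-one mapping greedily by score
(aligned length × identity), discarding any block overlapping a kept block
by > 80 % of the smaller span on either axis.

## Variants

Small variants are read off the gap alignments: mismatch columns → SNPs;
gap runs < 50 bp → INS/DEL in A coordinates, left-aligned against A (the
same normalisation the simulator applies to its truth records, so
positions compare exactly). The 50 bp boundary is exclusive for small
indels and inclusive for SVs. Inter-anchor gaps with a ≥ 50 bp size
difference are classified: lost B sequence whose content duplicates the
adjacent A sequence (≥ 85 % identity by edlib infix search) → contraction,
otherwise deletion; gained B sequence matching the adjacent A sequence →
duplication, otherwise insertion. For events ≥ 5 kb the missing/extra
segment is searched genome-wide in the partner haplotype (edlib, ≤ 10 %
edit distance): a deletion whose content is found elsewhere in B is a
translocation (reported with its B landing site), and the corresponding
over-sized insertion at the landing site is suppressed so the event is
reported once. Blocks paired with a non-dominant chromosome, or whose A/B
offset deviates from the median of their 5 nearest neighbours by more
than max(span, 20 kb), are also reported as translocations. Translocations
are deliberately conservative and excluded from gene-overlap statistics
downstream; per-sample heterozygous-genotype counting from a multi-sample
VCF uses cyvcf2 and excludes any genotype with a missing allele.

## Variant annotation

Twelve location groups with fixed precedence: splice acceptor/donor (first
and last 2 intronic bases) > splice region (exonic 1–3 bp or intronic
3–8 bp from a junction) > 5′/3′ UTR > exon (CDS) > intron > transcript
(inside mRNA, nothing finer) > gene (inside gene, outside mRNA) >
upstream/downstream (strand-aware, 5 kb window — configurable; 5 kb is the
common annotation-tool default) > intergenic. A multi-base variant takes
the highest-precedence category over the bases it touches, and the most
severe impact across overlapping genes/transcripts is reported per gene.
Coding effects: CDS indel of length ≢ 0 (mod 3) → frameshift (HIGH);
stop gained/lost, start lost, splice donor/acceptor → HIGH; in-frame
indels and missense → MODERATE; synonymous → LOW; everything else
MODIFIER. A CDS whose annotated length is not divisible by 3 draws a
warning and is translated in the start-anchored frame. The effect
vocabulary is a documented subset covering all HIGH classes, not a full
effect-prediction taxonomy.

## Allele catalogue

Protein similarity = global BLOSUM62 alignment score (gap open −11,
extend −1) normalised by the self-score of the longer protein, clamped to
[0, 1]; computed on the longest isoform. Stage 1 pairs genes that are each
other's top similarity among candidates of the same one-to-one block (a
gene belongs to a block when ≥ 90 % of its body lies inside; the largest
such block is used). Stage 2 applies reciprocal best hit to leftover genes
when at least one of the two is on an unplaced scaffold. Pairs below
similarity 0.2 are rejected; ties break by higher similarity then
lexicographically smaller id pair, making the matching input-order
invariant. Every unpaired gene is haplotype-specific, so
2·|pairs| + |specific| equals the total gene count by construction.
"Top similarity" is evaluated among block-mates (stage 1) and leftover
candidates (stage 2) rather than all-against-all, which is what the
block constraint makes meaningful and keeps the stage near-linear.
Feature statistics report mean ± sd of gene/CDS/exon/intron lengths and
RPKM (per-sample totals as the million-scale denominator; CV pooled over
the per-gene-per-sample RPKM vector), with Tukey HSD (α = 0.05) compact
letter displays; classes with < 2 members are suppressed with a warning.

## ASE

Per pair and experiment, the haplotype-A sum is tested against a symmetric
beta-binomial null conditioned on the pair total, two-sided by equal-tail
doubling (exact for a symmetric null). The overdispersion ρ is estimated
across pairs by median-quantile matching: the median standardised
deviation |p̂ − ½|/σ(ρ) is driven to the normal quartile 0.6745 by
bisection, using pairs with ≥ 20 reads. A plain second-moment average is
not used because genuinely imbalanced pairs dominate it; the median is
robust to them, and a second pass re-estimates ρ after excluding pairs
already significant at a loose criterion (|log₂FC| > 1, FDR < 5 %), which
removes the residual contamination without biasing the null case. ρ ≤ 0
falls back to binomial. Calibration on 10,000-pair null simulations keeps
the fraction passing the decision rule (|log₂FC| > 1 and BH-FDR < 0.01)
well under 1 %, with ≥ 90 % power at a planted log₂FC of 2 (mean 200,
3 replicates).

ASE blocks are maximal runs of ≥ 4 consecutive allele pairs (in
A-coordinate order, non-allelic genes ignored), all ASE in the same
direction; any non-ASE or opposite pair breaks the run. Interior tolerance
is configurable but off by default. Cross-experiment shared blocks use a
greedy maximal matching seeded from the first experiment: one
same-direction block per experiment, pairwise sharing ≥ 3 member pairs —
the sharing rule is this package's own definition and is configurable.
Promoter–SV association builds the 2 × 2 table {ASE, non-ASE} ×
{promoter insertion/deletion, none} over the strand-aware 2 kb window
upstream of the translation start (first CDS base) of either allele, each
tested in its own haplotype's coordinates, and applies a two-sided Fisher
exact test. Motif scanning counts overlapping IUPAC matches on both
strands of promoter sequences and ranks motifs by total occurrences and by
promoters-with-hit, with Spearman correlation to compare rankings between
gene classes.

## Report conventions

All printed ratios round half away from zero: two decimals for rates and
fractions, one decimal for BUSCO-style percentages (complete = single +
duplicated before division). N50 is the standard smallest length in the
minimal set of longest sequences covering half the assembly; GC is over
unambiguous bases.

## Problem sizes

The test suite and acceptance script run on simulations sized for a single
CPU: the shared end-to-end diploid is 2 × 500 kb with 40 genes per
chromosome at 2 % SNP rate; k-mer recovery uses 10 Mb diploids at 50×
simulated depth over SNP rates 0.5–3 %; SNP recovery uses 1 Mb at 0.1 %;
SV recovery plants 12 events of 50–2,000 bp on 2 × 500 kb; ASE calibration
uses 3 × 10,000 null pairs and 200 planted pairs in a 2,000-pair
background. The ASE-block recovery scenario plants log₂FC 2.5 at
dispersion 0.05 so that exact recovery measures the run rule rather than
per-pair detection power. Genome-scale counts (e.g. tens of millions of
variants) depend on real assemblies and are not simulation targets.

## Known limitations

- The anchor/chain aligner assumes homonymous chromosome pairing and is not
  a general whole-genome aligner; highly repetitive or rearranged regions
  beyond the repeat guard are unmodelled.
- Contraction/duplication calls detect tandem copy-number changes via flank
  matching; dispersed duplications classify as insertions.
- The beta-binomial ASE test consumes haplotype-uniquely assigned counts;
  read mapping, zero-mismatch filtering and mapping bias are upstream of
  this package.
- The simulator's uniform base composition lacks repeats, transposons and
  GC heterogeneity, so alignment performance on real plant genomes will be
  worse than the synthetic recovery rates suggest.
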