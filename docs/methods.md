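# Methods

## The scanning model

An ORFan candidate is a maximal run of in-frame non-stop codons strictly
between two consecutive in-frame stop codons, under the invertebrate
mitochondrial code (NCBI table 5). All six reading frames are scanned —
three per strand — even in genomes whose genes all sit on one strand;
the strand and frame of every candidate are reported. The filtering
order is fixed: runs shorter than 360 nt are removed first, survivors
intersecting annotated tRNA genes are split at the tRNA boundaries, and
the resulting pieces are refiltered at 210 nt. The thresholds apply to
raw nucleotide run lengths; tRNA splitting trims each remainder inward
to the nearest in-frame codon boundary, which preserves the no-stop
invariant of every emitted region. Candidates overlapping an annotated
protein-coding or rRNA gene by more than half their own length are
treated as rediscoveries and dropped; remaining candidates that overlap
one another positionally (any frame or strand) are clustered and the
longest member per cluster is kept, so each locus yields one ORFan,
named by its length (`ORFan-543`).

**Circularity.** Reading frames on a circle whose length is not a
multiple of three do not close on themselves, so the scanner uses the
sequence-doubling convention: each frame's reading thread is followed
through two copies of the genome, every run is attributed to the frame
of its opening codon (the left-bounding stop lying in the first copy),
and run lengths are capped at the largest codon multiple not exceeding
the genome length; a frame with no stops at all yields one such capped
run. Across the three frame values of a strand this reports every
circular run exactly once, including origin-spanning ones. The same
convention is implemented independently in the test oracle by
translating and splitting protein strings.

**Control-region heuristic.** Among unannotated intervals of at least
200 nt, an interval qualifies as a control-region candidate when it
contains at least one in-frame stop in all six (locally framed) reading
frames — the opposite of the ORFan signature — and its GC content is
strictly below the minimum GC over all annotated protein-coding genes.
Candidates are ranked by ascending GC. This is a composition heuristic
only; secondary-structure and replication-origin evidence are out of
scope.

## Selection statistics

All statistics are pairwise and alignment-based; no tree is used.

- **p-distances** (nucleotide and amino-acid): mismatches over
  comparable sites with pairwise deletion (a column counts for a pair
  only when neither member is gapped), averaged over all pairs.
  Variances come from bootstrapping columns with replacement, 500
  replicates by default, seeded and bit-reproducible.
- **Nei–Gojobori counting.** Per codon, the synonymous site count at
  each position is the fraction of non-stop single-nucleotide changes
  that are synonymous (stops removed from the denominator), so s + n = 3
  exactly. Between two codons differing at k positions, differences are
  averaged with equal weight over the k! mutational pathways whose
  intermediates avoid stop codons; if every pathway crosses a stop the
  pair is skipped with a warning. Codons containing gaps or ambiguity,
  and stop codons (e.g. terminal stops), are treated as missing data.
- **pN/pS.** Proportions are pooled over all pairs and columns:
  pS = ΣS_d/ΣS, pN = ΣN_d/ΣN, and the ratio of the pooled proportions is
  reported — not a mean of per-pair ratios, and with no multiple-hit
  (Jukes–Cantor-style) correction. Consequently the ratio is a *biased*
  estimator of a generating omega at appreciable divergence: synonymous
  sites saturate faster than nonsynonymous ones, so at 0.5 expected
  substitutions per codon per branch the simulated omega = 0.3 yields
  pooled ratios near 0.41 (and omega = 1 yields ≈ 1.0). The estimator is
  monotone in omega, which is what the recovery tests assert; its
  variance (not its saturation bias) shrinks with codon count.
- **Codon-based Z-test of purifying selection.**
  Z = (pS − pN)/√Var(pS − pN), with the variance estimated by bootstrap
  over codon columns (500 replicates, seeded) and a one-tailed p-value
  from the upper normal tail (H0: pN = pS, H1: pN < pS). The test is
  flagged undefined when there is no variation or zero bootstrap
  variance. Calibration measured by simulation at 5 taxa × 300 codons:
  type-I error ≈ 0.03 at alpha = 0.05 (slightly conservative, as
  expected of a bootstrap-variance Z-test), power ≈ 1.0 at omega = 0.3.

## Codon usage and CAI

RSCU follows the Sharp–Li convention: a codon's count over the mean
count within its synonymous family, with unobserved codons given a 0.5
pseudo-count before RSCU so no relative-adaptiveness weight is zero;
weights are RSCU over the family maximum; a fully unobserved family gets
uniform weights 1 with a warning. CAI is the geometric mean of the
gene's codon weights, skipping a terminal stop and (in principle)
single-codon families — under table 5 no such family exists, since
ATA/ATG are both Met and TGA/TGG both Trp. The background pools every
protein-coding gene of the genome set; a `pcg-only` switch excludes
ORFans from their own background as a sensitivity knob.

## Tracks

Genome tracks default to 100 nt windows stepped by 10 nt with circular
wrap-around — smooth at mitogenome scale. GC content excludes N from
numerator and denominator; AT skew is (A−T)/(A+T) and GC skew
(G−C)/(G+C), with zero-denominator windows emitting 0 plus a flag.
Hydropathy is the sliding mean of the Kyte–Doolittle residue scale,
default window 9 (odd, center-anchored). Conservation per alignment
column is the frequency of the modal non-gap residue among non-gap rows,
zeroed where more than half the rows are gapped, smoothed with a
5-column sliding mean; it is a simple occupancy score, not a
physico-chemical score, so cross-tool comparisons should stay
region-level rather than value-level. Window sizes are explicit knobs
everywhere.

## Expression

Expression input is a per-base depth table (samtools-depth-style TSV;
read mapping is out of scope). A feature's expression is its mean
per-base depth; relative level divides by the mean of means over the
normalization set (per-feature-mean convention, declared in output
headers), making levels invariant under rescaling the whole track.
Transcript segmentation reports maximal runs within a feature whose
depth is at least 10% of the mean protein-coding-gene depth and at least
50 nt long; both thresholds are configurable and reported, since the
underlying two-transcript observation is qualitative.

## The synthetic genome

The generator emulates the architecture that motivates the scanner: a
circular single-coding-strand genome with 13 protein-coding genes
(realistic codon-multiple lengths, AT-biased codon usage, terminal TAA),
two rRNA placeholders, 22 tRNA placeholders of 60–72 nt plus a
duplicated trnM, three intergenic ORFans (543, 1059 and 426 nt — the
codon-trimmed sizes of the loci that motivated the design), and an
AT-rich control region (AT fraction 0.85) verified at generation to
contain stops in all six frames and to undercut every PCG's GC content.

Two constructions make recovery exact rather than merely likely. Every
inter-feature junction carries a 15-mer stop cassette (`TAATTAATTAATTAA`,
a TAA in all three frames of both strands), so stop-free runs never leak
across feature boundaries; and each ORFan is flanked by an immediate
in-frame TAA on both sides, so the maximal run in its frame is exactly
the true interval. ORFan bodies are resampled until no *other*
frame/strand holds a stop-free run of 360 nt within the locus, and until
the locus GC (diluted by its zero-GC flanks) stays above the PCG GC
floor, so the locus is never mistaken for a control region. The truth
control region is the whole terminal unannotated gap, which is exactly
what an annotation-complement caller can observe.

What the simulator does *not* emulate: realistic tRNA/rRNA structure,
indels, strand-asymmetric skew gradients, within-gene rate variation,
or sequencing-coverage biases beyond Poisson noise. Passing recovery
tests therefore demonstrates the correctness of the scanning and
counting machinery under the stated genome architecture, not robustness
to annotation errors or assembly artifacts in real data.

## The codon-evolution harness

A star phylogeny (sufficient because every target statistic is a
pairwise average) with a continuous-time codon model: single-nucleotide
exchanges only, transitions weighted by kappa, nonsynonymous changes by
omega, stop-creating changes set to rate zero, generator scaled to one
expected substitution per codon per unit branch length (uniform
sense-codon weighting). Tip sequences are drawn directly from
expm(Q·t), which is exact for end states. Defaults: 5 taxa, branch
length 0.5 substitutions per codon (congeneric-mitogenome-scale
divergence), kappa = 1 — chosen so the Nei–Gojobori estimator, which
assumes unbiased mutation, is interpretable in calibration runs; kappa
is a knob for studying its bias. omega = 0 is allowed (purely
synonymous evolution); negative omega is rejected.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng(seed)`; the
  same seed gives bit-identical bootstrap variances, simulated genomes
  and depth tracks.
- Identical alignment rows: p-distance (0, 0); pN = pS = 0 with the
  ratio flagged undefined; Z-test flagged undefined (no variance).
- Bootstrap replicates with an empty synonymous (or nonsynonymous) site
  sum contribute 0 for the affected proportion.
- Clustering ties in the scanner (equal lengths) break toward the
  leftmost region; region sorting is total, so output order is
  deterministic.
- Features wrapping the circular origin are stored with end > L and a
  wrap flag, serialized as two GFF3 lines sharing an ID.

## Problem sizes used in the validation suite

Scanner benchmarking uses 1,000 random sequences of 0.6–3 kb (half
circular); Z-test calibration and power use 500 replicates of 5 taxa ×
300 codons; omega recovery uses 10 replicates per omega; end-to-end
recovery uses the default ~19.4 kb genome. These sizes give binomial
standard errors below 0.01 on the calibration rates while keeping the
whole suite fast.

## Known limitations

- The pooled pN/pS is not a substitution-rate ratio; for publication-
  grade omega estimates a likelihood codon model should be used.
- Start codons are not called; candidate boundaries are stop-delimited
  (refining boundaries via cross-species codon alignments is consumed
  as input, not computed).
- Alignments are inputs (aligned FASTA); no aligner is wrapped.
- The control-region heuristic is compositional only.
- Multi-chromosome genomes and non-N ambiguity codes are rejected.
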