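# Methods

`srnascape` re-implements an integrated multi-tissue small-RNA analysis for
a plant genome as a tested, reusable pipeline, and validates every stage
against a synthetic dataset with planted ground truth.  This note records
the models, the parameter choices that matter, the numerical decisions, and
the limits of what the synthetic validation shows.

## Pipeline model

Reads from many libraries (several per tissue) are collapsed to distinct
sequences, aligned to the genome allowing at most one substitution and no
indels (every placement on either strand is kept), normalised to
transcripts per million (TPM = count x 10^6 / library mapped total), and
passed through a fixed filter cascade: size (retain 18–26 nt), structural
RNA (tRNA/rRNA/snRNA/snoRNA blacklist, matched at <= 1 substitution),
low abundance, and repetitivity (> 20 genomic placements).  Replicate-mean
TPM per tissue is the expression unit for all downstream statistics.

**Low-abundance predicate.** The removal rule "total abundance <= 100 TPM
and abundance in at least one library <= 10 TPM", read literally as a
conjunction, removes almost everything (some library is nearly always
<= 10 TPM).  We retain a read iff total TPM > 100 AND its maximum
single-library TPM > 10 — aggregate support plus support in at least one
library — which is the evident intent.  Both thresholds are configurable.

**TPM denominator.** The mapped total counts aligned reads that also pass
the size filter, so length junk does not deflate TPM; a switch
(`FilterParams.tpm_denominator`) restores the all-aligned-reads convention.
Filter order (size, unaligned, structural, low-abundance, repetitive) is
fixed so attrition tallies are reproducible; each read receives exactly one
status.

## miRNA locus discovery

Candidate windows are strand-specific clusters of placements of passing
reads (merge gap 200 nt, flank 20 nt); windows longer than 300 nt are
discarded, matching the precursor length cap.  Each window must clear five
gates: precursor <= 300 nt; strand bias = sense/(sense+antisense) >= 0.9;
abundance bias = (mature + star + isomiRs)/sense >= 0.75; and a mature/star
duplex with <= 5 mismatches and <= 3 asymmetric bulges.  Bias computations
pool raw counts across libraries.  The canonical mature is the most
abundant window read, ties broken towards the 5'-most placement.

**Folding.** Hairpins are folded with a maximum-base-pairing dynamic
program over nested structures (Watson–Crick plus G:U, minimum hairpin loop
3), with deterministic traceback preferring smaller opening indices.  This
combinatorial folder is sufficient for the pass/fail duplex geometry the
gates need; it is not a thermodynamic (minimum-free-energy) model and does
not rank structures by stability.  Its pairing counts are verified against
exhaustive enumeration for all sequences up to 20 nt.

**Duplex scoring.** The mature/star duplex is scored on a local
antiparallel alignment of the two strand sequences (gap penalty chosen so
that a mismatch is never realised as two compensating single-base bulges
unless the shifted register gains at least two pairs).  We deliberately do
not read the duplex off the global fold: a maximum-pairing structure will
bulge a mismatched base out whenever the shift gains a pair, which
systematically overcounts asymmetric bulges.  The global fold is still used
to locate the arms and to infer the star position (standard Dicer geometry:
2-nt 3' overhangs; star support is accepted from reads starting within
±1 nt of the structure-implied star 5' end, otherwise the star is inferred
from the structure).

**Known vs novel.** A discovered mature matching a reference mature with
<= 2 substitutions (equal length, no indels) is "known"; otherwise novel.

## isomiR classification

Reads attributed to a locus are anchored through their genomic placement
and classified against the canonical mature into seven classes: 5'/3'
trimming (negative end offsets), 5'/3' addition (positive offsets matching
the genomic template), non-templated 3' addition (positive 3' offset not
matching the template), and seed/tail SNP (internal substitutions inside or
outside mature positions 2–8, 5'-anchored — the standard plant/animal seed
convention; configurable).  Decisions taken where the class system is
under-specified: end offsets beyond ±4 nt mark a distinct sRNA, not an
isomiR; a read shifted at both ends carries both end classes; substitutions
are measured against the canonical sequence (which can differ from the
genome template at a duplicated locus), while templated-ness of 3'
extensions is measured against the genome; non-templated added bases are
never additionally counted as SNPs; at most two internal substitutions are
tolerated before a read is left unclassified.  Classification is a pure
function of (read, canonical, flanking template, anchor offset).

## Expression statistics

**Exact test.** For two count-scale values x, y (TPM rounded to integers)
under equal normalisation totals N1 = N2 = 10^6, the pointwise probability
is P(x|y) = (x+y)! / (x! y!) / 2^(x+y+1), the NB(y+1, 1/2) mass function in
x, evaluated in log space via log-gamma.  The two-sided p-value doubles the
smaller tail and caps at 1.  The default differential call (p < 0.01 and
|log2 fold change| >= 1, pseudocount 1) is configurable; it is a design
choice, as no cutoff is canonical for this statistic.

**Tissue specificity.** For an expression vector over n tissues, H is the
Shannon entropy (bits) of relative expression. modH is the entropy of
absolute deviations from a one-step Tukey biweight center (c = 5,
epsilon = 1e-4, the Affymetrix constants), which makes the score symmetric
for one-tissue-on and one-tissue-off patterns.  Z scores use the sample
(n−1) standard deviation (switchable to population).  A locus is called
specific iff modH < 1.8 and max Z > 3, with the target tissue at argmax Z.
For a one-hot profile over 14 tissues, max Z = 13/sqrt(14) ≈ 3.474, which
clears the threshold; flat profiles have sigma = 0 or all-zero deviations
and are never called.

## PHAS detection

Reads of exactly the cycle length (21 or 24 nt) are scanned in windows of
W = 10 cycles anchored at each occupied position; antisense 5' starts are
shifted by the 2-nt duplex offset onto the sense register.  Significance is
the hypergeometric upper tail of drawing >= k register positions when
placing the occupied distinct starts uniformly among the window's
positions.  This is a re-derivation of the classic phasing-score family,
not a reproduction of any specific tool's internal statistic; "minDepth 3"
is interpreted as >= 3 distinct phased positions.  Accepted windows
(P < 1e-5) overlapping one another merge into a locus carrying the minimum
window p-value.  Triggers are assigned by complementarity scan of both
locus ends ±2 cycles (<= 4 mispairs, G:U counted 0.5; ties to the 5'-most
site).  Loci overlapping a retrotransposon-class transposon AND triggered
by 22-nt miR170/miR171a are flagged as easiRNA-like and excluded.  Two loci
are conserved partners when they share a trigger and >= 2 cross-locus
phasiRNA pairs match at <= 2 substitutions.

## Duplication analysis

Contexts partition loci with precedence PCG > TE > UI (one shared base is
an overlap); precedence is required because the three categories must
partition the locus set.  Loci pair as conserved when their matures differ
by <= 2 substitutions.  A same-chromosome pair with an end-to-end gap under
200 kb is tandem; a pair whose members fall into the two intervals of one
synteny block (consumed from a TSV, 1-based inclusive on file) is syntenic;
tandem takes precedence for the mechanism label when both hold.  Pair
distance is the gap between nearest precursor ends, not midpoints.

The ratio test compares a category's singleton/duplicate counts against the
genome-wide counts with a 2x2 Pearson chi-square, df = 1, upper tail, no
continuity correction.  This construction reproduces the published
context-wise and tissue-wise p-values from their printed counts to printed
precision, which a one-sample goodness-of-fit against fixed proportions
does not; the engine is verified cell-by-cell against an independent
Pearson computation on random tables.

## Synthetic data: what it emulates and what it does not

The generator plants every feature the pipeline is meant to recover, under
one root seed with per-library child streams derived by fixed arithmetic
(adding libraries never perturbs earlier ones; equal configurations give
byte-identical outputs).

Reference conditions (the defaults): 2 chromosomes x 300 kb; 14 tissues x 2
libraries at 100,000 reads each (counts drawn multinomially to an exact
total); 100 hairpin loci (arm 60 nt, loop 15 nt, mature 21 nt, star at the
2-nt 3' overhang position, 10% of mature abundance) split evenly across
PCG/TE/intergenic contexts; 20 one-hot tissue-specific loci, the remainder
with symmetric Dirichlet(5) profiles (one-hot profiles make specificity
recovery unambiguous; the duplicates of a pair share a profile); 5 tandem
pairs (same chromosome, < 200 kb, matures at 1 substitution) and 5 syntenic
pairs (cross-chromosome, in declared blocks); ten 21-nt and ten 24-nt PHAS
loci (10 fully occupied cycles, a perfect 22-nt trigger site at the 5'
end, expressed in reproductive-tissue pairs); 10% contamination split
between genome-embedded structural-RNA fragments (blacklisted) and random
degradation fragments of 15–30 nt; a 2% per-class isomiR rate with one
planted variant per class per locus (non-templated 3' additions are always
A, with the templated next base forced to C so the class is unambiguous).

Planted hairpins are deliberately imperfect: three substitutions are
injected opposite fixed mature positions (offsets 3, 10, 17), spread so
that no mature-sized antisense window across the duplex is within one
substitution of perfect self-complementarity.  Perfect stems would let
every hairpin read align antisense onto the opposite arm and drag strand
bias to 0.5 — a pathology real (imperfect) precursors do not have.

Not emulated: sequencing error beyond the planted substitutions, adapter
read-through, quality scores, expression dispersion beyond multinomial
sampling, multi-branch precursors, and genomic repeat families.  Passing
the recovery suite therefore demonstrates correctness of the statistical
machinery and the decision rules on clean, well-separated signals; it does
not measure robustness to noisy ends, repeat-dense genomes, or shallow
libraries.

## Problem sizes and determinism

The reference end-to-end run (the sizes above) completes in well under a
minute on one CPU; the test suite folds ~120 windows of <= 300 nt with the
O(n^3) dynamic program and compares 200+ short sequences against the
exhaustive enumeration oracle.  All stochastic tests are seeded; pipeline
reruns with an identical configuration are verified byte-identical.

## Known limitations

* The folder ranks structures by pair count only; thermodynamically
  implausible co-optimal structures are possible, mitigated by the
  sequence-level duplex scorer.
* The phasing statistic treats distinct 5' positions as exchangeable and
  ignores read abundance; very deep loci with scattered background could
  be over-called (the abundance-free form is also what makes the
  false-positive control exact).
* The exact test inherits the TPM-rounding convention; at very low counts
  the rounding dominates the statistic.
* Duplication analysis considers mature-sequence conservation only; it
  does not model precursor-level conservation or dating of duplication
  events.
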