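# Methods

This note documents the models, conventions and numerical choices behind
omegapair, in the order the pipeline applies them, and states what the
synthetic cohorts do and do not emulate.

## Genome model and coding density

A genome is its supplied contigs plus CDS annotations; no completeness
screening or gene calling is attempted. Coordinates are GFF3-style
(1-based, inclusive) at the I/O boundary. Translation uses NCBI genetic
code table 11 by default (configurable per genome); CDS whose length is
not divisible by 3 or whose translation contains an internal stop are
excluded and listed in a skip report rather than failing the run. Codons
containing ambiguous bases translate to `X` and are excluded from
codon-level counting (pairwise deletion).

Coding density is `(coding length / genome length) × 100`. The default
numerator is the **union** of genome positions covered by at least one
CDS, which guarantees density ≤ 100% (a requirement for using density as a
correlation input); a `literal` mode sums CDS lengths as the textbook
formula does, and the two agree exactly on non-overlapping annotations.
Whether overlapping genes should be deduplicated is genuinely
convention-dependent, so both modes are exposed.

Genome size is carried in two units — base pairs and CDS count — because
only protein-coding sequence enters the dN/dS analysis, and published
size/selection trends are checked in both units.

## Orthology

The ortholog finder is "collapse, then reciprocal best hit":

* **Paralog collapsing.** Single-linkage clusters over the graph linking
  proteins with ≥90% identity on ≥90% of both lengths; the longest member
  (ties: lexicographic id) represents the cluster. Collapsing precedes
  BBH so that a recent duplicate cannot steal its sibling's reciprocal
  best hit. Order and thresholds are configuration, not dogma.
* **Alignment.** Exact global Needleman–Wunsch with affine gaps
  (BLOSUM62; a gap of length k costs 11 + k; `X` scores 0 against
  everything) provides both the hit score and the alignment passed
  downstream. For two-sequence inputs an optimal pairwise alignment is at
  least as good as a progressive multiple aligner, and exactness removes
  heuristic nondeterminism. Ties in score are resolved by percent
  identity, then lexicographic id, so runs are reproducible and
  direction-symmetric.
* **Acceptance gates.** ≥30% identity over ≥50% of both lengths,
  configurable.
* **Scaling.** Above 400 cross-pairs, candidates are restricted to pairs
  sharing 4-residue peptides (10 shared for BBH candidates, 20 for
  clustering links). A 300-residue pair at 50% identity shares ~18
  4-mers and at 90% identity ~200, so in the congeneric regime this
  pipeline targets the prefilter is lossless in practice; near the 30%
  identity floor it can miss hits, and the exhaustive mode remains
  available via configuration. An external BLAST-style hit table can also
  be supplied in place of the internal search.

## dN/dS estimation

Protein alignments are back-threaded onto the CDS; columns with a gap, an
ambiguous codon or a stop are dropped and counted. Two counting methods
share one record shape:

* **NG86.** Synonymous sites per codon are the per-position synonymous
  fractions among single-nucleotide changes, with mutations to stop
  codons excluded from the denominator (so s + n = 3 always). Observed
  differences between codons differing at k positions are averaged with
  equal weight over the k! single-step pathways; pathways through stop
  codons are excluded and the average renormalised. In the degenerate
  case where every pathway passes through a stop, the k differences are
  split half synonymous / half nonsynonymous and a warning is logged.
  Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 yields an infinite (saturated)
  distance rather than an error so the filter stage can treat it
  uniformly.
* **YN00.** The same skeleton with three changes: (i) κ is estimated from
  fourfold-degenerate and nondegenerate sites (sites whose degeneracy
  class agrees in both codons) via the K80 model, combining the two
  class estimates weighted by site counts and falling back to κ = 1 when
  neither is estimable; (ii) site fractions and pathway steps are
  weighted by `π[target codon] · κ^[transition]` with F3×4 codon
  frequencies estimated from the pair (nucleotide counts smoothed with a
  0.5 pseudocount so no sense codon has zero frequency), normalised per
  position exactly as NG86 normalises its unweighted fractions — hence
  with κ = 1 and uniform frequencies the site counts reduce exactly to
  NG86's; (iii) transition and transversion differences are accumulated
  separately within the synonymous and nonsynonymous classes and
  corrected with the K80 distance, and because pathway weights carry
  `ω^[nonsynonymous steps]`, ω is iterated from 1 until |Δω| < 1e-6
  (at most 100 iterations; non-convergence is flagged, not raised).
  Pathway weights use the orientation with the smaller codon index first
  so estimates are symmetric in the two sequences. κ is estimated once,
  before the ω iteration; iterating κ as well was tried conceptually and
  rejected as circular, since κ enters its own site classification.

  This is a counting-method reconstruction in the Yang–Nielsen spirit,
  not a line-by-line port; on simulated data it agrees with the
  independent implementation in Bio.codonalign to within a few percent
  (sub-percent at neutrality), which is the scale on which variants of
  these approximate methods differ from each other.

`dS = 0` produces the sentinel ω = 999 instead of a division error; the
sentinel exceeds the ">99" discard threshold, so zero-divergence pairs are
disposed of by the same rule as exploding ratios.

## Filters, retention and pair summaries

An estimate is discarded iff dS < 0.1 (too little synonymous divergence
for a stable ratio) or dS > 1.6 (saturation) or dN/dS > 99; all three
comparisons are strict, and the first matching rule labels the discard.
A genome pair is kept only when the retained orthologs are at least 5%
(inclusive) of the pair's average CDS count — "coding capacity" is read in
CDS units, consistent with measuring genome size in CDS for the ω panels;
a coding-length (bp) variant is selectable. The pair summary reports the
arithmetic mean of retained per-ortholog ω and its SEM (sample SD/√n; the
mean of ratios rather than the ratio of summed rates, because the SEM is
defined over per-ortholog values); with fewer than two retained orthologs
the SEM is undefined and the pair is dropped.

**Known interaction.** At ω near 1 with pairwise distance t = 0.3
substitutions/codon, the expected dS is ≈ 0.10 — right at the dS < 0.1
cutoff — so the filter truncates roughly half of the per-gene dS
distribution and biases the retained-mean ω downward by 15–20%. This is a
property of the filter rule at that parameter combination, not of the
estimators (estimator-level neutral calibration is unbiased; the
unfiltered mean recovers ω). At the ω ≤ 0.5 values typical of real
genome pairs, dS sits comfortably inside the window and the bias is
negligible.

## ANI

Fragment-based ANI follows the fragment-alignment convention: 1,020-bp
consecutive fragments, a 30% identity / 70% coverage gate, mean identity
of passing fragments, symmetrised over both directions (so the result is
exactly order-independent). Placement uses a semi-global edit-distance
scan (edlib) over both strands; placements with ≤25% edit density are
scored directly from that alignment, and more divergent placements are
re-aligned locally (match +2, mismatch −3, gap 5/2) inside the located
window so that partial homology is trimmed and judged by the coverage
gate — this is what makes unrelated sequence fail the gate (short local
alignments ⇒ coverage ≪ 70%) and be reported as *missing*, never 0.
`max_fragments` (pipeline default 200 per direction, evenly spaced,
deterministic) bounds the cost on larger genomes; a precomputed ANI table
can be supplied instead when values from an external ANI service are to
be used. No multiple-hit correction is applied: ANI is observed identity,
by definition.

## Spearman correlation

Midranks for ties; rs is the Pearson correlation of the rank vectors. The
two-sided P value is exact by full enumeration of the n! permutations for
n ≤ 9 (the cohort sizes of interest sit in this range) and the usual
t-approximation on n − 2 degrees of freedom above that, except |rs| = 1,
where the t statistic degenerates and the exact value 2/n! is reported.
The method used is recorded with every result. Missing values must be
dropped by the caller — the pipeline does pairwise deletion explicitly,
never silently.

## Simulator

The generator is a GY94 codon model: a reversible 61-state chain with
rate `π_j · κ^[transition] · ω^[nonsynonymous]` for single-nucleotide
codon changes, scaled so one unit of branch length is one expected
substitution per codon at stationarity. A pair diverges symmetrically
(t/2 per branch). Genes are wrapped with ATG/TAA, placed on one contig
with noncoding spacers sized (multinomially) to a requested noncoding
fraction; spacers descend from common ancestral sequence under
Jukes–Cantor at the coding-average per-site divergence t/3, so fragment
ANI is homogeneous across the genome. All randomness flows from one seed;
identical configurations write byte-identical FASTA/GFF3.

Cohort regimes (desk-scale study conditions, fixed once): 60–180 genes of
150–250 codons per genome, true ω spanning 0.05–0.20 (the empirical range
of prokaryotic genome-pair means), pairwise t uniform on 0.25–0.55 so
computed ANI falls in the 75–95% congeneric window. The archaeal-like
regime ties both ω and the noncoding fraction (0.08–0.30, i.e. coding
density 92→70%) increasingly to genome size; the bacterial-like regime
ties ω decreasingly to size and draws the noncoding fraction around 0.12
with ±0.03 jitter independent of size.

What the simulation does **not** emulate: indels (back-threading's gap
handling is exercised by unit fixtures instead), gene gain/loss and HGT
(so ortholog recall is measured under the identity pairing, a best case),
per-gene ω variation (single ω per pair by default; a gamma-distributed
extension is off by default), mobile-element structure in noncoding DNA,
and codon-usage bias beyond what F3×4 can express. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to annotation error or
alignment ambiguity in real genomes.

## Problem sizes

Validation runs use 500-gene × 300-codon pairs for recovery grids,
20 × 20,000-codon replicates for neutral calibration, and 12-pair cohorts
for sign recovery — sizes at which sampling error of the quantities under
test is a few percent, well inside the asserted tolerances.
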