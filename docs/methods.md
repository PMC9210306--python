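# Methods

`genome_workbench` packages four downstream analyses that recur in repeat-rich
bivalve genome projects — LTR retroelement discovery, circular mitogenome
structure validation, Hi-C organelle-contig classification, and bulk RNA-seq
tissue-specificity / differential expression — together with a synthetic-data
generator that provides exact ground truth for all of them. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

Coordinates are 0-based half-open on the forward strand everywhere in the
library; BED output keeps that convention and GFF3 converts to 1-based
inclusive.

## Synthetic data

The generator emulates the study system the workbench was built around: an
AT-rich (35% GC) nuclear genome carrying a family of recently transposed LTR
retroelements, a 67,195 bp circular mitogenome whose non-coding half is three
blocks of direct tandem repeats with unit lengths 125, 1030 and 86 bp around
a compact ~17.5 kb coding region, a 16-pseudo-chromosome Hi-C assembly with
an unlinked organelle contig, and a three-tissue (mantle/gill/foot),
two-condition, four-replicate RNA-seq design.

Background sequence is i.i.d. at the configured GC; no higher-order
composition model is used because planted-feature recovery does not require
one. Planted elements substitute equal-length background segments so
recorded coordinates are final. Each element family derives from one master
LTR (copies at ~1% divergence from the master; the two LTRs of one element
separated by the configured pair divergence, default 2%, reflecting recent
transposition) and a master internal region whose open reading frame is
built from sense codons with stop codons repaired after mutation.
"Degenerate" copies lose either the internal ORF (replaced by random
sequence) or 60% of one LTR; "solo" copies are isolated LTR scars. Elements
are spaced at least 20 kb apart so that windowed self-comparison never
cross-pairs neighbours.

Long reads draw lengths from a gamma distribution (shape 3, configurable
mean, default 8 kb); on circular references the start is uniform on [0, L)
and reads wrap the origin, with the wrapped source interval and an
origin-spanning flag recorded per read. Errors are independent per-base
substitutions and indels; no instrument-specific or homopolymer error
profile is modelled, so error-robustness results here do not transfer
quantitatively to any particular platform.

Hi-C pairs mix cis contacts (power-law distance decay, Pareto exponent 1,
1 kb minimum) with uniform trans background at a configurable cis fraction
(default 0.8); the organelle contig's partners are drawn uniformly over
nuclear chromosomes proportional to length, which is the contact signature
of DNA that is physically absent from the nucleus. Counts are
gamma-Poisson (negative binomial) with a single dispersion (default 0.1),
log-normal baseline means, per-sample depth jitter, planted tissue-specific
genes (fold 50 concentrated in one tissue) and planted DE genes
(|log2FC| = 2 between conditions). Gene lengths place 5% of genes below the
200 bp filter boundary.

All randomness flows from one integer seed through named substreams
(`SeedSequence([seed, crc32(stage)])`); identical config + seed reproduces
byte-identical files.

## LTR discovery

The discovery procedure follows the probe-driven workflow used for
Steamer-like elements: an internal-region probe seeds a genome-wide search;
dotplot inspection of the surroundings is operationalized as windowed
self-comparison to find flanking direct-repeat pairs; the repeat copies are
star-aligned into a majority-rule consensus; a second scan with the
consensus recovers all copies including solo scars; and paired hits are
classified.

The external BLAST dependency is replaced by exact k-mer seeding (k = 13)
with diagonal-band clustering and edlib edit-distance extension. This is
adequate in the ≥85% identity regime of recent element families, and the
test suite holds it to agreement with brute-force iterative Smith-Waterman
on 50 kb fixtures. Truncated copies are handled by extending only the
seed-supported probe slice, approximating local alignment.

Thresholds the source procedure leaves implicit are explicit parameters:
minimum LTR length 100 bp, maximum 1,500 bp; maximum element span 15 kb;
minimum LTR-pair identity 85%; a copy shorter than 50% of the consensus
length counts as truncated. "Intact" requires an open reading frame
strictly longer than 3,000 nt (nucleotide length, strict inequality; an
exactly-3,000 nt ORF is degenerate) between paired LTRs on the element
strand, where an ORF is a maximal stop-to-stop frame segment with no start
codon requirement. When several pairings are feasible, the matcher prefers
pairs with a qualifying ORF, then longer ORFs, then tighter spans. Repeat
boundaries are refined by outward extension while local identity stays
high; at nonzero divergence (and even at zero divergence, where background
bases may extend a maximal repeat by chance) boundaries are identifiable
only to within a few bases, so recovery is asserted with a ±5–10 bp
tolerance rather than exact span equality.

## Circular mitogenome validation

A circular genome mapped with a linear aligner splits or clips every read
that crosses the arbitrary origin. The workbench maps reads against a
doubled reference (two head-to-tail copies), where every read has a
contiguous placement, and folds coordinates modulo L back onto the circle;
origin-spanning reads become exactly two wrapped intervals [s, L) + [0, e).
The internal mapper is minimizer-style seeding (k = 15, every 3rd k-mer) with
diagonal clustering and edlib extension, one primary alignment per read:
selection prefers query coverage, then seed support, then the smaller
canonical start (so placements fold deterministically onto copy one).
Query tails over 50 bp unsupported by the chain are reported as clips.
External PAF is ingested into the same record type. On error-free synthetic
reads placements agree with truth within ±5 bp, origin-spanning reads are
100% contiguous, and circular coverage shows no origin dip, while mapping
the same reads to the undoubled sequence produces a ≥50% dip — the
practical signature the doubled-reference approach removes.

Collapsed tandem repeats are detected from canonical coverage plus
clipping: anomalies are maximal runs of 100 bp windows where mean coverage
exceeds 3× the genome-wide median and more than half of the overlapping
reads carry a clip of ≥20 bp. Both thresholds are package choices (the
original detection of this signature was visual); on a construction with a
1,030 bp unit collapsed from 20 to 2 copies the block is flagged at ~6-fold
enrichment. Enrichment scales with the ratio of true to assembled array
length as read placements pile into the collapsed block.

Tandem decomposition estimates a per-position candidate period from the
distance to the next occurrence of each 12-mer, segments dense runs of
consistent period (tolerating 2× and 3× harmonic skips from mutated
copies), refines block boundaries by walking the lag-u self-match outward,
and refines the unit by base-level autocorrelation: the smallest lag whose
match fraction reaches 95% of the maximum, which resolves harmonic
ambiguity such as 250 vs 125. Blocks shorter than two units are not
reported. Planted units in [20, 2000] bp at ≤2% divergence are recovered
within ±2 bp.

Homoplasmy checking re-aligns each mapped read base-level (edlib global
alignment of the aligned slice), accumulates an A/C/G/T pileup, and calls a
site a variant when depth ≥10 and the top non-reference allele fraction
≥0.2 — conservative settings chosen to detect a putative second
mitochondrial haplotype at plausible minor fraction. A coding region with
no coverage raises an error rather than reporting "no variants".

## Hi-C organelle classification

For a query contig or window, contacts to each pseudo-chromosome are
counted and divided by the query's total contacts; contacts with both ends
inside the query (self-contacts) are excluded from numerator and
denominator, so fractions sum to 1. Sau3AI (GATC) site counts per contig
are computed for optional secondary normalization; total-contact
normalization is primary.

Classification compares the query against a panel of background nuclear
windows (ten 50–100 kb windows per chromosome, seeded selection). The
original comparison was visual (boxplots); the operational rule here calls
the query nuclear-linked to its top chromosome c only if its fraction at c
(i) exceeds the robust upper fence (median + 1.5·IQR) of the background
windows' *maximum* trans fractions — the comparable statistic, since the
query statistic is itself a maximum over chromosomes; (ii) is at least the
robust lower fence (median − 1.5·IQR) of the background home-chromosome
fractions — a linked contig looks like other linked contigs, not merely
above trans noise; and (iii) stands out from the query's own runner-up
fraction by more than 1.5·IQR of the pooled trans fractions — linkage means
one chromosome dominates. A free organelle contig passes (i) but fails
(ii) and (iii) decisively, nuclear windows pass all three ≥95% of the time,
and shuffling pair partners drives linked calls below 5%. The reported
effect size is (max query fraction − trans median) / trans IQR.

Note that with self-contacts excluded, a background window's home fraction
is far below the generator's cis fraction (most short-range cis contacts
land inside the window itself); the fences are estimated from the panel, so
the rule does not depend on that value.

## Expression: τ and NB quasi-likelihood DE

Counts are filtered in two steps: genes shorter than 200 bp are removed
(strict <), then genes are kept only if at least X samples have counts
≥10, where X is the replicate count of the smallest (tissue, condition)
group — the standard keep-if-expressed reading of the low-expression rule,
with X tied to the smallest condition.

τ is computed from per-tissue mean CPM: x_i = tissue mean / maximum tissue
mean (so x_i ∈ [0, 1], the index's standard form), τ = Σ(1 − x_i)/(N − 1).
τ = 0 for uniform expression, 1 for single-tissue expression. Genes with
τ ≥ 0.95 (inclusive) are assigned to their maximally expressing tissue;
argmax ties are left unassigned and flagged; all-zero genes are excluded
with an `undefined` flag. An option computes x_i from log2(CPM + 0.5)
floored at 0 instead, since which scale the index is run on is a genuine
analysis choice; linear CPM is the default.

The DE test is a deliberately simplified reimplementation of the
negative-binomial quasi-likelihood workflow, not a port; calibration, not
numerical identity, is the contract. Size factors are median-of-ratios
(robust to composition shifts from DE genes). Tagwise dispersions maximize
the Cox-Reid adjusted profile likelihood on a 41-point log grid
(10⁻⁴–10); a lowess trend of log-dispersion on log-mean (frac 0.4) is the
shrinkage target, with empirical-Bayes weighting at prior df 10 against
the residual df. The test statistic is the NB deviance drop from the
one-mean to the two-mean model scaled by a squeezed quasi-dispersion
(deviance/df shrunk toward its lowess trend, prior df 10), referred to
F(1, residual + prior df). log2FC uses group abundances with a 0.125
pseudo-count. On null simulations the empirical type-I error at nominal
0.01 sits in [0.005, 0.02]; power at |log2FC| = 2, dispersion 0.1, 4 vs 4
is ≥0.8; and on a shared fixture the p-values and fold changes track the
reference edgeR QL implementation (log-p correlation > 0.9, fold-change
correlation > 0.99), which the test suite runs through Rscript as an
independent oracle.

## Problem sizes

The bundled benchmarks run at desk scale by design: a 2 Mb nuclear genome
with 12 planted elements, the 67,195 bp mitogenome at 50× long-read and
100× short-read coverage, 100,000 Hi-C pairs over ten to sixteen 600 kb
chromosomes, and 2,000–3,000-gene count matrices. These sizes were chosen
so every property that matters is measured with comfortable statistical
margin; the acceptance script reports the n used alongside each value.

## Known limitations

- The internal aligner is not a general-purpose mapper: no spliced
  alignment, no supplementary alignments, multi-mapping capped per k-mer.
- Read simulation has no platform-specific error structure; diploidy and
  heteroplasmy beyond a single planted site are not modelled.
- Hi-C simulation does not model restriction-fragment religation chemistry
  or matrix balancing; background windows substitute for sub-contigs.
- The QL machinery fixes prior degrees of freedom at 10 instead of
  estimating them; exact agreement with any published DE package is a
  non-goal.
- Repeat decomposition assumes direct (same-strand) tandem arrays;
  inverted repeats and dispersed repeats are out of scope.
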