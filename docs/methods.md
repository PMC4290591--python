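# Methods

This note documents the model behind `miredit`, the parameters that matter,
the numerical choices, what the synthetic data does and does not emulate,
and the known limitations.

## The statistical model

A sequenced base disagrees with its hairpin template either because of a
sequencing error or because the molecule genuinely differs (editing,
mutation, non-templated addition). At a hairpin position with weighted
coverage *n* and weighted non-reference count MER, the observed fraction
*p₀* = MER/*n* is compared with the expected error rate *p*ₑ through the
one-sample proportion statistic

    Z = (p₀ − pₑ) / sqrt(pₑ (1 − pₑ) / n),

treated as standard normal under the error-only null. The p-value is the
**upper tail only**: an excess of non-reference reads is the only
alternative of interest, and a one-sided test is strictly more sensitive to
it. Within each library, p-values of all candidate tallies (every
(position, alternative) with positive coverage) form one Benjamini–Hochberg
family; the family is the set of tests actually performed, which is the
least arbitrary choice available.

*p*ₑ is the coverage-weighted mean of per-base phred errors (10^(−q/10)) at
the position, **floored at 0.01**. The floor corresponds to the phred-20
base-quality threshold: bases below phred 20 are excluded from the tallies
altogether, so 1% is the largest error rate a counted base can have, and
using it as a floor keeps the test conservative — important for collapsed
inputs whose per-base qualities are synthetic constants.

### Accuracy of the normal approximation

The normal tail tracks the exact binomial tail to within a factor of ~3
when the expected error count *n*·*p*ₑ is at least ~3 and the excess is
moderate (Z ≲ 2); the property test asserts exactly that envelope. For
smaller expected counts or far tails the uncorrected normal approximation
can be off by a factor of 5 or more — irrelevant for calling (those sites
are far beyond any threshold) but worth knowing if the printed p-values are
interpreted literally.

## Calling criteria

A site is significant when, within one library, (i) MER ≥ 10 supporting
reads, (ii) *p₀* ≥ 5%, and (iii) BH-corrected p < 0.05. Both MER and *n*
are weighted sums and may be fractional; the support criterion compares the
weighted MER (a flag-equivalent raw-count mode is deliberately not offered —
weighting is the whole point of the cross-mapping correction). Sites in the
last positions of the mature 3' end are **not** excluded: 3' editing is one
of the things the pipeline exists to find, so the classical third exclusion
criterion for editing sites is dropped deliberately.

## Alignment

The read-to-hairpin aligner is an affine-gap Smith–Waterman: match +4,
mismatch −3, a gap of length *k* costs gap_open + *k*·gap_extend = −4 − 2*k*
(opening is a fee separate from per-base extension; the first gap base
therefore costs −6). Traceback ties prefer substitution over
deletion-from-read over insertion-in-read, yielding one deterministic
alignment. The default minimum score of 50 corresponds roughly to a 14-nt
perfect core and filters spurious seeded hits.

Candidate hairpins come from an exact k-mer index. The standalone seeding
function defaults to k = 12 (a BLAST-like word size), but the pipeline
default is **seed_k = 8**: a 22-nt read with a single central mismatch
shares no 12-mer with its hairpin, and the edited reads are precisely the
ones the pipeline must not lose. k = 8 guarantees a shared word for any
≤ 25-nt read with up to two well-separated differences, at negligible cost
on hairpin-sized references.

Local alignment drops trailing mismatching bases (they lower the score), yet
those bases are where 3' non-templated additions live. The pileup therefore
re-attaches each read's unaligned 3' tail column by column: against the next
templated hairpin positions where available, and as soft columns
(reference "−") past the hairpin end.

Genome mapping is exact-occurrence search of the read (both strands) —
appropriate because the genome pass exists only to count loci and feed the
cross-mapping correction, and reads are short. An importer for
Bowtie-default-format alignment files lets an external aligner take over
for real genomes, where exact search would miss mismatched loci.

## Cross-mapping correction

Reads mapping to several near-identical loci start with uniform weights; at
each iteration a read's weight at a locus is set proportional to the
locus's expression — the weighted read count over the locus's footprint
window, i.e. all placements whose intervals overlap it — and renormalised.
Iteration stops when the largest weight change is below 10⁻⁶ or after 100
iterations (non-convergence warns and returns the last iterate; the map is
a monotone averaging and converges in a handful of iterations in practice).
The footprint window is the natural locality for "expression of the locus
this read came from"; a configurable fixed window would change little at
hairpin scale.

Two boundary rules complete the bookkeeping. Reads occurring at more than
100 genomic loci are discarded outright. Reads that align to a hairpin but
appear nowhere in the genome — the edited reads themselves, whose sequence
is not templated — are **missed reads**: if some genomic locus outscores
the hairpin alignment the read is neglected (weight 0 everywhere),
otherwise its count is divided evenly across its best-scoring loci. Per
read, weights therefore sum to exactly 1, or to 0 for neglected/discarded
reads.

## 3'-tail coverage (terminator evidence)

For a position in the 3'-tail region (past a mature 3' end), a read whose
alignment stops at the immediately preceding position is counted toward the
position's coverage: a read ending exactly at the mature 3' end is direct
evidence of an unmodified 3' end. Without this rule the denominator at a
tail position would contain only the (few) reads extending past the mature
end, and the MEP of a 30% adenylation event would read ~100%. With it, MEP
at tail positions is the fraction of transcripts carrying the addition,
which is the quantity of biological interest. The tail region extends
`tail_window` = 6 positions past a mature 3' end (additions are
overwhelmingly 1–3 nt) and everything beyond the hairpin's own 3' end.

## Classification

Each significant site receives exactly one category, tested in order:

1. **Pseudo** — the site's tally is recomputed from the pileup restricted to
   reads with cross-mapping weight ≥ 0.05; if the filtered tally no longer
   meets the support/fraction criteria with raw p < α, the original
   significance was an artefact of abundant low-weight multi-mapped reads.
   Recomputing (rather than flagging on weight alone) matters because a
   site can be supported by a mixture of confident and ambiguous reads.
   The raw p-value is compared against α in this counterfactual because the
   BH family cannot be meaningfully re-formed for a single filtered site;
   in practice the support criterion decides.
2. **SNP** — exact (hairpin, position, ref, alt) match in the known-SNP
   table.
3. **3'-A / 3'-U / 3'-Other** — position in the 3'-tail region (as above),
   split by the added nucleotide. This outranks A-to-I/C-to-U: an A→g
   signature just past the mature end is far more plausibly adenylation of
   a templated-A-adjacent end than editing, and positional evidence beats
   substitution identity there.
4. **A-to-I** — reference A, alternative g (inosine base-pairs as G).
5. **C-to-U** — reference C, alternative u.
6. **Other** — everything else, including read-borne insertions
   (reference "−") inside the mature.

Known-editing (DARNED-style) tables annotate the report; they never drive
classification. When libraries disagree on a category the library with the
smallest corrected p-value decides.

## Coordinates, alphabets, naming

All hairpin coordinates are 1-based inclusive on the miRBase hairpin record
(positions in site names count from the hairpin 5' end). Sequences are
stored internally as DNA (U→T on input); reports render the RNA alphabet,
reference upper-case and alternative lower-case:
`hsa-mir-376a-1_49_A_g`, `hsa-mir-378c_30_-_g` (an insertion of g at
position 30). Sites absent from a library print MER 0.00, MEP 0.0,
FDR_P 1.00E+00; corrected p-values below 10⁻³⁰⁰ print as 0.00E+00
(numerical underflow).

## Preprocessing choices

"Low-quality 3' tail" is interpreted as iterative 3'-end trimming while the
terminal base is below the phred threshold — the simplest rule consistent
with giving reads clean 3' ends; a `tail_mode="drop"` alternative removes
such reads whole. Adapter matching accepts the leftmost occurrence of the
full adapter anywhere, or a 3'-truncated prefix (≥ 5 nt) at the read end,
with a per-occurrence mismatch fraction ≤ 0.1; both knobs are exposed since
no single tolerance is canonical. Collapsing keeps sequences ≥ 18 nt,
sums counts, takes the per-position maximum phred across members, and
orders by descending count then sequence. Collapsed FASTA inputs without
qualities are assigned a constant phred 40 — collapsing happens after
quality trimming, so retained bases are high quality.

## The synthetic data

The simulator emulates the structure of a multi-library small-RNA
experiment: hairpins of 76–84 nt with a 5p mature arm at positions 10–31,
embedded once each in a padded genome; 200× coverage per mature arm per
library; reads with 5' (+0…+2) and 3' (±1) end jitter; per-base sequencing
error at 10^(−phred/10) (default phred 40) with uniform substitution to the
three alternatives; the 3' adapter appended and the read cut at a fixed
36 nt. Planted events are independent per read: substitutions at a given
rate, or single non-templated 3' additions. Hairpins carrying a 3'-addition
event keep fixed templated 3' ends so the addition is the only source of
variation past the mature end. The default experiment plants one event per
hairpin — A-to-I 20%, C-to-U 10%, 3'-A 30%, 3'-U 30%, SNP 100%,
a deliberately sub-threshold 2% edit — plus a 21-copy identical-hairpin
family edited at 30%.

The family is the cross-mapping stress case: with an exact-match genome
mapper, sub-0.05 weights at a hairpin can only arise from reads shared
across ≥ 21 near-identical loci, so every read of the family (unedited via
cross-mapping, edited via the missed-read even split) carries weight
1/21 ≈ 0.048 and the planted site surfaces at every copy as a Pseudo site.

What the simulator does **not** emulate: realistic expression distributions
across a miRNome, sequence-dependent error profiles, 5'-isomiR biology
beyond uniform jitter, multi-nucleotide tails, RNA secondary structure, or
reads from non-miRNA loci. Passing tests therefore demonstrate the
correctness of the machinery under controlled conditions, not calling
performance on real tissue libraries.

## Problem sizes

The standard simulated experiment is four libraries × 2,800 reads
(~100 unique sequences each after collapsing), eight single-copy hairpins
plus the 21-copy family. The full pipeline runs in a few seconds on one
CPU at these sizes; the scale was chosen so that every planted event is
recovered with comfortable statistical margins (≥ 3 binomial SE) while the
entire test suite stays interactive.

## Known limitations

- The internal genome mapper is exact-match: genomic loci differing from
  the read by even one base are invisible to the >100-loci and cross-mapping
  machinery unless an external Bowtie-format alignment file is supplied.
- Deletions from reads are aligned and scored but not called as sites (the
  category scheme has no deletion type; only insertions surface, as Other).
- The pseudo recomputation does not re-run BH on the filtered family (see
  above).
- Per-position error rates assume independence across reads and positions;
  systematic sequencer artefacts (e.g. homopolymer effects) will inflate
  *p*ₑ violations and are not modelled.
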