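# Methods

## Problem and approach

indelscout identifies insertions and deletions (indels) from
coordinate-sorted, indexed BAM alignments of paired-end short reads.  No
single evidence type covers the whole indel size range: split reads give
base-exact breakpoints but lose power as events grow beyond what a read
can span, while discordant read pairs detect large deletions (and, weakly,
insertions) but only bound the breakpoints to intervals.  indelscout is a
hybrid caller: it harvests both evidence types, clusters them in an
evidence graph, and merges split-read and paired-end calls that describe
the same event, so small and medium indels get exact breakpoints and
large deletions are still recovered.

## Fragment model

Each read group is summarised as `R(a, b, o)`: the expected outer-distance
(insert-size) interval `[a, b]` and the expected relative orientation `o`
of the mate that comes earlier on the chromosome versus the later one
(`'+-'` for a standard Illumina paired-end library).  A sequenced fragment
is `P(r1, r2, r, o, i)` with observed orientation `o` and outer distance
`i` (leftmost aligned base to rightmost aligned base across both mates).

`[a, b]` is estimated per read group from the first `sample_size`
(default 10 000) mapped pairs as `median ± k·1.4826·MAD` with `k = 3`
(`--sd-multiplier`), rounded outward.  The robust median/MAD form was
chosen over mean ± sd because chimeric fragments and pairs spanning real
deletions contaminate the upper tail; the MAD is insensitive to both.  The
scaled MAD is also kept as `sigma`, the spread estimate used as a noise
floor below.  Orientation is the sample mode.  Fewer than 100 usable
pairs in a group is a hard error; explicit `--insert-a/--insert-b`
overrides take precedence.

## Candidate classification

Walking the BAM in coordinate order (duplicates, QC-fails and
secondary/supplementary records skipped), each fragment falls into one of:

* **SR_PARTIAL** — properly paired (`o` matches, `a ≤ i ≤ b`) but one
  mate aligns with a gap (I/D CIGAR) or a soft-clip of ≥ `min_clip`
  (default 5 bp; shorter clips are treated as base-call noise).
* **SR_UNALIGNED_MATE** — exactly one mate aligned; the other is a
  split-read candidate anchored at the mate's position `mpos`.
* **PE_DISCORDANT** — both mates aligned with the expected orientation
  but `i < a` or `i > b` by more than `2·sigma`.  The `2·sigma` margin
  suppresses the tails of the insert distribution itself: with
  `b ≈ median + 3·1.4826·MAD` plus the margin, a concordant library
  essentially never produces discordant classifications, which is also
  what makes a clean no-indel dataset yield zero candidates.
* **NONE** — everything else.  In call mode, fragments where neither
  mate maps with MAPQ > 0 are NONE: with no unambiguous anchor there is
  nothing to realign against.  Tag mode (below) deliberately lifts this.

Wrong-orientation pairs (`'++'`, `'--'`, `'-+'`) are ignored rather than
modelled; they are inversion/duplication signatures, out of scope here.

## Split-read realignment

A candidate read is realigned in two stages against the reference window
`[mpos − b, mpos + b]` around its anchor:

1. **Diagonal seeding.** k-mers occurring exactly once in the read
   (k = 10, `--kmer-size`) vote for the diagonal `ref_pos − read_pos`;
   the diagonal with the most votes wins, ties broken by distance to the
   anchor, then leftmost.  Unique k-mers make homopolymers and short
   tandem repeats self-silencing.
2. **Second fragment.** The read segment left unexplained by the first
   diagonal is seeded again: downstream within `maxsrdelsize`
   (default 1 000 bp, `--max-sr-del`) when the unexplained tail is on the
   right, symmetrically upstream otherwise, with enough margin to also
   capture insertions (second diagonal *smaller* than the first).

The offset between the two diagonals fixes the event size exactly:
`diag_right − diag_left > 0` is a deletion of that size, `< 0` an
insertion.  The split point between the two read halves is then chosen to
maximise the number of matching bases (micro-homology at the junction
makes several split points equivalent; the leftmost maximal one is taken
and the final indel is left-aligned, i.e. shifted to the smallest
reference coordinate giving an identical alternate haplotype).  Each half
must align with ≥ `min_flank` (10) bases and ≥ 90% identity
(`--min-identity`), verified by a banded global alignment.

The banded aligner scores match +1, mismatch −2, gap open −4, gap
extend −1 (a gap of length L costs 4 + L), preferring one long gap over
scattered mismatches; it evaluates only cells within `W` (default 15) of
the seeded diagonal — O(N·W) time — and is verified in the test suite
against an independent unbanded Needleman–Wunsch oracle.

Two deliberate departures from the mate-anchored window: (i) clipped
mates of *discordant* pairs are realigned anchored on their **own**
aligned position, because for a deletion larger than `b` the mate-centred
window cannot contain the read's aligned flank — this is what lets large
deletions get exact breakpoints; (ii) reads whose primary alignment
already contains a gap are realigned from sequence anyway, so the caller
never simply trusts the upstream mapper's gap placement.  The realigner
resolves one indel per read; reads covering several indels at once are a
known failure mode of any split-read method and are not specially
handled (the simulator's spacing invariant keeps them out of the study
conditions, so passing tests say nothing about such regions).

Unaligned mates have arbitrary stored orientation, so both the sequence
and its reverse complement are tried and the higher-scoring
interpretation kept.

## Paired-end evidence

A discordant pair with `i > b` implies a deletion of size in
`[i − b, i − a]` (capped at `maxpedelsize`, default 100 000 bp) lying
inside the unsequenced inner span between the mates; `i < a` implies an
insertion with size bounds `[a − i, b − i]`.  Insertion evidence from
pairs alone is size-ambiguous (an insertion can shrink `i` by at most
about a read length), so a paired-end-only insertion call is kept only
when its minimum size clears `2·sigma`; otherwise it must merge with
split-read support or it is dropped.

## Evidence graph and calls

Per chromosome, every evidence record is a vertex.  Split-read vertices
are joined iff their left-aligned breakpoints (and inserted sequence) are
identical — left-alignment first, or homopolymer jitter would shatter
components.  Paired-end vertices are joined iff a single placement
(breakpoint, size) satisfies both pairs' constraints, implemented as a
box intersection over the size interval and the shared inner span.
Split-read and paired-end vertices are never joined directly.

Each connected component is one putative variant; sequencing errors and
ambiguous alignments keep real components from being cliques, so a
maximal clique is grown greedily (seed with the highest-degree vertex,
repeatedly add the highest-degree vertex adjacent to all members; ties by
leftmost breakpoint, then index) and provides the breakpoints, while the
entire component counts as support (`NSR`/`NPE`).  For paired-end
cliques the call is placed at the midpoint of the intersection of all
members' admissible intervals, and `CIPOS`/`CIEND` record that
intersection.  Interval intersection here is safe because pairwise
intersecting 1-D intervals always share a common point; the rare joint
infeasibility across the two axes is clamped defensively.

A final sorted left-to-right pass merges an adjacent split-read-only and
paired-end-only call of the same type when the exact breakpoints fall
inside the paired-end confidence intervals and the exact size satisfies
every supporting pair's own `[i − b, i − a]` bound.  The merged call
keeps the exact breakpoints and pools support; the pass is idempotent.

## Annotation, filtering, VCF

Each call is annotated across its breakpoint region (the deleted
interval padded by one base on each side — a homozygous deletion has no
reads strictly inside it, its spanning reads are clipped *at* the
breakpoints; for insertions, the two bases straddling the insertion
point): mean depth, RMS mapping quality, MAPQ-0 read count, and
per-supporting-read flank lengths.  Filters (defaults: support ≥ 2,
RMS MAPQ ≥ 10, MAPQ-0 fraction ≤ 0.5, depth bounds off) record the
failed threshold for every rejection and are order-independent.

Output is VCF 4.2, written deterministically: explicit REF/ALT for
events ≤ 1 000 bp (POS on the base before the event; events at a contig
start anchor on the following base), symbolic `<DEL>`/`<INS>` with `END`
above that cutoff.  INFO carries SVTYPE, END, SVLEN, NSR, NPE, AVGDP,
RMSMQ, MQ0 and CIPOS/CIEND when nonzero.  All coordinates are 0-based
half-open internally and converted to 1-based only at emission.

## Tag mode

Given calls from sample A and a BAM for sample B (normal/tumor pairs,
trios), each call is tagged present/absent in B by scanning all reads in
a window (default: B's insert maximum `b`) around the breakpoints —
*including* MAPQ-0, secondary/supplementary and duplicate records, the
opposite of call mode, because the question is "is there any evidence at
all", not "can we discover this de novo".  Evidence is (i) a gapped
alignment reproducing the identical left-aligned indel, (ii) a
split-realignment of a clipped or unaligned read yielding the same
breakpoints (insertion sequence compared by length, tolerating base
errors), or (iii) a discordant pair, beyond the `2·sigma` noise floor,
whose size bounds admit the call and whose inner span contains it.  One
supporting read flips the tag to present, so adding reads to B is
monotone (absent → present only).  Calls on contigs absent from B are
tagged absent with a warning.

## Synthetic data

The simulator defines the study conditions: homozygous, well-separated
implants (non-overlapping, ≥ 2 read lengths apart) in a uniform-random
reference; Illumina-style '+-' pairs, 100 bp reads, insert
Normal(500, 30) truncated at two read lengths, 20× coverage, uniform
fragment starts, substitution errors at 0.1% by default (acceptance runs
use 0 where a criterion is stated error-free).  Truth records are stored
left-aligned so breakpoint-exact comparison is well defined.

Reads are *placed*, not mapped: a coordinate map from the mutated
haplotype back to the reference decides each read's signature — gapped
CIGAR when a read spans an indel ≤ 30 bp with ≥ 10 bp anchors on both
sides (mirroring what a mapper resolves in-line), soft-clips at the event
edge otherwise, unmapped-with-placed-mate for reads inside large
insertions, and inflated/shrunken outer distances for pairs straddling
large events.  MAPQ is 60 with a configurable MAPQ-0 fraction.  The
10 bp gap/clip anchor matches the caller's `min_flank` so every emitted
signature is in principle consumable.  Not emulated: mapper-specific
mismapping, indel-induced soft errors, quality-score profiles, PCR
duplicates, heterozygosity, overlapping events.  Passing tests therefore
demonstrate algorithmic correctness on clean signatures, not robustness
to real-library artefacts.

The evaluator marks a deletion call validated iff the overlap covers at
least half of the truth interval *and* half of the call interval
(reciprocal overlap), with greedy best-overlap 1:1 matching.  The
overlap rule is stated for deletions only, so insertions use a rule of
this package's own: position within one insert-sd (30 bp) and length
within 25%.  FP% is reported against observed calls and FN% against the
truth count, and the CLI evaluator prints both denominators, since either
convention appears in published comparisons.

## Problem sizes and numerical choices

The bundled acceptance computations run at desk scale, chosen so the
whole suite completes in minutes on one core while still exercising every
code path at the stated library parameters: a 1 Mb genome with 50 + 50
implants of 1–50 bp for the headline recall/FP numbers, 300 kb with ten
300–800 bp deletions for the paired-end path, and 150 kb three-way
designs for tag mode.  Determinism: call mode has no random step; all
simulation randomness flows from a single integer seed; ties are broken
lexicographically everywhere (diagonal selection, clique growth, merge
order, VCF sorting), so repeated runs are byte-identical.

## Known limitations

* One indel per read; nearby events whose signatures share reads degrade
  recall.
* Insertions longer than `read_length − 2·min_flank` (~80 bp at default
  settings) cannot be sequence-resolved; they surface, if at all, as
  size-bounded paired-end insertion calls.
* No genotyping (the caller does not distinguish het from hom), no local
  assembly fallback, no inversion/translocation handling, and no
  multi-sample joint calling.
* `[a, b]` estimation assumes a unimodal insert distribution per read
  group; mixed-insert libraries should be split into read groups.
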