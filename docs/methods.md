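# Methods

## Input model and coordinate conventions

The pipeline starts downstream of alignment. Its primary input is a
headerless 14-column tab-separated chimeric-junction table (donor
chromosome/breakpoint/strand, acceptor chromosome/breakpoint/strand, a
junction code, two repeat lengths, read name, and per-segment start +
CIGAR), optionally accompanied by the matching chimeric SAM for read
sequences, an SJ-style 9-column split-read table (or SAM) for linear
junction counts, one to three ordered exon lists (GTF / BED6 / BED12), and a
genome FASTA.

All coordinates are 1-based inclusive internally; BED input/output is
converted at the boundary. Breakpoints are assumed to name the first
excluded base beyond each segment, so on the plus strand a circle is
`[acceptor breakpoint + 1, donor breakpoint - 1]` (mirrored on minus). The
aligner's convention is not self-describing, so the offset pair `(+1, -1)`
is an explicit config value; a wrong pair is caught by the start > end check
and by the simulator round-trip test rather than silently shifting every
circle by one base.

## CCR selection

A chimeric record is a circular chimeric read (CCR) iff both segments share
chromosome and strand, sit in inverted genomic order for that strand, each
aligns at least `min_segment` read bases (default 15, matching the smallest
segment the aligner was allowed to map), and the junction code marks a
within-read junction (negative codes are junctions spanned between two
mates, which contain no circle; they are post-filtered rather than assumed
absent). Reads appearing in more than one chimeric line have more than two
segments or ambiguous placements and are dropped entirely. Mates are treated
as independent single-end reads; mate identity is kept only for diagnostics
such as the per-locus reads-1 / reads-2 split, and a mate whose own mapping
disagrees is never a reason to reject a CCR (sequencing is unreliable in
GC-rich regions, and systematic mate rejection would selectively erase
exactly those loci).

The junction code is never used as a filter: intron-derived and sub-exonic
junctions almost never show GT/AG, so motif filtering would remove the
classes this package exists to find. Codes are carried through to output.

## LACs and the abundance threshold

CCR junctions are clustered by exact (chromosome, strand, start, end); each
cluster is a LAC. Two read-support numbers are kept: the raw CCR count and
the number of *distinct* alignment fingerprints, a fingerprint being
(segment-1 start, segment-1 CIGAR, segment-2 start, segment-2 CIGAR, read
length). Read length is part of the fingerprint because datasets may mix
read lengths (e.g. 100 and 125 nt) and two same-start reads of different
lengths are different molecules. The retained set keeps LACs with
`ccr_count >= 5` and `distinct >= 4` (both configurable); the distinct
criterion stops PCR duplicate towers from passing the threshold.

## Exonic labelling (standard + iterative)

Boundary sets are built from each exon list: every exon contributes its
genomic start (a candidate circle 5' edge) and genomic end (candidate 3'
edge), strand-aware, side-typed. Matching is exact; edges may come from
different genes (read-through or undescribed transcripts), recorded in the
label's evidence.

Round 1 labels every LAC with at least one matching known boundary
(`standard_both` when both edges match, `iterative_one_known` otherwise).
The unmatched edge of a one-edge LAC is promoted as a *novel* boundary —
side-typed, so a novel start can only ever match later LAC starts.
Subsequent rounds label LACs touching novel entries (`iterative_novel_match`)
and promote their unmatched edges in turn, until a round adds no label.
Within a round, matches are evaluated against the boundary set as it stood
at the round's start and promotions are applied between rounds, making the
result independent of LAC order. A cap of 20 rounds guards against
pathological chains (a cap violation raises; it does not truncate silently).
Promotion is unconditional by default; `min_promote_support` can require a
minimum CCR count before a LAC's novel edge is promoted.

The cascade runs the iterative labeller over the ordered exon lists
(reference annotation, then external lncRNA exons, then candidate novel
exons), removing labelled LACs between lists, so a circle matching two lists
is attributed to the earlier one. Novel boundaries never carry across lists.
Exons identical across lists are kept only in the lowest list for the same
reason.

## Non-canonical cascade

Remaining LACs are tested in decreasing order of specificity; the order
enforces mutual exclusivity:

1. **intron circle** — coordinates equal an intron exactly;
2. **lariat-derived intronic** — the 5' edge equals an intron's first
   transcribed base (strand-aware) and the other edge lies strictly inside
   with `tail_gap >= min_tail` (default 1). A full intron can never be
   called a lariat because its tail gap is 0. `branch_window` optionally
   caps the tail gap; it defaults to 0 (disabled) because no firm maximal
   branch-point distance is assumed, and no minimum circle size is applied
   to intron-derived classes;
3. **sub-exonic** — both edges inside the single exon of a mono-exonic gene,
   not equal to the full exon (that is an ordinary mono-exonic exonic
   circRNA, caught by boundary matching), and at least `min_subexonic_size`
   (default 55 nt: with 15-nt minimum segments and the read lengths modelled
   here, smaller LACs cannot be delimited reliably). Sizes above 70 nt are
   flagged confident;
4. otherwise **unallocated**, reported for manual review.

Introns are derived per transcript from gaps between consecutive exons and
unioned per gene; only coding genes' introns are searched. All matching is
strand-aware throughout — no anti-sense matching. Sub-exonic LACs of one
gene are partitioned into sets by single-linkage on positive interval
overlap (a sweep over sorted intervals, verified against graph connected
components in tests).

## Junction-sequence refinement

When h bases at the circle's 5' edge repeat immediately after its 3' edge
(microhomology), the aligner can place the junction at any of h+1 coordinate
pairs. `shift_equivalent` tests whether two LACs differ by a common shift
`s` (|s| <= `max_shift`, default 5) whose flanking bases satisfy exactly
this repeat condition, which is equivalent to both coordinate pairs
reconstructing the same junction-spanning read. Shift-equivalent LACs are
merged into circularisation events by single linkage.

Within an event, read-derived junction-sequences (up to k = 15 read bases
each side of the split, truncated on short sides) are clustered:
sequences join a cluster when their junction-anchored overlap is identical
except for at most `mismatch_tol` (default 2) substitutions within
`mismatch_window` (default 5) nt of the junction — reverse transcription
across a lariat's 2'-5' bond is locally error-prone, so near-junction
mismatches are noise, while any further-out difference marks a genuinely
distinct co-located circRNA. Identical sequences are pooled first so the
consensus, not a mutated singleton, anchors each cluster. The event's
number of distinct circRNAs is the cluster count (1 when no read sequences
are available). Coordinate shifts between members need no sequence
realignment: by construction the microhomology makes shifted reads'
junction windows identical.

A read at least twice as long as its claimed circle must traverse the
junction twice; `check_multipass` flags single-junction reads on such small
circles as inconsistent. `splice_motif` reports the strand-oriented
donor/acceptor dinucleotides flanking a junction (GT/AG = canonical) for
annotation only — never filtering.

## Reporting

All percentages are computed from counts at report time and rounded half
away from zero (the convention that reproduces the published summary values
digit-for-digit); one derived share is floored where the published summary
floors it. The circular-to-linear balance of an intronic locus is
`round(CCR/SR)` with a zero split-read count reported as infinite rather
than an error. The report validates that per-class LAC and CCR counts
partition the retained totals.

## Synthetic data

The generator emulates the study conditions so the whole cascade is testable
offline. Defaults: 3 chromosomes; 15 coding multi-exonic genes (4-6 exons of
80-300 nt, introns 100-800 nt), 4 multi-exonic lncRNA genes (exons published
only in list 2), 3 "novel" genes (exons only in list 3), 8 mono-exonic nc
genes (exons 100-600 nt — sub-exonic hosts are short). Planted circles: 100
exonic (20% with one edge pushed 5-30 nt into the adjacent intron to stand
in for an uncharacterised exon boundary), 50 lariat (branch 15-60 nt
upstream of the intron 3' end, a standard branch-point geometry, clipped so
circles stay >= 56 nt), 10 intron circles, 40 sub-exonic (55-250 nt,
strictly inside their exon) — about 200 circles, the scale used throughout
the tests. Per circle, 8-40 junction-spanning reads mixing 100- and 125-nt
lengths at 1:3 (three quarters of the modelled dataset's reads are 125 nt).

Read emission draws the (read length, split) alignment combinations
*without replacement*, so with the duplicate rate at 0 every read has a
distinct fingerprint and read counts are capped at the number of physically
distinguishable alignments — real for small circles. Noise knobs (all 0 by
default; `with_noise()` sets study-realistic values): PCR duplicate rate
0.2; junction microhomology lengths 0-3 (weights 0.5/0.2/0.2/0.1) with 25%
of reads reported at a shifted coordinate; near-junction substitution rate
0.2 on lariat reads (1-2 substitutions within 5 nt of the split); 10% of
circles carry a second junction variant (3 untemplated bases inserted at the
junction); a mate-1 dropout rate mimicking GC-related sequencing failure
(default 0, exercised in tests at 0.3-0.8). Reads at least twice the circle
length are emitted to the SAM only, with two junction passages in their
sequence: a two-pass read has more than two segments and cannot be
represented in the two-segment chimeric table — mirroring why an aligner
restricted to two segments reports only shorter reads at such loci.

Simulator guarantees: planted coordinates are unique; non-exonic circle
edges avoid every exon-boundary position (known or promoted) so the exonic
cascade cannot capture them; microhomology is planted by editing the genome
before any read is generated, and an edit that would overwrite another
circle's homology region truncates instead (the recorded homology length is
the effective one). Everything is driven by one seed; fixed config means
byte-identical output files.

What the simulator does *not* model: base-quality, expression-level
realism, rRNA contamination, true alignment (reads are emitted as aligned
records directly, so variant-carrying reads keep clean CIGARs a realigner
would soft-clip), or annotation errors beyond withheld exon lists. Passing
tests therefore demonstrate the correctness of the selection, clustering,
labelling and merging logic under the stated read model — not robustness to
every artefact of real aligner output.

## Limitations

* Chimeras with more than two segments are out of scope (dropped), so
  circles shorter than half the read length are only observable through the
  multipass diagnostic, not called directly.
* The iterative labeller trusts single known edges; with
  `min_promote_support = 0` a spurious one-edge LAC can seed novel
  boundaries. The support knob exists for stricter runs.
* Junction-sequence clustering is greedy (support-ranked); ties are broken
  deterministically but a different tolerance could split or merge
  borderline variant pairs.
* The branch-point geometry of lariat circles is parameterised, not
  inferred from sequence; no de-novo branch-point calling is attempted.
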