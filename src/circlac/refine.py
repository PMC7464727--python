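"""Read-sequence-level refinement of circular junctions.

Alignment of a junction-spanning read is ambiguous when the bases on either
side of the junction repeat across the circle's two borders (microhomology):
the aligner can shift the junction point by up to the homology length, so a
single circularisation event surfaces as several LACs whose coordinates
differ by a few bases.  This module reconstructs junction-spanning genomic
sequence to detect such shift-equivalent LAC pairs and merges them (single
linkage) into circularisation events.  Within one event, the read-derived
junction-sequences are clustered — tolerating a few substitutions right next
to the junction, where reverse transcription across a 2'-5' link is
error-prone — and the number of clusters is the number of distinct circRNAs
the event produced.  Circles shorter than half the read length should show
the junction twice in one read; reads that do not are flagged inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .chimeric import ChimericRecord, cigar_query_length, _parse_cigar
from .lac import LAC

__all__ = [
    "GenomeView",
    "JunctionSequence",
    "CircularizationEvent",
    "read_split_point",
    "extract_junction_sequence",
    "junction_genome_sequence",
    "shift_equivalent",
    "merge_events",
    "check_multipass",
    "splice_motif",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeView:
    """1-based inclusive access to genome sequence (pyfaidx or dict backed)."""

    def __init__(self, source):
        # source: pyfaidx.Fasta-like mapping of chrom -> sliceable sequence
        self._src = source

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive, uppercase."""
        if start < 1:
            raise ValueError(f"genome fetch before position 1: {chrom}:{start}")
        try:
            seq = self._src[chrom][start - 1 : end]
        except KeyError as exc:
            raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
        seq = str(seq)
        if len(seq) != end - start + 1:
            raise ValueError(f"genome fetch out of bounds: {chrom}:{start}-{end}")
        return seq.upper()


@dataclass
class JunctionSequence:
    """A read-derived nucleotide string spanning a circular junction.

    ``left_len`` bases precede the junction (the circle's 3' side), the rest
    follow it (the circle's 5' side); both sides are truncated to at most k.
    """

    sequence: str
    left_len: int
    support_r1: int = 0
    support_r2: int = 0

    @property
    def support(self) -> int:
        return self.support_r1 + self.support_r2


@dataclass
class CircularizationEvent:
    """One or more shift-equivalent LACs describing a single locus's circles."""

    member_lacs: list[LAC]
    representative: tuple[str, str, int, int]  # chrom, strand, start, end
    junction_sequences: list[JunctionSequence] = field(default_factory=list)
    n_distinct_circrnas: int = 1


def read_split_point(rec: ChimericRecord) -> int:
    """Read offset of the circular junction: query bases consumed by segment 1.

    Segment CIGARs carry the other segment as a soft clip, so the aligned
    prefix length of segment 1 (leading clip + aligned bases) is the split.
    Raises ``ValueError`` when the two CIGARs disagree on the read length.
    """
    ops1 = _parse_cigar(rec.seg1_cigar)
    if cigar_query_length(rec.seg1_cigar) != cigar_query_length(rec.seg2_cigar):
        raise ValueError(
            f"segment CIGARs of {rec.read_id} disagree on read length: "
            f"{rec.seg1_cigar} vs {rec.seg2_cigar}"
        )
    split = 0
    leading = True
    for n, op in ops1:
        if op == "S" and not leading:
            break  # trailing clip = segment 2
        if op in "MIS=X":
            split += n
        leading = False
    if split <= 0 or split >= cigar_query_length(rec.seg1_cigar):
        raise ValueError(f"cannot locate junction in read {rec.read_id}")
    return split


def extract_junction_sequence(
    rec: ChimericRecord, k: int = 15, split: Optional[int] = None
) -> JunctionSequence:
    """Junction-sequence of one CCR: up to k read bases each side of the split.

    The read must carry its sequence (``read_seq``); the split is taken from
    the segment CIGARs unless given.  Sides shorter than k are truncated, so
    the returned string has length <= 2k.
    """
    if rec.read_seq is None:
        raise ValueError(f"read {rec.read_id} has no sequence attached")
    if split is None:
        split = read_split_point(rec)
    if not 0 < split < len(rec.read_seq):
        raise ValueError(
            f"junction split {split} outside read {rec.read_id} "
            f"({len(rec.read_seq)} nt)"
        )
    left = rec.read_seq[max(0, split - k) : split]
    right = rec.read_seq[split : split + k]
    js = JunctionSequence(sequence=left + right, left_len=len(left))
    if rec.mate == 1:
        js.support_r1 = 1
    else:
        js.support_r2 = 1
    return js


def junction_genome_sequence(
    genome: GenomeView, chrom: str, strand: str, start: int, end: int, k: int = 15
) -> str:
    """Genomic reconstruction of the circle's junction-spanning sequence.

    Concatenates the circle's last k bases and first k bases in transcript
    orientation (reverse-complemented on the minus strand).  For circles
    shorter than k each side is the whole circle.
    """
    size = end - start + 1
    kk = min(k, size)
    tail = genome.fetch(chrom, end - kk + 1, end)
    head = genome.fetch(chrom, start, start + kk - 1)
    if strand == "+":
        return tail + head
    return revcomp(head) + revcomp(tail)


def shift_equivalent(
    lac_a: LAC, lac_b: LAC, genome: GenomeView, max_shift: int = 5
) -> Optional[int]:
    """Shift making the two LACs describe the same junction, or None.

    Returns s = startB - startA when both edges differ by the same s with
    |s| <= max_shift and the s bases flanking the junction repeat across the
    circle's two borders (microhomology of length >= |s|), which makes the
    two junction-spanning genomic sequences identical.  shift 0 (identical
    coordinates) is always equivalent.
    """
    if lac_a.chrom != lac_b.chrom or lac_a.strand != lac_b.strand:
        return None
    s = lac_b.start - lac_a.start
    if lac_b.end - lac_a.end != s or abs(s) > max_shift:
        return None
    if s == 0:
        return 0
    lo, hi = (lac_a, lac_b) if s > 0 else (lac_b, lac_a)
    h = abs(s)
    # bases entering the circle at the 5' edge must equal those leaving at 3'
    head = genome.fetch(lo.chrom, lo.start, lo.start + h - 1)
    tail = genome.fetch(lo.chrom, lo.end + 1, lo.end + h)
    return s if head == tail else None


def _cluster_junction_sequences(
    seqs: Sequence[JunctionSequence],
    mismatch_tol: int = 2,
    mismatch_window: int = 5,
    min_overlap: int = 8,
) -> list[JunctionSequence]:
    """Greedy clustering of junction-sequences, junction-anchored.

    Sequences are compared over their overlap around the junction; two
    sequences belong to one circRNA when the overlap matches everywhere
    except for at most ``mismatch_tol`` substitutions, all within
    ``mismatch_window`` nt of the junction (reverse-transcriptase infidelity
    near the 2'-5' link).  Any mismatch further out, or an overlap shorter
    than ``min_overlap``, separates them.  Returns one representative (the
    best-supported, longest) per cluster with pooled support.
    """

    def compatible(a: JunctionSequence, b: JunctionSequence) -> bool:
        left = min(a.left_len, b.left_len)
        right = min(len(a.sequence) - a.left_len, len(b.sequence) - b.left_len)
        if left + right < min_overlap:
            return False
        bad = 0
        for off in range(-left, right):
            ca = a.sequence[a.left_len + off]
            cb = b.sequence[b.left_len + off]
            if ca != cb:
                distance = -off if off < 0 else off + 1  # nt from the junction
                if distance > mismatch_window:
                    return False
                bad += 1
                if bad > mismatch_tol:
                    return False
        return True

    # pool identical sequences first so the consensus (not a mutated
    # singleton) anchors its cluster
    pooled_by_seq: dict[tuple, JunctionSequence] = {}
    for js in seqs:
        key = (js.sequence, js.left_len)
        if key in pooled_by_seq:
            pooled_by_seq[key].support_r1 += js.support_r1
            pooled_by_seq[key].support_r2 += js.support_r2
        else:
            pooled_by_seq[key] = JunctionSequence(
                js.sequence, js.left_len, js.support_r1, js.support_r2
            )
    clusters: list[JunctionSequence] = []
    members: list[list[JunctionSequence]] = []
    for js in sorted(
        pooled_by_seq.values(), key=lambda j: (-j.support, -len(j.sequence), j.sequence)
    ):
        for i, rep in enumerate(clusters):
            if compatible(rep, js):
                members[i].append(js)
                break
        else:
            clusters.append(js)
            members.append([js])
    out = []
    for rep, mem in zip(clusters, members):
        pooled = JunctionSequence(
            sequence=rep.sequence,
            left_len=rep.left_len,
            support_r1=sum(m.support_r1 for m in mem),
            support_r2=sum(m.support_r2 for m in mem),
        )
        out.append(pooled)
    return out


def merge_events(
    lacs: Sequence[LAC],
    genome: Optional[GenomeView],
    junction_sequences: Optional[Mapping[str, Sequence[JunctionSequence]]] = None,
    max_shift: int = 5,
    k: int = 15,
    mismatch_tol: int = 2,
    mismatch_window: int = 5,
) -> list[CircularizationEvent]:
    """Merge shift-equivalent LACs into circularisation events (single linkage).

    ``junction_sequences`` maps lac_id to the junction-sequences of its reads
    (e.g. from :func:`extract_junction_sequence`); an event whose reads carry
    no sequence is reported as one distinct circRNA.  Without a genome, no
    merging happens and every LAC is its own event.

    The number of distinct circRNAs of an event is the number of
    junction-sequence clusters after aligning members onto the event's
    representative coordinates (coordinate shifts between members are exactly
    compensated by the microhomology, so sequences are compared as-is).
    """
    lacs = sorted(lacs, key=lambda l: (l.chrom, l.strand, l.start, l.end))
    parent = list(range(len(lacs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if genome is not None:
        for i, a in enumerate(lacs):
            for j in range(i + 1, len(lacs)):
                b = lacs[j]
                if (b.chrom, b.strand) != (a.chrom, a.strand) or b.start - a.start > max_shift:
                    break
                if shift_equivalent(a, b, genome, max_shift=max_shift) is not None:
                    union(i, j)

    groups: dict[int, list[LAC]] = {}
    for i, lac in enumerate(lacs):
        groups.setdefault(find(i), []).append(lac)

    events: list[CircularizationEvent] = []
    for members in groups.values():
        # representative: the best-supported member's coordinates
        rep = max(members, key=lambda l: (l.ccr_count, -l.start))
        seqs: list[JunctionSequence] = []
        if junction_sequences:
            for m in members:
                seqs.extend(junction_sequences.get(m.lac_id, ()))
        if seqs:
            clustered = _cluster_junction_sequences(
                seqs, mismatch_tol=mismatch_tol, mismatch_window=mismatch_window
            )
            n_distinct = len(clustered)
        else:
            clustered = []
            n_distinct = 1
        events.append(
            CircularizationEvent(
                member_lacs=members,
                representative=(rep.chrom, rep.strand, rep.start, rep.end),
                junction_sequences=clustered,
                n_distinct_circrnas=n_distinct,
            )
        )
    events.sort(key=lambda e: e.representative)
    return events


def check_multipass(read_length: int, circle_size: int, n_junctions: int = 1) -> str:
    """Consistency of a read with the claimed circle size.

    A read at least twice as long as the circle must traverse the junction at
    least twice; observing a single junction passage in such a read is
    evidence against the claimed circle ("inconsistent").  Returns
    "consistent" or "inconsistent".
    """
    if circle_size <= 0 or read_length <= 0:
        raise ValueError("read length and circle size must be positive")
    if read_length >= 2 * circle_size and n_junctions < 2:
        return "inconsistent"
    return "consistent"


def splice_motif(
    genome: GenomeView, chrom: str, strand: str, start: int, end: int
) -> tuple[str, bool]:
    """Strand-oriented donor/acceptor dinucleotides flanking a circular junction.

    For a back-splice of [start, end], the donor site follows the circle's 3'
    edge and the acceptor site precedes its 5' edge (in transcript
    orientation).  Returns ("GT/AG", True) for the canonical spliceosomal
    motif; anything else is non-canonical.  Positions outside the chromosome
    raise an error.
    """
    if strand == "+":
        donor = genome.fetch(chrom, end + 1, end + 2)
        acceptor = genome.fetch(chrom, start - 2, start - 1)
    else:
        donor = revcomp(genome.fetch(chrom, start - 2, start - 1))
        acceptor = revcomp(genome.fetch(chrom, end + 1, end + 2))
    pair = f"{donor}/{acceptor}"
    return pair, pair == "GT/AG"
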