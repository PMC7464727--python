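"""Parsing of aligner chimeric-junction output and selection of circular chimeric reads.

A splice-aware aligner run in single-end mode reports reads it could only map
in two segments ("chimeric reads", CRs) in a headerless tab-separated table.
When the two segments of one read map to the same chromosome and strand in
*inverted* genomic order, the read spans a circular junction and directly
exposes the genomic boundaries of a circularised transcript; such reads are
circular chimeric reads (CCRs).

Coordinates are 1-based inclusive everywhere in this package; conversion to
0-based half-open happens only at BED output boundaries.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

__all__ = [
    "ChimericRecord",
    "CircularJunction",
    "parse_chimeric_junctions",
    "drop_multiline_reads",
    "is_ccr",
    "ccr_to_junction",
    "filter_chromosomes",
    "count_split_reads",
    "attach_read_sequences",
    "cigar_reference_length",
    "cigar_query_length",
    "cigar_aligned_query_length",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: number of tab-separated columns the chimeric-junction dialect requires
N_CHIMERIC_COLUMNS = 14


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(n + op for n, op in ops) != cigar:
        raise ValueError(f"unparsable CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_reference_length(cigar: str) -> int:
    """Reference bases consumed by a CIGAR (M/D/N/=/X)."""
    return sum(n for n, op in _parse_cigar(cigar) if op in "MDN=X")


def cigar_query_length(cigar: str) -> int:
    """Read bases consumed by a CIGAR (M/I/S/=/X)."""
    return sum(n for n, op in _parse_cigar(cigar) if op in "MIS=X")


def cigar_aligned_query_length(cigar: str) -> int:
    """Read bases actually aligned to the reference (M/I/=/X; soft clips excluded)."""
    return sum(n for n, op in _parse_cigar(cigar) if op in "MI=X")


_MATE_SUFFIX_RE = re.compile(r"[/._]([12])$")


def _mate_from_read_id(read_id: str) -> int:
    m = _MATE_SUFFIX_RE.search(read_id)
    return int(m.group(1)) if m else 0


@dataclass(frozen=True)
class ChimericRecord:
    """One parsed chimeric alignment line (a read mapped in two segments)."""

    read_id: str
    chrom_donor: str
    brkpt_donor: int
    strand_donor: str
    chrom_acceptor: str
    brkpt_acceptor: int
    strand_acceptor: str
    junction_code: int
    repeat_left: int
    repeat_right: int
    seg1_start: int
    seg1_cigar: str
    seg2_start: int
    seg2_cigar: str
    read_seq: Optional[str] = None

    @property
    def mate(self) -> int:
        """Mate index (1/2) recovered from the read-id suffix; 0 when unknown."""
        return _mate_from_read_id(self.read_id)

    @property
    def read_length(self) -> int:
        return cigar_query_length(self.seg1_cigar)

    def fingerprint(self) -> tuple:
        """Alignment fingerprint used to count *distinct* CCRs.

        Two reads with identical segment placements, CIGARs and read length
        are treated as PCR duplicates of one molecule; read length is part of
        the fingerprint because the data may mix read lengths (e.g. 100 and
        125 nt) and same-start reads of different lengths are distinct
        molecules.
        """
        return (
            self.seg1_start,
            self.seg1_cigar,
            self.seg2_start,
            self.seg2_cigar,
            self.read_length,
        )


@dataclass(frozen=True)
class CircularJunction:
    """Strand-aware closed genomic interval [start, end] implied by one CCR."""

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    mate: int
    record: Optional[ChimericRecord] = None

    @property
    def size(self) -> int:
        return self.end - self.start + 1


_STRANDS = frozenset("+-")


def parse_chimeric_junctions(path: str | Path) -> Iterator[ChimericRecord]:
    """Parse a headerless 14-column tab-separated chimeric-junction file.

    Columns: donor chrom, donor breakpoint, donor strand, acceptor chrom,
    acceptor breakpoint, acceptor strand, junction code, left repeat, right
    repeat, read name, segment-1 first base, segment-1 CIGAR, segment-2 first
    base, segment-2 CIGAR.  '#'-prefixed lines are skipped and extra trailing
    columns are ignored.

    Raises ``ValueError`` naming the offending line number on malformed input.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < N_CHIMERIC_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {N_CHIMERIC_COLUMNS} "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                rec = ChimericRecord(
                    chrom_donor=fields[0],
                    brkpt_donor=int(fields[1]),
                    strand_donor=fields[2],
                    chrom_acceptor=fields[3],
                    brkpt_acceptor=int(fields[4]),
                    strand_acceptor=fields[5],
                    junction_code=int(fields[6]),
                    repeat_left=int(fields[7]),
                    repeat_right=int(fields[8]),
                    read_id=fields[9],
                    seg1_start=int(fields[10]),
                    seg1_cigar=fields[11],
                    seg2_start=int(fields[12]),
                    seg2_cigar=fields[13],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
            for strand in (rec.strand_donor, rec.strand_acceptor):
                if strand not in _STRANDS:
                    raise ValueError(
                        f"{path}:{lineno}: unknown strand symbol {strand!r}"
                    )
            if rec.brkpt_donor < 1 or rec.brkpt_acceptor < 1:
                raise ValueError(f"{path}:{lineno}: breakpoint positions must be >= 1")
            yield rec


def drop_multiline_reads(records: Iterable[ChimericRecord]) -> list[ChimericRecord]:
    """Keep only reads appearing in exactly one chimeric line.

    A read reported in several chimeric lines has more than two mappable
    segments or an ambiguous placement; the selection rule keeps chimeric
    reads with only two segments, so such reads are dropped entirely.  Mates
    are independent reads here, so the key is (read id, mate).
    """
    records = list(records)
    seen = Counter((r.read_id, r.mate) for r in records)
    return [r for r in records if seen[(r.read_id, r.mate)] == 1]


def is_ccr(rec: ChimericRecord, min_segment: int = 15) -> bool:
    """True iff the record is a circular chimeric read.

    Requires same chromosome and strand, segments in inverted genomic order
    (donor breakpoint downstream of acceptor breakpoint in transcription
    direction), both segments aligning at least ``min_segment`` read bases,
    and a within-read junction (junction code >= 0; negative codes mark
    junctions between the two mates of a pair, which span no circle).
    """
    if rec.chrom_donor != rec.chrom_acceptor:
        return False
    if rec.strand_donor != rec.strand_acceptor:
        return False
    if rec.junction_code < 0:
        return False
    if rec.strand_donor == "+":
        inverted = rec.brkpt_donor > rec.brkpt_acceptor
    else:
        inverted = rec.brkpt_donor < rec.brkpt_acceptor
    if not inverted:
        return False
    return (
        cigar_aligned_query_length(rec.seg1_cigar) >= min_segment
        and cigar_aligned_query_length(rec.seg2_cigar) >= min_segment
    )


def ccr_to_junction(
    rec: ChimericRecord, offsets: tuple[int, int] = (1, -1)
) -> CircularJunction:
    """Convert CCR breakpoints to the closed circle interval [start, end].

    Under the default dialect convention each breakpoint names the first
    excluded base beyond its segment, so on the + strand
    ``start = acceptor breakpoint + 1`` and ``end = donor breakpoint - 1``
    (mirrored on -).  ``offsets = (offset_acceptor, offset_donor)`` makes the
    convention explicit and configurable: a wrong pair is caught by the
    simulator round-trip test and by the start > end check here.
    """
    off_a, off_d = offsets
    if rec.strand_donor == "+":
        start = rec.brkpt_acceptor + off_a
        end = rec.brkpt_donor + off_d
    else:
        start = rec.brkpt_donor - off_d
        end = rec.brkpt_acceptor - off_a
    if start > end:
        raise ValueError(
            f"breakpoint conversion produced start > end ({start} > {end}) "
            f"for read {rec.read_id}; wrong dialect offsets?"
        )
    return CircularJunction(
        chrom=rec.chrom_donor,
        strand=rec.strand_donor,
        start=start,
        end=end,
        read_id=rec.read_id,
        mate=rec.mate,
        record=rec,
    )


def filter_chromosomes(
    records: Iterable[ChimericRecord], include: Sequence[str]
) -> list[ChimericRecord]:
    """Keep records on the named chromosomes; an empty list keeps everything."""
    records = list(records)
    if not include:
        return records
    allowed = set(include)
    return [
        r
        for r in records
        if r.chrom_donor in allowed and r.chrom_acceptor in allowed
    ]


def attach_read_sequences(
    records: Iterable[ChimericRecord], sam_path: str | Path
) -> list[ChimericRecord]:
    """Fill ``read_seq`` from a SAM file keyed by read name.

    The chimeric SAM stores each segment as one alignment line; the full read
    sequence is taken from the line carrying it (supplementary lines may hold
    hard-clipped sequence and are used only as fallback).
    """
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            # original read orientation, not reference orientation
            seq = aln.get_forward_sequence()
            if seq is None:
                continue
            name = aln.query_name
            if name not in seqs or len(seq) > len(seqs[name]):
                seqs[name] = seq
    return [replace(r, read_seq=seqs.get(r.read_id)) for r in records]


def count_split_reads(
    sj_source: str | Path,
    chrom: str,
    donor_exon_end: int,
    acceptor_exon_start: int,
    strand: str,
) -> int:
    """Unique-read count for one linear exon-exon junction; 0 if absent.

    ``sj_source`` is either an SJ-style 9-column tab file (chrom, intron
    start, intron end, strand code, motif, annotated flag, unique count,
    multi count, overhang) or a SAM file, in which case reads with an N gap
    exactly matching the intron are counted.
    """
    path = Path(sj_source)
    if not path.exists():
        raise FileNotFoundError(f"split-read source not found: {path}")
    intron_start = donor_exon_end + 1
    intron_end = acceptor_exon_start - 1
    if path.suffix.lower() == ".sam":
        return _count_split_reads_sam(path, chrom, intron_start, intron_end)
    strand_code = {"+": 1, "-": 2}.get(strand, 0)
    count = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 SJ columns, got {len(fields)}"
                )
            if (
                fields[0] == chrom
                and int(fields[1]) == intron_start
                and int(fields[2]) == intron_end
                and int(fields[3]) == strand_code
            ):
                count += int(fields[6])
    return count


def _count_split_reads_sam(
    path: Path, chrom: str, intron_start: int, intron_end: int
) -> int:
    count = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name != chrom:
                continue
            # walk the CIGAR to find N gaps at exact intron coordinates
            ref = aln.reference_start  # 0-based
            for op, n in aln.cigartuples or []:
                if op == 3:  # N
                    gap_start = ref + 1  # 1-based first intronic base
                    gap_end = ref + n
                    if gap_start == intron_start and gap_end == intron_end:
                        count += 1
                if op in (0, 2, 3, 7, 8):  # consumes reference
                    ref += n
    return count
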