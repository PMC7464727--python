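"""Exonic circRNA labelling: exact boundary matching plus iterative extension.

A back-spliced (exonic) circRNA has both genomic edges on annotated exon
boundaries.  The standard annotation method labels a LAC exonic when its
start equals an annotated exon start and its end an annotated exon end (same
chromosome and strand; exact match only).  The iterative strategy goes
further: a LAC with exactly one known edge is still labelled exonic and its
unmatched edge is promoted to a *novel* boundary — the presumed edge of an
uncharacterised exon.  Subsequent rounds label LACs against novel boundaries
too, repeating until a round adds nothing.  Run over several ordered exon
lists, each list labels and removes its LACs before the next list is
consulted, and novel boundaries never carry across lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import Boundary, BoundarySet, ExonRecord, build_boundary_set
from .lac import LAC

__all__ = ["ExonicLabel", "match_both", "iterative_label", "cascade"]

MODE_STANDARD = "standard_both"
MODE_ONE_KNOWN = "iterative_one_known"
MODE_NOVEL = "iterative_novel_match"

#: hard cap on labelling rounds; exceeding it indicates a pathological cycle
MAX_ROUNDS = 20


@dataclass(frozen=True)
class ExonicLabel:
    lac_id: str
    mode: str  # standard_both | iterative_one_known | iterative_novel_match
    round: int
    list_id: int
    gene_ids: frozenset[str]
    novel_boundary: Optional[tuple[int, str]] = None  # (position, side) promoted


def match_both(lac: LAC, boundaries: BoundarySet) -> bool:
    """True iff both LAC edges sit on known exon boundaries (standard method)."""
    b_start = boundaries.get(lac.chrom, lac.strand, lac.start, "start")
    b_end = boundaries.get(lac.chrom, lac.strand, lac.end, "end")
    return (
        b_start is not None
        and b_end is not None
        and b_start.origin == "known"
        and b_end.origin == "known"
    )


def _label_for(
    lac: LAC,
    b_start: Optional[Boundary],
    b_end: Optional[Boundary],
    round_no: int,
    list_id: int,
) -> ExonicLabel:
    matched = [b for b in (b_start, b_end) if b is not None]
    genes: set[str] = set()
    for b in matched:
        genes |= b.gene_ids
    if len(matched) == 2:
        if all(b.origin == "known" for b in matched) and round_no == 1:
            mode = MODE_STANDARD
        elif any(b.origin == "novel" for b in matched):
            mode = MODE_NOVEL
        else:
            mode = MODE_STANDARD
        novel = None
    else:
        (b,) = matched
        mode = MODE_ONE_KNOWN if b.origin == "known" else MODE_NOVEL
        if b is b_start:
            novel = (lac.end, "end")
        else:
            novel = (lac.start, "start")
    return ExonicLabel(
        lac_id=lac.lac_id,
        mode=mode,
        round=round_no,
        list_id=list_id,
        gene_ids=frozenset(genes),
        novel_boundary=novel,
    )


def iterative_label(
    lacs: Sequence[LAC],
    boundaries: BoundarySet,
    list_id: int = 1,
    max_rounds: int = MAX_ROUNDS,
    min_support: int = 0,
) -> tuple[dict[str, ExonicLabel], BoundarySet]:
    """Run the iterative exonic labelling to its fixpoint on one exon list.

    Round 1 labels every LAC with at least one matching known boundary; the
    unmatched edge of each one-known-edge LAC enters the boundary set as a
    side-typed novel boundary (a novel start only ever matches future LAC
    starts).  Later rounds label LACs whose edge matches a novel entry,
    promoting their own unmatched edges in turn, until a round adds no label.
    ``min_support`` optionally requires a LAC to reach that many CCRs before
    its unmatched edge is promoted (0 = promote unconditionally).

    Label assignment is independent of LAC input order: within a round all
    matches are computed against the boundary set as it stood at the round's
    start, and promotions are applied between rounds.

    Returns the labels keyed by LAC id and the augmented boundary set.
    Raises ``RuntimeError`` if ``max_rounds`` is exceeded.
    """
    labels: dict[str, ExonicLabel] = {}
    pending = list(lacs)
    round_no = 0
    while True:
        round_no += 1
        if round_no > max_rounds:
            raise RuntimeError(
                f"iterative labelling did not converge within {max_rounds} rounds"
            )
        new_labels: list[tuple[LAC, ExonicLabel]] = []
        still_pending: list[LAC] = []
        for lac in pending:
            b_start = boundaries.get(lac.chrom, lac.strand, lac.start, "start")
            b_end = boundaries.get(lac.chrom, lac.strand, lac.end, "end")
            if b_start is None and b_end is None:
                still_pending.append(lac)
                continue
            new_labels.append((lac, _label_for(lac, b_start, b_end, round_no, list_id)))
        if not new_labels:
            break
        # promotions happen after the round so ordering cannot matter
        for lac, label in new_labels:
            labels[lac.lac_id] = label
            if label.novel_boundary is not None and lac.ccr_count >= min_support:
                pos, side = label.novel_boundary
                boundaries.add(
                    Boundary(
                        chrom=lac.chrom,
                        strand=lac.strand,
                        position=pos,
                        side=side,
                        origin="novel",
                        list_id=list_id,
                        gene_ids=label.gene_ids,
                    )
                )
        pending = still_pending
    return labels, boundaries


def cascade(
    lacs: Sequence[LAC],
    exon_lists: Sequence[Sequence[ExonRecord]],
    max_rounds: int = MAX_ROUNDS,
    min_support: int = 0,
) -> dict[str, ExonicLabel]:
    """Run iterative labelling over ordered exon lists, purging between lists.

    Each list labels (and removes) its LACs before the next list is used, so
    a LAC matching exons in two lists is attributed to the earlier one.
    Novel boundaries discovered on one list are discarded before the next.
    """
    labels: dict[str, ExonicLabel] = {}
    pending = list(lacs)
    for i, exons in enumerate(exon_lists, start=1):
        if not pending:
            break
        bset = build_boundary_set(exons)
        list_ids = {ex.list_id for ex in exons}
        list_id = list_ids.pop() if len(list_ids) == 1 else i
        new, _ = iterative_label(
            pending, bset, list_id=list_id, max_rounds=max_rounds, min_support=min_support
        )
        labels.update(new)
        pending = [lac for lac in pending if lac.lac_id not in labels]
    return labels
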