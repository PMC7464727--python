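"""Classification of non-back-splice LACs: lariat intronic, intron circle, sub-exonic.

After exonic purging, the remaining LACs are tested in decreasing order of
specificity:

* **intron circle** — the LAC equals an intron's coordinates exactly (the
  whole intron circularised);
* **lariat-derived intronic circRNA** — the LAC starts at the intron's first
  transcribed (5') base and ends strictly inside the intron: a lariat whose
  3' tail was trimmed back to the branch point, leaving a 2'-5' link at the
  junction.  The distance from the LAC's 3' edge to the intron end is the
  tail gap;
* **sub-exonic circRNA** — both LAC edges fall strictly within the single
  exon of a mono-exonic gene, covering only part of the exon (a full-exon
  circle is an ordinary mono-exonic exonic circRNA handled by boundary
  matching).  Very short candidates are discarded (default < 55 nt, the
  smallest span two 15-nt segments can plausibly delimit in this data), and
  sizes above 70 nt are marked confident.

Everything else stays *unallocated* and is reported for manual review.
Only introns of coding genes are searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .annotation import ExonRecord, IntronRecord
from .lac import LAC

__all__ = [
    "NonCanonicalLabel",
    "match_intron_circle",
    "match_lariat",
    "match_subexonic",
    "classify",
    "group_sets",
    "size_stats",
    "set_summary",
]

KLASS_LARIAT = "lariat_intronic"
KLASS_CIRCLE = "intron_circle"
KLASS_SUBEXONIC = "sub_exonic"
KLASS_UNALLOCATED = "unallocated"


@dataclass(frozen=True)
class NonCanonicalLabel:
    lac_id: str
    klass: str
    gene_id: Optional[str] = None
    intron: Optional[tuple[int, int]] = None  # (start, end) of the matched intron
    tail_gap: Optional[int] = None  # lariat only: branch-to-intron-end distance
    set_id: Optional[int] = None  # sub-exonic only
    confident: Optional[bool] = None  # sub-exonic only


class _IntronIndex:
    def __init__(self, introns: Iterable[IntronRecord]):
        self.exact: dict[tuple, IntronRecord] = {}
        self.by_5p: dict[tuple, list[IntronRecord]] = {}
        for intr in introns:
            self.exact.setdefault(
                (intr.chrom, intr.strand, intr.start, intr.end), intr
            )
            self.by_5p.setdefault(
                (intr.chrom, intr.strand, intr.five_prime_base), []
            ).append(intr)


def match_intron_circle(
    lac: LAC, introns: Iterable[IntronRecord] | _IntronIndex
) -> Optional[IntronRecord]:
    """The intron whose coordinates the LAC matches exactly, else None."""
    idx = introns if isinstance(introns, _IntronIndex) else _IntronIndex(introns)
    return idx.exact.get((lac.chrom, lac.strand, lac.start, lac.end))


def match_lariat(
    lac: LAC,
    introns: Iterable[IntronRecord] | _IntronIndex,
    min_tail: int = 1,
    branch_window: int = 0,
) -> Optional[tuple[IntronRecord, int]]:
    """Match a LAC to a trimmed-lariat circle; returns (intron, tail_gap) or None.

    The LAC's 5' edge must coincide with an intron's first base (on the minus
    strand that is the intron's genomic end) and its other edge must lie
    strictly inside the intron with a tail gap of at least ``min_tail``
    bases.  ``branch_window > 0`` additionally caps the tail gap (a maximal
    branch-point-to-intron-end distance); 0 disables the cap.  No minimum
    circle size is applied.
    """
    idx = introns if isinstance(introns, _IntronIndex) else _IntronIndex(introns)
    five_p = lac.start if lac.strand == "+" else lac.end
    best: Optional[tuple[IntronRecord, int]] = None
    for intr in idx.by_5p.get((lac.chrom, lac.strand, five_p), []):
        if lac.start < intr.start or lac.end > intr.end:
            continue
        if lac.strand == "+":
            tail_gap = intr.end - lac.end
        else:
            tail_gap = lac.start - intr.start
        if tail_gap < min_tail:
            continue
        if branch_window > 0 and tail_gap > branch_window:
            continue
        # prefer the smallest tail gap (tightest containing intron)
        if best is None or tail_gap < best[1]:
            best = (intr, tail_gap)
    return best


def match_subexonic(
    lac: LAC,
    mono_exons: Iterable[ExonRecord],
    min_size: int = 55,
    confident_size: int = 70,
) -> Optional[tuple[ExonRecord, bool]]:
    """Match a LAC covering part of a mono-exonic gene's exon.

    Returns (exon, confident) or None.  The LAC must lie within the exon on
    the same strand, must not equal the full exon, and must span at least
    ``min_size`` nt; confident iff size > ``confident_size``.
    """
    if lac.size < min_size:
        return None
    for ex in mono_exons:
        if ex.chrom != lac.chrom or ex.strand != lac.strand:
            continue
        if ex.start <= lac.start and lac.end <= ex.end:
            if lac.start == ex.start and lac.end == ex.end:
                continue  # the full exon: exonic, not sub-exonic
            return ex, lac.size > confident_size
    return None


def classify(
    lacs: Sequence[LAC],
    introns: Iterable[IntronRecord],
    mono_exons: Sequence[ExonRecord],
    min_tail: int = 1,
    branch_window: int = 0,
    min_subexonic_size: int = 55,
    confident_size: int = 70,
) -> dict[str, NonCanonicalLabel]:
    """Assign each LAC one class via the cascade circle -> lariat -> sub-exonic.

    Evaluation order encodes decreasing specificity and guarantees mutual
    exclusivity; a full-intron LAC can never be called a lariat because its
    tail gap (0) is below ``min_tail``.  ``mono_exons`` should contain the
    exons of mono-exonic genes only.  Unmatched LACs are labelled
    unallocated.
    """
    idx = _IntronIndex(introns)
    # index mono-exonic exons per (chrom, strand) for containment queries
    trees: dict[tuple, IntervalTree] = {}
    for ex in mono_exons:
        trees.setdefault((ex.chrom, ex.strand), IntervalTree()).addi(
            ex.start, ex.end + 1, ex
        )
    labels: dict[str, NonCanonicalLabel] = {}
    for lac in lacs:
        circle = match_intron_circle(lac, idx)
        if circle is not None:
            labels[lac.lac_id] = NonCanonicalLabel(
                lac_id=lac.lac_id,
                klass=KLASS_CIRCLE,
                gene_id=circle.gene_id,
                intron=(circle.start, circle.end),
            )
            continue
        lariat = match_lariat(lac, idx, min_tail=min_tail, branch_window=branch_window)
        if lariat is not None:
            intr, tail_gap = lariat
            labels[lac.lac_id] = NonCanonicalLabel(
                lac_id=lac.lac_id,
                klass=KLASS_LARIAT,
                gene_id=intr.gene_id,
                intron=(intr.start, intr.end),
                tail_gap=tail_gap,
            )
            continue
        tree = trees.get((lac.chrom, lac.strand))
        candidates: list[ExonRecord] = []
        if tree is not None and lac.size >= min_subexonic_size:
            candidates = sorted(
                (
                    iv.data
                    for iv in tree.overlap(lac.start, lac.end + 1)
                    if iv.data.start <= lac.start and lac.end <= iv.data.end
                ),
                key=lambda e: (e.start, e.end, e.gene_id),
            )
        sub = None
        for ex in candidates:
            if lac.start == ex.start and lac.end == ex.end:
                continue
            sub = (ex, lac.size > confident_size)
            break
        if sub is not None:
            ex, confident = sub
            labels[lac.lac_id] = NonCanonicalLabel(
                lac_id=lac.lac_id,
                klass=KLASS_SUBEXONIC,
                gene_id=ex.gene_id,
                confident=confident,
            )
            continue
        labels[lac.lac_id] = NonCanonicalLabel(lac_id=lac.lac_id, klass=KLASS_UNALLOCATED)
    return labels


def group_sets(
    lacs: Sequence[LAC], labels: Mapping[str, NonCanonicalLabel]
) -> dict[str, NonCanonicalLabel]:
    """Partition each gene's sub-exonic LACs into overlap sets.

    Single-linkage on positive interval overlap: two LACs of one gene join
    the same set when their intervals overlap by at least one base, directly
    or through intermediates.  Returns a new label mapping with ``set_id``
    filled (numbered genomically within each gene).
    """
    by_gene: dict[str, list[LAC]] = {}
    for lac in lacs:
        lab = labels.get(lac.lac_id)
        if lab is not None and lab.klass == KLASS_SUBEXONIC:
            by_gene.setdefault(lab.gene_id or "", []).append(lac)
    out = dict(labels)
    for gene_id, glacs in by_gene.items():
        glacs = sorted(glacs, key=lambda l: (l.start, l.end))
        set_no = 0
        current_end = None
        assign: dict[str, int] = {}
        for lac in glacs:
            if current_end is None or lac.start > current_end:
                set_no += 1
                current_end = lac.end
            else:
                current_end = max(current_end, lac.end)
            assign[lac.lac_id] = set_no
        for lac in glacs:
            lab = out[lac.lac_id]
            out[lac.lac_id] = NonCanonicalLabel(
                lac_id=lab.lac_id,
                klass=lab.klass,
                gene_id=lab.gene_id,
                intron=lab.intron,
                tail_gap=lab.tail_gap,
                set_id=assign[lac.lac_id],
                confident=lab.confident,
            )
    return out


def size_stats(
    lacs: Sequence[LAC], labels: Mapping[str, NonCanonicalLabel]
) -> dict:
    """Summary over classified LACs: class counts, mean lariat size, large fraction.

    The mean circle size and the fraction above 600 nt are computed over
    lariat-derived intronic circRNAs; both are None when the class is empty.
    """
    by_id = {lac.lac_id: lac for lac in lacs}
    counts: dict[str, int] = {}
    lariat_sizes: list[int] = []
    for lac_id, lab in labels.items():
        counts[lab.klass] = counts.get(lab.klass, 0) + 1
        if lab.klass == KLASS_LARIAT and lac_id in by_id:
            lariat_sizes.append(by_id[lac_id].size)
    mean_size = sum(lariat_sizes) / len(lariat_sizes) if lariat_sizes else None
    frac_gt_600 = (
        sum(1 for s in lariat_sizes if s > 600) / len(lariat_sizes)
        if lariat_sizes
        else None
    )
    return {
        "counts": counts,
        "mean_lariat_size": mean_size,
        "fraction_lariat_gt_600": frac_gt_600,
    }


def set_summary(
    lacs: Sequence[LAC],
    labels: Mapping[str, NonCanonicalLabel],
    mono_exons: Sequence[ExonRecord],
    genome=None,
) -> "pd.DataFrame":
    """Per-gene summary of sub-exonic LAC sets.

    One row per (gene, set): a "count x min-max nt" set spec, the pooled CCR
    count, the host gene, its biotype, its exon length, and the exon's GC
    percentage when a genome is available (``genome`` is a
    :class:`~circlac.refine.GenomeView`).
    """
    import pandas as pd

    exon_by_gene = {ex.gene_id: ex for ex in mono_exons}
    groups: dict[tuple, list[LAC]] = {}
    for lac in lacs:
        lab = labels.get(lac.lac_id)
        if lab is not None and lab.klass == KLASS_SUBEXONIC:
            groups.setdefault((lab.gene_id or "", lab.set_id or 0), []).append(lac)
    rows = []
    for (gene_id, set_id), members in sorted(groups.items()):
        sizes = sorted(m.size for m in members)
        spec = (
            f"{len(members)} x {sizes[0]} nt"
            if sizes[0] == sizes[-1]
            else f"{len(members)} x {sizes[0]}-{sizes[-1]} nt"
        )
        ex = exon_by_gene.get(gene_id)
        gc = None
        if ex is not None and genome is not None:
            seq = genome.fetch(ex.chrom, ex.start, ex.end)
            gc = round(100.0 * sum(seq.count(b) for b in "GC") / len(seq), 1)
        rows.append(
            {
                "gene_id": gene_id,
                "set_id": set_id,
                "set_spec": spec,
                "n_ccr": sum(m.ccr_count for m in members),
                "biotype": ex.biotype if ex is not None else "",
                "exon_length": ex.end - ex.start + 1 if ex is not None else -1,
                "gc_pct": gc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "set_id", "set_spec", "n_ccr", "biotype", "exon_length", "gc_pct"],
    )
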