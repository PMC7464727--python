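"""Ordered exon lists, derived introns, mono-exonic genes and boundary sets.

The classification cascade consumes up to three ordered exon lists (e.g. the
reference annotation, an external lncRNA exon catalogue, and a list of
candidate novel exons assembled from the data).  Lists are kept disjoint with
priority to the lowest list id, so a circle matching an exon present in two
lists is attributed to the earlier one.  Introns are derived per transcript
from the gaps between consecutive exons and unioned per gene; mono-exonic
genes (whose every transcript has a single exon) are the substrate of
sub-exonic circRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd

__all__ = [
    "ExonRecord",
    "IntronRecord",
    "GeneRecord",
    "Boundary",
    "BoundarySet",
    "read_exons_gtf",
    "read_exons_bed",
    "dedup_exon_lists",
    "derive_introns",
    "find_mono_exonic",
    "build_boundary_set",
]

BIOTYPES = ("coding", "lnc", "other_nc", "novel")

#: default mapping from annotation gene_biotype attribute values
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "lncRNA": "lnc",
    "lincRNA": "lnc",
    "antisense": "lnc",
}


@dataclass(frozen=True)
class ExonRecord:
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    gene_id: str
    transcript_id: str
    biotype: str  # coding | lnc | other_nc | novel
    list_id: int  # 1, 2 or 3 — ordered priority

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start > end: {self}")
        if self.list_id not in (1, 2, 3):
            raise ValueError(f"list_id must be 1, 2 or 3: {self.list_id}")


@dataclass(frozen=True)
class IntronRecord:
    """First and last intronic base of a gap between consecutive exons."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    upstream_exon_end: int
    downstream_exon_start: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime_base(self) -> int:
        """Genomic position of the intron's first transcribed (5') base."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    exon_count: int
    mono_exonic: bool


@dataclass(frozen=True)
class Boundary:
    chrom: str
    strand: str
    position: int
    side: str  # "start" (circle 5' genomic edge) or "end"
    origin: str = "known"  # known | novel
    list_id: int = 0
    gene_ids: frozenset[str] = frozenset()

    def key(self) -> tuple:
        return (self.chrom, self.strand, self.position, self.side)


class BoundarySet:
    """Set of exon-boundary positions, side-typed and strand-aware.

    Novel entries are only added by the iterative labeller when a circle with
    one known edge promotes its unmatched edge to a candidate boundary.
    """

    def __init__(self, boundaries: Iterable[Boundary] = ()):
        self._entries: dict[tuple, Boundary] = {}
        for b in boundaries:
            self.add(b)

    def add(self, boundary: Boundary) -> bool:
        """Add a boundary; returns False (and keeps the first) on duplicates."""
        key = boundary.key()
        if key in self._entries:
            return False
        self._entries[key] = boundary
        return True

    def get(self, chrom: str, strand: str, position: int, side: str) -> Optional[Boundary]:
        return self._entries.get((chrom, strand, position, side))

    def __contains__(self, key: tuple) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def known_only(self) -> "BoundarySet":
        return BoundarySet(b for b in self if b.origin == "known")


def read_exons_gtf(
    path: str | Path,
    biotype_map: Optional[Mapping[str, str]] = None,
    list_id: int = 1,
) -> list[ExonRecord]:
    """Load unique exons from an Ensembl-dialect GTF.

    One record is returned per unique (chrom, strand, start, end, gene);
    transcripts sharing an exon are deduplicated (the transcript id of the
    first occurrence is kept).  Gene biotypes are mapped to the package's
    coarse classes through ``biotype_map`` (unmapped values become
    ``other_nc``).  Non-exon features are ignored; an exon without a gene_id
    raises ``ValueError``.
    """
    biotype_map = dict(DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records: dict[tuple, ExonRecord] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise ValueError(f"exon feature without gene_id at {feat.seqid}:{feat.start}")
        gene_id = gene_ids[0]
        transcript_id = (feat.attributes.get("transcript_id") or [gene_id])[0]
        raw_bt = (feat.attributes.get("gene_biotype") or ["other"])[0]
        biotype = biotype_map.get(raw_bt, "other_nc")
        key = (feat.seqid, feat.strand, feat.start, feat.end, gene_id, transcript_id)
        if key not in records:
            records[key] = ExonRecord(
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                gene_id=gene_id,
                transcript_id=transcript_id,
                biotype=biotype,
                list_id=list_id,
            )
    return list(records.values())


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_BED12_EXTRA = ["thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]


def read_exons_bed(
    path: str | Path, list_id: int, biotype: str = "lnc"
) -> list[ExonRecord]:
    """Load exons from BED6 (one exon per line) or BED12 (blocks = exons).

    BED's 0-based half-open coordinates are converted to 1-based inclusive.
    The BED name field is used as the gene id (exon suffixes after the last
    '.' are stripped so block-less per-exon lines of one gene group together).
    """
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED6+ requires >= 6 columns, got {df.shape[1]}")
    ncols = min(df.shape[1], 12)
    df = df.iloc[:, :ncols]
    df.columns = (_BED_COLS + _BED12_EXTRA)[:ncols]
    records: list[ExonRecord] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chrom, bstart, bend = row.chrom, int(row.start), int(row.end)
            strand = row.strand
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
        if strand not in "+-":
            raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
        if bstart >= bend:
            raise ValueError(f"{path}: line {lineno}: start >= end")
        name = str(row.name)
        gene_id = name.rsplit(".", 1)[0] if "." in name else name
        if ncols == 12 and int(row.blockCount) > 0:
            sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
            starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
            if len(sizes) != int(row.blockCount) or len(starts) != int(row.blockCount):
                raise ValueError(f"{path}: line {lineno}: inconsistent BED12 blocks")
            for size, offset in zip(sizes, starts):
                records.append(
                    ExonRecord(
                        chrom=chrom,
                        strand=strand,
                        start=bstart + offset + 1,
                        end=bstart + offset + size,
                        gene_id=gene_id,
                        transcript_id=name,
                        biotype=biotype,
                        list_id=list_id,
                    )
                )
        else:
            records.append(
                ExonRecord(
                    chrom=chrom,
                    strand=strand,
                    start=bstart + 1,
                    end=bend,
                    gene_id=gene_id,
                    transcript_id=name,
                    biotype=biotype,
                    list_id=list_id,
                )
            )
    return records


def dedup_exon_lists(
    exon_lists: Sequence[list[ExonRecord]],
) -> list[list[ExonRecord]]:
    """Enforce disjointness across ordered lists, keeping the lowest list id.

    An exon (same chrom/strand/start/end) present in several lists survives
    only in the earliest one, matching the cascade that purges circles list
    by list.
    """
    seen: set[tuple] = set()
    out: list[list[ExonRecord]] = []
    for exons in exon_lists:
        kept = []
        local: set[tuple] = set()
        for ex in exons:
            key = (ex.chrom, ex.strand, ex.start, ex.end)
            if key in seen:
                continue
            local.add(key)
            kept.append(ex)
        seen |= local
        out.append(kept)
    return out


def derive_introns(exons: Iterable[ExonRecord]) -> list[IntronRecord]:
    """Introns of the given exons: per-transcript gaps, unioned per gene.

    Within each transcript, exons are sorted genomically and each gap between
    consecutive exons becomes one intron; introns identical across a gene's
    transcripts are deduplicated.  Overlapping exons within one transcript
    raise ``ValueError``.
    """
    by_tx: dict[tuple, list[ExonRecord]] = {}
    for ex in exons:
        by_tx.setdefault((ex.gene_id, ex.transcript_id), []).append(ex)
    introns: dict[tuple, IntronRecord] = {}
    for (gene_id, tx_id), tx_exons in by_tx.items():
        tx_exons = sorted(tx_exons, key=lambda e: (e.start, e.end))
        for left, right in zip(tx_exons, tx_exons[1:]):
            if right.start <= left.end:
                raise ValueError(
                    f"overlapping exons in transcript {tx_id}: "
                    f"[{left.start},{left.end}] and [{right.start},{right.end}]"
                )
            if right.start == left.end + 1:
                continue  # abutting exons leave no intronic base
            key = (left.chrom, left.strand, left.end + 1, right.start - 1, gene_id)
            if key not in introns:
                introns[key] = IntronRecord(
                    chrom=left.chrom,
                    strand=left.strand,
                    start=left.end + 1,
                    end=right.start - 1,
                    gene_id=gene_id,
                    upstream_exon_end=left.end,
                    downstream_exon_start=right.start,
                )
    return sorted(introns.values(), key=lambda i: (i.chrom, i.start, i.end, i.gene_id))


def find_mono_exonic(exons: Iterable[ExonRecord]) -> dict[str, GeneRecord]:
    """Gene table with the mono-exonic flag.

    A gene is mono-exonic iff every one of its transcripts has exactly one
    exon.
    """
    by_gene: dict[str, list[ExonRecord]] = {}
    for ex in exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)
    genes: dict[str, GeneRecord] = {}
    for gene_id, gexons in by_gene.items():
        tx_counts: dict[str, int] = {}
        for ex in gexons:
            tx_counts[ex.transcript_id] = tx_counts.get(ex.transcript_id, 0) + 1
        unique_exons = {(e.chrom, e.strand, e.start, e.end) for e in gexons}
        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            chrom=gexons[0].chrom,
            strand=gexons[0].strand,
            start=min(e.start for e in gexons),
            end=max(e.end for e in gexons),
            biotype=gexons[0].biotype,
            exon_count=len(unique_exons),
            mono_exonic=all(n == 1 for n in tx_counts.values()),
        )
    return genes


def build_boundary_set(exons: Iterable[ExonRecord]) -> BoundarySet:
    """Boundary set of one exon list: each exon contributes its genomic start
    (circle 5' edge candidate) and end (circle 3' edge candidate)."""
    by_key: dict[tuple, set[str]] = {}
    meta: dict[tuple, int] = {}
    for ex in exons:
        for side, pos in (("start", ex.start), ("end", ex.end)):
            key = (ex.chrom, ex.strand, pos, side)
            by_key.setdefault(key, set()).add(ex.gene_id)
            meta[key] = ex.list_id
    bset = BoundarySet()
    for (chrom, strand, pos, side), gene_ids in by_key.items():
        bset.add(
            Boundary(
                chrom=chrom,
                strand=strand,
                position=pos,
                side=side,
                origin="known",
                list_id=meta[(chrom, strand, pos, side)],
                gene_ids=frozenset(gene_ids),
            )
        )
    return bset
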