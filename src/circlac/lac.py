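"""Clustering of circular junctions into LACs and the abundance threshold.

A LAC (locus associated with circRNA production) is the cluster of all CCRs
whose circular junctions share exactly the same genomic coordinates.  LACs
supported by very few reads are likely sporadic circularisation events or
artefacts; the retained set keeps only LACs with at least ``min_ccr`` reads
of which at least ``min_distinct`` have distinct alignment fingerprints
(defaults 5 and 4), which suppresses loci supported only by PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd

from .chimeric import ChimericRecord, CircularJunction

__all__ = ["ReadEvidence", "LAC", "cluster_ccrs", "count_distinct", "apply_threshold", "lacs_to_frame"]


class ReadEvidence(NamedTuple):
    read_id: str
    mate: int
    fingerprint: tuple


@dataclass
class LAC:
    """Cluster of identical circular junctions."""

    chrom: str
    strand: str
    start: int
    end: int
    reads: list[ReadEvidence] = field(default_factory=list)
    records: list[ChimericRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def ccr_count(self) -> int:
        return len(self.reads)

    @property
    def distinct_ccr_count(self) -> int:
        return count_distinct(self)

    @property
    def lac_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    @property
    def mate_counts(self) -> tuple[int, int]:
        """(reads-1, reads-2) split, for mate-imbalance diagnostics."""
        r1 = sum(1 for r in self.reads if r.mate == 1)
        r2 = sum(1 for r in self.reads if r.mate == 2)
        return r1, r2


def cluster_ccrs(junctions: Iterable[CircularJunction]) -> list[LAC]:
    """Group junctions by exact (chrom, strand, start, end).

    The sum of per-LAC read counts equals the number of input junctions.
    Output is sorted genomically, independent of input order.
    """
    table: dict[tuple, LAC] = {}
    for j in junctions:
        key = (j.chrom, j.strand, j.start, j.end)
        lac = table.get(key)
        if lac is None:
            lac = table[key] = LAC(chrom=j.chrom, strand=j.strand, start=j.start, end=j.end)
        fp = j.record.fingerprint() if j.record is not None else (j.read_id, j.mate)
        lac.reads.append(ReadEvidence(j.read_id, j.mate, fp))
        if j.record is not None:
            lac.records.append(j.record)
    return sorted(table.values(), key=lambda l: (l.chrom, l.start, l.end, l.strand))


def count_distinct(lac: LAC) -> int:
    """Number of distinct alignment fingerprints supporting the LAC."""
    return len({r.fingerprint for r in lac.reads})


def apply_threshold(
    lacs: Iterable[LAC], min_ccr: int = 5, min_distinct: int = 4
) -> list[LAC]:
    """Keep LACs with >= min_ccr reads of which >= min_distinct are distinct."""
    return [
        lac
        for lac in lacs
        if lac.ccr_count >= min_ccr and lac.distinct_ccr_count >= min_distinct
    ]


def lacs_to_frame(lacs: Iterable[LAC]) -> pd.DataFrame:
    """LAC table as a DataFrame (chrom, start, end, strand, size, ccr, distinct)."""
    rows = [
        {
            "lac_id": lac.lac_id,
            "chrom": lac.chrom,
            "start": lac.start,
            "end": lac.end,
            "strand": lac.strand,
            "size": lac.size,
            "ccr_count": lac.ccr_count,
            "distinct_ccr_count": lac.distinct_ccr_count,
        }
        for lac in lacs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lac_id",
            "chrom",
            "start",
            "end",
            "strand",
            "size",
            "ccr_count",
            "distinct_ccr_count",
        ],
    )
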