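"""Synthetic genome, annotation and read-level evidence with a truth table.

The generator builds a toy genome with multi-exonic coding genes, multi-exonic
lncRNA genes (exon list 2), "novel" multi-exonic genes whose exons appear only
in the candidate-exon list (list 3), and short mono-exonic non-coding genes
(exon 100-600 nt); it plants circles of all four classes on that annotation
and emits the downstream files a splice-aware aligner would produce for
junction-spanning reads: the 14-column chimeric-junction table, a chimeric
SAM with read sequences, an SJ-style split-read table for the linear
exon-exon junctions, plus FASTA/GTF/BED and a truth TSV.

Emulated data features: configurable per-circle read counts mixing 100- and
125-nt reads (3:1 toward 125 by default, as in the source dataset), PCR
duplicates, junction microhomology causing the aligner to shift a fraction
of reads' junction coordinates (splitting one circularisation event over
several LACs), substitutions within a few bases of the junction on
lariat-derived reads (reverse-transcriptase infidelity near the 2'-5' link),
distinct co-located circRNA variants (untemplated inserts at the junction),
a mate-specific read deficit mimicking GC dropout, and reads long enough to
traverse a small circle twice (emitted to the SAM only, since a two-pass
read has more than two segments and the two-segment chimeric table cannot
represent it).

Reads are emitted directly as aligned records, never as FASTQ: the package's
scope starts downstream of alignment.  A fixed config (including the seed)
produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .refine import revcomp

__all__ = ["SimConfig", "Gene", "PlantedCircle", "PlantedRead", "SimBundle", "simulate",
           "build_genome_and_annotation", "plant_circles", "emit_reads"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 3
    intergenic_gap: tuple[int, int] = (200, 500)
    # gene content
    n_coding_genes: int = 15
    n_lnc_genes: int = 4
    n_novel_genes: int = 3
    n_mono_genes: int = 8
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (100, 800)
    mono_exon_length: tuple[int, int] = (100, 600)
    # circle mix
    n_exonic: int = 100
    n_lariat: int = 50
    n_intron_circle: int = 10
    n_subexonic: int = 40
    novel_edge_fraction: float = 0.2  # exonic circles with one unannotated edge
    exonic_host_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)  # coding/lnc/novel
    branch_offset: tuple[int, int] = (15, 60)  # branch point upstream of intron 3' end
    subexonic_size: tuple[int, int] = (55, 250)
    # read model
    reads_per_circle: tuple[int, int] = (8, 40)
    p_read_125: float = 0.75  # 3/4 of reads are 125 nt, the rest 100 nt
    duplicate_rate: float = 0.0
    shift_prob: float = 0.0  # fraction of a circle's reads reported shifted
    homology_weights: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)  # P(len 0..3)
    mismatch_rate: float = 0.0  # near-junction substitutions, lariat reads
    variant_prob: float = 0.0  # P(circle carries a second junction variant)
    mate_dropout: float = 0.0  # mate-1 deficit mimicking GC dropout
    # linear evidence & background
    sj_depth: tuple[int, int] = (20, 60)  # unique split reads per linear junction
    n_background: int = 30  # non-circular chimeric lines
    n_multiline: int = 5  # reads emitted on two chimeric lines (to be dropped)
    min_segment: int = 15

    def with_noise(self, **kw) -> "SimConfig":
        """Copy with noise knobs at realistic defaults, overridable."""
        base = dict(
            duplicate_rate=0.2,
            shift_prob=0.25,
            homology_weights=(0.5, 0.2, 0.2, 0.1),
            mismatch_rate=0.2,
            variant_prob=0.1,
        )
        base.update(kw)
        d = asdict(self)
        d.update(base)
        return SimConfig(**d)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str  # coding | lnc | other_nc | novel
    exons: list[tuple[int, int]]
    exon_list: int  # which exon list the exons are published in (1, 2, 3)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a_end + 1, b_start - 1)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class PlantedRead:
    read_id: str
    mate: int
    read_len: int
    split: int  # bases before the junction
    shift: int  # junction coordinate shift applied by the "aligner"
    variant: int  # 0-based junction-sequence variant index
    duplicate_of: Optional[str] = None
    multipass: bool = False
    seq: str = ""


@dataclass
class PlantedCircle:
    circle_id: str
    klass: str  # exonic | lariat_intronic | intron_circle | sub_exonic
    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    intron: Optional[tuple[int, int]] = None
    tail_gap: Optional[int] = None
    homology: int = 0
    novel_edge: bool = False
    expected_round: int = 1
    n_variants: int = 1
    variant_inserts: list[str] = field(default_factory=list)
    reads: list[PlantedRead] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def n_reads(self) -> int:
        return sum(1 for r in self.reads if r.duplicate_of is None and not r.multipass)

    @property
    def n_duplicates(self) -> int:
        return sum(1 for r in self.reads if r.duplicate_of is not None)

    @property
    def n_multipass(self) -> int:
        return sum(1 for r in self.reads if r.multipass)


@dataclass
class SimBundle:
    config: SimConfig
    genes: list[Gene]
    circles: list[PlantedCircle]
    paths: dict[str, Path]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# genome & annotation


def build_genome_and_annotation(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], list[Gene]]:
    """Random genome with sequentially placed, non-overlapping genes."""
    genome: dict[str, list[str]] = {f"chr{i+1}": [] for i in range(cfg.n_chroms)}
    cursors = {c: 0 for c in genome}

    def grow(chrom: str, upto: int) -> None:
        need = upto - len(genome[chrom])
        if need > 0:
            genome[chrom].extend(rng.choice(_BASES, size=need).tolist())

    genes: list[Gene] = []
    plan = (
        [("coding", 1)] * cfg.n_coding_genes
        + [("lnc", 2)] * cfg.n_lnc_genes
        + [("novel", 3)] * cfg.n_novel_genes
        + [("other_nc", 1)] * cfg.n_mono_genes
    )
    for i, (biotype, exon_list) in enumerate(plan):
        chrom = f"chr{(i % cfg.n_chroms) + 1}"
        gap = int(rng.integers(*_incl(cfg.intergenic_gap)))
        start = max(cursors[chrom] + gap, 60)  # margin so breakpoints stay >= 1
        strand = "+" if rng.random() < 0.5 else "-"
        exons: list[tuple[int, int]] = []
        pos = start
        if biotype == "other_nc":  # mono-exonic short nc gene
            length = int(rng.integers(*_incl(cfg.mono_exon_length)))
            exons.append((pos, pos + length - 1))
            pos += length
        else:
            n_ex = int(rng.integers(*_incl(cfg.exons_per_gene)))
            for k in range(n_ex):
                length = int(rng.integers(*_incl(cfg.exon_length)))
                exons.append((pos, pos + length - 1))
                pos += length
                if k < n_ex - 1:
                    pos += int(rng.integers(*_incl(cfg.intron_length)))
        genes.append(
            Gene(
                gene_id=f"SIMG{i:04d}",
                chrom=chrom,
                strand=strand,
                biotype=biotype,
                exons=exons,
                exon_list=exon_list,
            )
        )
        cursors[chrom] = pos
        grow(chrom, pos + 10)
    for chrom in genome:
        grow(chrom, cursors[chrom] + 300)
    return genome, genes


def _incl(bounds: tuple[int, int]) -> tuple[int, int]:
    lo, hi = bounds
    return lo, hi + 1


# ---------------------------------------------------------------------------
# circle planting


def plant_circles(
    cfg: SimConfig, genes: list[Gene], rng: np.random.Generator
) -> list[PlantedCircle]:
    """Choose circle coordinates of all four classes on the annotation.

    Exonic circles sit on exon boundary pairs of multi-exonic genes (a
    configurable fraction has one edge pushed a few bases into the adjacent
    intron, standing in for an uncharacterised exon boundary); lariat circles
    run from an intron's first base to a branch position upstream of its 3'
    end; intron circles are whole introns; sub-exonic circles lie strictly
    inside mono-exonic exons.  Edges of non-exonic circles are kept clear of
    every exon-boundary position (known or promoted) so the exonic cascade
    cannot capture them, and all circle coordinates are unique.

    Raises ``ValueError`` when a class is requested but no compatible gene or
    coordinate remains.
    """
    multi = {
        "coding": [g for g in genes if g.biotype == "coding" and len(g.exons) > 1],
        "lnc": [g for g in genes if g.biotype == "lnc" and len(g.exons) > 1],
        "novel": [g for g in genes if g.biotype == "novel" and len(g.exons) > 1],
    }
    mono = [g for g in genes if len(g.exons) == 1]
    coding_introns = [
        (g, intr) for g in multi["coding"] for intr in g.introns
    ]

    # every exon-boundary position that the exonic labeller could match
    exonic_positions: set[tuple] = set()
    for g in genes:
        for s, e in g.exons:
            exonic_positions.add((g.chrom, g.strand, s, "start"))
            exonic_positions.add((g.chrom, g.strand, e, "end"))
    used_coords: set[tuple] = set()
    circles: list[PlantedCircle] = []

    def register(c: PlantedCircle) -> bool:
        key = (c.chrom, c.strand, c.start, c.end)
        if key in used_coords:
            return False
        used_coords.add(key)
        circles.append(c)
        return True

    # --- exonic ------------------------------------------------------------
    host_kinds = list(multi)
    n_novel_edge = int(round(cfg.n_exonic * cfg.novel_edge_fraction))
    for i in range(cfg.n_exonic):
        placed = False
        for _attempt in range(200):
            kind = host_kinds[
                int(rng.choice(3, p=np.array(cfg.exonic_host_weights) / sum(cfg.exonic_host_weights)))
            ]
            pool = multi[kind] or multi["coding"]
            if not pool:
                raise ValueError("no multi-exonic gene available for exonic circles")
            g = pool[int(rng.integers(len(pool)))]
            a = int(rng.integers(len(g.exons)))
            b = int(rng.integers(a, len(g.exons)))
            start = g.exons[a][0]
            end = g.exons[b][1]
            novel_edge = i < n_novel_edge and b < len(g.exons) - 1
            if novel_edge:
                intron_len = g.exons[b + 1][0] - 1 - g.exons[b][1]
                delta = int(rng.integers(5, min(30, intron_len - 70) + 1)) if intron_len > 80 else 0
                if delta == 0:
                    novel_edge = False
                else:
                    end = g.exons[b][1] + delta
            c = PlantedCircle(
                circle_id=f"SIMC{len(circles):04d}",
                klass="exonic",
                chrom=g.chrom,
                strand=g.strand,
                start=start,
                end=end,
                gene_id=g.gene_id,
                novel_edge=novel_edge,
            )
            if register(c):
                if novel_edge:
                    exonic_positions.add((c.chrom, c.strand, c.end, "end"))
                placed = True
                break
        if not placed:
            raise ValueError("could not place all requested exonic circles")

    def clear_of_boundaries(chrom, strand, start, end) -> bool:
        return (
            (chrom, strand, start, "start") not in exonic_positions
            and (chrom, strand, end, "end") not in exonic_positions
        )

    # --- intron circles -----------------------------------------------------
    if cfg.n_intron_circle > len(coding_introns):
        raise ValueError("more intron circles requested than coding introns available")
    order = rng.permutation(len(coding_introns))
    picked = 0
    for idx in order:
        if picked == cfg.n_intron_circle:
            break
        g, (istart, iend) = coding_introns[idx]
        if not clear_of_boundaries(g.chrom, g.strand, istart, iend):
            continue
        if register(
            PlantedCircle(
                circle_id=f"SIMC{len(circles):04d}",
                klass="intron_circle",
                chrom=g.chrom,
                strand=g.strand,
                start=istart,
                end=iend,
                gene_id=g.gene_id,
                intron=(istart, iend),
            )
        ):
            picked += 1
    if picked < cfg.n_intron_circle:
        raise ValueError("could not place all requested intron circles")

    # --- lariat intronic -----------------------------------------------------
    for _ in range(cfg.n_lariat):
        placed = False
        for _attempt in range(300):
            g, (istart, iend) = coding_introns[int(rng.integers(len(coding_introns)))]
            ilen = iend - istart + 1
            lo, hi = cfg.branch_offset
            hi = min(hi, ilen - 56)  # keep the circle >= 56 nt
            if hi < lo:
                continue
            tail = int(rng.integers(lo, hi + 1))
            if g.strand == "+":
                start, end = istart, iend - tail
            else:
                start, end = istart + tail, iend
            if not clear_of_boundaries(g.chrom, g.strand, start, end):
                continue
            if register(
                PlantedCircle(
                    circle_id=f"SIMC{len(circles):04d}",
                    klass="lariat_intronic",
                    chrom=g.chrom,
                    strand=g.strand,
                    start=start,
                    end=end,
                    gene_id=g.gene_id,
                    intron=(istart, iend),
                    tail_gap=tail,
                )
            ):
                placed = True
                break
        if not placed:
            raise ValueError("could not place all requested lariat circles")

    # --- sub-exonic ----------------------------------------------------------
    if cfg.n_subexonic and not mono:
        raise ValueError("sub-exonic circles requested but no mono-exonic gene")
    for _ in range(cfg.n_subexonic):
        placed = False
        for _attempt in range(300):
            g = mono[int(rng.integers(len(mono)))]
            es, ee = g.exons[0]
            elen = ee - es + 1
            lo, hi = cfg.subexonic_size
            hi = min(hi, elen - 2)  # strictly inside the exon
            if hi < lo:
                continue
            size = int(rng.integers(lo, hi + 1))
            start = es + 1 + int(rng.integers(0, elen - size - 1))
            end = start + size - 1
            if not clear_of_boundaries(g.chrom, g.strand, start, end):
                continue
            if register(
                PlantedCircle(
                    circle_id=f"SIMC{len(circles):04d}",
                    klass="sub_exonic",
                    chrom=g.chrom,
                    strand=g.strand,
                    start=start,
                    end=end,
                    gene_id=g.gene_id,
                )
            ):
                placed = True
                break
        if not placed:
            raise ValueError("could not place all requested sub-exonic circles")

    # homology and junction-sequence variants
    weights = np.array(cfg.homology_weights, dtype=float)
    weights = weights / weights.sum()
    for c in circles:
        c.homology = int(rng.choice(len(weights), p=weights))
        if rng.random() < cfg.variant_prob:
            c.n_variants = 2
            c.variant_inserts = ["", "".join(rng.choice(_BASES, size=3).tolist())]
        else:
            c.variant_inserts = [""]
    return circles


# ---------------------------------------------------------------------------
# read emission


def _apply_homology(genome: dict[str, list[str]], circles: list[PlantedCircle]) -> None:
    # copy the circle's first h bases to just past its end so the junction is
    # ambiguous by h bases and the aligner can shift it; edits touching a
    # position already used by another circle's homology (e.g. two exonic
    # circles sharing an exon end) truncate this circle's homology instead of
    # corrupting the earlier plant
    protected: set[tuple[str, int]] = set()
    for c in circles:
        seq = genome[c.chrom]
        effective = 0
        for off in range(c.homology):
            tgt = (c.chrom, c.end + 1 + off)
            src = (c.chrom, c.start + off)
            if tgt in protected:
                break
            seq[c.end + off] = seq[c.start - 1 + off]
            protected.add(tgt)
            protected.add(src)
            effective += 1
        c.homology = effective


def _circle_sequence(genome: dict[str, list[str]], c: PlantedCircle) -> str:
    return "".join(genome[c.chrom][c.start - 1 : c.end])


def emit_reads(
    cfg: SimConfig,
    genome: dict[str, list[str]],
    circles: list[PlantedCircle],
    genes: list[Gene],
    rng: np.random.Generator,
    outdir: Path,
) -> dict[str, Path]:
    """Write the chimeric table, chimeric SAM and SJ file for planted circles.

    Fills each circle's ``reads`` bookkeeping in place.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chimeric": outdir / "chimeric.junction.tsv",
        "sam": outdir / "chimeric.sam",
        "sj": outdir / "sj.tsv",
    }
    _apply_homology(genome, circles)

    chim_lines: list[str] = []
    sam_reads: list[tuple] = []  # (read_id, flags/positions..., seq)

    p_mate1 = (1.0 - cfg.mate_dropout) / (2.0 - cfg.mate_dropout)

    for c in circles:
        transcript = _circle_sequence(genome, c)
        if c.strand == "-":
            transcript = revcomp(transcript)
        size = c.size
        n_reads = int(rng.integers(*_incl(cfg.reads_per_circle)))
        # enumerate the distinct single-pass alignments (read length, split);
        # sampling them without replacement keeps independent molecules
        # distinguishable, so only planted PCR duplicates share a fingerprint
        unused: dict[int, list[int]] = {}
        for rl in (100, 125):
            if rl >= 2 * size:
                continue
            lo = max(cfg.min_segment, rl - size)
            hi = min(size, rl - cfg.min_segment)
            if lo <= hi:
                splits = list(range(lo, hi + 1))
                unused[rl] = [splits[i] for i in rng.permutation(len(splits))]
        if unused:
            n_reads = min(n_reads, sum(len(v) for v in unused.values()))
        for ridx in range(n_reads):
            read_len = 125 if rng.random() < cfg.p_read_125 else 100
            mate = 1 if rng.random() < p_mate1 else 2
            read_id = f"{c.circle_id}:{ridx}/{mate}"
            variant = int(rng.integers(c.n_variants)) if c.n_variants > 1 else 0
            if not unused:
                # the circle is shorter than half of every read length: any
                # read traverses the junction twice, has >2 segments and
                # cannot appear in the two-segment chimeric table
                offset = int(rng.integers(size))
                tiled = transcript * (read_len // size + 2)
                seq = tiled[offset : offset + read_len]
                pr = PlantedRead(read_id, mate, read_len, 0, 0, variant,
                                 multipass=True, seq=seq)
                c.reads.append(pr)
                sam_reads.append((read_id, c, None, None, seq, True))
                continue
            if read_len not in unused or not unused[read_len]:
                read_len = next(rl for rl, v in sorted(unused.items()) if v)
            split = unused[read_len].pop()
            seq = transcript[size - split :] + transcript[: read_len - split]
            insert = c.variant_inserts[variant]
            if insert:
                seq = (seq[:split] + insert + seq[split:])[:read_len]
            if c.klass == "lariat_intronic" and rng.random() < cfg.mismatch_rate:
                n_mut = int(rng.integers(1, 3))
                for _ in range(n_mut):
                    p = split + int(rng.integers(-5, 5))
                    p = min(max(p, 0), read_len - 1)
                    alts = [b for b in "ACGT" if b != seq[p]]
                    seq = seq[:p] + alts[int(rng.integers(3))] + seq[p + 1 :]
            shift = 0
            if c.homology > 0 and rng.random() < cfg.shift_prob:
                shift = int(rng.integers(1, c.homology + 1))
            pr = PlantedRead(read_id, mate, read_len, split, shift, variant, seq=seq)
            c.reads.append(pr)
            chim_lines.append(_chimeric_line(c, pr))
            sam_reads.append((read_id, c, pr, None, seq, False))
            if rng.random() < cfg.duplicate_rate:
                dup_id = f"{c.circle_id}:{ridx}d/{mate}"
                dup = PlantedRead(dup_id, mate, read_len, split, shift, variant,
                                  duplicate_of=read_id, seq=seq)
                c.reads.append(dup)
                chim_lines.append(_chimeric_line(c, dup))
                sam_reads.append((dup_id, c, dup, None, seq, False))

    # background: chimeric lines that are not circular junctions
    chroms = sorted(genome)
    for i in range(cfg.n_background):
        kind = i % 3
        rid = f"BG{i:04d}/1"
        c1 = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(500, 2000))
        if kind == 0:  # inter-chromosomal
            c2 = chroms[(chroms.index(c1) + 1) % len(chroms)]
            line = f"{c1}\t{pos+1000}\t+\t{c2}\t{pos}\t+\t1\t0\t0\t{rid}\t{pos+940}\t60M40S\t{pos}\t60S40M"
        elif kind == 1:  # strand mismatch
            line = f"{c1}\t{pos+1000}\t+\t{c1}\t{pos}\t-\t1\t0\t0\t{rid}\t{pos+940}\t60M40S\t{pos}\t60S40M"
        else:  # same strand, linear order (mate-encompassing junction)
            line = f"{c1}\t{pos}\t+\t{c1}\t{pos+1000}\t+\t-1\t0\t0\t{rid}\t{pos-60}\t60M40S\t{pos+1000}\t60S40M"
        chim_lines.append(line)
    # reads reported on two chimeric lines (ambiguous; the parser-side filter
    # must drop both lines)
    for i in range(cfg.n_multiline):
        rid = f"ML{i:04d}/1"
        c1 = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(500, 2000))
        for rep in range(2):
            line = (
                f"{c1}\t{pos+600+rep}\t+\t{c1}\t{pos-rep}\t+\t1\t0\t0\t{rid}"
                f"\t{pos+540+rep}\t60M40S\t{pos-rep}\t60S40M"
            )
            chim_lines.append(line)

    with open(paths["chimeric"], "w") as fh:
        fh.write("# donor_chrom\tdonor_brkpt\tdonor_strand\tacceptor_chrom\t"
                 "acceptor_brkpt\tacceptor_strand\tjunction_code\trepeat_left\t"
                 "repeat_right\tread_id\tseg1_start\tseg1_cigar\tseg2_start\tseg2_cigar\n")
        fh.write("\n".join(chim_lines) + ("\n" if chim_lines else ""))

    _write_sam(paths["sam"], genome, sam_reads)
    _write_sj(paths["sj"], genes, cfg, rng)
    return paths


def _chimeric_line(c: PlantedCircle, r: PlantedRead) -> str:
    s = c.start + r.shift
    e = c.end + r.shift
    l1, l2 = r.split, r.read_len - r.split
    if c.strand == "+":
        donor, acceptor = e + 1, s - 1
        seg1_start = e - l1 + 1
        seg2_start = s
    else:
        donor, acceptor = s - 1, e + 1
        seg1_start = s
        seg2_start = e - l2 + 1
    return (
        f"{c.chrom}\t{donor}\t{c.strand}\t{c.chrom}\t{acceptor}\t{c.strand}"
        f"\t1\t{c.homology}\t{c.homology}\t{r.read_id}"
        f"\t{seg1_start}\t{l1}M{l2}S\t{seg2_start}\t{l1}S{l2}M"
    )


def _write_sam(path: Path, genome: dict[str, list[str]], sam_reads: list[tuple]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": chrom, "LN": len(seq)} for chrom, seq in sorted(genome.items())
        ],
    }
    order = {chrom: i for i, chrom in enumerate(sorted(genome))}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for read_id, c, pr, _unused, seq, multipass in sam_reads:
            if multipass:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = read_id
                a.query_sequence = seq
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
                sam.write(a)
                continue
            s = c.start + pr.shift
            e = c.end + pr.shift
            l1, l2 = pr.split, pr.read_len - pr.split
            if c.strand == "+":
                segs = [
                    (e - l1 + 1, f"{l1}M{l2}S", 0, seq),
                    (s, f"{l1}S{l2}M", 2048, seq),
                ]
            else:
                stored = revcomp(seq)
                segs = [
                    (s, f"{l2}S{l1}M", 16, stored),
                    (e - l2 + 1, f"{l2}M{l1}S", 16 | 2048, stored),
                ]
            for pos, cigar, flag, sseq in segs:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = read_id
                a.query_sequence = sseq
                a.flag = flag
                a.reference_id = order[c.chrom]
                a.reference_start = pos - 1
                a.mapping_quality = 60
                a.cigarstring = cigar
                sam.write(a)


def _write_sj(path: Path, genes: list[Gene], cfg: SimConfig, rng: np.random.Generator) -> None:
    strand_code = {"+": 1, "-": 2}
    with open(path, "w") as fh:
        for g in genes:
            for istart, iend in g.introns:
                unique = int(rng.integers(*_incl(cfg.sj_depth)))
                fh.write(
                    f"{g.chrom}\t{istart}\t{iend}\t{strand_code[g.strand]}"
                    f"\t1\t1\t{unique}\t0\t30\n"
                )


# ---------------------------------------------------------------------------
# annotation / genome writers


def _write_fasta(path: Path, genome: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gtf(path: Path, genes: list[Gene]) -> None:
    biotype_attr = {"coding": "protein_coding", "other_nc": "snoRNA"}
    with open(path, "w") as fh:
        for g in genes:
            if g.exon_list != 1:
                continue
            for s, e in g.exons:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'gene_biotype "{biotype_attr.get(g.biotype, g.biotype)}";'
                )
                fh.write(f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def _write_bed(path: Path, genes: list[Gene], exon_list: int) -> None:
    with open(path, "w") as fh:
        for g in genes:
            if g.exon_list != exon_list:
                continue
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\t{s-1}\t{e}\t{g.gene_id}.{i}\t0\t{g.strand}\n")


def _truth_frame(circles: list[PlantedCircle], genome: dict[str, list[str]]) -> pd.DataFrame:
    from .refine import GenomeView, junction_genome_sequence

    gv = GenomeView({c: "".join(s) for c, s in genome.items()})
    rows = []
    for c in circles:
        rows.append(
            {
                "circle_id": c.circle_id,
                "klass": c.klass,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "gene_id": c.gene_id,
                "intron_start": c.intron[0] if c.intron else -1,
                "intron_end": c.intron[1] if c.intron else -1,
                "tail_gap": c.tail_gap if c.tail_gap is not None else -1,
                "homology": c.homology,
                "novel_edge": c.novel_edge,
                "n_variants": c.n_variants,
                "n_reads": c.n_reads,
                "n_duplicates": c.n_duplicates,
                "n_multipass": c.n_multipass,
                "junction_seq": junction_genome_sequence(
                    gv, c.chrom, c.strand, c.start, c.end
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate(cfg: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate the full synthetic bundle into ``outdir``.

    Writes genome.fa, annotation.gtf (exon list 1), lnc.bed (list 2),
    novel.bed (list 3), chimeric.junction.tsv, chimeric.sam, sj.tsv and
    truth.tsv; returns the in-memory bundle with per-circle bookkeeping.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, genes = build_genome_and_annotation(cfg, rng)
    circles = plant_circles(cfg, genes, rng)
    paths = emit_reads(cfg, genome, circles, genes, rng, outdir)
    paths["fasta"] = outdir / "genome.fa"
    paths["gtf"] = outdir / "annotation.gtf"
    paths["lnc_bed"] = outdir / "lnc.bed"
    paths["novel_bed"] = outdir / "novel.bed"
    paths["truth"] = outdir / "truth.tsv"
    _write_fasta(paths["fasta"], genome)
    _write_gtf(paths["gtf"], genes)
    _write_bed(paths["lnc_bed"], genes, 2)
    _write_bed(paths["novel_bed"], genes, 3)
    truth = _truth_frame(circles, genome)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return SimBundle(config=cfg, genes=genes, circles=circles, paths=paths, truth=truth)
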