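"""End-to-end orchestration: chimeric input -> classified LACs -> events -> report.

Stages (all deterministic given the inputs):

1. parse the chimeric-junction table; drop reads seen in more than one line;
2. select circular chimeric reads and restrict to the configured chromosomes;
3. convert breakpoints to circle intervals and cluster into LACs; apply the
   abundance threshold (default: >= 5 CCRs of which >= 4 distinct);
4. exonic labelling: iterative boundary matching cascaded over the ordered
   exon lists;
5. non-canonical cascade on the remainder: intron circle, trimmed lariat,
   sub-exonic (within mono-exonic genes), else unallocated;
6. with a genome (and optionally the chimeric SAM), merge shift-equivalent
   LACs into circularisation events and count distinct junction-sequences;
7. assemble the summary report.

Per-stage record counts are logged to standard error so a run's selection
funnel can be compared against published totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import pyfaidx

from . import annotation as anno
from . import chimeric as chio
from . import exonic
from . import noncanonical as nc
from . import refine
from .config import PipelineConfig
from .lac import LAC, apply_threshold, cluster_ccrs, lacs_to_frame
from .report import SummaryReport

logger = logging.getLogger("circlac")

__all__ = ["PipelineResult", "run_pipeline", "write_tables"]

KLASS_EXONIC = "exonic"


@dataclass
class PipelineResult:
    lacs: list[LAC]
    retained: list[LAC]
    exonic_labels: dict[str, exonic.ExonicLabel]
    noncanonical_labels: dict[str, nc.NonCanonicalLabel]
    events: Optional[list[refine.CircularizationEvent]]
    report: SummaryReport
    classification: pd.DataFrame = field(default_factory=pd.DataFrame)
    subexonic_sets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def klass_of(self, lac_id: str) -> str:
        if lac_id in self.exonic_labels:
            return KLASS_EXONIC
        lab = self.noncanonical_labels.get(lac_id)
        return lab.klass if lab is not None else nc.KLASS_UNALLOCATED


def _origin_of(label: exonic.ExonicLabel, gene_biotypes: dict[str, str]) -> str:
    biotypes = {gene_biotypes.get(g, "other_nc") for g in label.gene_ids}
    if "coding" in biotypes:
        return "coding"
    if "lnc" in biotypes:
        return "lnc"
    return "other"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full classification cascade described in the module docstring."""
    for name in ("chimeric_junctions", "exons_gtf"):
        value = getattr(config, name)
        if value is None:
            raise FileNotFoundError(f"config.{name} is required")
        if not Path(value).exists():
            raise FileNotFoundError(f"input not found: {name} = {value}")
    for name in ("exons_lnc_bed", "exons_novel_bed", "genome_fasta", "chimeric_sam", "sj_file"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"input not found: {name} = {value}")

    records = list(chio.parse_chimeric_junctions(config.chimeric_junctions))
    report = SummaryReport(n_chimeric_lines=len(records))
    records = chio.drop_multiline_reads(records)
    report.n_after_multiline_filter = len(records)
    logger.info("chimeric lines: %d (unique-read: %d)", report.n_chimeric_lines, len(records))

    ccrs = [r for r in records if chio.is_ccr(r, min_segment=config.min_segment)]
    report.n_ccr = len(ccrs)
    ccrs = chio.filter_chromosomes(ccrs, config.chromosomes)
    report.n_ccr_retained_chroms = len(ccrs)
    logger.info("CCRs: %d (on retained chromosomes: %d)", report.n_ccr, len(ccrs))

    if config.chimeric_sam:
        ccrs = chio.attach_read_sequences(ccrs, config.chimeric_sam)

    junctions = [chio.ccr_to_junction(r, offsets=config.offsets) for r in ccrs]
    lacs = cluster_ccrs(junctions)
    report.n_lac = len(lacs)
    retained = apply_threshold(lacs, min_ccr=config.min_ccr, min_distinct=config.min_distinct)
    report.n_lac_retained = len(retained)
    report.n_ccr_retained = sum(l.ccr_count for l in retained)
    logger.info(
        "LACs: %d, retained at >=%d CCRs / >=%d distinct: %d (%d CCRs)",
        len(lacs), config.min_ccr, config.min_distinct, len(retained), report.n_ccr_retained,
    )

    # --- annotation resources ---------------------------------------------
    exon_lists = [anno.read_exons_gtf(config.exons_gtf, list_id=1)]
    if config.exons_lnc_bed:
        exon_lists.append(anno.read_exons_bed(config.exons_lnc_bed, list_id=2, biotype="lnc"))
    if config.exons_novel_bed:
        exon_lists.append(anno.read_exons_bed(config.exons_novel_bed, list_id=3, biotype="novel"))
    exon_lists = anno.dedup_exon_lists(exon_lists)
    gene_biotypes = {ex.gene_id: ex.biotype for exons in exon_lists for ex in exons}
    coding_exons = [ex for ex in exon_lists[0] if ex.biotype == "coding"]
    introns = anno.derive_introns(coding_exons)
    genes = anno.find_mono_exonic(exon_lists[0])
    mono_exons = [
        ex for ex in exon_lists[0] if genes[ex.gene_id].mono_exonic
    ]

    # --- exonic cascade ----------------------------------------------------
    exonic_labels = exonic.cascade(
        retained, exon_lists, max_rounds=config.max_rounds,
        min_support=config.min_promote_support,
    )
    remaining = [l for l in retained if l.lac_id not in exonic_labels]
    logger.info("exonic LACs: %d (remaining: %d)", len(exonic_labels), len(remaining))

    # --- non-canonical cascade --------------------------------------------
    nc_labels = nc.classify(
        remaining, introns, mono_exons,
        min_tail=config.min_tail,
        branch_window=config.branch_window,
        min_subexonic_size=config.min_subexonic_size,
        confident_size=config.confident_subexonic_size,
    )
    nc_labels = nc.group_sets(remaining, nc_labels)

    # --- refinement --------------------------------------------------------
    events = None
    genome = None
    subexonic_sets = nc.set_summary(remaining, nc_labels, mono_exons)
    if config.genome_fasta:
        genome = refine.GenomeView(pyfaidx.Fasta(str(config.genome_fasta)))
        subexonic_sets = nc.set_summary(remaining, nc_labels, mono_exons, genome)
        jseqs: dict[str, list[refine.JunctionSequence]] = {}
        for lac in retained:
            seqs = []
            for rec in lac.records:
                if rec.read_seq is None:
                    continue
                try:
                    seqs.append(refine.extract_junction_sequence(rec, k=config.junction_k))
                except ValueError:
                    logger.warning("could not locate junction in read %s", rec.read_id)
            if seqs:
                jseqs[lac.lac_id] = seqs
        events = refine.merge_events(
            retained, genome, jseqs,
            max_shift=config.max_shift, k=config.junction_k,
            mismatch_tol=config.mismatch_tol, mismatch_window=config.mismatch_window,
        )
        report.n_events = len(events)
        report.n_distinct_circrnas = sum(e.n_distinct_circrnas for e in events)
        logger.info("events: %d (distinct circRNAs: %d)", len(events), report.n_distinct_circrnas)

    # --- summary -----------------------------------------------------------
    rows = []
    for lac in retained:
        if lac.lac_id in exonic_labels:
            klass = KLASS_EXONIC
            lab = exonic_labels[lac.lac_id]
            gene = ",".join(sorted(lab.gene_ids))
            extra = {"mode": lab.mode, "round": lab.round, "list_id": lab.list_id}
        else:
            lab = nc_labels[lac.lac_id]
            klass = lab.klass
            gene = lab.gene_id or ""
            extra = {"mode": "", "round": 0, "list_id": 0}
        r1, r2 = lac.mate_counts
        rows.append(
            {
                "lac_id": lac.lac_id, "chrom": lac.chrom, "start": lac.start,
                "end": lac.end, "strand": lac.strand, "size": lac.size,
                "ccr_count": lac.ccr_count, "distinct_ccr_count": lac.distinct_ccr_count,
                "klass": klass, "gene_ids": gene, "reads1": r1, "reads2": r2,
                **extra,
            }
        )
        report.class_lac_counts[klass] = report.class_lac_counts.get(klass, 0) + 1
        report.class_ccr_counts[klass] = report.class_ccr_counts.get(klass, 0) + lac.ccr_count
        report.mate_split[lac.lac_id] = (r1, r2)
        if klass == KLASS_EXONIC:
            origin = _origin_of(exonic_labels[lac.lac_id], gene_biotypes)
            report.origin_ccr_counts[origin] = (
                report.origin_ccr_counts.get(origin, 0) + lac.ccr_count
            )
    stats = nc.size_stats(remaining, nc_labels)
    report.mean_lariat_size = stats["mean_lariat_size"]
    report.validate()

    classification = pd.DataFrame(rows)
    return PipelineResult(
        lacs=lacs,
        retained=retained,
        exonic_labels=exonic_labels,
        noncanonical_labels=nc_labels,
        events=events,
        report=report,
        classification=classification,
        subexonic_sets=subexonic_sets,
    )


def _write_bed(path: Path, frame: pd.DataFrame) -> None:
    # 1-based inclusive -> 0-based half-open at the output boundary only
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.lac_id}"
                f"\t{row.ccr_count}\t{row.strand}\n"
            )


def write_tables(result: PipelineResult, outdir: str | Path) -> None:
    """Write the LAC/classification/event/set tables, per-class BEDs, report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lac_frame = lacs_to_frame(result.lacs)
    lac_frame.to_csv(outdir / "lacs.tsv", sep="\t", index=False)
    _write_bed(outdir / "lacs.bed", lac_frame)
    result.classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    if len(result.classification):
        for klass, sub in result.classification.groupby("klass"):
            _write_bed(outdir / f"class_{klass}.bed", sub)
    result.subexonic_sets.to_csv(outdir / "subexonic_sets.tsv", sep="\t", index=False)
    if result.events is not None:
        rows = []
        for i, ev in enumerate(result.events, start=1):
            chrom, strand, start, end = ev.representative
            rows.append(
                {
                    "event_id": i, "chrom": chrom, "strand": strand,
                    "start": start, "end": end,
                    "n_members": len(ev.member_lacs),
                    "members": ";".join(m.lac_id for m in ev.member_lacs),
                    "n_distinct_circrnas": ev.n_distinct_circrnas,
                    "junction_sequences": ";".join(
                        js.sequence for js in ev.junction_sequences
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "events.tsv", sep="\t", index=False)
    from .report import format_report

    (outdir / "summary.txt").write_text(format_report(result.report))
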