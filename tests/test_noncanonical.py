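"""Intron circles, trimmed lariats, sub-exonic circles and their sets."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from circlac.annotation import ExonRecord, IntronRecord
from circlac.noncanonical import (
    KLASS_CIRCLE,
    KLASS_LARIAT,
    KLASS_SUBEXONIC,
    KLASS_UNALLOCATED,
    classify,
    group_sets,
    match_intron_circle,
    match_lariat,
    match_subexonic,
    size_stats,
)

from conftest import make_lac


def _intron(start, end, gene="g1", chrom="chr1", strand="+"):
    return IntronRecord(chrom=chrom, strand=strand, start=start, end=end, gene_id=gene,
                        upstream_exon_end=start - 1, downstream_exon_start=end + 1)


def _mono_exon(start, end, gene="sno1", chrom="chr1", strand="+"):
    return ExonRecord(chrom=chrom, strand=strand, start=start, end=end, gene_id=gene,
                      transcript_id=f"{gene}.t", biotype="other_nc", list_id=1)


class TestIntronCircle:
    def test_exact_match(self):
        assert match_intron_circle(make_lac(start=201, end=299), [_intron(201, 299)])

    def test_near_miss_rejected(self):
        assert match_intron_circle(make_lac(start=202, end=299), [_intron(201, 299)]) is None

    def test_all_planted_circles_recovered(self, clean_bundle, clean_result):
        planted = {(c.chrom, c.strand, c.start, c.end)
                   for c in clean_bundle.circles if c.klass == "intron_circle"}
        called = {
            (l.chrom, l.strand, l.start, l.end)
            for l in clean_result.retained
            if clean_result.klass_of(l.lac_id) == KLASS_CIRCLE
        }
        assert called == planted


class TestLariat:
    def test_defining_case_with_tail_gap(self):
        got = match_lariat(make_lac(start=201, end=470), [_intron(201, 500)])
        assert got is not None and got[1] == 30

    def test_five_prime_mismatch_rejected(self):
        assert match_lariat(make_lac(start=202, end=470), [_intron(201, 500)]) is None

    def test_minus_strand_uses_intron_end(self):
        intron = _intron(201, 500, strand="-")
        got = match_lariat(make_lac(strand="-", start=231, end=500), [intron])
        assert got is not None and got[1] == 30
        assert match_lariat(make_lac(strand="-", start=231, end=499), [intron]) is None

    def test_small_lariat_not_size_filtered(self):
        """A 78-nt lariat circle from a short intron is accepted: no minimum
        circle size applies to intron-derived circRNAs."""
        got = match_lariat(make_lac(start=1000, end=1077), [_intron(1000, 1139)])
        assert got is not None
        lac = make_lac(start=1000, end=1077)
        assert lac.size == 78

    def test_full_intron_is_not_a_lariat(self):
        assert match_lariat(make_lac(start=201, end=500), [_intron(201, 500)]) is None

    def test_branch_window_cap(self):
        lac = make_lac(start=201, end=400)
        assert match_lariat(lac, [_intron(201, 500)], branch_window=50) is None
        assert match_lariat(lac, [_intron(201, 500)], branch_window=150) is not None


class TestSubExonic:
    EXON = [_mono_exon(1000, 1258)]  # 259-exon hosting the circles

    def test_inside_exon_confident(self):
        got = match_subexonic(make_lac(start=1040, end=1184), self.EXON)
        assert got is not None and got[1] is True
        assert make_lac(start=1040, end=1184).size == 145

    def test_below_minimum_size(self):
        assert match_subexonic(make_lac(start=1040, end=1093), self.EXON) is None

    def test_at_but_not_above_confident_size(self):
        got = match_subexonic(make_lac(start=1040, end=1109), self.EXON)  # 70 nt
        assert got is not None and got[1] is False

    def test_full_exon_rejected(self):
        assert match_subexonic(make_lac(start=1000, end=1258), self.EXON) is None

    def test_edge_outside_rejected(self):
        assert match_subexonic(make_lac(start=990, end=1184), self.EXON) is None


class TestCascade:
    def test_each_lac_gets_exactly_one_class(self, clean_result):
        labelled = set(clean_result.exonic_labels) | set(clean_result.noncanonical_labels)
        assert labelled == {l.lac_id for l in clean_result.retained}
        assert not set(clean_result.exonic_labels) & set(clean_result.noncanonical_labels)

    def test_circle_beats_lariat(self):
        """A full-intron LAC is an intron circle, never a lariat (tail gap 0)."""
        lac = make_lac(start=201, end=500)
        labels = classify([lac], [_intron(201, 500)], [])
        assert labels[lac.lac_id].klass == KLASS_CIRCLE

    def test_unallocated_fallback(self):
        lac = make_lac(start=5, end=80)
        labels = classify([lac], [_intron(201, 500)], [])
        assert labels[lac.lac_id].klass == KLASS_UNALLOCATED

    def test_noise_free_synthetic_run_is_fully_correct(self, clean_bundle, clean_result):
        truth = {(c.chrom, c.strand, c.start, c.end): c.klass for c in clean_bundle.circles}
        assert len(clean_result.retained) == len(clean_bundle.circles)
        for lac in clean_result.retained:
            assert clean_result.klass_of(lac.lac_id) == truth[
                (lac.chrom, lac.strand, lac.start, lac.end)
            ]


class TestSets:
    def _classify(self, lacs, exon):
        labels = classify(lacs, [], [exon])
        return group_sets(lacs, labels)

    def test_all_overlapping_one_set(self):
        exon = _mono_exon(1000, 1600)
        lacs = [make_lac(start=1100 + i * 10, end=1300 + i * 10) for i in range(5)]
        labels = self._classify(lacs, exon)
        assert {labels[l.lac_id].set_id for l in lacs} == {1}

    def test_disjoint_clusters_split(self):
        exon = _mono_exon(1000, 1600)
        lacs = [make_lac(start=1010, end=1100), make_lac(start=1020, end=1110),
                make_lac(start=1015, end=1090),
                make_lac(start=1300, end=1400), make_lac(start=1350, end=1460)]
        labels = self._classify(lacs, exon)
        sets = [labels[l.lac_id].set_id for l in lacs]
        assert sets[:3] == [sets[0]] * 3 and sets[3] == sets[4] != sets[0]

    def test_partition_equals_connected_components(self):
        """Random intervals in one exon: sets equal graph components under
        positive-overlap edges (single linkage)."""
        rng = np.random.default_rng(5)
        exon = _mono_exon(1000, 4000, gene="big")
        lacs = []
        coords = set()
        while len(lacs) < 40:
            s = int(rng.integers(1001, 3800))
            e = s + int(rng.integers(55, 200))
            if e >= 4000 or (s, e) in coords:
                continue
            coords.add((s, e))
            lacs.append(make_lac(start=s, end=e))
        labels = self._classify(lacs, exon)
        g = nx.Graph()
        g.add_nodes_from(l.lac_id for l in lacs)
        for i, a in enumerate(lacs):
            for b in lacs[i + 1:]:
                if min(a.end, b.end) >= max(a.start, b.start):
                    g.add_edge(a.lac_id, b.lac_id)
        components = {frozenset(c) for c in nx.connected_components(g)}
        by_set: dict[int, set] = {}
        for l in lacs:
            by_set.setdefault(labels[l.lac_id].set_id, set()).add(l.lac_id)
        assert {frozenset(v) for v in by_set.values()} == components


class TestSizeStats:
    def test_mean_of_lariat_sizes(self):
        from circlac.noncanonical import NonCanonicalLabel

        lacs = [make_lac(start=1, end=100), make_lac(start=201, end=400),
                make_lac(start=1001, end=1300)]
        labels = {l.lac_id: NonCanonicalLabel(l.lac_id, KLASS_LARIAT) for l in lacs}
        stats = size_stats(lacs, labels)
        assert stats["mean_lariat_size"] == pytest.approx(200.0)
        assert stats["fraction_lariat_gt_600"] == 0.0

    def test_empty_class_reports_absent(self):
        stats = size_stats([], {})
        assert stats["mean_lariat_size"] is None

    def test_simulated_mean_matches_generator(self, clean_bundle, clean_result):
        sizes = [c.size for c in clean_bundle.circles if c.klass == "lariat_intronic"]
        remaining = [l for l in clean_result.retained
                     if l.lac_id not in clean_result.exonic_labels]
        stats = size_stats(remaining, clean_result.noncanonical_labels)
        assert stats["mean_lariat_size"] == pytest.approx(sum(sizes) / len(sizes))


class TestSetSummary:
    def test_summary_rows_cover_all_subexonic_lacs(self, clean_bundle, clean_result):
        import pyfaidx
        from circlac.noncanonical import set_summary
        from circlac.refine import GenomeView
        from circlac.annotation import find_mono_exonic, read_exons_gtf

        exons = read_exons_gtf(clean_bundle.paths["gtf"])
        genes = find_mono_exonic(exons)
        mono = [e for e in exons if genes[e.gene_id].mono_exonic]
        remaining = [l for l in clean_result.retained
                     if l.lac_id not in clean_result.exonic_labels]
        genome = GenomeView(pyfaidx.Fasta(str(clean_bundle.paths["fasta"])))
        df = set_summary(remaining, clean_result.noncanonical_labels, mono, genome)
        n_sub = sum(1 for lab in clean_result.noncanonical_labels.values()
                    if lab.klass == KLASS_SUBEXONIC)
        # set specs ("count x min-max nt") account for every sub-exonic LAC
        counts = df.set_spec.str.extract(r"^(\d+) x").iloc[:, 0].astype(int)
        assert counts.sum() == n_sub
        assert (df.gc_pct.between(0, 100)).all()
        mono_len = {e.gene_id: e.end - e.start + 1 for e in mono}
        for row in df.itertuples(index=False):
            assert row.exon_length == mono_len[row.gene_id]
            assert row.n_ccr > 0
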