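"""Junction sequences, shift-equivalence, event merging, multipass, motifs."""

from __future__ import annotations

import numpy as np
import pytest

from circlac.chimeric import ChimericRecord
from circlac.refine import (
    GenomeView,
    JunctionSequence,
    check_multipass,
    extract_junction_sequence,
    junction_genome_sequence,
    merge_events,
    read_split_point,
    revcomp,
    shift_equivalent,
    splice_motif,
)

from conftest import make_lac


def _rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _ccr(seq, l1, mate=1, rid=None):
    l2 = len(seq) - l1
    return ChimericRecord(
        read_id=rid or f"r/{mate}", chrom_donor="chr1", brkpt_donor=5000,
        strand_donor="+", chrom_acceptor="chr1", brkpt_acceptor=2000,
        strand_acceptor="+", junction_code=1, repeat_left=0, repeat_right=0,
        seg1_start=4941, seg1_cigar=f"{l1}M{l2}S", seg2_start=2001,
        seg2_cigar=f"{l1}S{l2}M", read_seq=seq,
    )


def _genome(seqs: dict[str, str]) -> GenomeView:
    return GenomeView(seqs)


class TestExtraction:
    def test_centered_window(self):
        seq = "A" * 60 + "C" * 40
        js = extract_junction_sequence(_ccr(seq, 60), k=15)
        assert js.sequence == "A" * 15 + "C" * 15 and js.left_len == 15

    def test_truncated_short_side(self):
        seq = "A" * 10 + "C" * 90
        js = extract_junction_sequence(_ccr(seq, 10), k=15)
        assert js.sequence == "A" * 10 + "C" * 15 and js.left_len == 10

    def test_split_point_from_cigars(self):
        assert read_split_point(_ccr("A" * 100, 37)) == 37

    def test_missing_sequence_errors(self):
        rec = _ccr("A" * 100, 60)
        rec = ChimericRecord(**{**rec.__dict__, "read_seq": None})
        with pytest.raises(ValueError, match="no sequence"):
            extract_junction_sequence(rec)

    def test_simulated_reads_share_planted_junction_context(self, clean_bundle):
        """Unmutated reads of one circle all yield the planted junction
        sequence (simulator truth)."""
        import pysam

        seqs = {}
        with pysam.AlignmentFile(str(clean_bundle.paths["sam"]), "r") as sam:
            for aln in sam:
                s = aln.get_forward_sequence()
                if s:
                    seqs[aln.query_name] = s
        checked = 0
        for c in clean_bundle.circles[:40]:
            planted = c.reads[0]
            truth_js = clean_bundle.truth.set_index("circle_id").junction_seq[c.circle_id]
            for r in c.reads:
                if r.multipass:
                    continue
                rec = _ccr(seqs[r.read_id], r.split, rid=r.read_id)
                js = extract_junction_sequence(rec, k=15)
                lo = 15 - min(15, js.left_len)
                expect = truth_js[lo: 15 + (len(js.sequence) - js.left_len)]
                assert js.sequence == expect
                checked += 1
        assert checked > 50


def _planted_genome(h, spacer=200, size=145, seed=0):
    """Genome with circle [1001, 1000+size] carrying exactly h bases of
    junction microhomology (the base after the homology is forced to differ,
    so chance extension cannot blur the planted length)."""
    rng = np.random.default_rng(seed)
    g = list(_rng_seq(rng, 1000 + size + spacer))
    for off in range(h):
        g[1000 + size + off] = g[1000 + off]  # bases past end = circle head
    src = g[1000 + h]
    if g[1000 + size + h] == src:
        g[1000 + size + h] = {"A": "C", "C": "A", "G": "T", "T": "G"}[src]
    return _genome({"chr1": "".join(g)})


def _junction_read(genome: GenomeView, lac, split: int, total: int = 60) -> str:
    """Brute-force reconstruction of a junction-spanning read of ``total``
    bases whose first ``split`` bases precede the junction."""
    tail = genome.fetch(lac.chrom, lac.end - split + 1, lac.end)
    head = genome.fetch(lac.chrom, lac.start, lac.start + (total - split) - 1)
    return tail + head


class TestShiftEquivalence:

    def test_two_base_homology_offset_two(self):
        genome = _planted_genome(2)
        a, b = make_lac(start=1001, end=1145), make_lac(start=1003, end=1147)
        assert shift_equivalent(a, b, genome) == 2
        assert shift_equivalent(b, a, genome) == -2

    def test_no_homology_not_equivalent(self):
        genome = _planted_genome(0)
        a, b = make_lac(start=1001, end=1145), make_lac(start=1002, end=1146)
        # random flanks: equivalence would need base equality, overwhelmingly false
        assert shift_equivalent(a, b, genome) is None

    def test_self_is_offset_zero(self):
        genome = _planted_genome(0)
        a = make_lac(start=1001, end=1145)
        assert shift_equivalent(a, a, genome) == 0

    def test_unequal_edge_shifts_rejected(self):
        genome = _planted_genome(3)
        a, b = make_lac(start=1001, end=1145), make_lac(start=1002, end=1147)
        assert shift_equivalent(a, b, genome) is None

    @pytest.mark.parametrize("h", [1, 2, 3, 5])
    def test_agrees_with_bruteforce_junction_reconstruction(self, h):
        """Two LACs are shift-equivalent exactly when one physical read can be
        reconstructed from both coordinate pairs (with splits compensating the
        shift) -- brute-force sequence comparison as the oracle."""
        genome = _planted_genome(h, seed=h)
        base = make_lac(start=1001, end=1145)
        for delta in range(0, 6):
            other = make_lac(start=1001 + delta, end=1145 + delta)
            got = shift_equivalent(base, other, genome, max_shift=5)
            brute_equal = _junction_read(genome, base, 30) == _junction_read(
                genome, other, 30 + delta
            )
            assert (got is not None) == brute_equal
            if delta <= h:
                assert got == delta
            else:
                assert got is None


class TestMergeEvents:
    def test_five_lacs_two_junction_sequences(self):
        """Five shift-equivalent 145-nt LACs collapse to one event carrying
        two distinct circRNAs (two junction-sequence clusters)."""
        genome = _planted_genome(4)
        lacs = [make_lac(start=1001 + d, end=1145 + d, n_reads=5) for d in range(5)]
        js_a = junction_genome_sequence(genome, "chr1", "+", 1001, 1145)
        # a second variant: 3 extra bases at the junction displace the tail
        js_b = js_a[:15] + "TTT" + js_a[15:27]
        jseqs = {
            lacs[0].lac_id: [JunctionSequence(js_a, 15, 1, 0)] * 3
            + [JunctionSequence(js_b, 15, 0, 1)] * 2,
            lacs[1].lac_id: [JunctionSequence(js_a, 15, 1, 0)],
            lacs[3].lac_id: [JunctionSequence(js_b, 15, 0, 1)],
        }
        events = merge_events(lacs, genome, jseqs)
        assert len(events) == 1
        assert events[0].n_distinct_circrnas == 2
        assert len(events[0].member_lacs) == 5

    def test_three_lacs_single_circrna(self):
        """Three shift-equivalent 115-nt LACs whose reads all share one
        junction-sequence are a single circRNA."""
        genome = _planted_genome(2, size=115)
        lacs = [make_lac(start=1001 + d, end=1115 + d, n_reads=4) for d in range(3)]
        js = junction_genome_sequence(genome, "chr1", "+", 1001, 1115)
        jseqs = {l.lac_id: [JunctionSequence(js, 15, 1, 1)] for l in lacs}
        events = merge_events(lacs, genome, jseqs)
        assert len(events) == 1 and events[0].n_distinct_circrnas == 1

    def test_non_overlapping_lacs_stay_separate(self):
        genome = _planted_genome(0, spacer=2000)
        lacs = [make_lac(start=1001, end=1145), make_lac(start=2001, end=2145)]
        events = merge_events(lacs, genome, {})
        assert len(events) == 2
        assert all(e.n_distinct_circrnas == 1 for e in events)

    def test_member_conservation(self, noisy_result):
        events = noisy_result.events
        assert sum(len(e.member_lacs) for e in events) == len(noisy_result.retained)
        assert len(events) <= len(noisy_result.retained)

    def test_near_junction_mismatches_tolerated(self):
        genome = _planted_genome(0)
        lac = make_lac(start=1001, end=1145, n_reads=4)
        js = junction_genome_sequence(genome, "chr1", "+", 1001, 1145)
        mutated = js[:14] + ("A" if js[14] != "A" else "C") + js[15:]
        jseqs = {lac.lac_id: [JunctionSequence(js, 15, 1, 0)] * 3
                 + [JunctionSequence(mutated, 15, 0, 1)]}
        (event,) = merge_events([lac], genome, jseqs)
        assert event.n_distinct_circrnas == 1
        # but a far-from-junction mismatch separates circRNAs
        far = js[:2] + ("A" if js[2] != "A" else "C") + js[3:]
        jseqs = {lac.lac_id: [JunctionSequence(js, 15, 1, 0)] * 3
                 + [JunctionSequence(far, 15, 0, 1)]}
        (event,) = merge_events([lac], genome, jseqs)
        assert event.n_distinct_circrnas == 2


class TestMultipass:
    def test_small_circle_single_junction_read_inconsistent(self):
        # a 61-nt circle must show its junction twice in a 125-nt read
        assert check_multipass(125, 61, 1) == "inconsistent"

    def test_hundred_nt_read_on_71_nt_circle_consistent(self):
        assert check_multipass(100, 71, 1) == "consistent"

    def test_double_passage_consistent(self):
        assert check_multipass(125, 63, 2) == "consistent"

    def test_simulated_multipass_reads(self, tmp_path):
        """Circles below half the read length yield two-pass reads whose
        sequence contains the junction twice."""
        from circlac.simulate import SimConfig, simulate

        cfg = SimConfig(
            seed=5, n_exonic=0, n_lariat=0, n_intron_circle=0, n_subexonic=6,
            subexonic_size=(40, 48), p_read_125=1.0,
        )
        bundle = simulate(cfg, tmp_path / "small")
        multi = [r for c in bundle.circles for r in c.reads if r.multipass]
        assert multi
        for c in bundle.circles:
            js = bundle.truth.set_index("circle_id").junction_seq[c.circle_id]
            for r in c.reads:
                if not r.multipass:
                    continue
                assert check_multipass(r.read_len, c.size, 2) == "consistent"
                assert js in r.seq or js in (r.seq + r.seq)


class TestSpliceMotif:
    def test_canonical_and_noncanonical(self):
        #          acceptor  circle       donor
        seq = "NNNN" + "AG" + "CCCCCCCCCC" + "GT" + "NNNN"
        genome = _genome({"chr1": seq})
        pair, canonical = splice_motif(genome, "chr1", "+", 7, 16)
        assert (pair, canonical) == ("GT/AG", True)
        seq2 = "NNNN" + "CC" + "CCCCCCCCCC" + "AT" + "NNNN"
        pair2, canonical2 = splice_motif(_genome({"chr1": seq2}), "chr1", "+", 7, 16)
        assert (pair2, canonical2) == ("AT/CC", False)

    def test_minus_strand_orientation(self):
        # on the minus strand the donor follows the circle's genomic start
        seq = "NNNN" + "AC" + "CCCCCCCCCC" + "CT" + "NNNN"
        genome = _genome({"chr1": seq})
        pair, canonical = splice_motif(genome, "chr1", "-", 7, 16)
        assert (pair, canonical) == ("GT/AG", True)

    def test_out_of_bounds_errors(self):
        genome = _genome({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError):
            splice_motif(genome, "chr1", "+", 2, 8)
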