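"""Junction-sequence refinement on a hand-built locus.

Builds a small genome holding a 145-nt circle whose junction carries four
bases of microhomology, so an aligner may place the junction at five
different coordinate pairs (five LACs for one circularisation event).  The
reads carry two distinct junction-sequences, i.e. the event produced two
co-located circRNAs.  Also shows the multipass consistency check for very
small circles.
"""

import numpy as np

from circlac.refine import (
    GenomeView, JunctionSequence, check_multipass, junction_genome_sequence,
    merge_events, shift_equivalent, splice_motif,
)
from circlac.lac import LAC

rng = np.random.default_rng(0)
g = list("".join(rng.choice(list("ACGT"), size=1500)))
for off in range(4):  # 4-base microhomology: bases after the end repeat the head
    g[1145 + off] = g[1000 + off]
genome = GenomeView({"chr1": "".join(g)})

lacs = [LAC("chr1", "+", 1001 + d, 1145 + d) for d in range(5)]
print("adjacent LACs shift-equivalent:",
      [shift_equivalent(lacs[0], lacs[d], genome) for d in range(5)])

js_a = junction_genome_sequence(genome, "chr1", "+", 1001, 1145)
js_b = js_a[:15] + "AGG" + js_a[15:27]  # a 3-base untemplated insert variant
jseqs = {
    lacs[0].lac_id: [JunctionSequence(js_a, 15, 6, 7)],
    lacs[2].lac_id: [JunctionSequence(js_b, 15, 2, 3)],
}
(event,) = merge_events(lacs, genome, jseqs)
print(f"events: 1 ({len(event.member_lacs)} member LACs, "
      f"{event.n_distinct_circrnas} distinct circRNAs)")

# a 61-nt circle must show its junction twice in a 125-nt read
print("125-nt read on 61-nt circle, one junction:", check_multipass(125, 61, 1))
print("100-nt read on 71-nt circle, one junction:", check_multipass(100, 71, 1))

# splice motif at the (non-back-splice) junction: GT/AG would be canonical
pair, canonical = splice_motif(genome, "chr1", "+", 1001, 1145)
print(f"flanking dinucleotides: {pair} (canonical: {canonical})")

# One event explains all five LACs; the junction-sequence clusters say the
# locus produced two distinct circles despite identical coordinates spread.
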