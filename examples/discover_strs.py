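"""Scan a contig for tetra/penta STR candidates and triage them.

Builds a small synthetic contig containing a good marker-grade repeat, an
interrupted repeat, and a too-short repeat, then runs discovery and the
candidacy rules.
"""

import numpy as np

from equistr import filter_candidates, find_tandem_repeats

rng = np.random.default_rng(1)
flank = lambda n: "".join(rng.choice(list("ACGT"), n))

contig = (
    flank(120)
    + "AGAT" * 13           # clean marker-grade array (LUS 13)
    + flank(400)
    + "TCTA" * 4 + "TCTG" + "TCTA" * 11   # interrupted array (LUS 11)
    + flank(400)
    + "GATC" * 5            # LUS 5: too short for reliable polymorphism
    + flank(120)
)

loci = find_tandem_repeats(contig, unit_lengths=(4, 5), min_copies=4,
                           sequence_id="contig1")
for verdict in filter_candidates(loci):
    loc = verdict.locus
    reasons = "; ".join(r for r, _ in verdict.reasons) or "-"
    print(f"{loc.start:5d}-{loc.end:<5d} {loc.motif.unit:6s} "
          f"LUS={loc.lus:<3d} SW={loc.sw_score:<4d} {verdict.status:5s} "
          f"{loc.structure_string:30s} {reasons}")

print()
print("A PASS locus has LUS >= 8 (enough slippage polymorphism) and an")
print("alignment score inside the 450-700 window (variable but low-stutter);")
print("short-LUS loci FAIL because score alone does not predict variability,")
print("and only the best locus per chromosome keeps PASS status.")
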