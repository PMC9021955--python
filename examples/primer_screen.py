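"""Multiplex primer QC on the packaged 17-plex + amelogenin panel.

Runs the AA-3' census, the pairwise dimer scan, and the 3'-templating rule
over all 36 primers.
"""

from equistr import load_panel
from equistr.primer_qc import qc_panel_primers

panel = load_panel()
report = qc_panel_primers(panel, dimer_threshold=7, max_templating=2)

n = report["n_primers"]
aa = len(report["aa_rule_primers"])
print(f"AA-3' census: {aa}/{n} primers end in AA "
      f"({100 * report['aa_rule_fraction']:.0f}%)")
print("(A:A cannot base-pair, so AA 3' ends rarely seed primer-dimers.)\n")

fails = report["dimer_failures"]
print(f"dimer screen: {len(report['dimer_reports'])} pairs scanned, "
      f"{len(fails)} at score >= 7 under the package's operational score:")
for r in fails:
    print(f"  {r.primer_a} x {r.primer_b}: score {r.best_score}")
print("\n3'-templating failures (> 2 anchored bases):",
      len(report["templating_failures"]))
print("\nThe operational dimer score (matches - mismatches at the best")
print("ungapped offset) is a package convention; scores near the threshold")
print("flag pairs worth checking, not necessarily failed chemistry.")
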