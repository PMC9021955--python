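"""Multiplex primer QC: the AA-3′ rule, dimer screening, 3′ templating.

Primer-dimer is the dominant failure mode of large multiplexes.  Three
checks are applied to every primer in the panel:

* **AA-3′ rule** — primers whose templated sequence ends in two adenines are
  far less likely to seed dimers (A:A cannot pair), so the panel aims for a
  high AA-ending fraction.
* **Dimer score** — for each primer pair (self-pairs included) the best
  ungapped antiparallel annealing register is scored as Watson–Crick matches
  minus mismatches; a score of 7 or more fails.  Pigtails are physically
  present in the tube, so they participate here.
* **3′ templating** — the longest run of Watson–Crick pairings anchored at a
  primer's 3′ terminus against any position of a partner primer; more than
  two templated bases risks extendable artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .panel import Panel, Primer

__all__ = [
    "DimerReport",
    "check_aa_rule",
    "dimer_score",
    "three_prime_templating",
    "qc_panel_primers",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class DimerReport:
    primer_a: str
    primer_b: str
    best_score: int
    offset: int
    aligned_span: str
    verdict: str  # OK | FAIL


def check_aa_rule(primer: Primer) -> bool:
    """True iff the templated (pigtail-stripped) sequence ends in ``AA``."""
    return primer.templated.endswith("AA")


def dimer_score(
    primer_a: Primer,
    primer_b: Primer,
    threshold: int = 7,
    name_a: str = "a",
    name_b: str = "b",
) -> DimerReport:
    """Best ungapped annealing score between two primers (symmetric).

    Primer b is taken in its annealing (reverse-complement) orientation and
    slid along primer a at every offset; each overlap position scores +1 for
    an A:T / G:C pair and −1 otherwise.  Only canonical Watson–Crick pairs
    count (no G:T wobble).  Verdict FAIL iff the best score reaches
    ``threshold``.  Pigtails are included — they are physically present.
    """
    a = primer_a.full_upper
    b_rc = _revcomp(primer_b.full_upper)
    if len(primer_a.templated) < 8 or len(primer_b.templated) < 8:
        raise ValueError("primers must have >= 8 templated nt for dimer scanning")
    best, best_off, best_span = None, 0, ""
    for off in range(-(len(b_rc) - 1), len(a)):
        lo_a, hi_a = max(0, off), min(len(a), off + len(b_rc))
        if hi_a <= lo_a:
            continue
        score = 0
        for i in range(lo_a, hi_a):
            score += 1 if a[i] == b_rc[i - off] else -1
        if best is None or score > best:
            best, best_off = score, off
            best_span = a[lo_a:hi_a]
    verdict = "FAIL" if best >= threshold else "OK"
    return DimerReport(name_a, name_b, int(best), best_off, best_span, verdict)


def three_prime_templating(
    extending: Primer,
    template: Primer,
    max_bases: int = 2,
) -> tuple[int, bool]:
    """Longest 3′-anchored pairing run of ``extending`` on ``template``.

    Counts the longest contiguous Watson–Crick run that ends at the 3′
    terminus of the extending primer, annealed antiparallel at any position
    of the template (both template orientations searched).  The extending 3′
    end is the templated sequence (a pigtail is never a 3′ end); the template
    side is searched with its pigtail stripped (only templated sequence can
    be copied).  Returns ``(count, passed)`` with failure iff
    ``count > max_bases``.
    """
    e = extending.templated
    targets = (template.templated, _revcomp(template.templated))
    best = 0
    for t in targets:
        # a 3'-anchored pairing run of length m == the m-suffix of `e`
        # appearing as a substring of revcomp(t)
        rc = _revcomp(t)
        for m in range(len(e), 0, -1):
            if e[-m:] in rc:
                best = max(best, m)
                break
    return best, best <= max_bases


def qc_panel_primers(
    panel: Panel,
    dimer_threshold: int = 7,
    max_templating: int = 2,
) -> dict:
    """Batch QC over all panel primers (STR markers + sex marker).

    Returns all pairwise (self included) dimer reports ordered by primer
    name, per-marker reverse-on-forward 3′-templating failures (the
    templating rule applies within a primer set, where both primers reach
    high local concentration on the same amplicon), and the AA-rule census.
    """
    primers: list[tuple[str, Primer]] = []
    for m in panel.all_markers:
        primers.append((f"{m.name}.F", m.primer_f))
        primers.append((f"{m.name}.R", m.primer_r))
    primers.sort(key=lambda kv: kv[0])
    reports: list[DimerReport] = []
    for i, (na, pa) in enumerate(primers):
        for nb, pb in primers[i:]:
            reports.append(dimer_score(pa, pb, dimer_threshold, na, nb))
    templating_failures: list[tuple[str, str, int]] = []
    for m in panel.all_markers:
        count, ok = three_prime_templating(m.primer_r, m.primer_f, max_templating)
        if not ok:
            templating_failures.append((f"{m.name}.R", f"{m.name}.F", count))
    aa_hits = [name for name, p in primers if check_aa_rule(p)]
    return {
        "dimer_reports": reports,
        "dimer_failures": [r for r in reports if r.verdict == "FAIL"],
        "templating_failures": templating_failures,
        "aa_rule_primers": aa_hits,
        "aa_rule_fraction": len(aa_hits) / len(primers),
        "n_primers": len(primers),
    }
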