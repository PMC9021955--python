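"""Tetra/penta-STR discovery: repeat scanning, scoring, and candidate triage.

A candidate profiling marker is a tandem repeat with a 4- or 5-base unit whose
repeat-alignment score sits in a window (roughly 450–700 under the historical
RepeatMasker weights) and whose longest uninterrupted stretch (LUS) of exact
motif copies is at least 8 — long enough for useful polymorphism — but ideally
below 16 — short enough to keep stutter manageable.  This module finds the
repeats, scores them, decomposes them into bracketed nomenclature
(``[TCTA]4[TCTG][TCTA]11``), and applies those rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio import Align

from .panel import Motif, parse_structure

__all__ = [
    "Scoring",
    "StrLocus",
    "CandidateVerdict",
    "find_tandem_repeats",
    "sw_score",
    "decompose_structure",
    "lus",
    "higher_order_lus",
    "flag_flanking",
    "candidate_filter",
    "filter_candidates",
    "loci_to_bed",
]

_SEQ_RE = re.compile(r"^[ACGTN]+$")

#: Default repeat-alignment weights.  The +9 match weight is calibrated so a
#: perfect array of total length L bases scores 9*L, matching the published
#: scores of perfect-repeat loci ([TAAAA]9 -> 405, [AGAT]13 -> 468); the
#: mismatch/gap weights follow simple-repeat-masking practice.  A gap of
#: length L costs open + (L-1)*extend.
DEFAULT_SCORING = (9, -9, -13, -4)


@dataclass(frozen=True)
class Scoring:
    match: int = 9
    mismatch: int = -9
    gap_open: int = -13
    gap_extend: int = -4


@dataclass
class StrLocus:
    """A discovered tandem repeat (0-based half-open coordinates)."""

    sequence_id: str
    start: int
    end: int
    motif: Motif
    lus: int
    sw_score: int
    structure_string: str
    sequence: str
    higher_order_lus: Optional[tuple[int, int]] = None
    flanking_unique: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")
        if self.lus < 1 or self.sw_score < 0:
            raise ValueError("locus must have lus >= 1 and sw_score >= 0")


@dataclass
class CandidateVerdict:
    locus: StrLocus
    status: str  # PASS | WARN | FAIL
    reasons: list[tuple[str, str]] = field(default_factory=list)


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if not _SEQ_RE.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"illegal characters in sequence: {bad}")
    return seq


def _is_primitive(unit: str, max_period: Optional[int] = None) -> bool:
    """True if the unit is not itself a repetition of a shorter unit."""
    limit = max_period if max_period is not None else len(unit) - 1
    for d in range(1, limit + 1):
        if len(unit) % d == 0 and d < len(unit) and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _perfect_runs(seq: str, u: int) -> list[tuple[int, int, int]]:
    """Maximal perfect tandem runs of period u: (start, end, copies), copies >= 2.

    N (or any non-ACGT symbol) breaks runs.  Runs are trimmed to whole copies.
    """
    n = len(seq)
    runs: list[tuple[int, int, int]] = []
    i = 0
    while i + 2 * u <= n:
        if seq[i] not in "ACGT" or seq[i:i + u] != seq[i + u:i + 2 * u] or "N" in seq[i:i + 2 * u]:
            i += 1
            continue
        # extend the periodic stretch
        j = i + 2 * u
        while j < n and seq[j] == seq[j - u] and seq[j] in "ACGT":
            j += 1
        copies = (j - i) // u
        unit = seq[i:i + u]
        if copies >= 2 and _is_primitive(unit):
            runs.append((i, i + copies * u, copies))
        # next candidate run cannot start inside this periodic stretch with
        # the same period; skip past it
        i = j - u + 1
    return runs


def find_tandem_repeats(
    sequence: str,
    unit_lengths: Iterable[int] = (4, 5),
    min_copies: int = 4,
    max_interruption: int = 6,
    sequence_id: str = "seq",
    scoring: Scoring = Scoring(),
) -> list[StrLocus]:
    """Scan a sequence for tetra/penta tandem repeats.

    Perfect runs of the same motif (up to rotation) separated by short
    interruptions (``<= max_interruption`` bases, e.g. a one-unit variant
    block or a 3-bp indel remnant) are merged into one locus.  A locus is
    reported when its longest perfect run reaches ``min_copies``.  The motif
    is reported as the upper-strand unit at the locus's first full copy; N
    breaks runs.
    """
    seq = _validate_sequence(sequence)
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    loci: list[StrLocus] = []
    for u in sorted(set(unit_lengths)):
        runs = _perfect_runs(seq, u)
        # group mergeable chains: same canonical motif, small gap
        chains: list[list[tuple[int, int, int]]] = []
        for run in sorted(runs):
            unit = seq[run[0]:run[0] + u]
            merged = False
            if chains:
                last = chains[-1][-1]
                last_unit = seq[last[0]:last[0] + u]
                if (_canonical_rotation(unit) == _canonical_rotation(last_unit)
                        and 0 <= run[0] - last[1] <= max_interruption):
                    chains[-1].append(run)
                    merged = True
            if not merged:
                chains.append([run])
        for chain in chains:
            best_run = max(r[2] for r in chain)
            if best_run < min_copies:
                continue
            start, end = chain[0][0], chain[-1][1]
            motif = Motif(seq[start:start + u])
            locus_seq = seq[start:end]
            structure = decompose_structure(locus_seq, motif)
            loci.append(StrLocus(
                sequence_id=sequence_id,
                start=start,
                end=end,
                motif=motif,
                lus=lus(structure, motif=motif),
                sw_score=sw_score(locus_seq, motif, scoring),
                structure_string=structure,
                sequence=locus_seq,
                higher_order_lus=higher_order_lus(locus_seq),
            ))
    loci.sort(key=lambda l: (l.start, l.end))
    return loci


def sw_score(locus_sequence: str, motif: Motif, scoring: Scoring = Scoring()) -> int:
    """Local-alignment score of a sequence against a perfect array of the motif.

    The reference side is a perfect tandem array long enough to cover the
    query, so a perfect repeat of total length L scores ``match * L``.
    Alignment uses affine gaps (``gap_open`` for the first gapped base,
    ``gap_extend`` thereafter).
    """
    seq = _validate_sequence(locus_sequence)
    u = motif.unit_length
    copies = len(seq) // u + 3
    array = motif.unit * copies
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return int(round(aligner.score(seq, array)))


def decompose_structure(locus_sequence: str, motif: Motif) -> str:
    """Greedy left-to-right bracketed decomposition of a repeat region.

    Unit-length blocks equal to the motif, or one substitution away from it
    when the reading frame is confirmed by the following block, are emitted as
    bracketed runs (``[TCTA]4``, ``[TCTG]``); anything else is a bare literal
    (``ATC``).  Concatenating the decomposition reproduces the input exactly.
    """
    seq = _validate_sequence(locus_sequence)
    unit = motif.unit
    u = len(unit)
    parts: list[tuple[str, int, bool]] = []
    i, n = 0, len(seq)
    while i < n:
        if n - i >= u:
            block = seq[i:i + u]
            nxt = seq[i + u:i + 2 * u]
            hamming = sum(a != b for a, b in zip(block, unit))
            in_frame = nxt == block or nxt == unit or i + u == n
            if block == unit or (hamming == 1 and in_frame):
                j, count = i, 0
                while seq[j:j + u] == block:
                    j, count = j + u, count + 1
                parts.append((block, count, True))
                i = j
                continue
        k = seq.find(unit, i + 1)
        stop = k if k != -1 else n
        parts.append((seq[i:stop], 1, False))
        i = stop
    rendered = []
    for block, count, bracketed in parts:
        if bracketed:
            rendered.append(f"[{block}]{count if count > 1 else ''}")
        else:
            rendered.append(block)
    return "".join(rendered)


def lus(structure: "str | StrLocus", motif: Optional[Motif] = None) -> int:
    """Longest uninterrupted stretch: max run count of exact motif copies.

    Accepts a structure string or a discovered locus.  Without an explicit
    motif, the largest bracketed run count is used (the motif run always
    dominates variant-unit runs in practice).
    """
    if isinstance(structure, StrLocus):
        motif = structure.motif
        structure = structure.structure_string
    counts = [
        count
        for block, count, bracketed in parse_structure(structure)
        if bracketed and (motif is None or block == motif.unit)
    ]
    return max(counts, default=0)


def higher_order_lus(
    sequence: str, unit_range: tuple[int, int] = (6, 20), min_copies: int = 3
) -> Optional[tuple[int, int]]:
    """Best higher-order perfect repeat: ``(unit_length, copies)`` or None.

    Searches unit lengths 6–20 for tandem arrays of at least ``min_copies``
    exact copies whose unit is not itself a short-period repeat.  This is the
    structure behind markers that are polymorphic despite a short motif LUS
    (a 16-bp unit repeated five times, say).
    """
    seq = sequence.upper()
    best: Optional[tuple[int, int]] = None
    for u in range(unit_range[0], unit_range[1] + 1):
        for start, end, copies in _perfect_runs(seq, u):
            unit = seq[start:start + u]
            if copies < min_copies or not _is_primitive(unit, max_period=5):
                continue
            if best is None or u * copies > best[0] * best[1]:
                best = (u, copies)
    return best


def flag_flanking(loci: Sequence[StrLocus], amplicon_span_bp: int = 300) -> list[StrLocus]:
    """Mark loci whose amplicon span would co-amplify another detected STR.

    Flanking uniqueness here means: no other detected repeat locus on the same
    sequence within ``amplicon_span_bp`` of the locus midpoint.
    """
    out = []
    for loc in loci:
        mid = (loc.start + loc.end) / 2
        clean = all(
            other is loc
            or other.sequence_id != loc.sequence_id
            or abs((other.start + other.end) / 2 - mid) > amplicon_span_bp
            for other in loci
        )
        out.append(replace(loc, flanking_unique=clean))
    return out


def candidate_filter(
    locus: StrLocus,
    sw_window: tuple[int, int] = (450, 700),
    lus_window: tuple[int, int] = (8, 15),
    require_flanking_unique: bool = True,
) -> CandidateVerdict:
    """Apply the marker-candidacy rules to one locus.

    Hard failures: LUS below 8 (too little polymorphism regardless of score)
    and non-unique flanking sequence (co-amplified repeats).  Soft warnings:
    score outside the 450–700 window and LUS of 16 or more (stutter/mutation
    risk) — soft because the published panel itself fields a score-931 and an
    LUS-18 marker.
    """
    reasons: list[tuple[str, str]] = []
    hard = False
    if locus.lus < lus_window[0]:
        hard = True
        msg = f"LUS {locus.lus} < {lus_window[0]}: insufficient polymorphism expected"
        if locus.higher_order_lus is not None:
            u, c = locus.higher_order_lus
            msg += f" (higher-order {u}-bp unit x{c} present; may still vary)"
        reasons.append(("lus-too-short", msg))
    elif locus.lus > lus_window[1]:
        reasons.append(("lus-above-window",
                        f"LUS {locus.lus} > {lus_window[1]}: high stutter expected"))
    if not sw_window[0] <= locus.sw_score <= sw_window[1]:
        side = "above" if locus.sw_score > sw_window[1] else "below"
        reasons.append(("sw-outside-window",
                        f"SW {locus.sw_score} {side} window {sw_window}"))
    if require_flanking_unique and not locus.flanking_unique:
        hard = True
        reasons.append(("flanking-contamination",
                        "another STR within the amplicon span"))
    status = "FAIL" if hard else ("WARN" if reasons else "PASS")
    return CandidateVerdict(locus, status, reasons)


def filter_candidates(
    loci: Sequence[StrLocus],
    one_per_chromosome: bool = True,
    **rules,
) -> list[CandidateVerdict]:
    """Batch candidate filtering with the one-marker-per-chromosome rule.

    When several loci on one sequence pass, only the highest-scoring PASS is
    kept; the rest are demoted to WARN ("secondary on chromosome").
    """
    verdicts = [candidate_filter(loc, **rules) for loc in loci]
    if one_per_chromosome:
        best: dict[str, CandidateVerdict] = {}
        for v in verdicts:
            if v.status != "PASS":
                continue
            cur = best.get(v.locus.sequence_id)
            if cur is None or v.locus.sw_score > cur.locus.sw_score:
                best[v.locus.sequence_id] = v
        for v in verdicts:
            if v.status == "PASS" and best.get(v.locus.sequence_id) is not v:
                v.status = "WARN"
                v.reasons.append(("secondary-on-chromosome",
                                  "higher-scoring candidate on same chromosome"))
    return verdicts


def loci_to_bed(loci: Sequence[StrLocus]) -> str:
    """Render loci as BED6 text (name=motif, score=SW, strand=+)."""
    lines = [
        f"{l.sequence_id}\t{l.start}\t{l.end}\t{l.motif.unit}\t{l.sw_score}\t+"
        for l in loci
    ]
    return "\n".join(lines) + ("\n" if lines else "")
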