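"""Independent brute-force oracles used to validate the production code.

Everything here is deliberately naive (quadratic DP, exhaustive enumeration,
position-by-position scans) and shares no code with the implementations it
checks.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _complement(a: str, b: str) -> bool:
    return (a, b) in _PAIR


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# local alignment (Gotoh affine-gap DP)


def local_align_score(
    query: str,
    target: str,
    match: int = 9,
    mismatch: int = -9,
    gap_open: int = -13,
    gap_extend: int = -4,
) -> int:
    """Smith-Waterman with affine gaps: a gap of length L costs
    ``-(open + (L-1)*extend)``; quadratic DP, no shortcuts."""
    n, m = len(query), len(target)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (skip query)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def repeat_score(locus_sequence: str, unit: str, **weights) -> int:
    """Score against a perfect array long enough to cover the query."""
    copies = len(locus_sequence) // len(unit) + 3
    return local_align_score(locus_sequence, unit * copies, **weights)


# ---------------------------------------------------------------------------
# primer interaction oracles


def dimer_best_score(a: str, b: str) -> int:
    """Best ungapped antiparallel annealing score, matches − mismatches.

    Enumerates every diagonal: position i of `a` pairs position j of `b`
    (both 5'→3') on diagonal i + j = s.
    """
    a, b = a.upper(), b.upper()
    best = None
    for s in range(len(a) + len(b) - 1):
        score, any_pair = 0, False
        for i in range(len(a)):
            j = s - i
            if 0 <= j < len(b):
                any_pair = True
                score += 1 if _complement(a[i], b[j]) else -1
        if any_pair and (best is None or score > best):
            best = score
    return best


def templating_count(extending: str, template: str) -> int:
    """Longest 3'-anchored pairing run, scanned base by base on both strands."""
    e = extending.upper()
    best = 0
    for t in (template.upper(), revcomp(template.upper())):
        for j in range(len(t)):
            m = 0
            while (m < len(e) and j + m < len(t)
                   and _complement(e[len(e) - 1 - m], t[j + m])):
                m += 1
            best = max(best, m)
    return best


# ---------------------------------------------------------------------------
# forensic-statistic enumeration oracles (small k only)


def _genotype_probs(freqs: Mapping[str, float]) -> dict[tuple[str, str], float]:
    alleles = list(freqs)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            out[(a, b)] = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    return out


def pi_enum(freqs: Mapping[str, float]) -> float:
    """P(two unrelated HWE genotypes match) by genotype-pair enumeration."""
    return sum(p ** 2 for p in _genotype_probs(freqs).values())


def pisib_enum(freqs: Mapping[str, float]) -> float:
    """P(two full sibs match) by enumerating parents and transmissions."""
    alleles = list(freqs)
    total = 0.0
    for m1, m2, f1, f2 in itertools.product(alleles, repeat=4):
        p_par = freqs[m1] * freqs[m2] * freqs[f1] * freqs[f2]
        child: dict[tuple[str, str], float] = {}
        for cm in (m1, m2):
            for cf in (f1, f2):
                g = tuple(sorted((cm, cf)))
                child[g] = child.get(g, 0.0) + 0.25
        total += p_par * sum(q ** 2 for q in child.values())
    return total


def ne1p_enum(freqs: Mapping[str, float]) -> float:
    """P(random non-parent shares >= 1 allele with a random HWE offspring)."""
    total = 0.0
    for (c1, c2), pc in _genotype_probs(freqs).items():
        q = freqs[c1] + (freqs[c2] if c2 != c1 else 0.0)
        total += pc * (1.0 - (1.0 - q) ** 2)
    return total


def ne2p_enum(freqs: Mapping[str, float]) -> float:
    """P(random candidate can supply the paternal allele), mother known.

    Enumerates mother and true-father genotypes and the four transmissions;
    the candidate is not excluded iff it carries one of the alleles that
    could be paternal given the mother-child pair.
    """
    alleles = list(freqs)
    total = 0.0
    for m1, m2, f1, f2 in itertools.product(alleles, repeat=4):
        p_par = freqs[m1] * freqs[m2] * freqs[f1] * freqs[f2]
        maternal = {m1, m2}
        for cm in (m1, m2):
            for cf in (f1, f2):
                paternal_options = set()
                if cm in maternal:
                    paternal_options.add(cf)
                if cf in maternal:
                    paternal_options.add(cm)
                q = sum(freqs[a] for a in paternal_options)
                total += p_par * 0.25 * (1.0 - (1.0 - q) ** 2)
    return total


def build_from_structure(parts: Sequence[tuple[str, int]]) -> str:
    """Sequence from (block, count) parts — the generator side of the
    decomposition round-trip property."""
    return "".join(block * count for block, count in parts)
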