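"""Mendelian trio checking and homozygosity-based candidate-gene exclusion.

Trio checks tolerate single-step STR mutation: a locus where the offspring
can be explained by mutating one transmitted allele by exactly one repeat
unit is flagged as a mutation suspect rather than a mismatch, and exclusion
of a candidate parent requires mismatches at two or more loci.

Candidate-gene exclusion triages genes by the genotypes of affected, inbred
individuals at STR markers flanking each gene (within ~2 Mb): under a
recessive model all affecteds should be identical-by-descent, hence
effectively homozygous, at a tightly linked marker — a heterozygote with
alleles more than one repeat apart excludes the gene; under a dominant or
X-linked model all affecteds should share an allele — two affecteds
homozygous for different alleles exclude the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .panel import Marker, Panel, allele_repeat_value

__all__ = [
    "LocusVerdict",
    "TrioResult",
    "ExclusionResult",
    "trio_check",
    "exclude_candidate_gene",
]

Genotype = Optional[tuple[str, str]]


@dataclass
class LocusVerdict:
    marker: str
    verdict: str  # COMPATIBLE | MUTATION_SUSPECT | MISMATCH
    mismatch_size_repeats: int = 0


@dataclass
class TrioResult:
    per_locus: list[LocusVerdict]
    excluded: bool
    n_mismatch: int
    n_suspect: int


def _min_transmission_cost(
    child: tuple[str, str], dam: tuple[str, str], sire: tuple[str, str],
    unit_length: int,
) -> float:
    """Minimal total repeat-step edit making the trio Mendelian.

    Considers both assignments of the child's alleles to maternal/paternal
    origin; each transmitted allele costs its repeat distance to the nearest
    allele of the putative transmitting parent (0 if present).
    """
    def dist(allele: str, parent: tuple[str, str]) -> float:
        v = allele_repeat_value(allele, unit_length)
        return min(abs(v - allele_repeat_value(p, unit_length)) for p in parent)

    best = float("inf")
    for c_mat, c_pat in (child, child[::-1]):
        cost = dist(c_mat, dam) + dist(c_pat, sire)
        best = min(best, cost)
    return best


def trio_check(
    offspring: Mapping[str, Genotype],
    dam: Mapping[str, Genotype],
    sire: Mapping[str, Genotype],
    panel: Panel,
    exclusion_threshold: int = 2,
) -> TrioResult:
    """Check offspring/dam/sire genotypes locus by locus.

    Per locus: COMPATIBLE if some assignment gives one allele from each
    parent; a minimal edit of exactly one repeat unit on one transmission is
    MUTATION_SUSPECT; two or more units (or edits on both transmissions) is
    MISMATCH.  Loci with missing data are skipped.  The trio is excluded when
    at least ``exclusion_threshold`` loci mismatch (single-locus conflicts
    may be mutations).
    """
    per_locus: list[LocusVerdict] = []
    for marker in panel.markers:
        g_c, g_d, g_s = (m.get(marker.name) for m in (offspring, dam, sire))
        if g_c is None or g_d is None or g_s is None:
            continue
        cost = _min_transmission_cost(g_c, g_d, g_s, marker.unit_length)
        if cost == 0:
            verdict = "COMPATIBLE"
        elif cost <= 1:
            verdict = "MUTATION_SUSPECT"
        else:
            verdict = "MISMATCH"
        per_locus.append(LocusVerdict(marker.name, verdict, int(round(cost))))
    n_mis = sum(v.verdict == "MISMATCH" for v in per_locus)
    n_sus = sum(v.verdict == "MUTATION_SUSPECT" for v in per_locus)
    return TrioResult(per_locus, n_mis >= exclusion_threshold, n_mis, n_sus)


@dataclass
class ExclusionResult:
    gene: str
    model: str  # RECESSIVE | DOMINANT_OR_XLINKED
    verdict: str  # EXCLUDED | NOT_EXCLUDED | UNTESTABLE
    flanking_markers: list[str] = field(default_factory=list)
    evidence: list[tuple[str, str, tuple[str, str]]] = field(default_factory=list)


def exclude_candidate_gene(
    gene: str,
    gene_chromosome: str,
    gene_position_mb: float,
    affected: Mapping[str, Mapping[str, Genotype]],
    markers: Sequence[Marker],
    model: str,
    window_mb: float = 2.0,
) -> ExclusionResult:
    """Test one candidate gene against affected-cohort genotypes.

    RECESSIVE: excluded iff any affected individual is heterozygous at a
    flanking marker with alleles more than one repeat unit apart (one-repeat
    heterozygotes are tolerated as possible mutations).
    DOMINANT_OR_XLINKED: excluded iff two affected individuals are homozygous
    for different alleles at the same flanking marker.  With no marker inside
    the window the gene is UNTESTABLE — never silently "not excluded".
    """
    if model not in ("RECESSIVE", "DOMINANT_OR_XLINKED"):
        raise ValueError(f"unknown inheritance model {model!r}")
    flank = [
        m for m in markers
        if m.chromosome == gene_chromosome and m.position_mb is not None
        and abs(m.position_mb - gene_position_mb) <= window_mb
    ]
    if not flank:
        return ExclusionResult(gene, model, "UNTESTABLE")
    evidence: list[tuple[str, str, tuple[str, str]]] = []
    if model == "RECESSIVE":
        for ind, genos in affected.items():
            for m in flank:
                g = genos.get(m.name)
                if g is None or g[0] == g[1]:
                    continue
                sep = abs(allele_repeat_value(g[0], m.unit_length)
                          - allele_repeat_value(g[1], m.unit_length))
                if sep > 1:
                    evidence.append((ind, m.name, g))
    else:
        for m in flank:
            homs: dict[str, str] = {}  # allele -> first individual
            for ind, genos in affected.items():
                g = genos.get(m.name)
                if g is None or g[0] != g[1]:
                    continue
                for seen_allele, seen_ind in homs.items():
                    if seen_allele != g[0]:
                        evidence.append((seen_ind, m.name, (seen_allele, seen_allele)))
                        evidence.append((ind, m.name, g))
                homs.setdefault(g[0], ind)
    verdict = "EXCLUDED" if evidence else "NOT_EXCLUDED"
    return ExclusionResult(gene, model, verdict, [m.name for m in flank], evidence)
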