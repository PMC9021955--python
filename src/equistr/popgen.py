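"""Forensic population-genetic statistics for STR panels.

Per-locus statistics are functions of the allele-frequency power sums
``S_k = sum_i p_i^k``:

* expected heterozygosity  He = 1 − S2
* probability of identity (unrelated)  PI = 2·S2² − S4
* probability of identity (full sibs)  PIsib = 1/4 + S2/2 + S2²/2 − S4/4
* first-parent exclusion (no known parent)
  PE1 = 1 − 4·S2 + 2·S2² + 4·S3 − 3·S4   (non-exclusion NE1P = 1 − PE1)
* second-parent exclusion (one parent known)
  PE2 = 1 − 2·S2 + S3 + 3·(S2·S3 − S5) − 2·(S2² − S4)   (NE2P = 1 − PE2)

These are the standard match-probability and Jamieson–Taylor exclusion forms
computed by the usual parentage software.  Panel-wide statistics multiply
across independently assorting loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import GenotypeDataset, Panel, allele_repeat_value

__all__ = [
    "AlleleFrequencies",
    "LocusStats",
    "PanelStats",
    "allele_frequencies",
    "power_sums",
    "locus_stats_from_freqs",
    "locus_stats",
    "combine_panel",
    "hwe_test",
    "assign_population",
]


@dataclass
class AlleleFrequencies:
    """Allele frequencies per (population, marker) stratum.

    ``freqs[(population, marker)]`` maps allele name → frequency; the pooled
    stratum uses population label ``"ALL"``.  ``n_typed`` counts genotyped
    individuals per stratum.
    """

    freqs: dict[tuple[str, str], dict[str, float]]
    n_typed: dict[tuple[str, str], int]

    def get(self, marker: str, population: str = "ALL") -> dict[str, float]:
        return self.freqs[(population, marker)]


def allele_frequencies(
    dataset: GenotypeDataset, by_population: bool = False
) -> AlleleFrequencies:
    """Count-based allele frequencies; missing genotypes leave the denominator."""
    strata: dict[tuple[str, str], dict[str, int]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    for ind in dataset.individuals:
        pops = ["ALL"] + ([ind.population] if by_population else [])
        for m in dataset.markers:
            g = ind.genotypes.get(m)
            if g is None:
                continue
            for pop in pops:
                key = (pop, m)
                counts = strata.setdefault(key, {})
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
                n_typed[key] = n_typed.get(key, 0) + 1
    freqs = {
        key: {a: c / (2 * n_typed[key]) for a, c in sorted(counts.items())}
        for key, counts in strata.items()
    }
    for key, f in freqs.items():
        if not math.isclose(sum(f.values()), 1.0, abs_tol=1e-9):
            raise AssertionError(f"frequencies at {key} do not sum to 1")
    return AlleleFrequencies(freqs, n_typed)


def power_sums(freqs: Mapping[str, float], k_max: int = 5) -> list[float]:
    """Power sums ``[S2, ..., S_kmax]`` of a frequency vector."""
    p = np.asarray(list(freqs.values()), float)
    if p.size == 0:
        raise ValueError("empty frequency map")
    return [float(np.sum(p ** k)) for k in range(2, k_max + 1)]


@dataclass
class LocusStats:
    marker: str
    s2: float
    s3: float
    s4: float
    s5: float
    he: float
    ho: Optional[float] = None
    pi: float = 1.0
    pisib: float = 1.0
    ne1p: float = 1.0
    ne2p: float = 1.0
    hwe_p: Optional[float] = None
    null_r: Optional[float] = None
    n_typed: Optional[int] = None


def locus_stats_from_freqs(
    marker: str,
    freqs: Mapping[str, float],
    ho: Optional[float] = None,
    n_typed: Optional[int] = None,
    unbiased_he: bool = False,
) -> LocusStats:
    """Closed-form per-locus statistics from an allele-frequency vector.

    ``unbiased_he`` applies the small-sample 2n/(2n−1) correction; the default
    plain 1 − S2 matches the usual software convention.  Monomorphic loci have
    no discriminating or exclusion power (PI = PIsib = NE = 1).
    """
    s2, s3, s4, s5 = power_sums(freqs)
    he = 1.0 - s2
    if unbiased_he and n_typed:
        he *= (2 * n_typed) / (2 * n_typed - 1)
    pi = 2 * s2 ** 2 - s4
    pisib = 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4
    pe1 = 1 - 4 * s2 + 2 * s2 ** 2 + 4 * s3 - 3 * s4
    pe2 = 1 - 2 * s2 + s3 + 3 * (s2 * s3 - s5) - 2 * (s2 ** 2 - s4)
    null_r = None
    if ho is not None:
        null_r = (he - ho) / (1 + he)  # Brookfield null-allele estimator
    return LocusStats(
        marker=marker, s2=s2, s3=s3, s4=s4, s5=s5, he=he, ho=ho,
        pi=pi, pisib=pisib, ne1p=1 - pe1, ne2p=1 - pe2,
        null_r=null_r, n_typed=n_typed,
    )


def locus_stats(
    dataset: GenotypeDataset,
    marker: str,
    population: Optional[str] = None,
    hwe_method: Optional[str] = None,
    hwe_reps: int = 10_000,
    seed: Optional[int] = None,
    unbiased_he: bool = False,
) -> LocusStats:
    """Per-locus statistics from observed genotypes (Ho from the data)."""
    inds = [
        ind for ind in dataset.individuals
        if (population is None or ind.population == population)
        and ind.genotypes.get(marker) is not None
    ]
    if not inds:
        raise ValueError(f"no typed individuals at {marker}")
    counts: dict[str, int] = {}
    het = 0
    for ind in inds:
        a, b = ind.genotypes[marker]
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
        het += a != b
    n = len(inds)
    freqs = {a: c / (2 * n) for a, c in sorted(counts.items())}
    st = locus_stats_from_freqs(marker, freqs, ho=het / n, n_typed=n,
                                unbiased_he=unbiased_he)
    if hwe_method is not None:
        st.hwe_p = hwe_test(dataset, marker, method=hwe_method,
                            population=population, mc_reps=hwe_reps, seed=seed)
    return st


@dataclass
class PanelStats:
    """Panel-wide products and means over per-locus statistics."""

    loci: list[LocusStats]
    combined_pi: float
    combined_pisib: float
    combined_ne1p: float
    combined_ne2p: float
    mean_ho: Optional[float]
    mean_he: float
    excluded_loci: list[str] = field(default_factory=list)


def combine_panel(
    per_locus: Sequence[LocusStats], loci: Optional[Sequence[str]] = None
) -> PanelStats:
    """Multiply per-locus statistics across independently assorting loci.

    Loci with undefined values are excluded from the affected product/mean
    and reported in ``excluded_loci``.
    """
    chosen = [s for s in per_locus if loci is None or s.marker in set(loci)]
    if not chosen:
        raise ValueError("no loci to combine")
    defined = [s for s in chosen if np.isfinite(s.pi)]
    excluded = [s.marker for s in chosen if s not in defined]
    hos = [s.ho for s in chosen if s.ho is not None]
    return PanelStats(
        loci=list(chosen),
        combined_pi=float(np.prod([s.pi for s in defined])),
        combined_pisib=float(np.prod([s.pisib for s in defined])),
        combined_ne1p=float(np.prod([s.ne1p for s in chosen])),
        combined_ne2p=float(np.prod([s.ne2p for s in chosen])),
        mean_ho=float(np.mean(hos)) if hos else None,
        mean_he=float(np.mean([s.he for s in chosen])),
        excluded_loci=excluded,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg / null-allele screening


def _genotype_counts(dataset: GenotypeDataset, marker: str,
                     population: Optional[str]) -> list[tuple[str, str]]:
    out = []
    for ind in dataset.individuals:
        if population is not None and ind.population != population:
            continue
        g = ind.genotypes.get(marker)
        if g is not None:
            out.append(tuple(sorted(g)))
    return out


def hwe_test(
    dataset: GenotypeDataset,
    marker: str,
    method: str = "mc_exact",
    mc_reps: int = 10_000,
    seed: Optional[int] = None,
    population: Optional[str] = None,
) -> float:
    """Hardy-Weinberg test geared to null-allele screening.

    ``chi2``: goodness-of-fit over genotype classes with rare expected classes
    (< 1) pooled.  ``mc_exact``: Monte-Carlo permutation of alleles among
    individuals; the p-value is the fraction of permuted datasets whose
    heterozygote count is at most the observed count (one-sided heterozygote
    deficiency — the signature of a segregating null allele).
    """
    genos = _genotype_counts(dataset, marker, population)
    if len(genos) < 5:
        raise ValueError(f"{marker}: need >= 5 typed individuals for HWE")
    n = len(genos)
    alleles = sorted({a for g in genos for a in g})
    freqs = {a: 0.0 for a in alleles}
    for g in genos:
        for a in g:
            freqs[a] += 1 / (2 * n)
    if method == "chi2":
        obs: dict[tuple[str, str], int] = {}
        for g in genos:
            obs[g] = obs.get(g, 0) + 1
        classes = []
        for i, a in enumerate(alleles):
            for b in alleles[i:]:
                exp = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
                classes.append((obs.get((a, b), 0), exp))
        pooled_o = pooled_e = 0.0
        terms = []
        for o, e in classes:
            if e < 1.0:
                pooled_o += o
                pooled_e += e
            else:
                terms.append((o, e))
        if pooled_e > 0:
            terms.append((pooled_o, pooled_e))
        chi2 = sum((o - e) ** 2 / e for o, e in terms)
        dof = max(len(terms) - len(alleles), 1)
        return float(sps.chi2.sf(chi2, dof))
    if method == "mc_exact":
        rng = np.random.default_rng(seed)
        pool = np.array([a for g in genos for a in g])
        het_obs = sum(a != b for a, b in genos)
        hits = 0
        for _ in range(mc_reps):
            rng.shuffle(pool)
            pairs = pool.reshape(-1, 2)
            het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
            hits += het <= het_obs
        return (hits + 1) / (mc_reps + 1)
    raise ValueError(f"unknown HWE method {method!r}")


# ---------------------------------------------------------------------------
# breed assignment


def assign_population(
    individual_genotypes: Mapping[str, Optional[tuple[str, str]]],
    freqs: AlleleFrequencies,
    populations: Optional[Sequence[str]] = None,
    zero_freq: float = 0.005,
    leave_one_out: bool = False,
    self_population: Optional[str] = None,
) -> tuple[str, dict[str, float], bool]:
    """Assign an individual to the population with the highest genotype likelihood.

    Log-likelihood sums ``log P(genotype | HWE, population frequencies)`` over
    typed loci, substituting ``zero_freq`` for alleles unseen in a population.
    With ``leave_one_out`` the individual's own alleles are removed from its
    source population's counts first (requires ``self_population``).  Returns
    ``(best, loglik per population, tied)``; ties break by population name
    order and are flagged.
    """
    pops = list(populations) if populations is not None else sorted(
        {p for (p, _m) in freqs.freqs if p != "ALL"}
    )
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    loglik = {pop: 0.0 for pop in pops}
    for pop in pops:
        for m, g in individual_genotypes.items():
            if g is None or (pop, m) not in freqs.freqs:
                continue
            f = freqs.freqs[(pop, m)]
            n = freqs.n_typed[(pop, m)]
            counts = {a: p * 2 * n for a, p in f.items()}
            denom = 2 * n
            if leave_one_out and pop == self_population:
                for a in g:
                    if counts.get(a, 0) > 0:
                        counts[a] -= 1
                        denom -= 1
            pa = max(counts.get(g[0], 0) / denom if denom else 0.0, zero_freq)
            pb = max(counts.get(g[1], 0) / denom if denom else 0.0, zero_freq)
            prob = pa * pb if g[0] == g[1] else 2 * pa * pb
            loglik[pop] += math.log(prob)
    best = max(pops, key=lambda p: (loglik[p], ))
    top = [p for p in pops if math.isclose(loglik[p], loglik[best], abs_tol=1e-12)]
    tied = len(top) > 1
    return sorted(top)[0], loglik, tied
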