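"""Synthetic study generator with known ground truth.

The real study genotypes were never released, so every pipeline input is
emulated here with the study's own regime as the defaults: the 17 panel
markers, roughly 8.3 alleles per marker, expected heterozygosity in the
0.62–0.82 within-breed band (mean ≈ 0.72), 16 breed strata with modest
divergence, one high-frequency (38%) deletion-derived micro-variant on the
Eca12 marker, per-marker stutter ratios and predicted mutation rates from the
panel table, and fragment sizes with ~0.05 bp sizing noise.  Everything is a
pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import (
    GenotypeDataset,
    Individual,
    Marker,
    Panel,
    load_panel,
    parse_allele_name,
)

__all__ = [
    "MicrovariantSpec",
    "PeakSpec",
    "PedigreeSpec",
    "SimulationConfig",
    "gen_allele_frequencies",
    "gen_breeds",
    "gen_genotypes",
    "gen_trios",
    "gen_peak_table",
    "gen_amel_peaks",
    "simulate_study",
]

NULL = "NULL"  # hidden non-amplifying allele


@dataclass(frozen=True)
class MicrovariantSpec:
    marker: str = "ECA12.004.8"
    allele: str = "17.3"
    frequency: float = 0.38


@dataclass(frozen=True)
class PeakSpec:
    mean_height_rfu: float = 1000.0
    height_cv: float = 0.25
    size_jitter_sd_bp: float = 0.05
    stutter_sd_pp: float = 0.5
    pull_up_rate: float = 0.0


@dataclass(frozen=True)
class PedigreeSpec:
    n_trios: int = 100
    single_step_prob: float = 0.9
    rate_scale: float = 1.0  # multiplies the per-marker rates (per 100 meioses)


@dataclass
class SimulationConfig:
    """Study-scale defaults: 128 horses, 16 breeds, the builtin 17-plex."""

    seed: int = 0
    n_individuals: int = 128
    n_breeds: int = 16
    divergence_f: float = 0.05
    alleles_per_marker_mean: float = 8.3
    alleles_min: int = 4
    alleles_max: int = 17
    he_band: tuple[float, float] = (0.62, 0.82)
    null_allele_rate: float = 0.0
    microvariant: Optional[MicrovariantSpec] = MicrovariantSpec()
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)

    def __post_init__(self) -> None:
        for r in (self.divergence_f, self.null_allele_rate,
                  self.pedigree.single_step_prob, self.peaks.pull_up_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


def _allele_grid(marker: Marker) -> list[int]:
    """Whole-repeat allele names representable inside the marker's size range."""
    lo, hi = marker.size_range_bp
    u, ref_n, ref_s = marker.unit_length, marker.ref_repeats, marker.ref_size_bp
    lo_n = ref_n + math.ceil((lo - ref_s) / u)
    hi_n = ref_n + math.floor((hi - ref_s) / u)
    return [n for n in range(max(lo_n, 2), hi_n + 1)]


def _he(p: np.ndarray) -> float:
    return float(1.0 - np.sum(p ** 2))


def gen_allele_frequencies(
    config: SimulationConfig, panel: Optional[Panel] = None
) -> dict[str, dict[str, float]]:
    """Base (species-wide) allele frequencies per marker.

    Allele counts are Poisson-like around the configured mean (clipped to
    [min, max] and to what the marker's size range can hold); frequencies are
    symmetric-Dirichlet draws on the whole-repeat grid, rejection-resampled
    until He lands in the configured band; the configured micro-variant
    allele is then inserted at its fixed frequency.
    """
    panel = panel or load_panel()
    rng = np.random.default_rng(config.seed)
    out: dict[str, dict[str, float]] = {}
    for marker in panel.markers:
        grid = _allele_grid(marker)
        k = int(np.clip(rng.poisson(config.alleles_per_marker_mean),
                        config.alleles_min, config.alleles_max))
        k = min(k, len(grid))
        start = rng.integers(0, len(grid) - k + 1)
        names = [str(n) for n in grid[start:start + k]]
        lo_he, hi_he = config.he_band
        hi_he = min(hi_he, 1.0 - 1.0 / k - 1e-9) if k > 1 else hi_he
        best_p, best_d = None, float("inf")
        for _ in range(200):
            p = rng.dirichlet(np.ones(k))
            he = _he(p)
            if lo_he <= he <= hi_he:
                best_p = p
                break
            d = max(lo_he - he, he - hi_he)
            if d < best_d:
                best_p, best_d = p, d
        else:
            # extreme band: mix the closest draw toward the band edge —
            # toward a point mass (He -> 0) or the uniform vector (He -> max)
            he = _he(best_p)
            target = np.zeros(k)
            if he > hi_he:
                target[np.argmax(best_p)] = 1.0
                goal = hi_he
            else:
                target[:] = 1.0 / k
                goal = lo_he
            lam_lo, lam_hi = 0.0, 1.0
            for _ in range(60):  # He is continuous in the mixing weight
                lam = (lam_lo + lam_hi) / 2
                he_mid = _he((1 - lam) * best_p + lam * target)
                if (he_mid > goal) == (he > goal):
                    lam_lo = lam
                else:
                    lam_hi = lam
            best_p = (1 - lam_hi) * best_p + lam_hi * target
        freqs = {nm: float(pi) for nm, pi in zip(names, best_p)}
        mv = config.microvariant
        if mv is not None and marker.name == mv.marker:
            parse_allele_name(mv.allele, marker.unit_length)
            scale = 1.0 - mv.frequency
            freqs = {nm: f * scale for nm, f in freqs.items()}
            freqs[mv.allele] = mv.frequency
        out[marker.name] = dict(sorted(freqs.items(),
                                       key=lambda kv: parse_allele_name(kv[0])))
    return out


def gen_breeds(
    base_freqs: Mapping[str, Mapping[str, float]],
    f: float,
    n_breeds: int,
    seed: int,
) -> dict[str, dict[str, dict[str, float]]]:
    """Breed-structured frequencies via the Balding–Nichols construction.

    Each breed's frequency vector is Dirichlet with mean equal to the base
    vector and concentration (1−F)/F, so E[breed freq] = base freq and F
    controls the divergence.  Breeds are named breed01..breedNN.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("F must be in (0, 1)")
    rng = np.random.default_rng(seed)
    conc = (1.0 - f) / f
    out: dict[str, dict[str, dict[str, float]]] = {}
    for b in range(n_breeds):
        breed = f"breed{b + 1:02d}"
        out[breed] = {}
        for marker, freqs in base_freqs.items():
            names = list(freqs)
            alpha = np.array([freqs[a] for a in names]) * conc
            p = rng.dirichlet(np.maximum(alpha, 1e-9))
            out[breed][marker] = {a: float(x) for a, x in zip(names, p)}
    return out


def _with_null(freqs: Mapping[str, float], null_rate: float) -> dict[str, float]:
    if null_rate <= 0:
        return dict(freqs)
    scale = 1.0 - null_rate
    out = {a: f * scale for a, f in freqs.items()}
    out[NULL] = null_rate
    return out


def _draw_genotype(freqs: Mapping[str, float], rng) -> Optional[tuple[str, str]]:
    names = list(freqs)
    p = np.array([freqs[a] for a in names], float)
    p = p / p.sum()
    a, b = rng.choice(len(names), size=2, p=p)
    ga, gb = names[a], names[b]
    if ga == NULL and gb == NULL:
        return None  # total amplification failure: missing genotype
    if ga == NULL:
        return (gb, gb)  # null carrier looks homozygous
    if gb == NULL:
        return (ga, ga)
    return tuple(sorted((ga, gb), key=lambda s: parse_allele_name(s)))


def gen_genotypes(
    freqs: "Mapping[str, Mapping[str, float]] | Mapping[str, Mapping[str, Mapping[str, float]]]",
    n: int,
    null_rate: float,
    seed: int,
    population: str = "ALL",
) -> GenotypeDataset:
    """HWE genotypes from frequencies (one population, or per-breed nested).

    Null alleles segregate as a hidden allele at ``null_rate``: carriers
    appear homozygous for their visible allele and null/null genotypes come
    out missing — a population property, as a primer-site variant would be.

    ``freqs`` is either marker→allele→freq (single stratum labelled
    ``population``) or breed→marker→allele→freq (individuals split evenly
    across breeds, remainder to the earlier breeds).
    """
    rng = np.random.default_rng(seed)
    nested = any(isinstance(v, Mapping) and v and
                 isinstance(next(iter(v.values())), Mapping)
                 for v in freqs.values())
    strata: list[tuple[str, Mapping[str, Mapping[str, float]]]]
    if nested:
        breeds = list(freqs)
        counts = [n // len(breeds) + (1 if i < n % len(breeds) else 0)
                  for i in range(len(breeds))]
        strata = [(b, freqs[b]) for b in breeds]
    else:
        strata = [(population, freqs)]
        counts = [n]
    markers = list(strata[0][1])
    individuals = []
    idx = 0
    for (pop, mf), cnt in zip(strata, counts):
        for _ in range(cnt):
            idx += 1
            genos = {
                m: _draw_genotype(_with_null(mf[m], null_rate), rng)
                for m in markers
            }
            individuals.append(Individual(f"ind{idx:04d}", pop, genos))
    return GenotypeDataset(individuals, markers)


def _mutate(allele: str, rng, single_step_prob: float) -> tuple[str, int]:
    n, p = parse_allele_name(allele)
    step = 1 if rng.random() < single_step_prob else 2
    step *= 1 if rng.random() < 0.5 else -1
    n2 = max(n + step, 2)
    return (f"{n2}.{p}" if p else str(n2)), step


def gen_trios(
    freqs: Mapping[str, Mapping[str, float]],
    n_trios: int,
    panel: Panel,
    spec: PedigreeSpec,
    seed: int,
) -> tuple[GenotypeDataset, list[dict]]:
    """Mendelian trios with per-locus stepwise mutation.

    Parents are HWE draws; each transmitted allele mutates with probability
    ``rate/100`` per meiosis (rate = the marker's predicted rate per 100
    meioses, scaled by ``rate_scale``), stepping ±1 repeat unit with
    probability ``single_step_prob`` and ±2 otherwise.  Returns a dataset
    holding dam/sire/offspring for each trio (populations ``trioNNNN``) and a
    truth log with one record per mutation event.
    """
    rng = np.random.default_rng(seed)
    markers = [m for m in panel.markers if m.name in freqs]
    individuals: list[Individual] = []
    truth: list[dict] = []
    for t in range(1, n_trios + 1):
        dam = {m.name: _draw_genotype(freqs[m.name], rng) for m in markers}
        sire = {m.name: _draw_genotype(freqs[m.name], rng) for m in markers}
        child: dict[str, Optional[tuple[str, str]]] = {}
        for m in markers:
            rate = (m.predicted_mut_rate or 0.0) * spec.rate_scale / 100.0
            inherited = []
            for role, parent in (("dam", dam[m.name]), ("sire", sire[m.name])):
                allele = parent[int(rng.integers(0, 2))]
                if rng.random() < rate:
                    allele, step = _mutate(allele, rng, spec.single_step_prob)
                    truth.append({"trio": t, "marker": m.name, "parent": role,
                                  "to": allele, "step": step})
                inherited.append(allele)
            child[m.name] = tuple(sorted(inherited, key=lambda s: parse_allele_name(s)))
        pop = f"trio{t:04d}"
        individuals += [
            Individual(f"{pop}.dam", pop, dam),
            Individual(f"{pop}.sire", pop, sire),
            Individual(f"{pop}.child", pop, child),
        ]
    return GenotypeDataset(individuals, [m.name for m in markers]), truth


def gen_peak_table(
    dataset: GenotypeDataset,
    panel: Panel,
    spec: PeakSpec,
    seed: int,
) -> pd.DataFrame:
    """Electropherogram-style peak table for a genotype dataset.

    One peak per allele copy class (homozygotes get the summed height of two
    copies), a −1-repeat stutter peak at the marker's tabulated ratio with
    additive noise of ``stutter_sd_pp`` percentage points, Gaussian size
    jitter, lognormal peak heights, and optional random pull-up flags.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + spec.height_cv ** 2))
    mu = math.log(spec.mean_height_rfu) - sigma ** 2 / 2
    rows = []
    for ind in dataset.individuals:
        for marker in panel.markers:
            g = ind.genotypes.get(marker.name)
            if g is None:
                continue
            copies: dict[str, int] = {}
            for a in g:
                copies[a] = copies.get(a, 0) + 1
            for allele, cnt in copies.items():
                size = marker.allele_size(allele) + rng.normal(0.0, spec.size_jitter_sd_bp)
                height = float(sum(rng.lognormal(mu, sigma) for _ in range(cnt)))
                flags = "PULL_UP" if rng.random() < spec.pull_up_rate else ""
                rows.append((ind.id, marker.dye, round(size, 2),
                             round(height, 1), flags))
                if marker.stutter_pct:
                    ratio = max(rng.normal(marker.stutter_pct, spec.stutter_sd_pp),
                                0.05) / 100.0
                    s_size = (marker.allele_size(allele) - marker.unit_length
                              + rng.normal(0.0, spec.size_jitter_sd_bp))
                    rows.append((ind.id, marker.dye, round(s_size, 2),
                                 round(height * ratio, 1), ""))
    return pd.DataFrame(rows, columns=["sample_id", "dye", "size_bp",
                                       "height_rfu", "flags"])


def gen_amel_peaks(
    sexes: Mapping[str, str],
    panel: Panel,
    spec: PeakSpec,
    seed: int,
) -> pd.DataFrame:
    """Amelogenin-channel peaks for individuals of known sex.

    Males get the invariant Y product plus one X product; females one or two
    X products (the X product carries a variable di-STR, sizes 134–150 on the
    2-bp grid).
    """
    amel = panel.sex_marker
    if amel is None:
        raise ValueError("panel has no sex marker")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + spec.height_cv ** 2))
    mu = math.log(spec.mean_height_rfu) - sigma ** 2 / 2
    x_grid = np.arange(amel.x_size_bp, amel.size_range_bp[1] + 1e-9, 2.0)
    rows = []
    for sid, sex in sexes.items():
        if sex not in ("MALE", "FEMALE"):
            raise ValueError(f"{sid}: sex must be MALE or FEMALE")
        x_alleles = list(rng.choice(x_grid, size=1 if sex == "MALE" else 2))
        sizes = ([amel.y_size_bp] if sex == "MALE" else []) + sorted(set(x_alleles))
        for s in sizes:
            rows.append((sid, amel.dye,
                         round(s + rng.normal(0.0, spec.size_jitter_sd_bp), 2),
                         round(rng.lognormal(mu, sigma), 1), ""))
    return pd.DataFrame(rows, columns=["sample_id", "dye", "size_bp",
                                       "height_rfu", "flags"])


def simulate_study(
    config: SimulationConfig, panel: Optional[Panel] = None
) -> dict:
    """One full synthetic study: frequencies, breeds, genotypes, trios, peaks.

    Sub-seeds are derived deterministically from ``config.seed`` so the whole
    bundle is reproducible from the one integer.
    """
    panel = panel or load_panel()
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_breed, s_geno, s_trio, s_peak = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)
    ]
    import dataclasses

    base = gen_allele_frequencies(dataclasses.replace(config, seed=s_freq), panel)
    breeds = gen_breeds(base, config.divergence_f, config.n_breeds, s_breed)
    genotypes = gen_genotypes(breeds, config.n_individuals,
                              config.null_allele_rate, s_geno)
    trios, truth = gen_trios(base, config.pedigree.n_trios, panel,
                             config.pedigree, s_trio)
    peaks = gen_peak_table(genotypes, panel, config.peaks, s_peak)
    return {
        "panel": panel,
        "base_freqs": base,
        "breed_freqs": breeds,
        "genotypes": genotypes,
        "trios": trios,
        "mutation_truth": truth,
        "peaks": peaks,
    }
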