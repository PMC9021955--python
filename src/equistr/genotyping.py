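"""Electropherogram genotyping: peak tables → named allele calls.

Peaks arrive pre-sized (as from a fragment-analysis export): sample, dye,
size in bases, height in RFU.  This module clusters sizes into allele bins,
names alleles by repeat count relative to the sequenced reference allele
(micro-variants as ``n.p``), removes stutter peaks, measures stutter ratios
under the homozygote / well-separated-heterozygote eligibility protocol, and
calls sex from the amelogenin channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import GenotypeDataset, Individual, Marker, Panel, parse_allele_name

__all__ = [
    "Peak",
    "AlleleCall",
    "StutterRecord",
    "read_peaks",
    "write_peaks",
    "bin_sizes",
    "call_allele",
    "bin_microvariant",
    "call_genotypes",
    "measure_stutter",
    "call_sex",
]

PEAK_COLUMNS = ["sample_id", "dye", "size_bp", "height_rfu", "flags"]


@dataclass(frozen=True)
class Peak:
    sample_id: str
    dye: str
    size_bp: float
    height_rfu: float
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.size_bp <= 0 or self.height_rfu <= 0:
            raise ValueError("peak size and height must be positive")


@dataclass(frozen=True)
class AlleleCall:
    sample_id: str
    marker: str
    allele_name: str
    size_bp: float
    height_rfu: float
    is_microvariant: bool = False
    off_ladder: bool = False


@dataclass(frozen=True)
class StutterRecord:
    marker: str
    sample_id: str
    parent_allele: str
    parent_height: float
    stutter_height: float

    @property
    def ratio_pct(self) -> float:
        return 100.0 * self.stutter_height / self.parent_height


def read_peaks(path) -> pd.DataFrame:
    """Read a peak-table CSV (columns sample_id, dye, size_bp, height_rfu, flags)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "dye": str, "flags": str})
    missing = [c for c in PEAK_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing column(s): {missing}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return df


def write_peaks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.2f")


def bin_sizes(
    sizes: Sequence[float],
    max_gap_bp: float = 0.7,
) -> list[tuple[float, list[float]]]:
    """Single-linkage clustering of fragment sizes along the bp axis.

    Two sizes join the same bin iff the gap to the nearest member is at most
    ``max_gap_bp`` (default 0.7 bp: comfortably above sizing noise, safely
    below the 1-bp micro-variant spacing).  Returns ordered, disjoint bins as
    ``(center, members)`` with the center at the member median.  This is the
    "rounding-error" correction that makes 100.48 and 100.52 one allele.
    """
    for s in sizes:
        if not (20.0 <= s <= 600.0):
            raise ValueError(f"size {s} bp outside plausible range 20-600")
    if not len(sizes):
        return []
    order = sorted(sizes)
    bins: list[list[float]] = [[order[0]]]
    for s in order[1:]:
        if s - bins[-1][-1] <= max_gap_bp:
            bins[-1].append(s)
        else:
            bins.append([s])
    return [(float(np.median(b)), b) for b in bins]


def call_allele(
    size_bp: float,
    marker: Marker,
    whole_repeat_tolerance: float = 0.5,
    sample_id: str = "",
) -> AlleleCall:
    """Name the allele at a measured size, relative to the sequenced reference.

    The size offset from the reference allele is decomposed into whole repeat
    units plus a residual.  Within ``whole_repeat_tolerance`` of a whole unit
    the allele is the whole-repeat name; otherwise it is a micro-variant
    ``n.p`` where n counts whole units below the size and p the extra bases
    (e.g. 3 bases short of a whole repeat on a tetra → ``17.3``).  Sizes
    outside the marker's range are flagged off-ladder but still named.
    """
    if size_bp <= 0:
        raise ValueError("size must be positive")
    if marker.ref_size_bp is None or marker.ref_repeats is None:
        raise ValueError(f"{marker.name}: marker has no reference size/repeats")
    u = marker.unit_length
    delta = size_bp - marker.ref_size_bp
    n_units = round(delta / u)
    residual = delta - n_units * u
    if abs(residual) <= whole_repeat_tolerance:
        n, p, micro = marker.ref_repeats + n_units, 0, False
    else:
        n = marker.ref_repeats + math.floor(delta / u)
        p = round(delta - math.floor(delta / u) * u)
        p = min(max(p, 1), u - 1)
        micro = True
    name = f"{n}.{p}" if micro else str(n)
    lo, hi = marker.size_range_bp
    return AlleleCall(
        sample_id=sample_id,
        marker=marker.name,
        allele_name=name,
        size_bp=size_bp,
        height_rfu=float("nan"),
        is_microvariant=micro,
        off_ladder=not (lo <= size_bp <= hi),
    )


def bin_microvariant(
    call: AlleleCall,
    marker: Marker,
    deletion_derived: Optional[bool] = None,
) -> AlleleCall:
    """Optionally bin a deletion-derived micro-variant with its whole-repeat parent.

    Under the deletion-derived policy, ``n.(u-1)`` is one base short of the
    ``n+1`` whole-repeat allele (a single-base deletion outside the repeat),
    so it is renamed ``n+1``.  The policy is per-marker and defaults to ON
    only for the Eca12 marker, whose 38%-frequency micro-variant was sequenced
    and shown to be exactly that.
    """
    if not call.is_microvariant:
        return call
    if deletion_derived is None:
        deletion_derived = marker.short_name == "Eca12"
    if not deletion_derived:
        return call
    n, p = parse_allele_name(call.allele_name, marker.unit_length)
    if p != marker.unit_length - 1:
        return call
    return replace(call, allele_name=str(n + 1), is_microvariant=False)


def _marker_for(panel: Panel, dye: str, size: float,
                margin_bp: float = 0.0) -> Optional[Marker]:
    hits = [
        m for m in panel.markers
        if m.dye == dye
        and m.size_range_bp[0] - margin_bp <= size <= m.size_range_bp[1] + margin_bp
    ]
    if not hits:
        return None
    # boundary overlaps (1-2 bp) resolve to the nearer range center
    return min(hits, key=lambda m: abs(size - sum(m.size_range_bp) / 2))


def _merge_colocated(sizes: np.ndarray, heights: np.ndarray,
                     tol_bp: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Sum peak rows at the same position (e.g. an allele and a coincident
    stutter peak are one physical peak); position = height-weighted mean."""
    order = np.argsort(sizes)
    sizes, heights = sizes[order], heights[order]
    m_sizes, m_heights = [], []
    for s, h in zip(sizes, heights):
        if m_sizes and s - m_sizes[-1] <= tol_bp:
            tot = m_heights[-1] + h
            m_sizes[-1] = (m_sizes[-1] * m_heights[-1] + s * h) / tot
            m_heights[-1] = tot
        else:
            m_sizes.append(float(s))
            m_heights.append(float(h))
    return np.array(m_sizes), np.array(m_heights)


def call_genotypes(
    peaks: pd.DataFrame,
    panel: Panel,
    stutter_drop_ratio: float = 0.35,
    min_peak_fraction: float = 0.30,
    whole_repeat_tolerance: float = 0.5,
    range_margin_bp: float = 1.5,
    population: str = "unknown",
    microvariant_policy: Optional[Mapping[str, bool]] = None,
) -> tuple[GenotypeDataset, list[AlleleCall]]:
    """End-to-end genotyper: peak table → per-individual genotype dataset.

    Per sample and marker: peaks in the marker's dye and size range (padded by
    ``range_margin_bp`` so sizing noise cannot push a boundary allele off the
    ladder) are taken; co-located rows are summed into one physical peak; a
    peak one repeat unit below a peak at least ``1/stutter_drop_ratio`` times
    taller is removed as stutter; of the remainder, peaks below
    ``min_peak_fraction`` of the tallest are ignored; the top two surviving
    peaks (one → homozygote) are named via :func:`call_allele` and the
    deletion-derived micro-variant policy.
    """
    calls: list[AlleleCall] = []
    genos: dict[str, dict[str, Optional[tuple[str, str]]]] = {}
    sample_ids = list(dict.fromkeys(peaks["sample_id"].astype(str)))
    for sid, sdf in peaks.groupby("sample_id", sort=False):
        sid = str(sid)
        genos.setdefault(sid, {})
        for marker in panel.markers:
            lo, hi = marker.size_range_bp
            sub = sdf[(sdf["dye"] == marker.dye)
                      & (sdf["size_bp"] >= lo - range_margin_bp)
                      & (sdf["size_bp"] <= hi + range_margin_bp)]
            sub = sub[[
                _marker_for(panel, marker.dye, s, range_margin_bp) is marker
                for s in sub["size_bp"]
            ]] if len(sub) else sub
            if not len(sub):
                genos[sid][marker.name] = None
                continue
            sizes, heights = _merge_colocated(
                sub["size_bp"].to_numpy(float), sub["height_rfu"].to_numpy(float))
            u = marker.unit_length
            keep = np.ones(len(sizes), bool)
            for i in range(len(sizes)):
                parent = np.abs(sizes - (sizes[i] + u)) <= 0.5
                if np.any(heights[parent] * stutter_drop_ratio >= heights[i]):
                    keep[i] = False
            sizes, heights = sizes[keep], heights[keep]
            if not len(sizes):
                genos[sid][marker.name] = None
                continue
            strong = heights >= min_peak_fraction * heights.max()
            sizes, heights = sizes[strong], heights[strong]
            top = np.argsort(heights)[::-1][:2]
            pair = []
            for idx in sorted(top, key=lambda k: sizes[k]):
                c = call_allele(sizes[idx], marker, whole_repeat_tolerance, sid)
                c = replace(c, height_rfu=float(heights[idx]))
                policy = (microvariant_policy or {}).get(marker.name)
                c = bin_microvariant(c, marker, deletion_derived=policy)
                pair.append(c)
            if len(pair) == 1:
                pair = [pair[0], pair[0]]
            calls.extend(dict.fromkeys(pair))  # unique calls, order kept
            genos[sid][marker.name] = (pair[0].allele_name, pair[1].allele_name)
    dataset = GenotypeDataset(
        [Individual(sid, population, genos.get(sid, {})) for sid in sample_ids],
        [m.name for m in panel.markers],
    )
    return dataset, calls


def apply_microvariant_policy(
    dataset: GenotypeDataset,
    panel: Panel,
    policy: Optional[Mapping[str, bool]] = None,
) -> GenotypeDataset:
    """Rename dataset alleles under the deletion-derived binning policy.

    Brings an externally produced genotype table (e.g. simulation truth, which
    records the physical micro-variant) into the same ladder nomenclature the
    genotyper reports, so round trips compare like with like.
    """
    out = []
    for ind in dataset.individuals:
        genos: dict[str, Optional[tuple[str, str]]] = {}
        for m, g in ind.genotypes.items():
            try:
                marker = panel.get(m)
            except KeyError:
                genos[m] = g
                continue
            if g is None:
                genos[m] = None
                continue
            renamed = []
            for a in g:
                n, p = parse_allele_name(a, marker.unit_length)
                call = AlleleCall(ind.id, m, a, marker.allele_size(a), 1.0,
                                  is_microvariant=p > 0)
                call = bin_microvariant(call, marker,
                                        (policy or {}).get(m))
                renamed.append(call.allele_name)
            genos[m] = tuple(sorted(renamed, key=parse_allele_name))
        out.append(Individual(ind.id, ind.population, genos))
    return GenotypeDataset(out, list(dataset.markers))


def measure_stutter(
    peaks: pd.DataFrame,
    calls: Sequence[AlleleCall],
    marker: Marker,
    max_peaks: int = 10,
    position_tol_bp: float = 0.5,
) -> tuple[list[StutterRecord], Optional[float]]:
    """Measure −1-repeat stutter ratios under the eligibility protocol.

    A parent allele peak is eligible iff its sample is homozygous at the
    marker, or heterozygous with the two alleles more than one repeat apart;
    it is skipped when the stutter position (parent − one unit) coincides
    with another called allele or with a pull-up-flagged peak.  The first
    ``max_peaks`` eligible parents in sample order are used.  Returns the
    records and their mean ratio in percent (None when nothing is eligible —
    an undefined mean is reported as missing, never as 0).
    """
    mcalls = [c for c in calls if c.marker == marker.name]
    by_sample: dict[str, list[AlleleCall]] = {}
    for c in mcalls:
        by_sample.setdefault(c.sample_id, []).append(c)
    u = marker.unit_length
    records: list[StutterRecord] = []
    for sid, scalls in by_sample.items():
        if len(records) >= max_peaks:
            break
        names = {c.allele_name for c in scalls}
        if len(names) == 1:
            parents = scalls[:1]
        elif len(names) == 2:
            vals = sorted(c.size_bp for c in scalls)
            if vals[-1] - vals[0] <= u + position_tol_bp:  # <= one repeat apart
                continue
            parents = scalls
        else:
            continue
        sdf = peaks[(peaks["sample_id"].astype(str) == sid)
                    & (peaks["dye"] == marker.dye)]
        sizes = sdf["size_bp"].to_numpy(float)
        heights = sdf["height_rfu"].to_numpy(float)
        flags = sdf["flags"].fillna("").astype(str).to_numpy() if "flags" in sdf else \
            np.array([""] * len(sdf))
        for parent in parents:
            if len(records) >= max_peaks:
                break
            spos = parent.size_bp - u
            near = np.abs(sizes - spos) <= position_tol_bp
            # contaminated stutter position: another called allele or pull-up
            if any(abs(c.size_bp - spos) <= position_tol_bp for c in scalls):
                continue
            if any("PULL_UP" in f for f in flags[near]):
                continue
            stutter_h = float(heights[near].max()) if near.any() else 0.0
            records.append(StutterRecord(
                marker.name, sid, parent.allele_name,
                float(parent.height_rfu), stutter_h,
            ))
    mean = float(np.mean([r.ratio_pct for r in records])) if records else None
    return records, mean


def call_sex(
    peaks: pd.DataFrame,
    marker: Marker,
    y_bin_bp: tuple[float, float] = (113.0, 1.0),
    x_min_bp: float = 130.0,
    min_height_rfu: float = 0.0,
    range_margin_bp: float = 1.5,
) -> str:
    """Sex call from the amelogenin channel.

    The Y-chromosome product is the short invariant class (a deletion on Y
    shortens it); the X product carries a variable di-STR and sizes upward
    from ~134 bp, so females show one or two X-size peaks and males show a
    Y-bin peak plus an X-size peak.  Returns MALE / FEMALE / INCONCLUSIVE.
    """
    lo, hi = marker.size_range_bp
    sub = peaks[(peaks["dye"] == marker.dye)
                & (peaks["size_bp"] >= lo - range_margin_bp)
                & (peaks["size_bp"] <= hi + range_margin_bp)
                & (peaks["height_rfu"] > min_height_rfu)]
    sizes = sub["size_bp"].to_numpy(float)
    if not len(sizes):
        return "INCONCLUSIVE"
    y_center, y_tol = y_bin_bp
    has_y = bool(np.any(np.abs(sizes - y_center) <= y_tol))
    has_x = bool(np.any(sizes >= x_min_bp))
    if has_y and has_x:
        return "MALE"
    if has_x:
        return "FEMALE"
    return "INCONCLUSIVE"
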