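"""Domain types and tabular I/O for the horse tetra/penta-STR multiplex panel.

The package ships a transcription of the published 17-plex marker table
(primers, motifs, repeat-alignment scores, dyes, size ranges, stutter and
predicted mutation rates) plus the companion per-locus genetic summary table
(Ho, He, parentage statistics, probability of identity).  Everything else in
the package — discovery, primer QC, genotyping, statistics, simulation —
speaks in terms of the :class:`Marker`, :class:`Panel` and
:class:`GenotypeDataset` containers defined here.

Conventions
-----------
* Allele names are CODIS-style repeat counts: ``"17"`` for a whole-repeat
  allele, ``"17.3"`` for a micro-variant 3 bases above 17 whole repeats.
* Motifs are stored exactly as the upper-strand unit; no rotation or
  reverse-complement canonicalization is applied for naming.
* All locus coordinates elsewhere in the package are 0-based half-open.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "DYES",
    "Motif",
    "Primer",
    "Marker",
    "Panel",
    "Finding",
    "Individual",
    "GenotypeDataset",
    "parse_allele_name",
    "allele_repeat_value",
    "parse_structure",
    "build_sequence",
    "count_structure_repeats",
    "load_panel",
    "validate_panel",
    "load_locus_stats",
    "combined_from_locus_table",
    "read_genotypes",
    "write_genotypes",
]

DYES = frozenset({"FAM", "HEX", "NED"})

_DNA_RE = re.compile(r"^[ACGT]+$")
_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")
_STRUCT_RE = re.compile(r"\[([ACGT]+)\](\d*)|([ACGT]+)")


class PanelError(ValueError):
    """Raised for malformed panel/genotype inputs (names the offending row/cell)."""


@dataclass(frozen=True)
class Motif:
    """A repeat unit, stored as the upper-strand motif."""

    unit: str

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.unit):
            raise PanelError(f"motif unit {self.unit!r} is not an A/C/G/T string")

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.unit


@dataclass(frozen=True)
class Primer:
    """PCR primer, 5'→3'.

    A lowercase prefix is a non-templated pigtail (e.g. ``gtttctt``) added to
    drive complete adenylation; the uppercase remainder is the templated
    portion.  Pigtails add to product length but are not part of the
    target-annealing sequence.
    """

    sequence_5to3: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.sequence_5to3
        m = re.match(r"^([acgt]*)([ACGT]+)$", seq)
        if m is None:
            raise PanelError(
                f"primer {seq!r}: lowercase pigtail must be a prefix and the "
                "templated (uppercase) portion must be non-empty"
            )

    @property
    def pigtail(self) -> str:
        m = re.match(r"^[acgt]*", self.sequence_5to3)
        return m.group(0)

    @property
    def templated(self) -> str:
        return self.sequence_5to3[len(self.pigtail):]

    @property
    def full_upper(self) -> str:
        """Full physical sequence, uppercased (pigtail included)."""
        return self.sequence_5to3.upper()

    def __len__(self) -> int:
        return len(self.sequence_5to3)


@dataclass(frozen=True)
class Marker:
    """One multiplex marker: primers, motif, per-locus constants.

    ``ref_size_bp`` is the product size of the sequenced reference allele and
    ``ref_repeats`` its repeat count (all unit-length blocks of the printed
    repeat structure, interrupting units included).  The amelogenin sex marker
    stores its two products in ``y_size_bp``/``x_size_bp`` instead.
    """

    name: str
    chromosome: str
    motif: Motif
    dye: str
    primer_f: Primer
    primer_r: Primer
    conc_uM: float
    size_range_bp: tuple[float, float]
    sw_score: Optional[int] = None
    ref_size_bp: Optional[float] = None
    x_size_bp: Optional[float] = None
    y_size_bp: Optional[float] = None
    ref_repeats: Optional[int] = None
    observed_alleles: Optional[int] = None
    stutter_pct: Optional[float] = None
    predicted_mut_rate: Optional[float] = None
    structure_string: Optional[str] = None
    position_mb: Optional[float] = None
    short_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise PanelError(f"{self.name}: dye {self.dye!r} not in {sorted(DYES)}")
        if self.conc_uM <= 0:
            raise PanelError(f"{self.name}: concentration must be positive")
        lo, hi = self.size_range_bp
        if not lo < hi:
            raise PanelError(f"{self.name}: empty size range {self.size_range_bp}")
        for sz in (self.ref_size_bp, self.x_size_bp, self.y_size_bp):
            if sz is not None and not (lo <= sz <= hi):
                raise PanelError(
                    f"{self.name}: reference size {sz} outside range [{lo}, {hi}]"
                )
        if self.stutter_pct is not None and not (0 <= self.stutter_pct <= 100):
            raise PanelError(f"{self.name}: stutter {self.stutter_pct} not a percentage")

    @property
    def unit_length(self) -> int:
        return self.motif.unit_length

    @property
    def is_sex_marker(self) -> bool:
        return self.x_size_bp is not None or self.y_size_bp is not None

    def allele_size(self, allele_name: str) -> float:
        """Expected product size (bp) of a named allele."""
        if self.ref_size_bp is None or self.ref_repeats is None:
            raise PanelError(f"{self.name}: no reference size/repeat count")
        n, p = parse_allele_name(allele_name, unit_length=self.unit_length)
        return self.ref_size_bp + (n - self.ref_repeats) * self.unit_length + p


@dataclass(frozen=True)
class Finding:
    """One panel-validation finding."""

    severity: str  # "WARN" | "FAIL"
    rule: str
    message: str


@dataclass
class Panel:
    """An ordered multiplex of STR markers plus the amelogenin sex marker."""

    markers: list[Marker]
    sex_marker: Optional[Marker] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if self.sex_marker is not None:
            names.append(self.sex_marker.name)
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker name(s): {sorted(dupes)}")

    def __iter__(self):
        return iter(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def all_markers(self) -> list[Marker]:
        out = list(self.markers)
        if self.sex_marker is not None:
            out.append(self.sex_marker)
        return out

    def get(self, name: str) -> Marker:
        for m in self.all_markers:
            if name in (m.name, m.short_name):
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# allele-name and structure-string helpers


def parse_allele_name(name: str, unit_length: Optional[int] = None) -> tuple[int, int]:
    """Parse ``"n"`` / ``"n.p"`` into ``(repeats, partial_bases)``.

    The partial suffix must be a single digit in ``1..unit_length-1`` when the
    unit length is known (e.g. ``"17.9"`` is invalid for a tetranucleotide).
    """
    m = _ALLELE_RE.match(str(name).strip())
    if m is None:
        raise PanelError(f"unparsable allele name {name!r}")
    n = int(m.group(1))
    p = int(m.group(2)) if m.group(2) else 0
    if n < 1:
        raise PanelError(f"allele name {name!r}: repeat count must be >= 1")
    if p and unit_length is not None and not (1 <= p <= unit_length - 1):
        raise PanelError(
            f"allele name {name!r}: partial {p} not in 1..{unit_length - 1}"
        )
    return n, p


def allele_repeat_value(name: str, unit_length: int) -> float:
    """Numeric repeat value of an allele name (``"17.3"`` → 17.75 for tetra)."""
    n, p = parse_allele_name(name, unit_length)
    return n + p / unit_length


def parse_structure(structure: str) -> list[tuple[str, int, bool]]:
    """Parse a bracketed repeat decomposition into ``(block, count, bracketed)``.

    ``"[TCTA]4[TCTG][TCTA]11"`` → ``[("TCTA", 4, True), ("TCTG", 1, True),
    ("TCTA", 11, True)]``; bare literals such as interruption ``"ATC"`` come
    back with ``bracketed=False``.
    """
    out: list[tuple[str, int, bool]] = []
    pos = 0
    s = structure.replace(" ", "")
    while pos < len(s):
        m = _STRUCT_RE.match(s, pos)
        if m is None:
            raise PanelError(f"unparsable structure {structure!r} at offset {pos}")
        if m.group(1) is not None:
            out.append((m.group(1), int(m.group(2) or 1), True))
        else:
            out.append((m.group(3), 1, False))
        pos = m.end()
    return out


def build_sequence(structure: str) -> str:
    """Concatenate a structure string back into the DNA sequence it encodes."""
    return "".join(block * count for block, count, _ in parse_structure(structure))


def count_structure_repeats(structure: str, unit_length: int) -> int:
    """Repeat count of a structure: all bracketed blocks of the unit length.

    This is the convention behind the reference repeat counts: interrupting
    whole units (e.g. ``[TCTG]`` inside a TCTA array) count, sub-unit literals
    (``ATC``) do not.
    """
    return sum(
        count
        for block, count, bracketed in parse_structure(structure)
        if bracketed and len(block) == unit_length
    )


# ---------------------------------------------------------------------------
# panel loading / validation


def _builtin(name: str):
    return resources.files("equistr.data").joinpath(name)


def _short_names(rows: list[dict]) -> list[str]:
    """Table-2-style short names: Eca28, Eca04a/Eca04b for same-chromosome pairs."""
    by_chrom: dict[str, int] = {}
    for r in rows:
        by_chrom[r["chromosome"]] = by_chrom.get(r["chromosome"], 0) + 1
    seen: dict[str, int] = {}
    out = []
    for r in rows:
        chrom = r["chromosome"]
        if r["name"] == "amel":
            out.append("amel")
            continue
        base = f"Eca{int(chrom):02d}"
        if by_chrom[chrom] > 1:
            idx = seen.get(chrom, 0)
            out.append(base + "abcdef"[idx])
            seen[chrom] = idx + 1
        else:
            out.append(base)
    return out


def _opt_float(x: str) -> Optional[float]:
    x = x.strip()
    return None if x in ("", "NA", "ND") else float(x)


def load_panel(path: Optional[str | Path] = None) -> Panel:
    """Load a panel definition TSV; with no argument, the packaged 17-plex.

    The TSV mirrors the published marker table: one row per marker with
    primers, motif unit and bracketed structure, repeat-alignment (SW) score,
    dye, concentration, reference size, size range, observed allele count,
    stutter percentage and predicted mutation rate.
    """
    if path is None:
        text = _builtin("marker_panel.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    required = {
        "name", "chromosome", "dye", "unit", "structure", "sws", "conc_uM",
        "ref_size", "range_min", "range_max", "primer_f", "primer_r",
    }
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = sorted(required - set(reader.fieldnames or []))
        raise PanelError(f"panel table missing column(s): {missing}")
    rows = list(reader)
    names = [r["name"] for r in rows]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise PanelError(f"duplicate marker name(s): {sorted(dupes)}")

    shorts = _short_names(rows)
    markers: list[Marker] = []
    sex_marker: Optional[Marker] = None
    for i, (row, short) in enumerate(zip(rows, shorts)):
        try:
            motif = Motif(row["unit"].strip().upper())
            ref_size = row["ref_size"].strip()
            x_size = y_size = ref = None
            if ";" in ref_size:  # amel stores two products, "Y;X"
                y_s, x_s = ref_size.split(";")
                y_size, x_size = float(y_s), float(x_s)
            else:
                ref = float(ref_size)
            structure = row["structure"].strip() or None
            ref_repeats = (
                count_structure_repeats(structure, motif.unit_length)
                if structure and ref is not None
                else None
            )
            marker = Marker(
                name=row["name"].strip(),
                chromosome=row["chromosome"].strip(),
                motif=motif,
                dye=row["dye"].strip().replace("6-FAM", "FAM"),
                primer_f=Primer(row["primer_f"].strip(),
                                label=row.get("primer_f_label", "").strip() or None),
                primer_r=Primer(row["primer_r"].strip()),
                conc_uM=float(row["conc_uM"]),
                size_range_bp=(float(row["range_min"]), float(row["range_max"])),
                sw_score=int(row["sws"]) if _opt_float(row["sws"]) is not None else None,
                ref_size_bp=ref,
                x_size_bp=x_size,
                y_size_bp=y_size,
                ref_repeats=ref_repeats,
                observed_alleles=int(row["n_alleles"]) if row.get("n_alleles") else None,
                stutter_pct=_opt_float(row.get("stutter_pct", "")),
                predicted_mut_rate=_opt_float(row.get("mut_rate", "")),
                structure_string=structure,
                position_mb=_opt_float(row.get("position_mb", "")),
                short_name=short,
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"panel row {i + 1} ({row.get('name', '?')}): {exc}") from exc
        if marker.is_sex_marker:
            sex_marker = marker
        else:
            markers.append(marker)
    return Panel(markers=markers, sex_marker=sex_marker,
                 metadata={"source": str(path) if path else "builtin 17-plex"})


def validate_panel(
    panel: Panel,
    linkage_threshold_mb: float = 50.0,
    overlap_fail_bp: int = 3,
) -> list[Finding]:
    """Multiplexability checks: same-dye size-range overlap, same-chromosome
    linkage, and primer-concentration sanity.

    Same-dye range overlaps of 1–2 bp are warnings (the published panel itself
    contains two such boundary overlaps); overlaps of ``overlap_fail_bp`` or
    more fail.  STR markers on one chromosome closer than
    ``linkage_threshold_mb`` (a proxy for ~50 cM) fail.
    """
    findings: list[Finding] = []
    ms = panel.all_markers
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            a, b = sorted((ms[i], ms[j]), key=lambda m: (m.size_range_bp, m.name))
            if a.dye == b.dye:
                # inclusive bp overlap between closed ranges
                ov = min(a.size_range_bp[1], b.size_range_bp[1]) - max(
                    a.size_range_bp[0], b.size_range_bp[0]
                ) + 1
                if ov >= 1:
                    sev = "FAIL" if ov >= overlap_fail_bp else "WARN"
                    findings.append(Finding(
                        sev, "range-overlap",
                        f"{a.dye}: {a.name} range "
                        f"{a.size_range_bp[0]:g}-{a.size_range_bp[1]:g} overlaps "
                        f"{b.name} range {b.size_range_bp[0]:g}-{b.size_range_bp[1]:g} "
                        f"by {ov:g} bp",
                    ))
    strs = panel.markers
    for i in range(len(strs)):
        for j in range(i + 1, len(strs)):
            a, b = strs[i], strs[j]
            if (a.chromosome == b.chromosome
                    and a.position_mb is not None and b.position_mb is not None):
                dist = abs(a.position_mb - b.position_mb)
                if dist < linkage_threshold_mb:
                    findings.append(Finding(
                        "FAIL", "linkage",
                        f"{a.name} and {b.name} are {dist:g} Mb apart on "
                        f"chromosome {a.chromosome} (< {linkage_threshold_mb:g} Mb)",
                    ))
    for m in ms:
        if not (0 < m.conc_uM <= 10):
            findings.append(Finding(
                "WARN", "concentration",
                f"{m.name}: concentration {m.conc_uM} µM outside (0, 10]",
            ))
    return findings


def load_locus_stats(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load the per-locus genetic summary table (packaged transcription by default).

    Columns: marker, ho, he, he_sw, pe1, pe2, pi, pisib, unit_len.  ND/NA cells
    become NaN.  The amel row is included; STR-only summaries should drop it.
    """
    src = _builtin("locus_stats.tsv") if path is None else Path(path)
    df = pd.read_csv(src, sep="\t", comment="#", na_values=["NA", "ND"])
    return df


def combined_from_locus_table(stats: pd.DataFrame) -> dict[str, float]:
    """Recompute the published panel-wide summary rows from per-locus columns.

    Means are over STR loci (amel excluded) where defined.  The combined
    parentage row is the product over loci of the per-locus complements
    ``(1 - pe1)`` / ``(1 - pe2)`` — the convention that reproduces the
    published combined values from the published per-locus columns (see
    docs/methods.md).  PI/PIsib combine as plain products over the loci where
    they are defined.
    """
    df = stats[stats["marker"] != "amel"]
    out = {
        "mean_ho": float(df["ho"].mean()),
        "mean_he": float(df["he"].mean()),
        "mean_pe1": float(df["pe1"].mean()),
        "mean_pe2": float(df["pe2"].mean()),
        "mean_pi": float(df["pi"].mean()),
        "mean_pisib": float(df["pisib"].mean()),
        "combined_pe1": float((1.0 - df["pe1"].dropna()).prod()),
        "combined_pe2": float((1.0 - df["pe2"].dropna()).prod()),
        "combined_pi": float(df["pi"].dropna().prod()),
        "combined_pisib": float(df["pisib"].dropna().prod()),
        "n_pi_loci": int(df["pi"].notna().sum()),
    }
    return out


# ---------------------------------------------------------------------------
# genotype dataset I/O


@dataclass
class Individual:
    id: str
    population: str
    genotypes: dict[str, Optional[tuple[str, str]]]


@dataclass
class GenotypeDataset:
    """Two-allele genotype calls for a set of individuals at panel markers.

    Genotypes are unordered pairs of allele names; ``None`` marks a missing
    (untyped or null/null) genotype.
    """

    individuals: list[Individual]
    markers: list[str]

    def __post_init__(self) -> None:
        for ind in self.individuals:
            if not ind.population:
                raise PanelError(f"individual {ind.id}: empty population label")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def subset(self, population: str) -> "GenotypeDataset":
        return GenotypeDataset(
            [ind for ind in self.individuals if ind.population == population],
            list(self.markers),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row: dict[str, object] = {"id": ind.id, "population": ind.population}
            for m in self.markers:
                g = ind.genotypes.get(m)
                row[f"{m}.1"], row[f"{m}.2"] = (g if g else (None, None))
            rows.append(row)
        return pd.DataFrame(rows)


def write_genotypes(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "native"
) -> None:
    """Write a genotype CSV.

    ``native``: ``id,population`` then two columns per marker (marker name
    repeated).  ``genalex-like``: prepends the two bookkeeping header rows the
    GenAlEx spreadsheet layout expects (counts row; title + population row).
    """
    if dialect not in ("native", "genalex-like"):
        raise PanelError(f"unknown genotype dialect {dialect!r}")
    pops = dataset.populations
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "genalex-like":
            sizes = [sum(1 for i in dataset.individuals if i.population == p)
                     for p in pops]
            w.writerow([len(dataset.markers), len(dataset.individuals), len(pops),
                        *sizes])
            w.writerow(["equistr export", "", *pops])
        header = ["id", "population"]
        for m in dataset.markers:
            header += [m, m]
        w.writerow(header)
        for ind in dataset.individuals:
            row = [ind.id, ind.population]
            for m in dataset.markers:
                g = ind.genotypes.get(m)
                row += list(g) if g else ["", ""]
            w.writerow(row)


def read_genotypes(
    path: str | Path, dialect: str = "native", panel: Optional[Panel] = None
) -> GenotypeDataset:
    """Read a genotype CSV written by :func:`write_genotypes`.

    When a panel is supplied, allele names are validated against each marker's
    unit length (partial-repeat suffixes must be shorter than the unit).
    """
    if dialect not in ("native", "genalex-like"):
        raise PanelError(f"unknown genotype dialect {dialect!r}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if dialect == "genalex-like":
        rows = rows[2:]
    if not rows:
        raise PanelError(f"{path}: empty genotype file")
    header, body = rows[0], rows[1:]
    if len(header) < 4 or header[0] != "id":
        raise PanelError(f"{path}: expected header starting 'id,population,...'")
    marker_cols = header[2:]
    if len(marker_cols) % 2 != 0:
        raise PanelError(f"{path}: odd number of allele columns")
    markers: list[str] = []
    for k in range(0, len(marker_cols), 2):
        a, b = marker_cols[k], marker_cols[k + 1]
        if a != b:
            raise PanelError(
                f"{path}: allele-column pair {k // 2 + 1} names differ ({a!r} vs {b!r})"
            )
        markers.append(a)
    individuals = []
    for r, row in enumerate(body, start=2):
        gid, pop, cells = row[0], row[1], row[2:]
        genos: dict[str, Optional[tuple[str, str]]] = {}
        for k, m in enumerate(markers):
            a, b = cells[2 * k].strip(), cells[2 * k + 1].strip()
            if not a and not b:
                genos[m] = None
                continue
            if not a or not b:
                raise PanelError(f"{path}: row {r}, marker {m}: half-missing genotype")
            unit = None
            if panel is not None:
                try:
                    unit = panel.get(m).unit_length
                except KeyError:
                    unit = None
            for cell in (a, b):
                try:
                    parse_allele_name(cell, unit_length=unit)
                except PanelError as exc:
                    raise PanelError(f"{path}: row {r}, marker {m}: {exc}") from exc
            genos[m] = (a, b)
        individuals.append(Individual(gid, pop, genos))
    return GenotypeDataset(individuals, markers)
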