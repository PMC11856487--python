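"""Marker-panel definitions, genotype tables, and peak tables.

The panel describes eight grape phylloxera SSR loci (Dvit1-Dvit6, DVSSR3,
DVSSR4) amplified with universal-tailed forward primers and scored on three
platforms: the original polyacrylamide gels, fluorescent capillary
electrophoresis, and whole-genome short-read sequencing.  This module holds
the data model (loci, peaks, per-sample allele profiles, the reference
clonal-genotype panel), the readers/writers for the plain-text exchange
formats, and the packaged reference-genotype fixture transcribing the
published seven-genotype, three-platform allele-size table.
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import json
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DYES = ("FAM", "VIC", "NED", "PET")
PLATFORMS = ("polyacrylamide", "capillary", "hts")

LOCUS_ORDER = ("Dvit1", "Dvit2", "Dvit3", "Dvit4", "Dvit5", "Dvit6", "DVSSR3", "DVSSR4")
GENOTYPES = ("G1", "G4", "G7", "G19", "G20", "G30", "G38")

_BASES = set("ACGT")


class PanelError(ValueError):
    """Invalid panel or genotype-table input."""


@dataclass(frozen=True)
class LocusSpec:
    """One SSR marker: primers, universal tail, repeat motif, dye, size range.

    ``size_range`` spans the historic allele names expected at the locus (bp,
    tail excluded).  ``tail_length`` is the constant universal-tail length
    prepended to the forward primer (15-18 bp), which inflates every raw
    capillary fragment size.  ``historic_platform1`` is False for loci whose
    platform-1 entries are published expected sizes rather than measured
    polyacrylamide data.
    """

    name: str
    forward_primer: str
    reverse_primer: str
    tail_length: int
    motif: str
    dye: str
    size_range: tuple[int, int]
    mix_group: str
    historic_platform1: bool = True

    def __post_init__(self) -> None:
        for attr in ("forward_primer", "reverse_primer"):
            seq = getattr(self, attr)
            if not seq or set(seq) - _BASES:
                raise PanelError(f"{self.name}: {attr} must be non-empty over A/C/G/T")
        if not 15 <= self.tail_length <= 18:
            raise PanelError(
                f"{self.name}: tail_length {self.tail_length} outside 15-18 bp"
            )
        if not 1 <= len(self.motif) <= 6 or set(self.motif) - _BASES:
            raise PanelError(f"{self.name}: motif must be 1-6 bases over A/C/G/T")
        if self.dye not in DYES:
            raise PanelError(f"{self.name}: unknown dye {self.dye!r}")
        lo, hi = self.size_range
        if not lo < hi:
            raise PanelError(f"{self.name}: size_range min must be < max")

    @property
    def is_homopolymer(self) -> bool:
        return len(self.motif) == 1


@dataclass(frozen=True)
class PeakRecord:
    """A capillary electropherogram peak: fragment size (bp, tail included)
    against the size standard, and signal height."""

    sample_id: str
    dye: str
    raw_size: float
    height: float

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise PanelError(f"unknown dye {self.dye!r}")
        if self.raw_size <= 0:
            raise PanelError(f"raw_size must be > 0, got {self.raw_size}")
        if self.height < 0:
            raise PanelError(f"height must be >= 0, got {self.height}")


Pair = tuple[float, float]


@dataclass
class AlleleProfile:
    """Per-sample multilocus profile: locus -> sorted allele pair, or None (ND).

    Homozygotes are stored as ``(a, a)``.  ``raw`` keeps the verbatim cell
    strings from the source table (e.g. the unsorted printed order or a
    three-value replicate entry); ``notes`` records parsing remarks such as
    disagreeing replicates or applied corrections.
    """

    sample_id: str
    platform: str
    calls: dict[str, Pair | None] = field(default_factory=dict)
    raw: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise PanelError(f"unknown platform {self.platform!r}")
        for locus, pair in self.calls.items():
            if pair is not None:
                self.calls[locus] = (min(pair), max(pair))

    def typed_loci(self) -> list[str]:
        return [l for l, p in self.calls.items() if p is not None]


@dataclass
class ReferencePanel:
    """Reference clonal genotypes: name -> AlleleProfile on one platform."""

    profiles: dict[str, AlleleProfile]
    platform: str = "polyacrylamide"

    def __iter__(self):
        return iter(self.profiles.items())

    def __getitem__(self, genotype: str) -> AlleleProfile:
        return self.profiles[genotype]

    def validate(self, panel: Sequence[LocusSpec]) -> None:
        """Check every genotype covers all loci with sizes inside the locus range."""
        by_name = {l.name: l for l in panel}
        for gname, prof in self.profiles.items():
            for locus in by_name:
                if locus not in prof.calls:
                    raise PanelError(f"{gname}: locus {locus} missing")
                pair = prof.calls[locus]
                if pair is None:
                    continue
                lo, hi = by_name[locus].size_range
                for a in pair:
                    if not lo <= a <= hi:
                        raise PanelError(
                            f"{gname}/{locus}: allele {a} outside size_range {lo}-{hi}"
                        )


# ---------------------------------------------------------------------------
# panel loading


def _packaged(name: str):
    return importlib.resources.files("ssrbridge.data").joinpath(name)


def load_marker_panel(path: str | Path | None = None) -> list[LocusSpec]:
    """Load a marker panel from TOML/JSON; default: the packaged eight-locus panel.

    The file holds one table per locus keyed by the LocusSpec fields.
    """
    if path is None:
        text = _packaged("panel.toml").read_text()
        data = tomllib.loads(text)
    else:
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = tomllib.loads(text)
    if not data:
        raise PanelError("no loci defined")
    loci: list[LocusSpec] = []
    seen: set[str] = set()
    for name, fields in data.items():
        if name in seen:
            raise PanelError(f"duplicate locus name {name}")
        seen.add(name)
        try:
            loci.append(
                LocusSpec(
                    name=name,
                    forward_primer=fields["forward_primer"],
                    reverse_primer=fields["reverse_primer"],
                    tail_length=int(fields["tail_length"]),
                    motif=fields["motif"],
                    dye=fields["dye"],
                    size_range=tuple(fields["size_range"]),
                    mix_group=fields.get("mix_group", "MM1"),
                    historic_platform1=bool(fields.get("historic_platform1", True)),
                )
            )
        except KeyError as exc:
            raise PanelError(f"{name}: missing field {exc}") from None
    return loci


def panel_by_name(panel: Sequence[LocusSpec]) -> dict[str, LocusSpec]:
    return {l.name: l for l in panel}


# ---------------------------------------------------------------------------
# genotype tables


def _parse_pair(cell: str, locus: str) -> tuple[Pair | None, str | None]:
    """Parse an ``a/b`` (or replicate ``a/a/b``) cell; returns (pair, note)."""
    cell = cell.strip()
    if cell in ("", "ND", "nd"):
        return None, None
    try:
        values = [float(v) for v in cell.split("/")]
    except ValueError:
        raise PanelError(f"{locus}: unparseable allele pair {cell!r}") from None
    uniq = sorted(set(values))
    note = None
    if len(values) > 2:
        # replicate rows collapsed into one entry; a heterozygous consensus
        # wins if two distinct sizes are present
        if len(uniq) > 2:
            raise PanelError(f"{locus}: more than two distinct alleles in {cell!r}")
        note = f"replicates: {cell}"
        values = uniq if len(uniq) == 2 else [uniq[0], uniq[0]]
    if len(values) == 1:
        values = [values[0], values[0]]
    return (min(values), max(values)), note


def _format_allele(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else f"{a:.1f}"


def load_genotype_table(path: str | Path | None = None) -> list[AlleleProfile]:
    """Read a TSV genotype table (one row per genotype x platform).

    Columns: ``genotype``, ``platform``, then one column per locus holding
    ``a/b`` or ``ND``.  Defaults to the packaged seven-genotype fixture.
    """
    if path is None:
        text = _packaged("table1.tsv").read_text()
    else:
        text = Path(path).read_text()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    fields = reader.fieldnames or []
    if fields[:2] != ["genotype", "platform"]:
        raise PanelError("genotype table must start with genotype, platform columns")
    loci = [c for c in fields[2:] if c]
    unknown = set(loci) - set(LOCUS_ORDER)
    # locus columns outside the standard panel are allowed only if the caller
    # uses a custom panel; flag plainly misnamed ones
    profiles: list[AlleleProfile] = []
    for row in reader:
        prof = AlleleProfile(sample_id=row["genotype"], platform=row["platform"])
        for locus in loci:
            cell = (row.get(locus) or "ND").strip()
            pair, note = _parse_pair(cell, locus)
            prof.calls[locus] = pair
            prof.raw[locus] = cell
            if note:
                prof.notes[locus] = note
        profiles.append(prof)
    return profiles


def load_reference_panel(
    path: str | Path | None = None, platform: str = "polyacrylamide"
) -> ReferencePanel:
    """Load the reference clonal-genotype panel for one platform (default:
    the packaged fixture's original polyacrylamide rows)."""
    profiles = {
        p.sample_id: p for p in load_genotype_table(path) if p.platform == platform
    }
    if not profiles:
        raise PanelError(f"no rows for platform {platform!r}")
    return ReferencePanel(profiles=profiles, platform=platform)


def write_genotype_table(
    profiles: Iterable[AlleleProfile], path: str | Path, loci: Sequence[str] = LOCUS_ORDER
) -> None:
    """Write profiles as a TSV that round-trips through ``load_genotype_table``.

    Pairs are serialized ascending; ND stands for an untyped locus.
    """
    profiles = list(profiles)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["genotype", "platform", *loci])
        for prof in profiles:
            row = [prof.sample_id, prof.platform]
            for locus in loci:
                pair = prof.calls.get(locus)
                row.append(
                    "ND" if pair is None else "/".join(_format_allele(a) for a in pair)
                )
            writer.writerow(row)


# ---------------------------------------------------------------------------
# peak tables


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a CSV peak table with header ``sample_id,dye,size,height``."""
    records: list[PeakRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "dye", "size", "height"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PanelError("peak table must have columns sample_id,dye,size,height")
        for row in reader:
            records.append(
                PeakRecord(
                    sample_id=row["sample_id"],
                    dye=row["dye"],
                    raw_size=float(row["size"]),
                    height=float(row["height"]),
                )
            )
    return records


def write_peak_table(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "dye", "size", "height"])
        for p in peaks:
            writer.writerow([p.sample_id, p.dye, f"{p.raw_size:.2f}", f"{p.height:.1f}"])


# ---------------------------------------------------------------------------
# documented fixture corrections


@dataclass(frozen=True)
class Correction:
    genotype: str
    platform: str
    locus: str
    pair: Pair
    reason: str


#: G30's printed capillary Dvit6 entry 205.4/202.4 conflicts with its
#: homozygous 205/205 original genotype and with the published per-locus
#: discrepancy statistics, which it reproduces only if read as homozygous
#: 202.4 - a suspected transposition in the printed table.
TABLE_CORRECTIONS: tuple[Correction, ...] = (
    Correction(
        "G30",
        "capillary",
        "Dvit6",
        (202.4, 202.4),
        "suspected transposed cell; printed 205.4/202.4 vs homozygous 205/205 original",
    ),
)

#: The G30 HTS Dvit3 171 bp allele is attributed to a preferentially
#: sequenced stutter band (one repeat unit short); used when matching HTS
#: profiles back to the historic genotype definitions, but never when
#: recomputing the published concordance statistics.
MATCHING_CORRECTIONS: tuple[Correction, ...] = TABLE_CORRECTIONS + (
    Correction(
        "G30",
        "hts",
        "Dvit3",
        (173.0, 173.0),
        "171 bp allele consistent with amplification stutter; one AT unit short of 173",
    ),
)

#: Historic allele names known to be offset from sequence-true sizes by an
#: error in the original polyacrylamide scoring: Dvit4's names are 2 bp
#: larger than the sequenced alleles (the historic '159' allele is 157 bp).
HISTORIC_SCORING_CORRECTIONS: dict[str, int] = {"Dvit4": -2}


def apply_corrections(
    profiles: Iterable[AlleleProfile],
    corrections: Sequence[Correction] = TABLE_CORRECTIONS,
) -> list[AlleleProfile]:
    """Return copies of ``profiles`` with matching documented corrections applied."""
    index = {(c.genotype, c.platform, c.locus): c for c in corrections}
    out: list[AlleleProfile] = []
    for prof in profiles:
        new = AlleleProfile(
            sample_id=prof.sample_id,
            platform=prof.platform,
            calls=dict(prof.calls),
            raw=dict(prof.raw),
            notes=dict(prof.notes),
        )
        for locus in list(new.calls):
            corr = index.get((prof.sample_id, prof.platform, locus))
            if corr is not None:
                new.calls[locus] = (min(corr.pair), max(corr.pair))
                new.notes[locus] = corr.reason
        out.append(new)
    return out
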