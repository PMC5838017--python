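"""Core genomic data model: intervals, CpG-island and AMR records, methylome tracks.

Coordinates are 0-based half-open throughout (BED convention); any 1-based
display is formatting only.  Methylation tracks are 4-column TSVs
(chrom, pos, level, depth) with ``#key=value`` metadata header lines —
a deliberately diffable dialect instead of bigWig.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "CgiRecord",
    "AmrRecord",
    "CpGSiteCall",
    "MethylomeTrack",
    "Compartment",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_methylation_track",
    "write_methylation_track",
    "write_table",
    "read_table",
    "normalize_chrom",
]

MIN_CONVERSION_RATE = 0.95  # methylome inclusion rule: bisulfite conversion ≥ 0.95
DEFAULT_MIN_DEPTH = 10  # minimum read depth per CpG site


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class Compartment(str, enum.Enum):
    SOMATIC = "somatic"
    OOCYTE = "oocyte"
    SPERM = "sperm"
    BLASTOCYST = "blastocyst"
    PLACENTA = "placenta"
    CANCER = "cancer"
    STEM_DERIVED = "stem_derived"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base pair.

        Half-open semantics: [a, b) never overlaps [b, c).
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class CgiRecord:
    """A CpG island with a collection-unique identifier."""

    id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class AmrRecord:
    """An allelically methylated region called in one source methylome."""

    interval: GenomicInterval
    source_methylome: str


@dataclass(frozen=True)
class CpGSiteCall:
    """Methylation level and read depth at a single CpG position.

    ``level`` is None when the site failed the track's minimum-depth
    threshold; depth is retained so the filter is auditable.
    """

    chrom: str
    pos: int
    level: float | None
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.level is not None and not (0.0 <= self.level <= 1.0):
            raise ValueError(f"level {self.level} outside [0, 1]")


@dataclass
class MethylomeTrack:
    """An ordered per-sample collection of CpG site calls."""

    sample_id: str
    tissue: str = ""
    compartment: Compartment = Compartment.SOMATIC
    conversion_rate: float = 1.0
    sites: list[CpGSiteCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.compartment, str):
            self.compartment = Compartment(self.compartment)
        if not (0.0 <= self.conversion_rate <= 1.0):
            raise ValueError("conversion_rate must lie in [0, 1]")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.pos))
            keys = sorted(keys)
        for a, b in zip(keys, keys[1:]):
            if a == b:
                raise ValueError(f"duplicate CpG position {a[0]}:{a[1]}")

    def sites_in(self, interval: GenomicInterval) -> list[CpGSiteCall]:
        # binary search over the (chrom, pos)-sorted site list
        import bisect

        keys = self.__dict__.get("_keys")
        if keys is None or len(keys) != len(self.sites):
            keys = [(s.chrom, s.pos) for s in self.sites]
            self.__dict__["_keys"] = keys
        lo = bisect.bisect_left(keys, (interval.chrom, interval.start))
        hi = bisect.bisect_left(keys, (interval.chrom, interval.end))
        return self.sites[lo:hi]


def normalize_chrom(chrom: str) -> str:
    """Prefix bare chromosome names with 'chr' ('1' → 'chr1').

    Comparison elsewhere is string-exact; this is the opt-in normalizer.
    """
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


# ---------------------------------------------------------------------------
# BED I/O

def read_bed(path: str | Path, *, normalize: bool = False) -> list[tuple[str, GenomicInterval]]:
    """Read a BED3/BED4 file into (name, interval) pairs.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.  A
    missing 4th column yields a generated id ``region_<n>``.
    """
    out: list[tuple[str, GenomicInterval]] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if normalize:
                chrom = normalize_chrom(chrom)
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] else f"region_{len(out) + 1}"
            out.append((name, interval))
    return out


def write_bed(records: Iterable[tuple[str, GenomicInterval]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Methylation track I/O

def read_methylation_track(
    path: str | Path,
    min_depth: int = DEFAULT_MIN_DEPTH,
    *,
    allow_low_conversion: bool = False,
) -> MethylomeTrack:
    """Read a 4-column methylation TSV into a :class:`MethylomeTrack`.

    Header ``#key=value`` lines supply sample metadata (sample_id, tissue,
    compartment, conversion_rate).  Sites with depth below ``min_depth``
    have their level set missing.  Tracks with conversion_rate below 0.95
    are rejected unless ``allow_low_conversion`` is set.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    sites: list[CpGSiteCall] = []
    seen: set[tuple[str, int]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":  # column header
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns")
            chrom = fields[0]
            try:
                pos = int(fields[1])
                depth = int(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer pos/depth") from None
            level_s = fields[2]
            if level_s in ("NA", "nan", ""):
                level = None
            else:
                try:
                    level = float(level_s)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric level") from None
                if not (0.0 <= level <= 1.0):
                    raise ParseError(f"{path}:{lineno}: level {level} outside [0, 1]")
            if depth < min_depth:
                level = None
            if (chrom, pos) in seen:
                raise ParseError(f"{path}:{lineno}: duplicate position {chrom}:{pos}")
            seen.add((chrom, pos))
            sites.append(CpGSiteCall(chrom, pos, level, depth))

    conversion = float(meta.get("conversion_rate", "1.0"))
    if conversion < MIN_CONVERSION_RATE and not allow_low_conversion:
        raise ValueError(
            f"{path}: bisulfite conversion rate {conversion} below "
            f"{MIN_CONVERSION_RATE}; pass allow_low_conversion to override"
        )
    return MethylomeTrack(
        sample_id=meta.get("sample_id", path.stem),
        tissue=meta.get("tissue", ""),
        compartment=Compartment(meta.get("compartment", "somatic")),
        conversion_rate=conversion,
        sites=sites,
    )


def write_methylation_track(track: MethylomeTrack, path: str | Path) -> None:
    """Write a track so that re-reading preserves levels and missingness."""
    with Path(path).open("w") as fh:
        fh.write(f"#sample_id={track.sample_id}\n")
        fh.write(f"#tissue={track.tissue}\n")
        fh.write(f"#compartment={track.compartment.value}\n")
        fh.write(f"#conversion_rate={track.conversion_rate}\n")
        fh.write("chrom\tpos\tlevel\tdepth\n")
        for s in track.sites:
            level = "NA" if s.level is None else repr(s.level)
            fh.write(f"{s.chrom}\t{s.pos}\t{level}\t{s.depth}\n")


# ---------------------------------------------------------------------------
# Generic dataclass table I/O (TSV with header; round-trips exactly)

def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, frozenset) or isinstance(value, set):
        return ",".join(sorted(value)) if value else "-"
    return str(value)


def _parse_cell(text: str, typ):
    import types
    import typing

    origin = typing.get_origin(typ)
    if origin is typing.Union or origin is types.UnionType:  # Optional[...]
        args = [a for a in typing.get_args(typ) if a is not type(None)]
        if text == "NA":
            return None
        return _parse_cell(text, args[0])
    if typ is float:
        return float(text)
    if typ is int:
        return int(text)
    if typ is bool:
        return text == "true"
    if isinstance(typ, type) and issubclass(typ, enum.Enum):
        return typ(text)
    if typ in (frozenset, set) or origin in (frozenset, set):
        return frozenset() if text == "-" else frozenset(text.split(","))
    return text


def write_table(records: Sequence, path: str | Path, cls=None) -> None:
    """Write flat dataclass records of one type to a header-ed TSV.

    An empty record set with ``cls`` given yields a header-only file.
    """
    records = list(records)
    path = Path(path)
    if not records:
        if cls is not None:
            names = [f.name for f in dataclasses.fields(cls)]
            path.write_text("\t".join(names) + "\n")
        else:
            path.write_text("")
        return
    if cls is None:
        cls = type(records[0])
    if not dataclasses.is_dataclass(cls):
        raise TypeError("write_table expects dataclass records")
    if any(type(r) is not cls for r in records):
        raise TypeError("mixed record schemas in write_table")
    names = [f.name for f in dataclasses.fields(cls)]
    with path.open("w") as fh:
        fh.write("\t".join(names) + "\n")
        for r in records:
            fh.write(
                "\t".join(_format_cell(getattr(r, n)) for n in names) + "\n"
            )


def read_table(path: str | Path, cls) -> list:
    """Read a TSV written by :func:`write_table` back into dataclasses."""
    import typing

    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    lines = text.splitlines()
    names = lines[0].split("\t")
    hints = typing.get_type_hints(cls)
    out = []
    for line in lines[1:]:
        cells = line.split("\t")
        kwargs = {
            name: _parse_cell(cell, hints[name])
            for name, cell in zip(names, cells)
        }
        out.append(cls(**kwargs))
    return out
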