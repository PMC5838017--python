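"""Candidate-iDMR discovery screen.

Pipeline order: count AMR records overlapping each CpG island → keep CGIs
with at least ``min_records`` overlapping records → keep CGIs whose every
covered CpG site in the reference methylome lies in the intermediate band
[0.35, 0.65] → classify the survivors from gamete methylomes (oocyte
hyper + sperm hypo → gametic maternal; the mirror → gametic paternal; no
gametic asymmetry → secondary candidate) → annotate against the known
iDMR list.  Sex chromosomes are excluded by default; the analysis is
autosomal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome_data import AmrRecord, CgiRecord, GenomicInterval, MethylomeTrack
from .methylation_profiles import (
    INTERMEDIATE_HIGH,
    INTERMEDIATE_LOW,
    MethylationStatus,
    call_status,
    region_mean,
)

__all__ = [
    "ScreenParams",
    "CandidateClass",
    "CandidateIdmr",
    "count_overlapping_amrs",
    "filter_by_record_count",
    "intermediate_filter",
    "classify_candidate",
    "annotate_known",
    "run_screen",
]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


class CandidateClass(str, enum.Enum):
    GAMETIC_MATERNAL = "gametic_maternal"
    GAMETIC_PATERNAL = "gametic_paternal"
    SECONDARY_CANDIDATE = "secondary_candidate"
    KNOWN = "known"
    REJECTED = "rejected"


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the discovery screen.

    min_records: minimum number of overlapping AMR records per CGI (16,
    the minimal count observed for most known iDMRs).  The intermediate
    band [0.35, 0.65] is inclusive at both bounds.
    """

    min_records: int = 16
    intermediate_low: float = INTERMEDIATE_LOW
    intermediate_high: float = INTERMEDIATE_HIGH
    reference_methylome: str = ""
    min_covered_sites: int = 1
    count_distinct_methylomes: bool = False
    require_reference_amr: bool = False
    include_sex_chroms: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.intermediate_low < self.intermediate_high <= 1):
            raise ValueError("need 0 <= low < high <= 1")
        if self.min_records < 1:
            raise ValueError("min_records must be >= 1")


@dataclass
class CandidateIdmr:
    """One CGI's screen outcome.  Flat so it round-trips through TSV."""

    cgi_id: str
    chrom: str
    start: int
    end: int
    record_count: int
    methylome_count: int
    oocyte_mean: float | None
    sperm_mean: float | None
    oocyte_status: MethylationStatus
    sperm_status: MethylationStatus
    klass: CandidateClass
    novel: bool
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if self.record_count < self.methylome_count:
            raise ValueError("record_count must be >= methylome_count")
        if self.klass is CandidateClass.KNOWN and self.novel:
            raise ValueError("known candidates cannot be novel")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def count_overlapping_amrs(
    cgis: list[CgiRecord],
    amr_records: list[AmrRecord],
) -> dict[str, tuple[int, int]]:
    """Per CGI: (number of overlapping AMR records, distinct source methylomes).

    An AMR counts iff it shares >= 1 bp with the CGI (half-open
    coordinates, so abutting intervals do not overlap).  Every input CGI
    appears in the result, with (0, 0) when nothing overlaps.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in amr_records:
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, rec)
    out: dict[str, tuple[int, int]] = {}
    for cgi in cgis:
        iv = cgi.interval
        tree = trees.get(iv.chrom)
        hits = tree.overlap(iv.start, iv.end) if tree is not None else ()
        methylomes = {h.data.source_methylome for h in hits}
        out[cgi.id] = (len(hits), len(methylomes))
    return out


def filter_by_record_count(
    counts: dict[str, tuple[int, int]],
    params: ScreenParams,
) -> set[str]:
    """CGI ids whose overlapping-record count meets the inclusion threshold."""
    key = 1 if params.count_distinct_methylomes else 0
    return {cgi_id for cgi_id, c in counts.items() if c[key] >= params.min_records}


def intermediate_filter(
    cgi: CgiRecord,
    reference_track: MethylomeTrack,
    params: ScreenParams,
) -> tuple[bool, str]:
    """Does the CGI consistently show intermediate methylation in the reference?

    True iff the region has at least ``min_covered_sites`` covered sites
    and *every* covered site level lies in [low, high] (inclusive).
    Returns (passed, annotation).
    """
    levels = [
        s.level
        for s in reference_track.sites_in(cgi.interval)
        if s.level is not None
    ]
    if len(levels) < params.min_covered_sites:
        return False, "not evaluable: insufficient covered sites in reference"
    if all(params.intermediate_low <= lv <= params.intermediate_high for lv in levels):
        return True, ""
    return False, "site outside intermediate band in reference"


def classify_candidate(
    cgi: CgiRecord,
    oocyte_track: MethylomeTrack,
    sperm_track: MethylomeTrack,
    params: ScreenParams,
) -> tuple[CandidateClass, "RegionPair"]:
    """Gametic vs secondary classification from gamete methylomes.

    Oocyte hypermethylated and sperm hypomethylated → gametic maternal;
    the mirror → gametic paternal; every other combination — including
    both gametes hypomethylated (the secondary signature) or an
    unevaluable gamete — → secondary candidate.
    """
    if oocyte_track is None or sperm_track is None:
        raise ValueError("both gamete tracks are required for classification")
    oo = region_mean(oocyte_track, cgi.interval, params.intermediate_low, params.intermediate_high)
    sp = region_mean(sperm_track, cgi.interval, params.intermediate_low, params.intermediate_high)
    hyper, hypo = MethylationStatus.HYPERMETHYLATED, MethylationStatus.HYPOMETHYLATED
    if oo.status is hyper and sp.status is hypo:
        klass = CandidateClass.GAMETIC_MATERNAL
    elif oo.status is hypo and sp.status is hyper:
        klass = CandidateClass.GAMETIC_PATERNAL
    else:
        klass = CandidateClass.SECONDARY_CANDIDATE
    return klass, RegionPair(oo.mean, sp.mean, oo.status, sp.status)


@dataclass(frozen=True)
class RegionPair:
    oocyte_mean: float | None
    sperm_mean: float | None
    oocyte_status: MethylationStatus
    sperm_status: MethylationStatus


def annotate_known(
    candidates: list[CandidateIdmr],
    known_idmr_ids: set[str] | list[str],
    known_intervals: list[GenomicInterval] | None = None,
) -> list[CandidateIdmr]:
    """Flag candidates present in the known-iDMR list (by id, optionally by overlap).

    Matched candidates get klass=known, novel=false; all others novel=true.
    Rejected candidates are never marked novel.
    """
    known_ids = set(known_idmr_ids)
    out = []
    for cand in candidates:
        matched = cand.cgi_id in known_ids
        if not matched and known_intervals:
            matched = any(cand.interval.overlaps(k) for k in known_intervals)
        if cand.klass is CandidateClass.REJECTED:
            out.append(cand)
        elif matched:
            out.append(
                CandidateIdmr(
                    cand.cgi_id, cand.chrom, cand.start, cand.end,
                    cand.record_count, cand.methylome_count,
                    cand.oocyte_mean, cand.sperm_mean,
                    cand.oocyte_status, cand.sperm_status,
                    CandidateClass.KNOWN, False, cand.reject_reason,
                )
            )
        else:
            out.append(cand)
    return out


def run_screen(
    cgis: list[CgiRecord],
    amr_records: list[AmrRecord],
    reference_track: MethylomeTrack,
    oocyte_track: MethylomeTrack,
    sperm_track: MethylomeTrack,
    params: ScreenParams,
    known_idmr_ids: set[str] | None = None,
    known_intervals: list[GenomicInterval] | None = None,
) -> list[CandidateIdmr]:
    """Run the full screen; every input CGI appears exactly once in the output.

    Stage order: record counting → record-count filter → intermediate
    filter against the reference methylome → gamete classification →
    known-iDMR annotation.  Rejected CGIs retain the rejecting stage as
    ``reject_reason``.
    """
    counts = count_overlapping_amrs(cgis, amr_records)
    passed_count = filter_by_record_count(counts, params)
    results: list[CandidateIdmr] = []
    for cgi in cgis:
        record_count, methylome_count = counts[cgi.id]
        iv = cgi.interval

        def rejected(reason: str) -> CandidateIdmr:
            return CandidateIdmr(
                cgi.id, iv.chrom, iv.start, iv.end,
                record_count, methylome_count, None, None,
                MethylationStatus.UNEVALUABLE, MethylationStatus.UNEVALUABLE,
                CandidateClass.REJECTED, False, reason,
            )

        if not params.include_sex_chroms and iv.chrom in SEX_CHROMS:
            results.append(rejected("sex chromosome excluded"))
            continue
        if cgi.id not in passed_count:
            results.append(rejected(f"record_count {record_count} < {params.min_records}"))
            continue
        ok, note = intermediate_filter(cgi, reference_track, params)
        if not ok:
            results.append(rejected(note))
            continue
        klass, gametes = classify_candidate(cgi, oocyte_track, sperm_track, params)
        reason = ""
        if (
            gametes.oocyte_status is MethylationStatus.UNEVALUABLE
            or gametes.sperm_status is MethylationStatus.UNEVALUABLE
        ):
            reason = "unevaluable gamete"
        results.append(
            CandidateIdmr(
                cgi.id, iv.chrom, iv.start, iv.end,
                record_count, methylome_count,
                gametes.oocyte_mean, gametes.sperm_mean,
                gametes.oocyte_status, gametes.sperm_status,
                klass, True, reason,
            )
        )
    return annotate_known(results, known_idmr_ids or set(), known_intervals)
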