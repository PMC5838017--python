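"""Region-level methylation summaries, status calls, and the trisomy dosage model.

A region whose two parental alleles carry one methylated and one
unmethylated copy shows an intermediate ("hemimethylated") mean in
[0.35, 0.65].  In a trisomic sample the same locus carries three copies,
so the expected methylation level becomes methylated_copies/3: a maternal
imprint with a paternal supernumerary chromosome drops to 1/3 (<= 0.33
after rounding) and with a maternal supernumerary rises to 2/3 (>= 0.66) —
the basis of parent-of-origin calling without parental DNA.

Also implements the methylation-sensitive restriction enzyme (MSRE) PCR
proportion: digestion destroys unmethylated template, so the ratio of
digested to undigested target signal — each normalized by an enzyme-free
reference amplimer — estimates the fraction of resistant (methylated)
alleles.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass

import pandas as pd

from .genome_data import GenomicInterval, MethylomeTrack

__all__ = [
    "MethylationStatus",
    "RegionMethylationSummary",
    "DosageModel",
    "TrisomyOriginCall",
    "MsreTriplexMeasurement",
    "region_mean",
    "call_status",
    "expected_dosage_level",
    "call_trisomy_origin",
    "msre_proportion",
    "cohort_status_profile",
    "IncompleteDigestionError",
    "INTERMEDIATE_LOW",
    "INTERMEDIATE_HIGH",
]

# Intermediate (hemimethylated) band: one methylated + one unmethylated allele.
INTERMEDIATE_LOW = 0.35
INTERMEDIATE_HIGH = 0.65

# Trisomy parent-of-origin bounds on the observed region mean.
TRISOMY_LOWER = 0.33
TRISOMY_UPPER = 0.66


class MethylationStatus(str, enum.Enum):
    HYPOMETHYLATED = "hypomethylated"
    INTERMEDIATE = "intermediate"
    HYPERMETHYLATED = "hypermethylated"
    UNEVALUABLE = "unevaluable"


class TrisomyOriginCall(str, enum.Enum):
    PATERNAL_SUPERNUMERARY = "paternal_supernumerary"
    MATERNAL_SUPERNUMERARY = "maternal_supernumerary"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class RegionMethylationSummary:
    sample_id: str
    interval: GenomicInterval
    mean: float | None
    sd: float | None
    n_used: int
    n_missing: int
    status: MethylationStatus


@dataclass(frozen=True)
class DosageModel:
    """Allele-copy counting model for expected region methylation."""

    methylated_copies: int
    total_copies: int

    def __post_init__(self) -> None:
        if self.total_copies < 1:
            raise ValueError("total_copies must be >= 1")
        if not (0 <= self.methylated_copies <= self.total_copies):
            raise ValueError("need 0 <= methylated_copies <= total_copies")


@dataclass(frozen=True)
class MsreTriplexMeasurement:
    """Signal intensities from one MSRE-PCR triplex assay.

    The target amplimer contains enzyme recognition sites; the reference
    amplimer contains none and normalizes lane-to-lane amounts; the
    digestion control is an unmethylated locus whose signal must vanish
    after complete digestion.
    """

    target_digested: float
    target_undigested: float
    reference_digested: float
    reference_undigested: float
    digestion_control_digested: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "target_digested",
            "target_undigested",
            "reference_digested",
            "reference_undigested",
            "digestion_control_digested",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.reference_digested <= 0 or self.reference_undigested <= 0:
            raise ValueError("reference signals must be positive")


class IncompleteDigestionError(ValueError):
    """Digestion-control signal persists: the restriction digest failed."""


def call_status(
    mean: float | None,
    low: float = INTERMEDIATE_LOW,
    high: float = INTERMEDIATE_HIGH,
) -> MethylationStatus:
    """Map a region mean onto the hypo/intermediate/hyper scale.

    Bounds are inclusive for the intermediate band: hyper requires
    strictly > high, hypo strictly < low.
    """
    if mean is None:
        return MethylationStatus.UNEVALUABLE
    if not (0.0 <= mean <= 1.0):
        raise ValueError(f"mean {mean} outside [0, 1]")
    if mean < low:
        return MethylationStatus.HYPOMETHYLATED
    if mean > high:
        return MethylationStatus.HYPERMETHYLATED
    return MethylationStatus.INTERMEDIATE


def region_mean(
    track: MethylomeTrack,
    interval: GenomicInterval,
    low: float = INTERMEDIATE_LOW,
    high: float = INTERMEDIATE_HIGH,
) -> RegionMethylationSummary:
    """Mean/sd methylation across covered CpG sites in a region.

    Sites with no data (missing level) are excluded from the mean and
    counted in ``n_missing``.  sd uses the n−1 denominator and is absent
    for a single usable site.
    """
    sites = track.sites_in(interval)
    levels = [s.level for s in sites if s.level is not None]
    n_missing = len(sites) - len(levels)
    if not levels:
        return RegionMethylationSummary(
            track.sample_id, interval, None, None, 0, n_missing,
            MethylationStatus.UNEVALUABLE,
        )
    mean = sum(levels) / len(levels)
    sd = statistics.stdev(levels) if len(levels) > 1 else None
    return RegionMethylationSummary(
        track.sample_id, interval, mean, sd, len(levels), n_missing,
        call_status(mean, low, high),
    )


def expected_dosage_level(model: DosageModel) -> float:
    """Expected methylation level = methylated copies / total copies."""
    return model.methylated_copies / model.total_copies


def call_trisomy_origin(
    observed_mean: float,
    lower: float = TRISOMY_LOWER,
    upper: float = TRISOMY_UPPER,
) -> TrisomyOriginCall:
    """Parent-of-origin of a supernumerary chromosome at a maternal iDMR.

    The observed mean is rounded to two decimals before comparison so the
    theoretical 1/3 satisfies the <= 0.33 bound.  Only meaningful for
    maternally methylated iDMRs in trisomic samples.
    """
    if not (0.0 <= observed_mean <= 1.0):
        raise ValueError("observed_mean must lie in [0, 1]")
    rounded = round(observed_mean, 2)
    if rounded <= lower:
        return TrisomyOriginCall.PATERNAL_SUPERNUMERARY
    if rounded >= upper:
        return TrisomyOriginCall.MATERNAL_SUPERNUMERARY
    return TrisomyOriginCall.INDETERMINATE


def msre_proportion(
    measurement: MsreTriplexMeasurement,
    digestion_threshold: float = 0.05,
) -> float:
    """Proportion of restriction-enzyme-resistant (methylated) alleles.

    Reference-normalized ratio of ratios:
        (target_dig / reference_dig) / (target_undig / reference_undig),
    clamped to [0, 1].  Scale-invariant per lane by construction.
    The digestion-control signal, relative to its lane reference, must be
    below ``digestion_threshold`` or the digest is deemed incomplete.
    """
    control = measurement.digestion_control_digested / measurement.reference_digested
    if control > digestion_threshold:
        raise IncompleteDigestionError(
            f"digestion control signal ratio {control:.3g} exceeds "
            f"threshold {digestion_threshold}"
        )
    if measurement.target_undigested <= 0:
        raise ValueError("undigested target signal must be positive")
    digested_ratio = measurement.target_digested / measurement.reference_digested
    undigested_ratio = measurement.target_undigested / measurement.reference_undigested
    proportion = digested_ratio / undigested_ratio
    return min(1.0, max(0.0, proportion))


def cohort_status_profile(
    summaries: list[RegionMethylationSummary],
    low: float = INTERMEDIATE_LOW,
    high: float = INTERMEDIATE_HIGH,
) -> pd.DataFrame:
    """Per-sample status table with dysregulation flags for one region.

    Samples outside the intermediate band are flagged (hypo or hyper);
    the fraction of intermediate samples quantifies cohort-level
    epipolymorphism (1.0 = none).
    """
    if not summaries:
        raise ValueError("cohort_status_profile needs at least one summary")
    rows = []
    for s in summaries:
        status = call_status(s.mean, low, high)
        rows.append(
            {
                "sample_id": s.sample_id,
                "mean": s.mean,
                "status": status.value,
                "dysregulated": status
                in (MethylationStatus.HYPOMETHYLATED, MethylationStatus.HYPERMETHYLATED),
            }
        )
    df = pd.DataFrame(rows)
    evaluable = df[df["status"] != MethylationStatus.UNEVALUABLE.value]
    frac = (
        float((evaluable["status"] == MethylationStatus.INTERMEDIATE.value).mean())
        if len(evaluable)
        else math.nan
    )
    df.attrs["fraction_intermediate"] = frac
    return df
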