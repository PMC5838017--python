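"""Parental origin of methylation imprints from trios and digestion-resistant alleles.

After methylation-sensitive restriction digestion only the methylated
(resistant) alleles amplify; genotyping the surviving alleles in a
mother–father–child trio reveals which parental allele carries the
imprint.  A trio is informative only when the child is heterozygous and
Mendelian transmission assigns each child allele to exactly one parent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections import Counter

__all__ = [
    "TrioGenotype",
    "DigestResistantCall",
    "ImprintOriginCall",
    "Transmission",
    "MendelianError",
    "transmitted_alleles",
    "infer_imprint_origin",
    "cohort_consensus",
    "ConsensusResult",
]


class MendelianError(ValueError):
    """Child genotype cannot arise from the stated parents."""


class ImprintOriginCall(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL_METHYLATION = "biparental_methylation"
    UNMETHYLATED = "unmethylated"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class TrioGenotype:
    """Unordered biallelic genotypes of a nuclear family at one SNP."""

    snp_id: str
    mother: frozenset
    father: frozenset
    child: frozenset
    family_id: str = ""

    def __post_init__(self) -> None:
        for name in ("mother", "father", "child"):
            gt = getattr(self, name)
            if not isinstance(gt, frozenset):
                object.__setattr__(self, name, frozenset(gt))
            gt = getattr(self, name)
            if not 1 <= len(gt) <= 2:
                raise ValueError(f"{name} genotype must carry 1 or 2 distinct alleles")


@dataclass(frozen=True)
class DigestResistantCall:
    """Alleles still detected after methylation-sensitive digestion."""

    snp_id: str
    resistant_alleles: frozenset

    def __post_init__(self) -> None:
        if not isinstance(self.resistant_alleles, frozenset):
            object.__setattr__(
                self, "resistant_alleles", frozenset(self.resistant_alleles)
            )


@dataclass(frozen=True)
class Transmission:
    maternal_allele: str
    paternal_allele: str


def transmitted_alleles(trio: TrioGenotype) -> Transmission | None:
    """Assign the child's alleles to parents by Mendelian deduction.

    Returns None (uninformative) when the child is homozygous or when
    both assignments of a heterozygous child are consistent with the
    parents.  Raises :class:`MendelianError` when no assignment works.
    """
    child = sorted(trio.child)
    if len(child) == 1:
        a = child[0]
        if a not in trio.mother or a not in trio.father:
            raise MendelianError(
                f"trio {trio.family_id or trio.snp_id}: child allele {a!r} "
                "cannot come from both parents"
            )
        return None
    a, b = child
    assignments = [
        Transmission(m, p)
        for m, p in ((a, b), (b, a))
        if m in trio.mother and p in trio.father
    ]
    if not assignments:
        raise MendelianError(
            f"trio {trio.family_id or trio.snp_id}: child genotype "
            f"{set(trio.child)} inconsistent with parents"
        )
    if len(assignments) > 1:
        return None
    return assignments[0]


def infer_imprint_origin(
    transmission: Transmission | None,
    resistant_call: DigestResistantCall,
) -> ImprintOriginCall:
    """Parental origin of the methylated allele at one informative SNP.

    The resistant-allele set must be a subset of the child's alleles.
    Swapping parental labels in both inputs swaps maternal↔paternal.
    """
    if transmission is None:
        return ImprintOriginCall.UNINFORMATIVE
    child_alleles = {transmission.maternal_allele, transmission.paternal_allele}
    resistant = resistant_call.resistant_alleles
    if not resistant <= child_alleles:
        raise ValueError(
            f"resistant alleles {set(resistant)} not carried by the child "
            f"({child_alleles})"
        )
    if not resistant:
        return ImprintOriginCall.UNMETHYLATED
    if resistant == child_alleles:
        return ImprintOriginCall.BIPARENTAL_METHYLATION
    (allele,) = resistant
    if allele == transmission.maternal_allele:
        return ImprintOriginCall.MATERNAL
    return ImprintOriginCall.PATERNAL


@dataclass(frozen=True)
class ConsensusResult:
    consensus: ImprintOriginCall | None
    n_informative: int
    counts: dict
    conflict: bool


def cohort_consensus(calls: list[ImprintOriginCall]) -> ConsensusResult:
    """Per-locus consensus across families: unanimity among informative calls.

    Uninformative calls are excluded.  Zero informative calls raise; any
    disagreement yields a conflict report with no consensus.
    """
    informative = [c for c in calls if c is not ImprintOriginCall.UNINFORMATIVE]
    if not informative:
        raise ValueError("no informative family for consensus")
    counts = Counter(informative)
    if len(counts) == 1:
        return ConsensusResult(informative[0], len(informative), dict(counts), False)
    return ConsensusResult(None, len(informative), dict(counts), True)
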