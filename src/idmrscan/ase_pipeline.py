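"""Allele-specific expression (ASE) statistics, categories, and gene calls.

ASE at a heterozygous SNP is |0.5 − ref/(ref+alt)|: 0 for balanced
allelic read counts, 0.5 when only one allele is observed.  Per-donor
magnitudes are aggregated into quantile summaries (min, Q1, median, Q3,
max), each summary is sorted into one of four mutually exclusive
categories, and a gene×tissue profile is called only when at least
``min_snps`` informative SNPs agree in direction.  A cis-window scan
collects genes whose TSS lies within ``window_bp`` of an iDMR anchor,
and the unicity check screens RNA-Seq experiment collections for sample
purity using a panel of imprinted control loci.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .genome_data import GenomicInterval

__all__ = [
    "AseSiteObservation",
    "AseSiteSummary",
    "AseCategory",
    "GeneExpressionCall",
    "ExpressionProfile",
    "AseParams",
    "UnicityResult",
    "ase_magnitude",
    "ase_signed",
    "summarize_site",
    "classify_site",
    "call_gene_tissue",
    "maf_filter",
    "cis_window_genes",
    "unicity_check",
]

EPS = 1e-9  # tolerance for the equality cases of the "strictly" rules


@dataclass(frozen=True)
class AseParams:
    """Thresholds of the ASE pipeline.

    donor_min_depth: reads per site per donor for an observation to count.
    gene_snp_min_depth: reads per SNP required for a gene-level call.
    min_snps: non-discordant informative SNPs needed per gene per tissue.
    mono_threshold: Q1/max bound of the consistent-with-monoallelic rule.
    unicity_threshold: minimum ASE at control loci for sample purity.
    window_bp: half-width of the cis scan window around an iDMR.
    """

    donor_min_depth: int = 8
    gene_snp_min_depth: int = 12
    min_snps: int = 3
    mono_threshold: float = 0.33
    strict_value: float = 0.5
    maf_min: float = 0.1
    unicity_threshold: float = 0.42
    window_bp: int = 2_300_000
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not (0 < self.mono_threshold < self.strict_value <= 0.5):
            raise ValueError("need 0 < mono_threshold < strict_value <= 0.5")


@dataclass(frozen=True)
class AseSiteObservation:
    snp_id: str
    gene: str
    tissue: str
    donor: str
    ref_count: int
    alt_count: int
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError("maf must lie in [0, 0.5]")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class AseSiteSummary:
    snp_id: str
    gene: str
    tissue: str
    n_donors: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    min_depth_observed: int

    def __post_init__(self) -> None:
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(not (-EPS <= v <= 0.5 + EPS) for v in vals):
            raise ValueError("ASE quantiles must lie in [0, 0.5]")
        if any(a > b + EPS for a, b in zip(vals, vals[1:])):
            raise ValueError("ASE quantiles must be non-decreasing")


class AseCategory(str, enum.Enum):
    STRICTLY_MONOALLELIC = "strictly_monoallelic"
    CONSISTENT_MONOALLELIC = "consistent_monoallelic"
    STRICTLY_BIALLELIC = "strictly_biallelic"
    CONSISTENT_BIALLELIC = "consistent_biallelic"
    UNCLASSIFIED = "unclassified"


class ExpressionProfile(str, enum.Enum):
    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"
    NOT_CALLABLE = "not_callable"


@dataclass(frozen=True)
class GeneExpressionCall:
    gene: str
    tissue: str
    profile: ExpressionProfile
    n_informative_snps: int
    reason: str = ""


@dataclass(frozen=True)
class UnicityResult:
    experiment_id: str
    criterion_ase_pass: bool
    criterion_flip_pass: bool
    criterion_no_strict_biallelic_pass: bool

    @property
    def overall(self) -> bool:
        return (
            self.criterion_ase_pass
            and self.criterion_flip_pass
            and self.criterion_no_strict_biallelic_pass
        )


def ase_signed(ref_count: int, alt_count: int) -> float:
    """Signed ASE: 0.5 − ref/(ref+alt).  Positive when alt dominates."""
    total = ref_count + alt_count
    if total < 1:
        raise ValueError("ASE undefined for zero total reads")
    return 0.5 - ref_count / total


def ase_magnitude(ref_count: int, alt_count: int) -> float:
    """ASE magnitude |0.5 − ref/(ref+alt)| in [0, 0.5].

    Symmetric under ref↔alt swap (computed from the minor-allele
    fraction so the symmetry is exact in floating point); 0 iff
    ref == alt; 0.5 iff one count is zero.
    """
    total = ref_count + alt_count
    if total < 1:
        raise ValueError("ASE undefined for zero total reads")
    return 0.5 - min(ref_count, alt_count) / total


def summarize_site(
    observations: list[AseSiteObservation],
    params: AseParams = AseParams(),
) -> AseSiteSummary | None:
    """Aggregate per-donor ASE magnitudes at one SNP into quantiles.

    Donors with total depth below ``donor_min_depth`` are excluded.
    Returns None when no donor qualifies.  Quantiles use linear
    interpolation between order statistics by default.
    """
    if not observations:
        return None
    key = (observations[0].snp_id, observations[0].gene, observations[0].tissue)
    for o in observations:
        if (o.snp_id, o.gene, o.tissue) != key:
            raise ValueError("summarize_site requires one snp/gene/tissue group")
    kept = [o for o in observations if o.depth >= params.donor_min_depth]
    if not kept:
        return None
    values = np.array([ase_magnitude(o.ref_count, o.alt_count) for o in kept])
    q = np.quantile(values, [0.0, 0.25, 0.5, 0.75, 1.0], method=params.quantile_method)
    return AseSiteSummary(
        snp_id=key[0],
        gene=key[1],
        tissue=key[2],
        n_donors=len(kept),
        min=float(q[0]),
        q1=float(q[1]),
        median=float(q[2]),
        q3=float(q[3]),
        max=float(q[4]),
        min_depth_observed=min(o.depth for o in kept),
    )


def classify_site(
    summary: AseSiteSummary,
    params: AseParams = AseParams(),
) -> AseCategory:
    """Sort a site summary into the four mutually exclusive ASE categories.

    strictly monoallelic:     min = Q1 = max = 0.5
    consistent monoallelic:   min < 0.5, Q1 >= 0.33 and max >= 0.33
    strictly biallelic:       min = Q1 = max = 0
    consistent biallelic:     min < 0.5, Q1 < 0.33, max > 0
    Anything matching none of the four is unclassified.
    """
    lo, hi = summary.min, summary.max
    q1 = summary.q1
    strict = params.strict_value
    thr = params.mono_threshold
    if abs(lo - strict) <= EPS and abs(q1 - strict) <= EPS and abs(hi - strict) <= EPS:
        return AseCategory.STRICTLY_MONOALLELIC
    if abs(lo) <= EPS and abs(q1) <= EPS and abs(hi) <= EPS:
        return AseCategory.STRICTLY_BIALLELIC
    if lo < strict - EPS and q1 >= thr - EPS and hi >= thr - EPS:
        return AseCategory.CONSISTENT_MONOALLELIC
    if lo < strict - EPS and q1 < thr - EPS and hi > EPS:
        return AseCategory.CONSISTENT_BIALLELIC
    return AseCategory.UNCLASSIFIED


_DIRECTION = {
    AseCategory.STRICTLY_MONOALLELIC: ExpressionProfile.MONOALLELIC,
    AseCategory.CONSISTENT_MONOALLELIC: ExpressionProfile.MONOALLELIC,
    AseCategory.STRICTLY_BIALLELIC: ExpressionProfile.BIALLELIC,
    AseCategory.CONSISTENT_BIALLELIC: ExpressionProfile.BIALLELIC,
}


def call_gene_tissue(
    site_categories: dict[str, AseCategory],
    site_depths: dict[str, int],
    gene: str,
    tissue: str,
    params: AseParams = AseParams(),
) -> GeneExpressionCall:
    """Call a gene×tissue expression profile from its SNP categories.

    SNPs with depth below ``gene_snp_min_depth`` or an unclassified
    category are dropped; strict/consistent pairs collapse to a
    direction; the profile is emitted only when at least ``min_snps``
    SNPs remain and all agree ("non-discordant"); otherwise the call is
    not_callable with the reason.
    """
    directions: dict[str, ExpressionProfile] = {}
    for snp, cat in site_categories.items():
        depth = site_depths.get(snp, 0)
        if depth < params.gene_snp_min_depth:
            continue
        direction = _DIRECTION.get(cat)
        if direction is None:
            continue
        directions[snp] = direction
    n = len(directions)
    if n < params.min_snps:
        return GeneExpressionCall(
            gene, tissue, ExpressionProfile.NOT_CALLABLE, n, "too_few_snps"
        )
    unique = set(directions.values())
    if len(unique) > 1:
        return GeneExpressionCall(
            gene, tissue, ExpressionProfile.NOT_CALLABLE, n, "discordant"
        )
    return GeneExpressionCall(gene, tissue, unique.pop(), n)


def maf_filter(
    observations: list[AseSiteObservation],
    params: AseParams = AseParams(),
) -> list[AseSiteObservation]:
    """Drop SNP observations with minor allele frequency below the floor.

    Observations with missing MAF are removed (cannot verify the
    population-frequency criterion).
    """
    return [
        o
        for o in observations
        if o.maf is not None and o.maf >= params.maf_min
    ]


def cis_window_genes(
    anchor_interval: GenomicInterval,
    gene_annotations: pd.DataFrame,
    params: AseParams = AseParams(),
) -> list[str]:
    """Genes whose TSS lies within ``window_bp`` of the anchor midpoint.

    ``gene_annotations`` needs columns gene, chrom, tss.  Bounds are
    inclusive, so the full scanned span is 2 × window_bp.
    """
    mid = anchor_interval.midpoint
    lo, hi = mid - params.window_bp, mid + params.window_bp
    mask = (
        (gene_annotations["chrom"] == anchor_interval.chrom)
        & (gene_annotations["tss"] >= lo)
        & (gene_annotations["tss"] <= hi)
    )
    return gene_annotations.loc[mask, "gene"].tolist()


def unicity_check(
    control_panel_observations: list[AseSiteObservation],
    experiment_id: str = "",
    params: AseParams = AseParams(),
) -> UnicityResult:
    """Sample-purity screen over a panel of imprinted control loci.

    Three inclusion criteria, all required:
      (i) every control locus shows median ASE >= unicity_threshold across
          its qualifying observations (consistent with monoallelic
          expression; the median is the aggregate the source ASE tables
          report);
      (ii) allele flip — every control locus shows, within at least one
          single tissue, both alleles as the monoallelically expressed one
          across that tissue's experiments (a flip across different
          tissues does not count);
      (iii) no control observation is strictly biallelic (ASE = 0).
    Observations below donor_min_depth do not qualify.
    """
    qualifying = [
        o for o in control_panel_observations if o.depth >= params.donor_min_depth
    ]
    if not qualifying:
        raise ValueError("unicity_check needs a non-empty control panel")

    per_locus: dict[tuple[str, str], list[float]] = defaultdict(list)
    for o in qualifying:
        per_locus[(o.snp_id, o.tissue)].append(
            ase_magnitude(o.ref_count, o.alt_count)
        )
    ase_pass = all(
        float(np.median(vals)) >= params.unicity_threshold - EPS
        for vals in per_locus.values()
    )
    no_strict_biallelic = all(
        ase_magnitude(o.ref_count, o.alt_count) > EPS for o in qualifying
    )
    # Allele flip: within single tissues, the dominant allele must take
    # both signs; a locus passes when any one tissue shows the flip.
    signs: dict[tuple[str, str], set[int]] = defaultdict(set)
    for o in qualifying:
        s = ase_signed(o.ref_count, o.alt_count)
        if abs(s) > EPS:
            signs[(o.snp_id, o.tissue)].add(1 if s > 0 else -1)
    flipped_loci = {snp for (snp, _), sg in signs.items() if len(sg) == 2}
    all_loci = {snp for (snp, _) in signs}
    flip_pass = bool(all_loci) and flipped_loci == all_loci

    return UnicityResult(
        experiment_id=experiment_id,
        criterion_ase_pass=ase_pass,
        criterion_flip_pass=flip_pass,
        criterion_no_strict_biallelic_pass=no_strict_biallelic,
    )
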