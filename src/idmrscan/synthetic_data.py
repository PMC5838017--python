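"""Synthetic genomes, methylomes, AMR call sets, ASE tables and trios with known truth.

The generator emulates the statistical structure of the pipeline's real
inputs: intermediate (≈0.5) methylation at imprinted CGIs in somatic
tissue, hyper/hypo asymmetry in gametes, AMR detection with imperfect
sensitivity and a small false-call rate, binomial allelic read counts
under biallelic or monoallelic expression, and Mendelian trios whose
methylated (digestion-resistant) alleles follow a configured parental
origin.  Every generator is deterministic under a fixed seed; each stage
draws from its own seed stream so stages can be rerun independently.

Site-level noise uses a Beta distribution reparameterized by mean and
standard deviation — methylation fractions are bounded, and Beta is the
natural bounded-noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ase_pipeline import AseSiteObservation
from .genome_data import (
    AmrRecord,
    CgiRecord,
    Compartment,
    CpGSiteCall,
    GenomicInterval,
    MethylomeTrack,
    write_bed,
    write_methylation_track,
)
from .trio_imprint import DigestResistantCall, TrioGenotype

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimBundle",
    "simulate_genome",
    "simulate_methylomes",
    "simulate_amr_calls",
    "simulate_ase",
    "simulate_trios",
    "simulate_all",
    "write_bundle",
    "IDMR_CLASSES",
    "AMR_DETECTABLE_CLASSES",
    "SCREEN_CLASS_OF",
    "TRIO_ORIGIN_OF",
]

# CGI truth classes
IDMR_CLASSES = ("gametic_maternal", "gametic_paternal", "secondary")
AMR_DETECTABLE_CLASSES = IDMR_CLASSES + ("random_hemimethylated",)
ALL_CLASSES = AMR_DETECTABLE_CLASSES + ("unmethylated", "hypermethylated")

# What the screen is expected to label each class, given only methylomes.
# A randomly hemimethylated domain with oocyte-derived gamete asymmetry is
# indistinguishable from a gametic maternal iDMR at the screen stage; only
# the trio stage separates them (biparental digestion resistance).
SCREEN_CLASS_OF = {
    "gametic_maternal": "gametic_maternal",
    "gametic_paternal": "gametic_paternal",
    "secondary": "secondary_candidate",
    "random_hemimethylated": "gametic_maternal",
}

# True parental origin of the methylated allele per class, for trios.
TRIO_ORIGIN_OF = {
    "gametic_maternal": "maternal",
    "gametic_paternal": "paternal",
    "secondary": "maternal",
    "random_hemimethylated": "biparental",
}

# Per-class mean methylation by compartment.
_CLASS_MEANS = {
    "gametic_maternal": {"somatic": 0.50, "oocyte": 0.95, "sperm": 0.05, "blastocyst": 0.50},
    "gametic_paternal": {"somatic": 0.50, "oocyte": 0.05, "sperm": 0.95, "blastocyst": 0.50},
    "secondary": {"somatic": 0.50, "oocyte": 0.05, "sperm": 0.05, "blastocyst": 0.05},
    "random_hemimethylated": {"somatic": 0.50, "oocyte": 0.95, "sperm": 0.05, "blastocyst": 0.50},
    "unmethylated": {"somatic": 0.05, "oocyte": 0.05, "sperm": 0.05, "blastocyst": 0.05},
    "hypermethylated": {"somatic": 0.95, "oocyte": 0.95, "sperm": 0.95, "blastocyst": 0.95},
}

_SOMATIC_TISSUES = (
    "esophagus", "blood", "brain", "liver", "lung", "spleen", "thymus",
    "kidney", "heart", "muscle", "skin", "pancreas", "colon",
)

_ASE_MODES = ("biallelic", "monoallelic_imprinted", "monoallelic_random")


def _default_class_proportions() -> dict[str, float]:
    return {
        "gametic_maternal": 0.10,
        "gametic_paternal": 0.06,
        "secondary": 0.30,
        "random_hemimethylated": 0.04,
        "unmethylated": 0.30,
        "hypermethylated": 0.20,
    }


def _default_ase_mode_proportions() -> dict[str, float]:
    return {
        "biallelic": 0.70,
        "monoallelic_imprinted": 0.15,
        "monoallelic_random": 0.15,
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study's default conditions."""

    seed: int = 0
    # genome
    n_cgis: int = 300
    n_chroms: int = 4
    chrom_length: int = 60_000_000
    cgi_length: int = 1_000
    sites_per_cgi: int = 10
    class_proportions: dict = field(default_factory=_default_class_proportions)
    # methylomes
    n_methylomes: int = 39
    site_noise_sd: float = 0.03
    methyl_depth_mean: float = 30.0
    min_depth: int = 10
    n_trisomy_placentas: int = 4
    n_cancer_tracks: int = 2
    # AMR calling
    amr_sensitivity: float = 0.7
    amr_false_rate: float = 0.02
    # ASE
    n_genes: int = 50
    n_tissues: int = 4
    snps_per_gene: int = 4
    n_donors: int = 10
    read_depth_mean: float = 30.0
    mono_expression_p: float = 0.98
    ase_mode_proportions: dict = field(default_factory=_default_ase_mode_proportions)
    # trios
    n_trios: int = 30
    allele_freq: float = 0.5
    genotyping_error: float = 0.0

    def __post_init__(self) -> None:
        for name, props in (
            ("class_proportions", self.class_proportions),
            ("ase_mode_proportions", self.ase_mode_proportions),
        ):
            total = sum(props.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {total})")
        for name in ("amr_sensitivity", "amr_false_rate", "mono_expression_p",
                     "allele_freq", "genotyping_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth the generators committed to, for scoring recovery."""

    cgi_classes: dict  # cgi_id -> true class
    screen_classes: dict  # cgi_id -> expected screen label (AMR classes only)
    gene_modes: dict  # gene -> expression mode
    trio_origins: dict  # locus (cgi_id) -> parental origin of methylation


@dataclass
class SimBundle:
    config: SimConfig
    cgis: list
    genes: pd.DataFrame
    truth: TruthTable
    tracks: dict
    amrs: list
    ase_observations: list
    trios: dict  # locus -> list of (TrioGenotype, DigestResistantCall)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _beta_noise(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Beta draws with the given mean and sd, clamped to valid shapes."""
    mean = np.clip(np.asarray(mean, dtype=float), 0.02, 0.98)
    if sd <= 0:
        return mean.copy()
    max_var = mean * (1.0 - mean)
    var = np.minimum(sd * sd, 0.9 * max_var)
    nu = max_var / var - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu)


# ---------------------------------------------------------------------------
# Genome

def simulate_genome(config: SimConfig):
    """Place non-overlapping CGIs and gene TSSs; draw truth classes and modes.

    Returns (cgis, gene annotation DataFrame, TruthTable).  Genes are
    placed both inside and beyond the ±2.3 Mb cis window of the first
    maternal-iDMR anchor so window scans have informative negatives.
    """
    rng = _rng(config, 0)
    per_chrom = math.ceil(config.n_cgis / config.n_chroms) if config.n_cgis else 0
    if per_chrom:
        spacing = config.chrom_length // (per_chrom + 1)
        if spacing <= config.cgi_length:
            raise ValueError(
                f"cannot place {config.n_cgis} non-overlapping CGIs of "
                f"{config.cgi_length} bp on {config.n_chroms} chromosomes of "
                f"{config.chrom_length} bp"
            )

    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    cgis: list[CgiRecord] = []
    cgi_classes: dict[str, str] = {}
    for i in range(config.n_cgis):
        chrom = f"chr{i % config.n_chroms + 1}"
        slot = i // config.n_chroms
        start = spacing * (slot + 1)
        cgi_id = f"cgi_{i:04d}"
        cgis.append(
            CgiRecord(cgi_id, GenomicInterval(chrom, start, start + config.cgi_length))
        )
        cgi_classes[cgi_id] = classes[rng.choice(len(classes), p=probs)]

    screen_classes = {
        cid: SCREEN_CLASS_OF[klass]
        for cid, klass in cgi_classes.items()
        if klass in AMR_DETECTABLE_CLASSES
    }

    # One trio locus per represented AMR-detectable class.
    trio_origins: dict[str, str] = {}
    for klass in AMR_DETECTABLE_CLASSES:
        for cgi in cgis:
            if cgi_classes[cgi.id] == klass:
                trio_origins[cgi.id] = TRIO_ORIGIN_OF[klass]
                break

    # Genes: even indices near the anchor (inside the cis window), odd far.
    modes = list(config.ase_mode_proportions)
    mode_probs = np.array([config.ase_mode_proportions[m] for m in modes])
    anchor = next(
        (c for c in cgis if cgi_classes[c.id] == "gametic_maternal"),
        cgis[0] if cgis else None,
    )
    window = 2_300_000
    gene_rows = []
    gene_modes: dict[str, str] = {}
    for g in range(config.n_genes):
        gene = f"gene_{g:03d}"
        if anchor is not None and g % 2 == 0:
            mid = anchor.interval.midpoint
            tss = int(
                np.clip(mid + rng.integers(-window, window + 1), 0, config.chrom_length - 1)
            )
            chrom = anchor.interval.chrom
        else:
            chrom = f"chr{rng.integers(config.n_chroms) + 1}"
            tss = int(rng.integers(config.chrom_length))
        gene_rows.append({"gene": gene, "chrom": chrom, "tss": tss})
        gene_modes[gene] = modes[rng.choice(len(modes), p=mode_probs)]

    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "tss"])
    truth = TruthTable(cgi_classes, screen_classes, gene_modes, trio_origins)
    return cgis, genes, truth


# ---------------------------------------------------------------------------
# Methylomes

def _site_positions(cgi: CgiRecord, n: int) -> np.ndarray:
    iv = cgi.interval
    step = max(1, len(iv) // n)
    return iv.start + np.arange(n) * step


def _make_track(
    rng: np.random.Generator,
    sample_id: str,
    tissue: str,
    compartment: Compartment,
    cgis: list,
    means_per_cgi: np.ndarray,
    config: SimConfig,
) -> MethylomeTrack:
    n_sites = config.sites_per_cgi
    sites: list[CpGSiteCall] = []
    site_means = np.repeat(means_per_cgi, n_sites)
    levels = _beta_noise(rng, site_means, config.site_noise_sd)
    extra = max(0.0, config.methyl_depth_mean - config.min_depth)
    depths = config.min_depth + rng.poisson(extra, size=levels.size)
    idx = 0
    for cgi in cgis:
        for pos in _site_positions(cgi, n_sites):
            sites.append(
                CpGSiteCall(cgi.interval.chrom, int(pos),
                            float(levels[idx]), int(depths[idx]))
            )
            idx += 1
    return MethylomeTrack(
        sample_id=sample_id,
        tissue=tissue,
        compartment=compartment,
        conversion_rate=1.0,
        sites=sites,
    )


def simulate_methylomes(truth: TruthTable, cgis: list, config: SimConfig) -> dict:
    """Somatic, gamete, blastocyst, trisomy-placenta and cancer tracks.

    Site levels are Beta-distributed around the class means; a noise sd
    of zero reproduces the means exactly.  Trisomy placentas follow the
    copy-number dosage model (1/3 or 2/3 at imprinted loci, by the
    supernumerary chromosome's parental origin).
    """
    rng = _rng(config, 1)
    klass = np.array([truth.cgi_classes[c.id] for c in cgis])

    def class_means(compartment: str) -> np.ndarray:
        return np.array([_CLASS_MEANS[k][compartment] for k in klass]) if len(klass) else np.array([])

    tracks: dict[str, MethylomeTrack] = {}
    for m in range(config.n_methylomes):
        tissue = _SOMATIC_TISSUES[m % len(_SOMATIC_TISSUES)]
        sample = f"somatic_{m + 1:02d}"
        tracks[sample] = _make_track(
            rng, sample, tissue, Compartment.SOMATIC, cgis,
            class_means("somatic"), config,
        )
    for sample, compartment in (
        ("oocyte", Compartment.OOCYTE),
        ("sperm", Compartment.SPERM),
        ("blastocyst", Compartment.BLASTOCYST),
    ):
        tracks[sample] = _make_track(
            rng, sample, sample, compartment, cgis,
            class_means(compartment.value), config,
        )

    # Trisomy placentas: dosage means depend on which parent's chromosome
    # is supernumerary and which parental allele the class methylates.
    def trisomy_mean(k: str, supernumerary: str) -> float:
        methylated_parent = TRIO_ORIGIN_OF.get(k)
        if methylated_parent == "maternal":
            return 1 / 3 if supernumerary == "paternal" else 2 / 3
        if methylated_parent == "paternal":
            return 2 / 3 if supernumerary == "paternal" else 1 / 3
        if methylated_parent == "biparental":
            return 0.5
        return _CLASS_MEANS[k]["somatic"]

    for t in range(config.n_trisomy_placentas):
        supernumerary = "paternal" if t % 2 == 0 else "maternal"
        sample = f"placenta_trisomy_{supernumerary}_{t + 1}"
        means = np.array([trisomy_mean(k, supernumerary) for k in klass])
        tracks[sample] = _make_track(
            rng, sample, "placenta", Compartment.PLACENTA, cgis, means, config,
        )

    # Cancer tracks: imprinted classes dysregulated to hypo or hyper.
    for c in range(config.n_cancer_tracks):
        sample = f"cancer_{c + 1}"
        perturbed = np.where(rng.random(len(klass)) < 0.5, 0.05, 0.95) if len(klass) else np.array([])
        means = np.where(
            np.isin(klass, AMR_DETECTABLE_CLASSES),
            perturbed,
            class_means("somatic"),
        ) if len(klass) else np.array([])
        tracks[sample] = _make_track(
            rng, sample, "hematopoietic", Compartment.CANCER, cgis, means, config,
        )
    return tracks


# ---------------------------------------------------------------------------
# AMR calls

def simulate_amr_calls(truth: TruthTable, cgis: list, config: SimConfig) -> list:
    """AMR records per methylome: detected at allelically methylated CGIs
    with probability ``amr_sensitivity`` (boundaries jittered within ±50%
    of the CGI length, preserving overlap), plus false records elsewhere
    at ``amr_false_rate`` per methylome.
    """
    rng = _rng(config, 2)
    records: list[AmrRecord] = []
    for m in range(config.n_methylomes):
        source = f"somatic_{m + 1:02d}"
        for cgi in cgis:
            k = truth.cgi_classes[cgi.id]
            p = config.amr_sensitivity if k in AMR_DETECTABLE_CLASSES else config.amr_false_rate
            if rng.random() >= p:
                continue
            iv = cgi.interval
            shift = int(rng.uniform(-0.5, 0.5) * len(iv))
            start = max(0, iv.start + shift)
            records.append(
                AmrRecord(GenomicInterval(iv.chrom, start, start + len(iv)), source)
            )
    return records


# ---------------------------------------------------------------------------
# ASE observations

def simulate_ase(truth: TruthTable, config: SimConfig) -> list:
    """Per donor/SNP allelic read counts under the gene's expression mode.

    Reference counts are Binomial(depth, p) with p = 0.5 (biallelic) or
    mono_expression_p / 1 − mono_expression_p (monoallelic; direction
    fixed per gene for imprinted loci, random per donor for random
    allelic expression — the source of allele flips).  Depth is a
    shifted Poisson with the configured mean.
    """
    rng = _rng(config, 3)
    observations: list[AseSiteObservation] = []
    tissues = [f"tissue_{t + 1}" for t in range(config.n_tissues)]
    for gene, mode in truth.gene_modes.items():
        imprint_on_ref = bool(rng.random() < 0.5)  # imprinted direction, per gene
        for s in range(config.snps_per_gene):
            snp_id = f"{gene}_snp{s + 1}"
            maf = round(float(rng.uniform(0.1, 0.5)), 3)
            for tissue in tissues:
                for d in range(config.n_donors):
                    depth = 1 + int(rng.poisson(max(0.0, config.read_depth_mean - 1)))
                    if mode == "biallelic":
                        p = 0.5
                    elif mode == "monoallelic_imprinted":
                        p = config.mono_expression_p if imprint_on_ref else 1 - config.mono_expression_p
                    else:  # monoallelic_random: direction drawn per donor
                        p = config.mono_expression_p if rng.random() < 0.5 else 1 - config.mono_expression_p
                    ref = int(rng.binomial(depth, p))
                    observations.append(
                        AseSiteObservation(
                            snp_id=snp_id, gene=gene, tissue=tissue,
                            donor=f"donor_{d + 1:02d}",
                            ref_count=ref, alt_count=depth - ref, maf=maf,
                        )
                    )
    return observations


# ---------------------------------------------------------------------------
# Trios

def simulate_trios(
    origin: str,
    config: SimConfig,
    locus: str = "locus",
    rng: np.random.Generator | None = None,
) -> list:
    """Mendelian trios with digestion-resistant alleles of known origin.

    Parental alleles are drawn at ``allele_freq``; the child inherits one
    allele from each parent; the resistant set follows the truth origin
    (maternal/paternal transmitted allele, both for biparental, none for
    unmethylated), with each allele's membership flipped independently at
    ``genotyping_error``.
    """
    if origin not in ("maternal", "paternal", "biparental", "unmethylated"):
        raise ValueError(f"unknown imprint origin {origin!r}")
    if rng is None:
        rng = _rng(config, 4)
    alleles = np.array(["A", "B"])
    q = config.allele_freq
    out = []
    for i in range(config.n_trios):
        mother = [str(alleles[rng.random() < q]) for _ in range(2)]
        father = [str(alleles[rng.random() < q]) for _ in range(2)]
        mat_t = mother[int(rng.integers(2))]
        pat_t = father[int(rng.integers(2))]
        child = frozenset({mat_t, pat_t})
        if origin == "maternal":
            resistant = {mat_t}
        elif origin == "paternal":
            resistant = {pat_t}
        elif origin == "biparental":
            resistant = {mat_t, pat_t}
        else:
            resistant = set()
        if config.genotyping_error > 0:
            for allele in sorted(child):
                if rng.random() < config.genotyping_error:
                    resistant ^= {allele}
        trio = TrioGenotype(
            snp_id=locus,
            mother=frozenset(mother),
            father=frozenset(father),
            child=child,
            family_id=f"{locus}_fam{i + 1:04d}",
        )
        out.append((trio, DigestResistantCall(locus, frozenset(resistant))))
    return out


# ---------------------------------------------------------------------------
# Bundle

def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator under one config; deterministic per seed."""
    cgis, genes, truth = simulate_genome(config)
    tracks = simulate_methylomes(truth, cgis, config)
    amrs = simulate_amr_calls(truth, cgis, config)
    ase_observations = simulate_ase(truth, config)
    trio_rng = _rng(config, 4)
    trios = {
        locus: simulate_trios(origin, config, locus=locus, rng=trio_rng)
        for locus, origin in sorted(truth.trio_origins.items())
    }
    return SimBundle(config, cgis, genes, truth, tracks, amrs, ase_observations, trios)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Emit the bundle as BED, track TSVs, ASE TSV, trios TSV and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed([(c.id, c.interval) for c in bundle.cgis], outdir / "cgis.bed")
    with (outdir / "amrs.bed").open("w") as fh:
        for rec in bundle.amrs:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.source_methylome}\n")
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for sample, track in bundle.tracks.items():
        write_methylation_track(track, tracks_dir / f"{sample}.tsv")
    bundle.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    ase_rows = pd.DataFrame(
        [
            {
                "snp_id": o.snp_id, "gene": o.gene, "tissue": o.tissue,
                "donor": o.donor, "ref_count": o.ref_count,
                "alt_count": o.alt_count, "maf": o.maf,
            }
            for o in bundle.ase_observations
        ]
    )
    ase_rows.to_csv(outdir / "ase_observations.tsv", sep="\t", index=False)
    with (outdir / "trios.tsv").open("w") as fh:
        fh.write("family_id\tsnp_id\tmother_gt\tfather_gt\tchild_gt\tresistant_alleles\n")
        for locus in sorted(bundle.trios):
            for trio, call in bundle.trios[locus]:
                fh.write(
                    "\t".join(
                        [
                            trio.family_id, trio.snp_id,
                            "/".join(sorted(trio.mother)),
                            "/".join(sorted(trio.father)),
                            "/".join(sorted(trio.child)),
                            ",".join(sorted(call.resistant_alleles)) or "-",
                        ]
                    )
                    + "\n"
                )
    with (outdir / "truth.tsv").open("w") as fh:
        fh.write("kind\tkey\tvalue\n")
        for cid in sorted(bundle.truth.cgi_classes):
            fh.write(f"cgi_class\t{cid}\t{bundle.truth.cgi_classes[cid]}\n")
        for cid in sorted(bundle.truth.screen_classes):
            fh.write(f"screen_class\t{cid}\t{bundle.truth.screen_classes[cid]}\n")
        for gene in sorted(bundle.truth.gene_modes):
            fh.write(f"gene_mode\t{gene}\t{bundle.truth.gene_modes[gene]}\n")
        for locus in sorted(bundle.truth.trio_origins):
            fh.write(f"trio_origin\t{locus}\t{bundle.truth.trio_origins[locus]}\n")
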