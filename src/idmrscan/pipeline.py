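"""End-to-end orchestration: simulate → screen → profiles → ASE → trios → report.

Runs the whole analysis on a synthetic study bundle and (optionally)
writes per-stage TSVs plus a JSON summary.  Outputs are deterministic for
a fixed config/seed: reruns produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import ase_pipeline as ase
from . import idmr_screen as screen
from . import methylation_profiles as profiles
from . import trio_imprint as trio
from .genome_data import Compartment, write_table
from .synthetic_data import SimBundle, SimConfig, simulate_all, write_bundle

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic_pipeline"]

REFERENCE_SAMPLE = "somatic_01"


@dataclass
class PipelineResult:
    candidates: list
    region_summaries: pd.DataFrame
    trisomy_calls: pd.DataFrame
    site_categories: pd.DataFrame
    gene_calls: list
    unicity: ase.UnicityResult | None
    trio_calls: pd.DataFrame
    trio_consensus: pd.DataFrame
    summary: dict


def _screen_stage(bundle: SimBundle, params: screen.ScreenParams) -> list:
    tracks = bundle.tracks
    return screen.run_screen(
        bundle.cgis,
        bundle.amrs,
        reference_track=tracks[params.reference_methylome or REFERENCE_SAMPLE],
        oocyte_track=tracks["oocyte"],
        sperm_track=tracks["sperm"],
        params=params,
    )


def _profile_stage(bundle: SimBundle, candidates: list):
    """Region summaries for every candidate across every track, plus
    trisomy parent-of-origin calls at maternally methylated candidates."""
    accepted = [
        c for c in candidates if c.klass is not screen.CandidateClass.REJECTED
    ]
    rows = []
    trisomy_rows = []
    for cand in accepted:
        iv = cand.interval
        for sample, track in bundle.tracks.items():
            s = profiles.region_mean(track, iv)
            rows.append(
                {
                    "cgi_id": cand.cgi_id,
                    "sample_id": sample,
                    "compartment": track.compartment.value,
                    "mean": s.mean,
                    "sd": s.sd,
                    "n_used": s.n_used,
                    "n_missing": s.n_missing,
                    "status": s.status.value,
                }
            )
            if (
                track.compartment is Compartment.PLACENTA
                and cand.klass is screen.CandidateClass.GAMETIC_MATERNAL
                and s.mean is not None
            ):
                trisomy_rows.append(
                    {
                        "cgi_id": cand.cgi_id,
                        "sample_id": sample,
                        "mean": s.mean,
                        "origin_call": profiles.call_trisomy_origin(s.mean).value,
                    }
                )
    cols = ["cgi_id", "sample_id", "compartment", "mean", "sd", "n_used", "n_missing", "status"]
    tcols = ["cgi_id", "sample_id", "mean", "origin_call"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(trisomy_rows, columns=tcols),
    )


def _ase_stage(bundle: SimBundle, params: ase.AseParams):
    observations = ase.maf_filter(bundle.ase_observations, params)
    groups: dict[tuple, list] = defaultdict(list)
    for o in observations:
        groups[(o.snp_id, o.gene, o.tissue)].append(o)

    cat_rows = []
    per_gene: dict[tuple, dict] = defaultdict(dict)
    per_gene_depth: dict[tuple, dict] = defaultdict(dict)
    for (snp_id, gene, tissue), obs in sorted(groups.items()):
        summary = ase.summarize_site(obs, params)
        if summary is None:
            continue
        category = ase.classify_site(summary, params)
        cat_rows.append(
            {
                "snp_id": snp_id, "gene": gene, "tissue": tissue,
                "n_donors": summary.n_donors, "min": summary.min,
                "q1": summary.q1, "median": summary.median,
                "q3": summary.q3, "max": summary.max,
                "min_depth": summary.min_depth_observed,
                "category": category.value,
            }
        )
        per_gene[(gene, tissue)][snp_id] = category
        per_gene_depth[(gene, tissue)][snp_id] = summary.min_depth_observed

    gene_calls = [
        ase.call_gene_tissue(per_gene[key], per_gene_depth[key], key[0], key[1], params)
        for key in sorted(per_gene)
    ]

    # Sample-purity (unicity) check over the imprinted control-gene panel.
    panel_genes = {
        g for g, mode in bundle.truth.gene_modes.items() if mode == "monoallelic_random"
    }
    panel_obs = [o for o in observations if o.gene in panel_genes]
    unicity = (
        ase.unicity_check(panel_obs, experiment_id="synthetic_atlas", params=params)
        if panel_obs
        else None
    )
    cols = ["snp_id", "gene", "tissue", "n_donors", "min", "q1", "median",
            "q3", "max", "min_depth", "category"]
    return pd.DataFrame(cat_rows, columns=cols), gene_calls, unicity


def _trio_stage(bundle: SimBundle):
    call_rows = []
    consensus_rows = []
    for locus in sorted(bundle.trios):
        calls = []
        for trio_gt, resistant in bundle.trios[locus]:
            transmission = trio.transmitted_alleles(trio_gt)
            call = trio.infer_imprint_origin(transmission, resistant)
            calls.append(call)
            call_rows.append(
                {
                    "locus": locus,
                    "family_id": trio_gt.family_id,
                    "informative": transmission is not None,
                    "call": call.value,
                }
            )
        informative = [c for c in calls if c is not trio.ImprintOriginCall.UNINFORMATIVE]
        if informative:
            result = trio.cohort_consensus(calls)
            consensus_rows.append(
                {
                    "locus": locus,
                    "consensus": result.consensus.value if result.consensus else "conflict",
                    "n_informative": result.n_informative,
                    "conflict": result.conflict,
                }
            )
        else:
            consensus_rows.append(
                {"locus": locus, "consensus": "no_informative_family",
                 "n_informative": 0, "conflict": False}
            )
    return (
        pd.DataFrame(call_rows, columns=["locus", "family_id", "informative", "call"]),
        pd.DataFrame(consensus_rows, columns=["locus", "consensus", "n_informative", "conflict"]),
    )


def run_pipeline(
    bundle: SimBundle,
    screen_params: screen.ScreenParams | None = None,
    ase_params: ase.AseParams | None = None,
) -> PipelineResult:
    """Execute screen → profiles → ASE → trios on a study bundle."""
    screen_params = screen_params or screen.ScreenParams(reference_methylome=REFERENCE_SAMPLE)
    ase_params = ase_params or ase.AseParams()

    candidates = _screen_stage(bundle, screen_params)
    region_summaries, trisomy_calls = _profile_stage(bundle, candidates)
    site_categories, gene_calls, unicity = _ase_stage(bundle, ase_params)
    trio_calls, trio_consensus = _trio_stage(bundle)

    class_counts: dict[str, int] = defaultdict(int)
    for c in candidates:
        class_counts[c.klass.value] += 1
    profile_counts: dict[str, int] = defaultdict(int)
    for g in gene_calls:
        profile_counts[g.profile.value] += 1

    summary = {
        "n_cgis": len(bundle.cgis),
        "n_amr_records": len(bundle.amrs),
        "candidate_class_counts": dict(sorted(class_counts.items())),
        "gene_profile_counts": dict(sorted(profile_counts.items())),
        "unicity_overall": unicity.overall if unicity else None,
        "trio_consensus": {
            row["locus"]: row["consensus"] for _, row in trio_consensus.iterrows()
        },
    }
    return PipelineResult(
        candidates, region_summaries, trisomy_calls, site_categories,
        gene_calls, unicity, trio_calls, trio_consensus, summary,
    )


def _config_hash(config: SimConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_synthetic_pipeline(
    config: SimConfig,
    outdir: str | Path | None = None,
    screen_params: screen.ScreenParams | None = None,
    ase_params: ase.AseParams | None = None,
) -> PipelineResult:
    """Simulate a study under ``config`` and run the full pipeline.

    When ``outdir`` is given, writes the simulated inputs, per-stage TSVs,
    a JSON summary, and a run manifest naming the config hash and seed.
    """
    bundle = simulate_all(config)
    result = run_pipeline(bundle, screen_params, ase_params)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bundle(bundle, outdir / "inputs")
        write_table(result.candidates, outdir / "candidates.tsv")
        result.region_summaries.to_csv(outdir / "region_summaries.tsv", sep="\t", index=False)
        result.trisomy_calls.to_csv(outdir / "trisomy_calls.tsv", sep="\t", index=False)
        result.site_categories.to_csv(outdir / "ase_site_categories.tsv", sep="\t", index=False)
        gene_rows = pd.DataFrame(
            [
                {
                    "gene": g.gene, "tissue": g.tissue, "profile": g.profile.value,
                    "n_informative_snps": g.n_informative_snps, "reason": g.reason,
                }
                for g in result.gene_calls
            ],
            columns=["gene", "tissue", "profile", "n_informative_snps", "reason"],
        )
        gene_rows.to_csv(outdir / "gene_calls.tsv", sep="\t", index=False)
        if result.unicity is not None:
            pd.DataFrame(
                [
                    {
                        "experiment_id": result.unicity.experiment_id,
                        "criterion_ase_pass": result.unicity.criterion_ase_pass,
                        "criterion_flip_pass": result.unicity.criterion_flip_pass,
                        "criterion_no_strict_biallelic_pass":
                            result.unicity.criterion_no_strict_biallelic_pass,
                        "overall": result.unicity.overall,
                    }
                ]
            ).to_csv(outdir / "unicity.tsv", sep="\t", index=False)
        result.trio_calls.to_csv(outdir / "trio_calls.tsv", sep="\t", index=False)
        result.trio_consensus.to_csv(outdir / "trio_consensus.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "manifest.json").write_text(
            json.dumps(
                {"config_hash": _config_hash(config), "seed": config.seed},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
    return result
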