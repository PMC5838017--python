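# idmrscan

Discovery and validation of **imprinted differentially methylated regions
(iDMRs)** — CpG islands (CGIs) whose two parental alleles carry asymmetric
5mCpG methylation — from interval-level methylome evidence, with downstream
validation by allele-specific expression (ASE), trisomy dosage modelling,
and trio-based parent-of-origin inference.

The package is aimed at epigenomics analysts who have interval calls of
allelically methylated regions (AMRs) from bisulfite-sequencing methylomes
and want a reproducible, testable pipeline from those calls to classified
candidate iDMRs and their validation read-outs. A synthetic-data module
generates complete studies with known ground truth, so every stage can be
exercised and calibrated without any external download.

## The method

**Screen.** For each CGI, count the AMR records (across methylome
repositories) whose interval shares ≥ 1 bp with it (0-based half-open
coordinates). Keep CGIs with at least 16 overlapping records, then require
every covered CpG site in a designated reference methylome to show an
intermediate (hemimethylated) level, 0.35 ≤ β ≤ 0.65 — the signature of one
methylated and one unmethylated allele. Survivors are classified from
gamete methylomes: oocyte hypermethylated (β > 0.65) with sperm
hypomethylated (β < 0.35) → *gametic maternal*; the mirror → *gametic
paternal*; no gametic asymmetry → *secondary candidate* (somatically
acquired imprint). Sex chromosomes are excluded by default.

**Trisomy dosage model.** At a maternally methylated iDMR the expected
region methylation is m/n for m methylated of n allele copies. In a
trisomic sample, a paternal supernumerary chromosome gives 1/3 (call
threshold ≤ 0.33) and a maternal one 2/3 (≥ 0.66), so the parental origin
of a nondisjunction is readable from the methylation level alone.

**ASE.** At a heterozygous SNP, ASE = |0.5 − ref/(ref + alt)| ∈ [0, 0.5].
Per-donor magnitudes (depth ≥ 8 per donor) are aggregated into min/Q1/
median/Q3/max and sorted into four mutually exclusive categories
(strictly/consistent-with monoallelic or biallelic). A gene × tissue
profile is called only from ≥ 3 non-discordant informative SNPs with
depth ≥ 12. Cis windows of ± 2.3 Mb around an iDMR anchor select the genes
to scan, and a unicity (sample-purity) check on an imprinted control-gene
panel requires high ASE, within-tissue allele flips, and no strictly
biallelic pattern.

**Trios.** After methylation-sensitive restriction digestion only
methylated (resistant) alleles amplify. For a heterozygous child with an
unambiguous Mendelian assignment of each allele to a parent, the resistant
allele set yields maternal / paternal / biparental / unmethylated calls,
combined across families by unanimity consensus.

## Worked example

Simulate a default study (300 CGIs, 39 somatic methylomes, AMR sensitivity
0.7, site noise sd 0.03) and run every stage:

```sh
idmrscan run-all --seed 1 --out demo/
```

prints the run summary

```json
{
  "candidate_class_counts": {
    "gametic_maternal": 39,
    "gametic_paternal": 21,
    "rejected": 147,
    "secondary_candidate": 93
  },
  "gene_profile_counts": { "biallelic": 148, "monoallelic": 52 },
  "n_amr_records": 4312,
  "n_cgis": 300,
  "trio_consensus": {
    "cgi_0002": "paternal",
    "cgi_0004": "maternal",
    "cgi_0009": "maternal",
    "cgi_0022": "biparental_methylation"
  },
  "unicity_overall": true
}
```

Of 300 simulated CGIs, 153 pass the record-count and intermediate filters
and are classified (39 gametic maternal, 21 gametic paternal, 93 secondary);
the rest are rejected with their reason recorded in `demo/candidates.tsv`.
The 200 gene × tissue ASE profiles split into 148 biallelic and 52
monoallelic calls, and the trio stage recovers the configured imprint
origin at each of the four probed loci — note `cgi_0022`, a randomly
hemimethylated (non-imprinted) domain that the screen necessarily labels
gametic-maternal but the trios expose as biparentally methylated.
Per-stage tables (candidates, region summaries, trisomy calls, ASE
categories, gene calls, unicity report, trio calls) land in `demo/`, along
with the simulated inputs and a manifest naming the config hash and seed;
reruns with the same seed are byte-identical.

Individual stages are available as `idmrscan simulate | screen | profile |
ase | trio`, and everything is importable from the library
(`idmrscan.run_screen`, `idmrscan.classify_site`, ...).

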