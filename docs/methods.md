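# Methods

## Screening model

A CpG island (CGI) is a candidate iDMR when interval-level evidence of
allele-specific methylation recurs across methylomes and the island is
hemimethylated in a reference somatic methylome.

The screen runs in a fixed order: (1) count AMR records overlapping each
CGI; (2) keep CGIs with `min_records ≥ 16` overlapping records; (3) keep
CGIs whose *every* covered CpG site in the reference methylome lies in the
intermediate band `[0.35, 0.65]`, bounds inclusive — the per-site
"consistently intermediate" reading rather than a mean-based one, so a
single clearly hyper- or hypomethylated site disqualifies the island;
(4) classify survivors from oocyte and sperm region means via the status
scale hypo < 0.35 ≤ intermediate ≤ 0.65 < hyper; (5) annotate against a
known-iDMR list (id match, optionally interval overlap). Overlap is
0-based half-open throughout: `[a, b)` does not overlap `[b, c)`.

Assumptions and choices:

- **Records, not methylomes.** The record-count filter counts AMR
  *records*; the same source methylome may contribute several. The
  distinct-methylome count is computed alongside and can be made the
  filter criterion (`count_distinct_methylomes`).
- **Gamete status from region means.** Per-site gamete coverage is sparse
  in practice, so gametic asymmetry is judged on the CGI's mean in each
  gamete, not site-by-site.
- **Unevaluable gametes default to secondary.** Secondary iDMRs are
  defined by the *absence* of gametic asymmetry, so a CGI that passes both
  somatic filters but cannot be evaluated in a gamete is reported as a
  secondary candidate with an `unevaluable gamete` annotation instead of
  being dropped.
- **Autosomes only** by default (`include_sex_chroms` overrides).
- An optional `require_reference_amr` flag additionally demands an AMR
  record from the reference methylome itself; it is off by default.

## Methylation profiles and the trisomy dosage model

Region summaries average the non-missing site levels inside an interval;
sites with no data are excluded and counted. The sd uses the n−1
denominator and is absent for a single usable site. A site is "missing"
when its read depth falls below the track's minimum (default 10 reads);
tracks also carry a bisulfite conversion rate and are rejected below 0.95
unless overridden.

The dosage model is allele-copy counting: expected methylation =
methylated copies / total copies. For a maternal iDMR in a trisomic
sample, a paternal supernumerary chromosome gives 1/3 and a maternal one
2/3. The origin call compares the observed region mean, **rounded to two
decimals**, against ≤ 0.33 / ≥ 0.66, so the theoretical 1/3 lands exactly
on the paternal bound. Between the bounds the call is indeterminate. The
call is only meaningful at maternally methylated iDMRs in trisomic
samples; the caller is responsible for that restriction, and the pipeline
applies it only to gametic-maternal candidates in placenta tracks.

The MSRE-PCR proportion of digestion-resistant (methylated) alleles is
the reference-normalized ratio of ratios
`(target_dig / ref_dig) / (target_undig / ref_undig)`, clamped to [0, 1].
The reference amplimer carries no enzyme sites and cancels lane-to-lane
template amounts, making the statistic scale-invariant per lane. The
formula is isolated in one function so an alternative can be swapped in.
A digestion-control amplimer (an unmethylated locus) must show a
near-zero post-digestion signal — above 5% of the lane reference the
measurement is rejected as an incomplete digest.

Cohort profiling labels each sample's status and flags departures from
the intermediate band as dysregulation (hypo or hyper); the fraction of
intermediate samples summarizes epipolymorphism (1.0 = none).
Dysregulation is judged against the fixed band, not against matched
normals.

## ASE classification

ASE = |0.5 − ref/(ref + alt)|, computed from the minor-allele fraction so
the ref↔alt symmetry is exact in floating point. The signed value is kept
internally for allele-flip detection. Donors need depth ≥ 8 at the site;
quantiles over per-donor magnitudes use linear interpolation (configurable).
The four categories are applied as written, with tolerance ε = 1e−9 for
the equality ("strictly") cases — ASE values are exact rationals of small
integers, so this is safe:

| category | min | Q1 | max |
|---|---|---|---|
| strictly monoallelic | = 0.5 | = 0.5 | = 0.5 |
| consistent w/ monoallelic | < 0.5 | ≥ 0.33 | ≥ 0.33 |
| strictly biallelic | = 0 | = 0 | = 0 |
| consistent w/ biallelic | < 0.5 | < 0.33 | > 0 |

The four rules are pairwise disjoint (verified constructively over an
exhaustive value grid in the tests); summaries matching none are
`unclassified` and never contribute to gene calls.

Gene × tissue calls need ≥ 3 informative SNPs (depth ≥ 12, judged on the
SNP's minimum qualifying per-donor depth — the conservative reading) that
all share one direction after collapsing strict/consistent pairs; a single
opposing SNP voids the call (`discordant`). Cis windows are anchored at
the iDMR interval midpoint and select genes by TSS within ± 2.3 Mb,
bounds inclusive (4.6 Mb total span) — anchor and gene reference points
are a declared choice, since only the distance is specified by the
screen's design.

The unicity (sample-purity) check evaluates an imprinted control-gene
panel: (i) per control locus, the median ASE across qualifying
observations must reach 0.42 (the median is the aggregate the source ASE
tables report, and a per-observation reading would fail pure samples on
sampling noise alone); (ii) every control locus must show both alleles as
the dominant one *within at least one single tissue* — a flip across
different tissues does not count; (iii) no observation may be exactly
balanced (strictly biallelic pattern).

## Trio inference

A trio is informative when the child is heterozygous and exactly one
assignment of its alleles to the parents is Mendelian-consistent; a
homozygous child is uninformative even if resistant, because the parental
alleles cannot be separated. Inconsistent trios raise an error naming the
family. Digestion-resistant calls are presence/absence sets over the
child's alleles: {maternal} → maternal, {paternal} → paternal, both →
biparental methylation, none → unmethylated. Cross-family consensus
requires unanimity among informative calls; disagreement yields a
conflict report and no consensus (majority voting is deliberately not the
default).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* of the real inputs:

- **Methylomes.** Site levels are Beta-distributed around per-class,
  per-compartment means (somatic 0.5 at iDMRs; oocyte/sperm 0.95/0.05
  for maternal classes, mirrored for paternal; secondary hypomethylated
  in both gametes and blastocyst; background classes at 0.05/0.95). The
  Beta is reparameterized by mean and sd (default sd 0.03) and degrades
  gracefully: sd = 0 reproduces the means exactly. The somatic iDMR mean
  is the idealized 0.5 rather than any particular tissue's observed
  value, so class separation is controlled by configuration. Depth is
  `min_depth + Poisson(mean − min_depth)` (mean 30), so no site falls
  below the coverage floor; missingness handling is exercised by
  dedicated unit fixtures rather than the generator.
- **AMR calls.** Each allelically methylated CGI (the three iDMR classes
  plus the random-hemimethylated class) is detected per methylome with
  probability `amr_sensitivity` (default 0.7), with record boundaries
  jittered by up to ±50% of the CGI length (overlap is preserved by
  construction); other CGIs acquire false records at `amr_false_rate`
  (default 0.02) per methylome. Counts are therefore Binomial(39, ·) per
  CGI.
- **ASE.** Reference counts are Binomial(depth, p) with p = 0.5
  (biallelic) or 0.98/0.02 (monoallelic); imprinted genes fix the
  direction per gene, random-allelic genes redraw it per donor, which is
  what produces allele flips. Depth is a shifted Poisson (mean 30).
- **Trios.** Parental alleles are drawn at frequency 0.5; the child
  inherits one allele from each parent; the resistant set follows the
  configured truth origin with an optional per-allele flip error.

Default class proportions (10% gametic maternal, 6% gametic paternal,
30% secondary, 4% random-hemimethylated, 30% unmethylated, 20%
hypermethylated over 300 CGIs) keep all screen outcomes populated while
leaving a majority of non-iDMR background.

The generator does **not** simulate read-level bisulfite data, mapping
bias, probe chemistry, linkage between neighbouring sites, inter-tissue
correlation, or genotype imputation error. Passing recovery tests
therefore demonstrates that the *decision logic* is correct under the
declared noise model — not that the thresholds are robust to artefacts
those processes introduce in real data.

A deliberate adversarial feature: the random-hemimethylated class carries
oocyte-derived gamete asymmetry, so the screen *must* misclassify it as
gametic-maternal; its ground truth is recorded separately
(`screen_classes` vs `cgi_classes`), and only the trio stage, seeing
biparental digestion resistance, distinguishes it. Recovery of the screen
is scored against the expected screen label.

## Numerical and reproducibility choices

- Intermediate band inclusive at both ends; hyper/hypo strict.
- Trisomy comparison after two-decimal rounding (see above).
- ASE "strictly" equalities at ε = 1e−9; quantiles linear-interpolated.
- Every generator stage draws from `default_rng([seed, stage_index])`, so
  stages are independently reproducible and a single integer seed fixes
  the whole study. Rerunning `run-all` with one seed produces
  byte-identical output files; the run manifest records the config hash
  and seed.
- Table round-trips preserve float values exactly (`repr` formatting) and
  missingness (`NA`).

## Problem sizes

The shipped defaults — 300 CGIs × 39 methylomes for the screen, 50 genes
× 4 tissues × 10 donors for ASE, and up to 1,000 trios for origin
inference — were chosen so a full study simulates and analyses in a few
seconds while keeping every binomial calibration check well-powered
(3-standard-error bands on Binomial(39, 0.7) record counts and on the
trio informative fraction).

## Known limitations

- AMR detection itself is upstream: the screen consumes interval calls,
  it does not call AMRs from reads.
- The exact published MSRE-PCR equation is not reproduced here; the
  reference-normalized ratio-of-ratios is a declared stand-in behind a
  single function boundary.
- Gene calls use categorical rules, not statistical tests of imbalance;
  no multiple-testing machinery applies.
- Consensus is single-SNP trio deduction; no haplotype phasing.
- The cohort dysregulation call has no matched-normal mode.
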