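# chipcall

Clonal hematopoiesis of indeterminate potential (CHIP) — somatic blood
clones at variant allele frequency (VAF) ≥ 2% in people without
hematologic disease — is a common finding in deep blood sequencing of
older adults, and its burden interacts with cancer therapy outcomes.
`chipcall` is a tested, reusable implementation of a CHIP analysis
pipeline for cohort studies (e.g. lung-cancer patients on immune
checkpoint inhibitors): it calls CHIP from annotated somatic variant
evidence, stratifies samples by clone burden, quantifies cohort
prevalence, answers design questions with an exact detection-power model,
and tests single-cell expression signatures against CHIP burden with
preranked GSEA. A synthetic-data generator with ground truth makes every
stage testable without access to patient data.

## What it computes

**Filter cascade** (`chipcall.chip_filter`). A candidate variant passes as
CHIP iff, jointly: VAF ∈ [2%, 35%]; total site depth > 500× (targeted
panel) or > 40× (WES); ≥ 4 (panel) / ≥ 2 (WES) alt-supporting read pairs
on *each* strand; gnomAD frequency < 10⁻⁵ (< 10⁻³ if in COSMIC); the
identical variant in < 5% of all processed samples; no homopolymer run of
≥ 4 bases within ±6 bp; and a protein-altering consequence. Every
criterion is evaluated on every record, so each call carries a full audit
of flags. Passing calls are classified **CHIP-PD** (putative driver) when
the driver catalog reports the variant more than 10 times or lists it
explicitly (e.g. *DNMT3A* p.Arg882), otherwise plain CHIP.

**Burden and prevalence** (`chipcall.burden_stats`). Samples are
`negative` / `chip` / `high_burden` (largest clone VAF > 10%); prevalence
is compared between strata by the conditional exact 2×2 test and
age-adjusted logistic regression, with Benjamini–Hochberg correction
across comparisons, plus paired pre/post-treatment VAF concordance.

**Detection power** (`chipcall.power`). For a variant making up a
fraction *p* of gene-level CHIP carriers, the probability of observing it
among *n* carriers when it is absent from the comparison group is
1 − (1 − *p*)ⁿ. The module solves for the minimal carrier count at a
target power and the implied cohort size given gene-level prevalence, and
provides an exact Poisson-binomial engine for heterogeneous per-sample
carriage probabilities.

**Single-cell enrichment** (`chipcall.sc_enrichment`). Per cell cluster,
genes are ranked by Wilcoxon rank-sum AUC (= U/(n₁n₂)) between cell
groups; centered AUC is the preranked metric for a weighted
Kolmogorov–Smirnov enrichment score with a gene-label permutation null,
NES, and BH-adjusted p-values.

## Worked example

Minimum sample size for detecting a hotspot exclusively in one group —
*DNMT3A* p.Arg882 is ~10% of *DNMT3A* CHIP, observed gene-level
prevalence 8/50:

```sh
$ chip power --p-variant 0.1 --target 0.8 --gene-prevalence 8/50
min_carriers	16
achieved_power	0.8147
required_chip_samples	100
```

With 15 carriers the detection probability is 1 − 0.9¹⁵ ≈ 0.794 < 0.8;
16 carriers reach 0.815, and at 8/50 gene prevalence that requires
⌈16 · 50/8⌉ = 100 CHIP-positive samples per group.

End-to-end on synthetic data:

```sh
$ chip simulate cohort --n-samples 50 --seed 3 --out sim/
simulated 50 samples (135 records) in sim/
$ chip call --mode panel --cohort-size 50 --out calls/ $(ls sim/S*.vcf | sed 's/^/--vcf /')
53/135 records pass; VCFs in calls
$ chip stats --calls calls/ --cohort sim/cohort.tsv --stratify pathology --out stats/
burden and prevalence tables in stats
```

`stats/burden.tsv` holds per-sample counts, maximal VAF and burden
category; `stats/prevalence_pathology.tsv` the carriers/total per
pathology. The same library calls are available in Python
(`simulate_cohort`, `call_chip`, `classify_burden`, …).

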