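"""Simulators for every input the pipeline reads, with ground truth.

The cohort generator emulates the statistical structure the CHIP analysis
assumes: an aging cohort (age ~ Normal(64, 8), echoing a lung-cancer ICI
cohort), age-dependent CHIP incidence (logistic in age), clone gene
assignment from a frequency table dominated by DNMT3A / PPM1D / TET2,
log-normal clone VAFs truncated to the detectable somatic range, and
binomial read sampling at negative-binomial site depths around the panel
(~600x) or WES (~80x) median. Artifact classes are planted with signatures
constructed to trip exactly one filter criterion each:

- ``homopolymer``    — adjacent reference context carries a >= 5-base run;
- ``high_gnomad``    — gnomAD frequency 1e-4 (10x the somatic threshold),
                       no COSMIC membership;
- ``recurrent``      — the identical variant planted in ~8% of samples;
- ``germline_leak``  — true allele fraction 0.5 (caught by the 35% VAF cap);
- ``strand_bias``    — alt reads split 98:2 across strands at low VAF
                       (caught by the per-strand pair minimum).

The expression generator produces negative-binomial counts over a gene
universe with a planted pathway effect: in a designated myeloid-like
cluster, cells from high-burden samples have the planted set's means
multiplied by an effect factor; other clusters are untouched.

Everything is a pure function of (config, seed): fixed seed, identical
output, byte-for-byte when written to disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CohortSample, VariantRecordRaw, write_cohort_table, write_variant_vcf

logger = logging.getLogger(__name__)

#: Relative clone frequencies by gene, most-frequent CHIP drivers dominant.
DEFAULT_GENE_FREQ: Mapping[str, float] = {
    "DNMT3A": 0.30,
    "PPM1D": 0.16,
    "TET2": 0.13,
    "ASXL1": 0.09,
    "TP53": 0.08,
    "SF3B1": 0.06,
    "SRSF2": 0.05,
    "JAK2": 0.04,
    "GNB1": 0.03,
    "IDH2": 0.03,
    "CBL": 0.03,
}

#: Share of DNMT3A clones at the p.Arg882 hotspot (the most prevalent CHIP
#: variant, ~10% of DNMT3A CHIP cases).
DNMT3A_R882_SHARE = 0.10

DEFAULT_ARTIFACT_RATES: Mapping[str, float] = {
    "homopolymer": 0.5,
    "high_gnomad": 0.5,
    "recurrent": 0.08,  # fraction of samples carrying the recurrent artifact
    "germline_leak": 0.3,
    "strand_bias": 0.3,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the synthetic cohort.

    ``chip_intercept``/``chip_slope`` parametrize logit P(CHIP | age) =
    intercept + slope * age; defaults give ~45% prevalence at the cohort
    mean age of 64 with a plausible age gradient. Per-class artifact rates
    are expected counts per sample, except ``recurrent`` which is the
    fraction of samples sharing the planted recurrent variant.
    """

    n_samples: int = 100
    age_mean: float = 64.0
    age_sd: float = 8.0
    chip_intercept: float = -5.32
    chip_slope: float = 0.08
    gene_freq: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQ)
    )
    vaf_log_mean: float = float(np.log(0.08))
    vaf_log_sd: float = 0.7
    vaf_min: float = 0.03
    vaf_max: float = 0.30
    depth_mode: str = "panel"  # panel ~600x, wes ~80x
    depth_mean: float | None = None
    depth_dispersion: float = 500.0
    clone_rate_base: float = 0.9  # Poisson mean of extra clones at mean age
    clone_max: int = 4
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.gene_freq.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"gene_freq must sum to 1, got {total:.4f}")
        for name, rate in self.artifact_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"artifact_rates[{name!r}] outside [0,1]: {rate}")
        if self.depth_mode not in ("panel", "wes"):
            raise ValueError(f"depth_mode must be panel or wes, got {self.depth_mode!r}")

    @property
    def site_depth_mean(self) -> float:
        if self.depth_mean is not None:
            return self.depth_mean
        return 600.0 if self.depth_mode == "panel" else 80.0


@dataclass
class SimulatedCohort:
    records: list[VariantRecordRaw]
    samples: list[CohortSample]
    truth: pd.DataFrame  # sample_id, chrom, pos, ref, alt, true_class, true_vaf


def simulate_reads(
    true_vaf: float, depth: int, seed: int | np.random.Generator
) -> tuple[int, int, int]:
    """Binomial read sampling: (alt_depth, alt_fwd, alt_rev) at a site."""
    if not 0 <= true_vaf <= 1:
        raise ValueError("true_vaf must be in [0,1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alt = int(rng.binomial(depth, true_vaf))
    fwd = int(rng.binomial(alt, 0.5))
    return alt, fwd, alt - fwd


_BASES = "ACGT"


def _random_context(rng: np.random.Generator, length: int = 6, max_run: int = 3) -> str:
    """Reference context free of homopolymer runs longer than ``max_run``."""
    out: list[str] = []
    while len(out) < length:
        b = _BASES[rng.integers(4)]
        run = 0
        for prev in reversed(out):
            if prev != b:
                break
            run += 1
        if run < max_run:
            out.append(b)
    return "".join(out)


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB as gamma-Poisson; dispersion is the gamma shape (larger = tighter)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return max(1, int(rng.poisson(lam)))


_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()


def _random_hgvs_p(rng: np.random.Generator) -> str:
    a, b = rng.choice(len(_AA3), size=2)
    return f"p.{_AA3[a]}{int(rng.integers(20, 900))}{_AA3[b]}"


def _draw_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _truncated_lognormal(
    rng: np.random.Generator, log_mean: float, log_sd: float, lo: float, hi: float
) -> float:
    while True:
        v = float(rng.lognormal(log_mean, log_sd))
        if lo <= v <= hi:
            return v


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Generate a cohort of annotated variant records with ground truth.

    Each sample gets clinical covariates, CHIP clones by the age-dependent
    incidence curve, and planted artifacts per class. Reproducible per
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples: list[CohortSample] = []
    records: list[VariantRecordRaw] = []
    truth_rows: list[dict] = []
    genes = list(cfg.gene_freq)
    gene_probs = np.array([cfg.gene_freq[g] for g in genes])
    gene_chrom = {g: f"chr{1 + i % 22}" for i, g in enumerate(genes)}
    # fixed hotspot locus so recurrent true carriers share the variant key
    r882 = ("chr1", 25_234_373, "C", "T")

    n_recurrent = int(np.ceil(cfg.artifact_rates.get("recurrent", 0.0) * cfg.n_samples))
    recurrent_carriers = set(
        rng.choice(cfg.n_samples, size=n_recurrent, replace=False).tolist()
    )
    recurrent_key = ("chr20", 31_022_441, "G", "A")

    pathologies = ["LUAD", "LUSC", "other"]
    path_probs = [0.50, 0.43, 0.07]

    def emit(sample_id, chrom, pos, ref, alt, true_vaf, true_class, **kw):
        depth = _nb_depth(rng, cfg.site_depth_mean, cfg.depth_dispersion)
        strand_p = kw.pop("strand_split", 0.5)
        alt_depth = int(rng.binomial(depth, true_vaf))
        if alt_depth == 0:
            alt_depth = 1  # a caller only emits sites with alt support
        fwd = int(rng.binomial(alt_depth, strand_p))
        rec = VariantRecordRaw(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            sample_id=sample_id,
            total_depth=depth,
            alt_depth=min(alt_depth, depth),
            alt_fwd=fwd,
            alt_rev=alt_depth - fwd,
            gene=kw.pop("gene", None),
            consequence=kw.pop("consequence", "missense"),
            hgvs_p=kw.pop("hgvs_p", None),
            gnomad_af=kw.pop("gnomad_af", 0.0),
            cosmic_count=kw.pop("cosmic_count", 0),
            context_up=kw.pop("context_up", _random_context(rng)),
            context_down=kw.pop("context_down", _random_context(rng)),
        )
        records.append(rec)
        truth_rows.append(
            dict(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                true_class=true_class,
                true_vaf=true_vaf,
            )
        )

    for i in range(cfg.n_samples):
        sid = f"S{i:04d}"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 35, 95))
        samples.append(
            CohortSample(
                sample_id=sid,
                age=round(age, 1),
                sex="F" if rng.random() < 0.35 else "M",
                pathology=pathologies[rng.choice(3, p=path_probs)],
                smoking="ever/current" if rng.random() < 0.8 else "never",
                timepoint="pre",
                response=["responder", "non-responder", "unknown"][rng.choice(3, p=[0.3, 0.5, 0.2])],
            )
        )
        # --- true CHIP clones -------------------------------------------
        p_chip = 1.0 / (1.0 + np.exp(-(cfg.chip_intercept + cfg.chip_slope * age)))
        if rng.random() < p_chip:
            extra_rate = cfg.clone_rate_base * np.exp(
                0.03 * (age - cfg.age_mean)
            )
            n_clones = 1 + min(int(rng.poisson(extra_rate)), cfg.clone_max - 1)
            for _ in range(n_clones):
                gene = genes[rng.choice(len(genes), p=gene_probs)]
                vaf = _truncated_lognormal(
                    rng, cfg.vaf_log_mean, cfg.vaf_log_sd, cfg.vaf_min, cfg.vaf_max
                )
                if gene == "DNMT3A" and rng.random() < DNMT3A_R882_SHARE:
                    emit(
                        sid, *r882, vaf, "true_chip_pd",
                        gene=gene, hgvs_p="p.Arg882His", cosmic_count=800,
                    )
                else:
                    chrom = gene_chrom[gene]
                    pos = int(rng.integers(1_000_000, 50_000_000))
                    ref, alt = _draw_snv(rng)
                    emit(
                        sid, chrom, pos, ref, alt, vaf, "true_chip",
                        gene=gene, hgvs_p=_random_hgvs_p(rng),
                    )
        # --- planted artifacts ------------------------------------------
        rates = cfg.artifact_rates
        low_vaf = lambda: _truncated_lognormal(rng, np.log(0.05), 0.4, 0.03, 0.20)
        if rng.random() < rates.get("homopolymer", 0.0):
            ref, alt = _draw_snv(rng)
            run_base = _BASES[rng.integers(4)]
            up = _random_context(rng, 6)[: 6 - 5] + run_base * 5
            emit(
                sid, "chr2", int(rng.integers(1_000_000, 50_000_000)), ref, alt,
                low_vaf(), "artifact:homopolymer",
                gene="FAKE1", hgvs_p=_random_hgvs_p(rng), context_up=up,
            )
        if rng.random() < rates.get("high_gnomad", 0.0):
            ref, alt = _draw_snv(rng)
            emit(
                sid, "chr3", int(rng.integers(1_000_000, 50_000_000)), ref, alt,
                low_vaf(), "artifact:high_gnomad",
                gene="FAKE2", hgvs_p=_random_hgvs_p(rng), gnomad_af=1e-4,
            )
        if i in recurrent_carriers:
            emit(
                sid, *recurrent_key, low_vaf(), "artifact:recurrent",
                gene="FAKE3", hgvs_p="p.Ala100Val",
            )
        if rng.random() < rates.get("germline_leak", 0.0):
            ref, alt = _draw_snv(rng)
            emit(
                sid, "chr4", int(rng.integers(1_000_000, 50_000_000)), ref, alt,
                0.5, "germline",
                gene="FAKE4", hgvs_p=_random_hgvs_p(rng),
            )
        if rng.random() < rates.get("strand_bias", 0.0):
            ref, alt = _draw_snv(rng)
            emit(
                sid, "chr5", int(rng.integers(1_000_000, 50_000_000)), ref, alt,
                low_vaf(), "artifact:strand_bias",
                gene="FAKE5", hgvs_p=_random_hgvs_p(rng), strand_split=0.98,
            )
    truth = pd.DataFrame(truth_rows)
    logger.info(
        "simulated cohort: %d samples, %d records (%d true clones)",
        cfg.n_samples,
        len(records),
        int((truth["true_class"].str.startswith("true")).sum()) if len(truth) else 0,
    )
    return SimulatedCohort(records=records, samples=samples, truth=truth)


def write_cohort(sim: SimulatedCohort, out_dir: str | Path) -> None:
    """Write per-sample VCFs, the cohort TSV and the truth table under a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[VariantRecordRaw]] = {s.sample_id: [] for s in sim.samples}
    for r in sim.records:
        by_sample[r.sample_id].append(r)
    for sid, recs in by_sample.items():
        write_variant_vcf(recs, out / f"{sid}.vcf", sample_id=sid)
    write_cohort_table(sim.samples, out / "cohort.tsv")
    sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# --- expression simulator ----------------------------------------------------


def simulate_expression(
    n_cells_per_cluster: int = 500,
    clusters: Sequence[str] = ("myeloid", "lymphoid"),
    n_genes: int = 300,
    planted_set_size: int = 30,
    effect_multiplier: float = 3.0,
    target_cluster: str = "myeloid",
    groups: Sequence[str] = ("high_burden", "negative"),
    n_samples_per_group: int = 5,
    dispersion: float = 2.0,
    seed: int = 0,
):
    """Negative-binomial counts with a planted pathway effect.

    In ``target_cluster``, cells of the first group have the planted genes'
    means multiplied by ``effect_multiplier``; all other cluster/group
    combinations draw from the baseline means. Returns
    (ExpressionMatrix, planted GeneSet).
    """
    from .io import GeneSet
    from .sc_enrichment import ExpressionMatrix

    if effect_multiplier < 1:
        raise ValueError("effect_multiplier must be >= 1")
    if planted_set_size > n_genes:
        raise ValueError("planted set exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    planted = genes[:planted_set_size]
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    rows, cluster_lab, sample_lab, group_lab = [], [], [], []
    for cluster in clusters:
        for g_idx, group in enumerate(groups):
            n_cells = n_cells_per_cluster // len(groups)
            mean = base_mean.copy()
            if cluster == target_cluster and g_idx == 0:
                mean[:planted_set_size] *= effect_multiplier
            lam = rng.gamma(
                shape=dispersion, scale=mean / dispersion, size=(n_cells, n_genes)
            )
            rows.append(rng.poisson(lam))
            cluster_lab += [cluster] * n_cells
            sample_lab += [
                f"{group}_{rng.integers(n_samples_per_group)}" for _ in range(n_cells)
            ]
            group_lab += [group] * n_cells
    counts = np.vstack(rows)
    expr = ExpressionMatrix(
        counts=counts,
        genes=genes,
        cell_cluster=np.array(cluster_lab),
        cell_sample=np.array(sample_lab),
        cell_group=np.array(group_lab),
    )
    planted_set = GeneSet("PLANTED_INFLAMMATORY", "planted pathway", tuple(planted))
    return expr, planted_set


def write_expression(expr, out_dir: str | Path) -> None:
    """Write the matrix as dense TSV plus a cell-metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(expr.counts, columns=expr.genes).to_csv(
        out / "counts.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "cluster": expr.cell_cluster,
            "sample": expr.cell_sample,
            "group": expr.cell_group,
        }
    ).to_csv(out / "cells.tsv", sep="\t", index=False)
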