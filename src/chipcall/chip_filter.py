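"""Stepwise CHIP variant filter cascade and CHIP / CHIP-PD classification.

A candidate somatic variant in blood is accepted as CHIP when it passes,
jointly:

1. ``vaf_range`` — variant allele frequency within [2%, 35%] (inclusive
   endpoints); VAF below 2% is unreliable at these depths, above 35% is
   more consistent with germline or tumor contamination.
2. ``depth`` — total site depth strictly above the minimum (>500x on the
   targeted panel, >40x on WES).
3. ``strand_pairs`` — at least 4 (panel) / 2 (WES) alt-supporting read
   pairs on *each* strand orientation, rejecting strand-biased artifacts.
4. ``population`` — gnomAD global allele frequency < 1e-5, relaxed to
   < 1e-3 for variants present in COSMIC (known somatic hotspots can have
   nonzero population frequency).
5. ``cohort_recurrence`` — the identical variant is carried by < 5% of all
   processed samples (recurrent identical low-VAF calls across unrelated
   samples indicate panel artifacts or germline leakage).
6. ``homopolymer`` — no run of >= 4 identical bases within the 6 bp
   immediately up- or downstream of the variant.
7. ``protein_altering`` — the consequence changes the protein sequence
   (including exonic splice variants).

Every criterion is evaluated on every record — no short-circuiting — so
failing records carry a complete audit of which criteria rejected them.
Passing calls are classified CHIP-PD (putative driver) when the matched
driver-catalog entry has a recurrence count > 10 or the exact
(gene, protein change) pair is on the predefined driver list; otherwise
plain CHIP. Manual read-level review is represented only by a
``needs_review`` flag on passing calls.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import VariantRecordRaw

logger = logging.getLogger(__name__)

#: Criterion names in cascade order; also the FILTER codes written to VCF.
CRITERIA = (
    "vaf_range",
    "depth",
    "strand_pairs",
    "population",
    "cohort_recurrence",
    "homopolymer",
    "protein_altering",
)

DEFAULT_PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift",
        "inframe_insertion",
        "inframe_deletion",
        "splice_region_exonic",
    }
)

#: Consequence terms known to the vocabulary but not protein-altering.
NON_ALTERING_TERMS = frozenset(
    {
        "synonymous",
        "intronic",
        "splice_region_intronic",
        "utr_5",
        "utr_3",
        "upstream",
        "downstream",
        "intergenic",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade.

    ``mode`` selects the sequencing context: the targeted panel is deep
    (~600x median) so the depth and strand-support minimums are high; WES
    (~80x) uses the relaxed pair.
    """

    mode: str = "panel"
    vaf_min: float = 0.02
    vaf_max: float = 0.35
    min_depth: int = 500
    min_strand_pairs: int = 4
    gnomad_max: float = 1e-5
    gnomad_max_cosmic: float = 1e-3
    cohort_recurrence_max: float = 0.05
    homopolymer_window: int = 6
    homopolymer_min_run: int = 4
    protein_altering_terms: frozenset[str] = DEFAULT_PROTEIN_ALTERING

    def __post_init__(self) -> None:
        if not 0 <= self.vaf_min < self.vaf_max <= 1:
            raise ValueError("require 0 <= vaf_min < vaf_max <= 1")
        if min(self.min_depth, self.min_strand_pairs, self.homopolymer_window) < 0:
            raise ValueError("count thresholds must be non-negative")
        if self.gnomad_max > self.gnomad_max_cosmic:
            raise ValueError("gnomad_max must not exceed gnomad_max_cosmic")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "FilterConfig":
        """Preset thresholds: panel (>500x, >=4 pairs) or WES (>40x, >=2 pairs)."""
        if mode == "panel":
            base = dict(mode="panel", min_depth=500, min_strand_pairs=4)
        elif mode == "wes":
            base = dict(mode="wes", min_depth=40, min_strand_pairs=2)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ChipCall:
    """A filter-cascade verdict for one variant record."""

    record: VariantRecordRaw
    vaf: Fraction
    criterion_flags: Mapping[str, bool]
    passed: bool
    classification: str = "none"  # CHIP | CHIP_PD | none
    needs_review: bool = False


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    hgvs_p_pattern: str | None
    recurrence_count: int
    predefined: bool


@dataclass
class DriverCatalog:
    """Curated CHIP driver variants: recurrence counts and a predefined list.

    ``hgvs_p_pattern`` is a protein-change prefix: ``p.Arg882`` matches
    ``p.Arg882His`` and ``p.Arg882Cys``. An entry with no pattern matches
    any protein change in that gene.
    """

    entries: list[CatalogEntry] = field(default_factory=list)

    @property
    def predefined(self) -> set[tuple[str, str | None]]:
        return {
            (e.gene, e.hgvs_p_pattern) for e in self.entries if e.predefined
        }

    def lookup(self, gene: str | None, hgvs_p: str | None) -> CatalogEntry | None:
        """Best-matching entry for a (gene, protein change); None if no match."""
        if gene is None:
            return None
        best = None
        for e in self.entries:
            if e.gene != gene.upper():
                continue
            if e.hgvs_p_pattern is None:
                if best is None:
                    best = e
            elif hgvs_p is not None and hgvs_p.startswith(e.hgvs_p_pattern):
                best = e  # pattern match beats gene-only match
        return best

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DriverCatalog":
        df = pd.read_csv(path, sep="\t")
        entries = []
        for row in df.itertuples():
            pattern = getattr(row, "hgvs_p_pattern", None)
            if pd.isna(pattern) or pattern in ("", "."):
                pattern = None
            entries.append(
                CatalogEntry(
                    gene=str(row.gene).upper(),
                    hgvs_p_pattern=pattern,
                    recurrence_count=int(row.recurrence_count),
                    predefined=str(row.predefined).lower() in ("yes", "true", "1"),
                )
            )
        return cls(entries)

    @classmethod
    def bundled(cls) -> "DriverCatalog":
        """The catalog shipped with the package (canonical CHIP hotspots)."""
        ref = resources.files("chipcall").joinpath("data/driver_catalog.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def compute_vaf(alt_depth: int, total_depth: int) -> Fraction:
    """Variant allele frequency: alt-supporting reads / total reads.

    Returned as an exact rational so threshold comparisons carry no float
    rounding (``compute_vaf(a, d) * d == a`` holds identically).
    """
    if total_depth <= 0:
        raise ValueError(f"total_depth must be positive, got {total_depth}")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("require 0 <= alt_depth <= total_depth")
    return Fraction(alt_depth, total_depth)


def _max_run(seq: str) -> int:
    best = run = 0
    prev = None
    for base in seq.upper():
        if base not in "ACGT":  # N never extends a run
            prev, run = None, 0
            continue
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def has_homopolymer(
    context_up: str, context_down: str, window: int = 6, min_run: int = 4
) -> bool:
    """True iff a run of >= ``min_run`` identical bases lies within ``window``
    bases adjacent to the variant on either side.

    Runs are scanned within each flank separately; the variant base itself is
    not part of either context, so runs never bridge the two flanks.
    """
    if len(context_up) < window or len(context_down) < window:
        raise ValueError(
            f"contexts must be at least {window} bases "
            f"(got {len(context_up)} up, {len(context_down)} down)"
        )
    up = context_up[-window:]  # bases immediately 5' of the variant
    down = context_down[:window]  # bases immediately 3'
    return _max_run(up) >= min_run or _max_run(down) >= min_run


def passes_population_filter(
    gnomad_af: float, cosmic_count: int, cfg: FilterConfig
) -> bool:
    """gnomAD frequency below the somatic threshold, relaxed for COSMIC variants.

    Strict inequalities: a frequency exactly at the bound fails.
    """
    if not 0 <= gnomad_af <= 1:
        raise ValueError(f"gnomad_af must be in [0,1], got {gnomad_af}")
    if gnomad_af < cfg.gnomad_max:
        return True
    return cosmic_count > 0 and gnomad_af < cfg.gnomad_max_cosmic


def cohort_recurrence_pass(
    variant_key: tuple,
    per_sample_presence: Mapping[tuple, set],
    n_samples: int,
    cfg: FilterConfig,
) -> bool:
    """True iff the identical variant is carried by < 5% of processed samples.

    ``per_sample_presence`` maps variant key -> set of carrying sample ids,
    tallied over ALL samples of the run (the panel-of-normals-like view).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    n_carriers = len(per_sample_presence.get(variant_key, ()))
    # str() round-trip makes the bound the decimal it was written as (0.05 ->
    # exactly 1/20), so 5 carriers in 100 samples fails the strict inequality.
    return Fraction(n_carriers, n_samples) < Fraction(str(cfg.cohort_recurrence_max))


def is_protein_altering(consequence: str | None, cfg: FilterConfig) -> bool:
    """True iff the consequence term alters the protein sequence.

    Unknown terms fail closed (treated as non-altering) with a warning.
    """
    if consequence in cfg.protein_altering_terms:
        return True
    if consequence not in NON_ALTERING_TERMS:
        logger.warning(
            "unknown consequence term %r: failing closed (non-altering)", consequence
        )
    return False


def _dedupe(records: Sequence[VariantRecordRaw]) -> list[VariantRecordRaw]:
    """Collapse identical (sample, variant) records, keeping highest alt_depth."""
    best: dict[tuple, VariantRecordRaw] = {}
    for r in records:
        k = (r.sample_id, *r.key)
        if k not in best or r.alt_depth > best[k].alt_depth:
            best[k] = r
    if len(best) < len(records):
        logger.info(
            "collapsed %d duplicate (sample, variant) records", len(records) - len(best)
        )
    # deterministic output order, independent of input permutation
    return sorted(best.values(), key=lambda r: (r.sample_id, r.key))


def tally_presence(records: Iterable[VariantRecordRaw]) -> dict[tuple, set]:
    """Variant key -> set of sample ids carrying it, over the whole run."""
    presence: dict[tuple, set] = defaultdict(set)
    for r in records:
        presence[r.key].add(r.sample_id)
    return dict(presence)


def apply_filter_cascade(
    records: Sequence[VariantRecordRaw],
    cfg: FilterConfig,
    cohort_size: int | None = None,
) -> list[ChipCall]:
    """Evaluate every criterion on every record and return audited calls.

    Records from *all* processed samples must be supplied together: the
    cohort-recurrence criterion is a function of the whole run. If
    ``cohort_size`` is None, the number of distinct sample ids in
    ``records`` is used.
    """
    if not records:
        return []
    records = _dedupe(records)
    n_samples = cohort_size or len({r.sample_id for r in records})
    presence = tally_presence(records)
    # endpoints are inclusive and decimal-exact: VAF exactly 2% or 35% passes
    vaf_lo = Fraction(str(cfg.vaf_min))
    vaf_hi = Fraction(str(cfg.vaf_max))
    calls = []
    for r in records:
        vaf = compute_vaf(r.alt_depth, r.total_depth)
        flags = {
            "vaf_range": vaf_lo <= vaf <= vaf_hi,
            "depth": r.total_depth > cfg.min_depth,
            "strand_pairs": r.alt_fwd >= cfg.min_strand_pairs
            and r.alt_rev >= cfg.min_strand_pairs,
            "population": passes_population_filter(r.gnomad_af, r.cosmic_count, cfg),
            "cohort_recurrence": cohort_recurrence_pass(r.key, presence, n_samples, cfg),
            "homopolymer": not has_homopolymer(
                r.context_up,
                r.context_down,
                cfg.homopolymer_window,
                cfg.homopolymer_min_run,
            ),
            "protein_altering": is_protein_altering(r.consequence, cfg),
        }
        passed = all(flags.values())
        calls.append(
            ChipCall(
                record=r,
                vaf=vaf,
                criterion_flags=flags,
                passed=passed,
                needs_review=passed,
            )
        )
    n_pass = sum(c.passed for c in calls)
    logger.info(
        "filter cascade: %d/%d records pass across %d samples",
        n_pass,
        len(calls),
        n_samples,
    )
    return calls


def classify_chip(call: ChipCall, catalog: DriverCatalog) -> str:
    """CHIP_PD for recurrently reported (>10) or predefined driver variants.

    Raises on non-passing calls: classification is defined only for calls
    that survived the cascade.
    """
    if not call.passed:
        raise ValueError("classify_chip requires a passing call")
    entry = catalog.lookup(call.record.gene, call.record.hgvs_p)
    if entry is not None and (entry.recurrence_count > 10 or entry.predefined):
        return "CHIP_PD"
    return "CHIP"


def call_chip(
    records: Sequence[VariantRecordRaw],
    cfg: FilterConfig,
    catalog: DriverCatalog | None = None,
    cohort_size: int | None = None,
) -> list[ChipCall]:
    """Run the cascade and attach CHIP / CHIP-PD classification to passing calls."""
    catalog = catalog or DriverCatalog.bundled()
    calls = apply_filter_cascade(records, cfg, cohort_size)
    return [
        replace(c, classification=classify_chip(c, catalog)) if c.passed else c
        for c in calls
    ]
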