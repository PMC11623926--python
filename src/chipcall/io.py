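"""Readers and writers for the formats the pipeline touches.

Variant evidence arrives as VCF 4.2 with per-sample depth/strand FORMAT
fields and annotation INFO fields (gene, consequence, HGVS.p, gnomAD allele
frequency, COSMIC recurrence, ±6 bp reference context). Annotation is
consumed, never computed: the upstream caller/annotator is out of scope.
Cohort metadata is a TSV, gene sets are GMT.

Coordinates are 1-based as in VCF; the stored context strings exclude the
variant position itself. Multi-allelic lines are decomposed into one record
per alternate allele; spanning-deletion alleles (``*``) are dropped with a
logged count. FORMAT/INFO key names differ between callers, so the mapping
lives in :class:`VcfFieldMap`, not in code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_VALID_CONTEXT = set("ACGTN")

PATHOLOGIES = frozenset({"LUAD", "LUSC", "other"})
SMOKING = frozenset({"never", "ever/current"})
TIMEPOINTS = frozenset({"pre", "post"})
RESPONSES = frozenset({"responder", "non-responder", "unknown"})


class VcfFormatError(ValueError):
    """Malformed VCF content (header or records)."""


class VcfSchemaError(ValueError):
    """A mandatory FORMAT/INFO field is absent from the header."""


@dataclass(frozen=True)
class VariantRecordRaw:
    """One candidate somatic variant in one sample, with its evidence.

    ``total_depth``/``alt_depth`` are read counts at the site;
    ``alt_fwd``/``alt_rev`` are alt-supporting read pairs per strand
    orientation. ``gnomad_af`` is the global population allele frequency
    (0 when absent); ``cosmic_count`` is the COSMIC recurrence count
    (0 = not in COSMIC). ``context_up``/``context_down`` are the reference
    bases flanking the position, 5' and 3' respectively.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    total_depth: int
    alt_depth: int
    alt_fwd: int
    alt_rev: int
    gene: str | None = None
    consequence: str | None = None
    hgvs_p: str | None = None
    gnomad_af: float = 0.0
    cosmic_count: int = 0
    context_up: str = "NNNNNN"
    context_down: str = "NNNNNN"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )
        if self.alt_fwd + self.alt_rev > self.alt_depth:
            raise ValueError(
                "strand-pair counts exceed alt support: "
                f"{self.alt_fwd}+{self.alt_rev} > {self.alt_depth}"
            )
        for ctx in (self.context_up, self.context_down):
            if set(ctx.upper()) - _VALID_CONTEXT:
                raise ValueError(f"context contains non-ACGTN bases: {ctx!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant irrespective of sample: chrom:pos:ref:alt."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CohortSample:
    """Clinical covariates for one cohort sample."""

    sample_id: str
    age: float
    sex: str
    pathology: str
    smoking: str
    timepoint: str
    response: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.smoking not in SMOKING:
            raise ValueError(f"unknown smoking status {self.smoking!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass(frozen=True)
class VcfFieldMap:
    """Where each piece of evidence lives in the VCF.

    FORMAT keys hold per-sample depths; INFO keys hold the (per-alt)
    annotation. Defaults follow the VCF 4.3 reserved per-allele depth keys
    (AD/ADF/ADR) and plain descriptive INFO names.
    """

    dp: str = "DP"
    ad: str = "AD"
    adf: str = "ADF"
    adr: str = "ADR"
    gene: str = "GENE"
    consequence: str = "CONSEQ"
    hgvs_p: str = "HGVSP"
    gnomad_af: str = "GNOMAD_AF"
    cosmic_count: str = "COSMIC_CNT"
    context_up: str = "CTXU"
    context_down: str = "CTXD"

    @property
    def format_keys(self) -> tuple[str, ...]:
        return (self.dp, self.ad, self.adf, self.adr)


def _info_per_alt(value, n_alts: int, i: int):
    """Pull the i-th alt's entry from an INFO value that may be scalar or tuple."""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[i]
        return value[0]
    return value


def read_vcf(
    path: str | Path,
    dialect: str = "panel",
    field_map: VcfFieldMap | None = None,
) -> list[VariantRecordRaw]:
    """Read an annotated VCF into :class:`VariantRecordRaw` records.

    One record is produced per (sample, alternate allele); multi-allelic
    sites are decomposed. Missing gnomAD frequency is treated as 0 (absent
    from the population reference) and missing COSMIC count as 0.

    Parameters
    ----------
    dialect:
        ``"panel"`` or ``"wes"``; recorded for interface symmetry with the
        filter configuration — the evidence fields read are identical.
    """
    if dialect not in ("panel", "wes"):
        raise ValueError(f"dialect must be 'panel' or 'wes', got {dialect!r}")
    fm = field_map or VcfFieldMap()
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc

    with vcf:
        for key in fm.format_keys:
            if key not in vcf.header.formats:
                raise VcfSchemaError(
                    f"mandatory FORMAT field {key!r} missing from VCF header"
                )
        records: list[VariantRecordRaw] = []
        n_spanning = 0
        declared_info = set(vcf.header.info.keys())
        for rec in vcf:
            alts = rec.alts or ()
            n_alts = len(alts)
            for sample_id, sample in rec.samples.items():
                dp = sample.get(fm.dp)
                ad = sample.get(fm.ad)
                adf = sample.get(fm.adf)
                adr = sample.get(fm.adr)
                if dp is None or ad is None or ad[0] is None:
                    continue  # sample not genotyped at this site
                for i, alt in enumerate(alts):
                    if alt == "*":
                        n_spanning += 1
                        continue
                    info = rec.info

                    def _info(key):
                        # .get raises on keys absent from the header
                        return info.get(key) if key in declared_info else None

                    gnomad = _info(fm.gnomad_af)
                    cosmic = _info(fm.cosmic_count)

                    def _str_field(key: str) -> str | None:
                        val = _info_per_alt(_info(key), n_alts, i)
                        return None if val in (None, ".") else str(val)

                    records.append(
                        VariantRecordRaw(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            sample_id=sample_id,
                            total_depth=int(dp),
                            alt_depth=int(ad[i + 1]),
                            alt_fwd=int(adf[i + 1]) if adf is not None else 0,
                            alt_rev=int(adr[i + 1]) if adr is not None else 0,
                            gene=_str_field(fm.gene),
                            consequence=_str_field(fm.consequence),
                            hgvs_p=_str_field(fm.hgvs_p),
                            gnomad_af=float(_info_per_alt(gnomad, n_alts, i) or 0.0)
                            if gnomad is not None
                            else 0.0,
                            cosmic_count=int(_info_per_alt(cosmic, n_alts, i) or 0)
                            if cosmic is not None
                            else 0,
                            context_up=_str_field(fm.context_up) or "NNNNNN",
                            context_down=_str_field(fm.context_down) or "NNNNNN",
                        )
                    )
    if n_spanning:
        logger.info("dropped %d spanning-deletion (*) allele records", n_spanning)
    logger.info("read %d variant records from %s", len(records), path)
    return records


_COHORT_COLUMNS = (
    "sample_id",
    "age",
    "sex",
    "pathology",
    "smoking",
    "timepoint",
    "response",
)


def read_cohort_table(path: str | Path) -> list[CohortSample]:
    """Read the cohort metadata TSV into validated :class:`CohortSample` rows."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id in cohort table: {sorted(set(dupes))}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "sample_id"].tolist()
        raise ValueError(f"non-numeric age for samples: {bad}")
    samples = [
        CohortSample(
            sample_id=row.sample_id,
            age=float(row.age),
            sex=str(row.sex),
            pathology=str(row.pathology),
            smoking=str(row.smoking),
            timepoint=str(row.timepoint),
            response=str(row.response),
        )
        for row in df.itertuples()
    ]
    return samples


def write_cohort_table(samples: Sequence[CohortSample], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set file: one set per line, name TAB description TAB genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VcfFormatError(
                    f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3"
                )
            # dedupe, keeping first occurrence order
            seen = dict.fromkeys(g for g in parts[2:] if g)
            sets.append(GeneSet(parts[0], parts[1], tuple(seen)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join((s.name, s.description, *s.genes)) + "\n")


# --- filtered-call VCF output ------------------------------------------------

#: FILTER codes in cascade order; mirrored in chip_filter.CRITERIA.
FILTER_DESCRIPTIONS = {
    "vaf_range": "VAF outside the somatic clone range",
    "depth": "total site depth at or below the minimum",
    "strand_pairs": "too few alt-supporting read pairs on one strand",
    "population": "gnomAD frequency too high for a somatic call",
    "cohort_recurrence": "identical variant recurrent across cohort samples",
    "homopolymer": "homopolymer run adjacent to the variant",
    "protein_altering": "consequence does not alter the protein",
}


def _chip_header(sample_id: str, contigs: Sequence[str], fm: VcfFieldMap) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for code, desc in FILTER_DESCRIPTIONS.items():
        header.filters.add(code, None, None, desc)
    header.formats.add(fm.dp, 1, "Integer", "Total read depth at the site")
    header.formats.add(fm.ad, "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add(fm.adf, "R", "Integer", "Allelic depths on the forward strand")
    header.formats.add(fm.adr, "R", "Integer", "Allelic depths on the reverse strand")
    header.info.add(fm.gene, "A", "String", "Gene symbol")
    header.info.add(fm.consequence, "A", "String", "Protein consequence term")
    header.info.add(fm.hgvs_p, "A", "String", "HGVS.p protein change")
    # String, not Float: htslib squeezes Float INFO through 32-bit storage,
    # which would break exact round-tripping of small allele frequencies.
    header.info.add(fm.gnomad_af, "A", "String", "gnomAD global allele frequency")
    header.info.add(fm.cosmic_count, "A", "Integer", "COSMIC recurrence count")
    header.info.add(fm.context_up, "A", "String", "Reference context 5' of the variant")
    header.info.add(fm.context_down, "A", "String", "Reference context 3' of the variant")
    header.info.add("CHIP_PD", 0, "Flag", "Classified as CHIP with putative driver")
    header.add_sample(sample_id)
    return header


def write_variant_vcf(
    records: Sequence[VariantRecordRaw],
    path: str | Path,
    sample_id: str | None = None,
    field_map: VcfFieldMap | None = None,
) -> None:
    """Write raw (unfiltered) variant records for one sample as VCF 4.2."""
    _write_vcf(records, [None] * len(records), path, sample_id, field_map)


def write_chip_vcf(calls, path: str | Path, field_map: VcfFieldMap | None = None) -> None:
    """Write filtered calls as VCF 4.2 with per-criterion FILTER codes.

    Calls that pass every criterion get ``PASS``; otherwise the failing
    criterion codes are written semicolon-joined. CHIP-PD classification is
    an INFO flag. All calls must belong to one sample (per-call FILTER
    status cannot share a multi-sample line).
    """
    records = [c.record for c in calls]
    filters: list[list[str] | None] = []
    for c in calls:
        failed = [name for name, ok in c.criterion_flags.items() if not ok]
        filters.append(failed or None)
    pd_flags = [getattr(c, "classification", None) == "CHIP_PD" for c in calls]
    _write_vcf(records, filters, path, None, field_map, pd_flags)


def _write_vcf(
    records: Sequence[VariantRecordRaw],
    filters: Sequence[list[str] | None],
    path: str | Path,
    sample_id: str | None,
    field_map: VcfFieldMap | None,
    pd_flags: Sequence[bool] | None = None,
) -> None:
    fm = field_map or VcfFieldMap()
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    sid = sample_id or (next(iter(sample_ids)) if sample_ids else "SAMPLE")
    contigs = sorted({r.chrom for r in records})
    header = _chip_header(sid, contigs, fm)
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            r = records[i]
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt)
            )
            if filters[i] is None:
                rec.filter.add("PASS")
            else:
                for code in filters[i]:
                    rec.filter.add(code)
            rec.info[fm.gene] = (r.gene or ".",)
            rec.info[fm.consequence] = (r.consequence or ".",)
            rec.info[fm.hgvs_p] = (r.hgvs_p or ".",)
            rec.info[fm.gnomad_af] = (repr(r.gnomad_af),)
            rec.info[fm.cosmic_count] = (r.cosmic_count,)
            rec.info[fm.context_up] = (r.context_up,)
            rec.info[fm.context_down] = (r.context_down,)
            if pd_flags is not None and pd_flags[i]:
                rec.info["CHIP_PD"] = True
            sample = rec.samples[sid]
            sample[fm.dp] = r.total_depth
            sample[fm.ad] = (r.total_depth - r.alt_depth, r.alt_depth)
            sample[fm.adf] = (0, r.alt_fwd)
            sample[fm.adr] = (0, r.alt_rev)
            out.write(rec)
    logger.info("wrote %d records to %s", len(records), path)
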