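"""YAML configuration: VCF key mapping and filter thresholds.

Callers differ in how they encode per-strand alt support and annotation,
so the FORMAT/INFO key names live in the config file rather than in code.
A config file has two optional sections::

    vcf_fields:
      adf: "ALT_F"        # any VcfFieldMap attribute
    filter:
      mode: panel          # panel | wes (selects depth/strand presets)
      vaf_max: 0.40        # any FilterConfig attribute

Omitted keys keep their defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .chip_filter import FilterConfig
from .io import VcfFieldMap


def load_config(path: str | Path) -> tuple[FilterConfig, VcfFieldMap]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    fm_kwargs = raw.get("vcf_fields", {}) or {}
    valid_fm = {f.name for f in fields(VcfFieldMap)}
    unknown = set(fm_kwargs) - valid_fm
    if unknown:
        raise ValueError(f"unknown vcf_fields keys: {sorted(unknown)}")
    field_map = VcfFieldMap(**fm_kwargs)

    filt = dict(raw.get("filter", {}) or {})
    mode = filt.pop("mode", "panel")
    if "protein_altering_terms" in filt:
        filt["protein_altering_terms"] = frozenset(filt["protein_altering_terms"])
    valid_filter = {f.name for f in fields(FilterConfig)}
    unknown = set(filt) - valid_filter
    if unknown:
        raise ValueError(f"unknown filter keys: {sorted(unknown)}")
    cfg = FilterConfig.for_mode(mode, **filt)
    return cfg, field_map
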