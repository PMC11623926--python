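import numpy as np
import pytest

from chipcall import chip_filter, synthetic_data
from chipcall.io import VariantRecordRaw


@pytest.fixture(scope="session")
def panel_cfg():
    return chip_filter.FilterConfig.for_mode("panel")


@pytest.fixture(scope="session")
def wes_cfg():
    return chip_filter.FilterConfig.for_mode("wes")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample panel cohort reused by io/filter/burden tests."""
    cfg = synthetic_data.CohortSimConfig(n_samples=60, seed=5)
    return synthetic_data.simulate_cohort(cfg)


def make_record(**overrides) -> VariantRecordRaw:
    """A record that passes every panel criterion unless overridden."""
    defaults = dict(
        chrom="chr1",
        pos=1000,
        ref="C",
        alt="T",
        sample_id="S1",
        total_depth=600,
        alt_depth=60,
        alt_fwd=30,
        alt_rev=30,
        gene="DNMT3A",
        consequence="missense",
        hgvs_p="p.Arg320Cys",
        gnomad_af=0.0,
        cosmic_count=0,
        context_up="ACGTAC",
        context_down="GTACGT",
    )
    defaults.update(overrides)
    return VariantRecordRaw(**defaults)


@pytest.fixture
def passing_record():
    return make_record()
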