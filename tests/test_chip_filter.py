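import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipcall import chip_filter as cf
from chipcall.chip_filter import (
    DriverCatalog,
    FilterConfig,
    apply_filter_cascade,
    classify_chip,
    cohort_recurrence_pass,
    compute_vaf,
    has_homopolymer,
    is_protein_altering,
    passes_population_filter,
)

from conftest import make_record


def brute_force_run(seq: str, min_run: int) -> bool:
    """Independent oracle: scan every window for a homopolymer run."""
    return any(
        len(set(seq[i : i + min_run])) == 1 and seq[i] in "ACGT"
        for i in range(len(seq) - min_run + 1)
    )


class TestComputeVaf:
    @pytest.mark.parametrize(
        "alt,total,expected",
        [(10, 500, Fraction(1, 50)), (0, 100, Fraction(0)), (35, 100, Fraction(7, 20))],
    )
    def test_boundary_arithmetic(self, alt, total, expected):
        assert compute_vaf(alt, total) == expected
        assert float(compute_vaf(alt, total)) == pytest.approx(float(expected))

    def test_zero_depth_is_domain_error(self):
        with pytest.raises(ValueError):
            compute_vaf(0, 0)

    @given(total=st.integers(1, 10000), frac=st.fractions(0, 1))
    @settings(derandomize=True, max_examples=200)
    def test_exact_on_integers(self, total, frac):
        alt = int(frac * total)
        assert compute_vaf(alt, total) == Fraction(alt, total)


class TestHomopolymer:
    def test_run_of_four_upstream(self):
        assert has_homopolymer("TGAAAA", "CGTACG", 6, 4)

    def test_no_run(self):
        assert not has_homopolymer("ACGTAC", "GTACGT", 6, 4)

    def test_n_never_extends_a_run(self):
        assert not has_homopolymer("AANAAC", "GTACGT", 6, 4)
        assert not has_homopolymer("AAANAA", "GTACGT", 6, 4)

    def test_short_context_is_input_error(self):
        with pytest.raises(ValueError):
            has_homopolymer("ACG", "GTACGT", 6, 4)

    def test_only_window_adjacent_bases_count(self):
        # run is outside the 6 bp window next to the variant
        assert not has_homopolymer("AAAATACGTC", "GTACGT", 6, 4)
        assert has_homopolymer("ACGTAC", "GAAAAT", 6, 4)

    def test_exhaustive_against_brute_force_oracle(self):
        down = "GTACGT"
        for combo in itertools.product("ACGT", repeat=6):
            up = "".join(combo)
            assert has_homopolymer(up, down, 6, 4) == brute_force_run(up, 4), up

    @given(
        up=st.text(alphabet="ACGTN", min_size=6, max_size=10),
        down=st.text(alphabet="ACGTN", min_size=6, max_size=10),
        min_run=st.integers(2, 6),
    )
    @settings(derandomize=True, max_examples=300)
    def test_random_contexts_match_oracle(self, up, down, min_run):
        expected = brute_force_run(up[-6:], min_run) or brute_force_run(down[:6], min_run)
        assert has_homopolymer(up, down, 6, min_run) == expected


class TestPopulationFilter:
    @pytest.mark.parametrize(
        "af,cosmic,expected",
        [
            (2e-5, 0, False),  # above the somatic threshold, not in COSMIC
            (5e-4, 12, True),  # COSMIC membership relaxes the bound to 1e-3
            (0.0, 0, True),  # absent from gnomAD
            (1e-5, 0, False),  # strict: exactly at the bound fails
            (1e-3, 12, False),  # strict on the relaxed bound too
            (2e-5, 1, True),  # any COSMIC recurrence counts as membership
        ],
    )
    def test_thresholds(self, panel_cfg, af, cosmic, expected):
        assert passes_population_filter(af, cosmic, panel_cfg) is expected


class TestCohortRecurrence:
    def presence(self, n_carriers):
        return {("chr1", 1, "C", "T"): {f"S{i}" for i in range(n_carriers)}}

    def test_five_percent_exactly_fails(self, panel_cfg):
        key = ("chr1", 1, "C", "T")
        assert not cohort_recurrence_pass(key, self.presence(5), 100, panel_cfg)

    def test_below_threshold_passes(self, panel_cfg):
        key = ("chr1", 1, "C", "T")
        assert cohort_recurrence_pass(key, self.presence(4), 100, panel_cfg)

    def test_single_sample_cohort_always_fails(self, panel_cfg):
        key = ("chr1", 1, "C", "T")
        assert not cohort_recurrence_pass(key, self.presence(1), 1, panel_cfg)

    def test_zero_samples_is_domain_error(self, panel_cfg):
        with pytest.raises(ValueError):
            cohort_recurrence_pass(("chr1", 1, "C", "T"), {}, 0, panel_cfg)


class TestProteinAltering:
    @pytest.mark.parametrize(
        "term,expected",
        [
            ("missense", True),
            ("synonymous", False),
            ("splice_region_exonic", True),
            ("stop_gained", True),
            ("intronic", False),
            ("totally_new_term", False),  # unknown terms fail closed
        ],
    )
    def test_vocabulary(self, panel_cfg, term, expected):
        assert is_protein_altering(term, panel_cfg) is expected


def single_criterion_oracles(record, cfg, presence, n_samples):
    """Each criterion recomputed independently of the cascade."""
    vaf = record.alt_depth / record.total_depth
    return {
        "vaf_range": cfg.vaf_min <= vaf <= cfg.vaf_max,
        "depth": record.total_depth > cfg.min_depth,
        "strand_pairs": min(record.alt_fwd, record.alt_rev) >= cfg.min_strand_pairs,
        "population": passes_population_filter(record.gnomad_af, record.cosmic_count, cfg),
        "cohort_recurrence": cohort_recurrence_pass(record.key, presence, n_samples, cfg),
        "homopolymer": not has_homopolymer(
            record.context_up, record.context_down, cfg.homopolymer_window, cfg.homopolymer_min_run
        ),
        "protein_altering": is_protein_altering(record.consequence, cfg),
    }


class TestFilterCascade:
    def test_low_vaf_fails_only_vaf_range(self, panel_cfg):
        # 9/600 = 1.5% VAF; strand support 5+4 keeps every other criterion green
        rec = make_record(alt_depth=9, alt_fwd=5, alt_rev=4, total_depth=600)
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert call.vaf == pytest.approx(0.015)
        assert not call.passed
        failed = {k for k, ok in call.criterion_flags.items() if not ok}
        assert failed == {"vaf_range"}

    def test_depth_bound_is_strict(self, panel_cfg):
        rec = make_record(total_depth=500, alt_depth=50, alt_fwd=25, alt_rev=25)
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert not call.criterion_flags["depth"]
        rec = make_record(total_depth=501, alt_depth=50, alt_fwd=25, alt_rev=25)
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert call.criterion_flags["depth"]

    def test_vaf_endpoints_inclusive(self, panel_cfg):
        for alt in (12, 210):  # VAF 0.02 and 0.35 at depth 600
            rec = make_record(alt_depth=alt, alt_fwd=alt // 2, alt_rev=alt - alt // 2)
            (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
            assert call.criterion_flags["vaf_range"], alt

    def test_wes_mode_uses_relaxed_thresholds(self, wes_cfg):
        rec = make_record(total_depth=80, alt_depth=8, alt_fwd=2, alt_rev=6)
        (call,) = apply_filter_cascade([rec], wes_cfg, cohort_size=100)
        assert call.passed

    def test_flags_match_independent_oracles_on_synthetic_batch(
        self, small_cohort, panel_cfg
    ):
        calls = apply_filter_cascade(small_cohort.records, panel_cfg, cohort_size=60)
        presence = cf.tally_presence([c.record for c in calls])
        for call in calls:
            expected = single_criterion_oracles(call.record, panel_cfg, presence, 60)
            assert dict(call.criterion_flags) == expected

    def test_order_independence(self, small_cohort, panel_cfg):
        records = list(small_cohort.records)
        base = apply_filter_cascade(records, panel_cfg, cohort_size=60)
        random.Random(0).shuffle(records)
        shuffled = apply_filter_cascade(records, panel_cfg, cohort_size=60)
        assert base == shuffled  # output order is canonical

    def test_loosening_a_threshold_never_shrinks_passing_set(
        self, small_cohort, panel_cfg
    ):
        base_pass = {
            (c.record.sample_id, *c.record.key)
            for c in apply_filter_cascade(small_cohort.records, panel_cfg, cohort_size=60)
            if c.passed
        }
        for loosened in (
            FilterConfig.for_mode("panel", vaf_max=0.5),
            FilterConfig.for_mode("panel", min_depth=100),
            FilterConfig.for_mode("panel", min_strand_pairs=1),
            FilterConfig.for_mode("panel", gnomad_max=1e-3, gnomad_max_cosmic=1e-2),
            FilterConfig.for_mode("panel", cohort_recurrence_max=0.5),
            FilterConfig.for_mode("panel", homopolymer_min_run=7),
        ):
            loose_pass = {
                (c.record.sample_id, *c.record.key)
                for c in apply_filter_cascade(small_cohort.records, loosened, cohort_size=60)
                if c.passed
            }
            assert base_pass <= loose_pass

    def test_duplicates_collapse_to_highest_alt_depth(self, panel_cfg):
        low = make_record(alt_depth=30, alt_fwd=15, alt_rev=15)
        high = make_record(alt_depth=60, alt_fwd=30, alt_rev=30)
        calls = apply_filter_cascade([low, high], panel_cfg, cohort_size=100)
        assert len(calls) == 1 and calls[0].record.alt_depth == 60

    def test_empty_input_gives_empty_output(self, panel_cfg):
        assert apply_filter_cascade([], panel_cfg) == []

    def test_passing_calls_need_review(self, passing_record, panel_cfg):
        (call,) = apply_filter_cascade([passing_record], panel_cfg, cohort_size=100)
        assert call.passed and call.needs_review


@pytest.fixture(scope="module")
def catalog():
    return DriverCatalog.bundled()


class TestClassifyChip:
    def test_hotspot_with_high_recurrence_is_chip_pd(self, catalog, panel_cfg):
        rec = make_record(gene="DNMT3A", hgvs_p="p.Arg882His")
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert classify_chip(call, catalog) == "CHIP_PD"

    def test_recurrence_exactly_ten_is_plain_chip(self, panel_cfg):
        catalog = DriverCatalog(
            [cf.CatalogEntry("DNMT3A", "p.Arg882", 10, predefined=False)]
        )
        rec = make_record(gene="DNMT3A", hgvs_p="p.Arg882His")
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert classify_chip(call, catalog) == "CHIP"

    def test_predefined_entry_is_chip_pd_regardless_of_count(self, panel_cfg):
        catalog = DriverCatalog(
            [cf.CatalogEntry("PPM1D", "p.Arg552", 3, predefined=True)]
        )
        rec = make_record(gene="PPM1D", hgvs_p="p.Arg552Ter")
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert classify_chip(call, catalog) == "CHIP_PD"

    def test_gene_absent_from_catalog_is_chip(self, catalog, panel_cfg):
        rec = make_record(gene="NOVELGENE", hgvs_p="p.Ala1Val")
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        assert classify_chip(call, catalog) == "CHIP"

    def test_non_passing_call_is_precondition_error(self, catalog, panel_cfg):
        rec = make_record(consequence="synonymous")
        (call,) = apply_filter_cascade([rec], panel_cfg, cohort_size=100)
        with pytest.raises(ValueError):
            classify_chip(call, catalog)
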