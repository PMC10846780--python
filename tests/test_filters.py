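"""Stage-1 / three-level germline filtration: boundary behaviour,
brute-force predicate-oracle equivalence, level-order commutation, and
matched-subtraction ground-truth recovery."""

import itertools

import numpy as np
import pytest

from conftest import random_callset
from tmbkit.filters import (
    BaselinePanel,
    FilterConfig,
    FilterTrace,
    level1_population_filter,
    level2_vaf_filter,
    level3_baseline_filter,
    matched_subtraction,
    stage1_filter,
    tumor_only_somatic,
)
from tmbkit.model import SampleCallset, VariantRecord, variant_key
from tmbkit.simulate import SimParams, generate_matched_pair


def rec(qual=50.0, depth=100, vaf=0.3, csq="coding_nonsynonymous",
        pop_afs=None, pos=100):
    return VariantRecord("chr1", pos, "A", "G", qual, depth, vaf, csq,
                         pop_afs or {})


def cs(records, source="tumor"):
    return SampleCallset("s1", records, source)


class TestStage1:
    @pytest.mark.parametrize(
        "record,kept",
        [
            (rec(qual=9.9, depth=100), False),           # below quality floor
            (rec(qual=50, depth=30, csq="coding_synonymous"), False),
            (rec(qual=10, depth=30), True),              # inclusive boundaries
            (rec(qual=50, depth=29), False),             # below depth floor
            (rec(csq="noncoding"), False),
        ],
    )
    def test_quality_depth_and_coding_gates(self, record, kept, cfg):
        out = stage1_filter(cs([record]), cfg)
        assert (len(out.records) == 1) is kept

    def test_synonymous_kept_when_flag_disabled(self):
        cfg = FilterConfig(drop_synonymous=False)
        out = stage1_filter(cs([rec(csq="coding_synonymous")]), cfg)
        assert len(out.records) == 1


class TestLevel1:
    @pytest.mark.parametrize(
        "pop_afs,kept",
        [
            ({"global": 0.02}, False),                      # > 1% polymorphic
            ({"global": 0.001, "south_asian": 0.03}, False),  # ANY database rule
            ({"global": 0.01}, True),                       # exactly 1% retained
            ({}, True),                                     # unobserved -> keep
            ({"south_asian": 0.005}, True),
        ],
    )
    def test_any_database_rule(self, pop_afs, kept, cfg):
        out = level1_population_filter(cs([rec(pop_afs=pop_afs)]), cfg)
        assert (len(out.records) == 1) is kept
        # oracle: retained iff max over annotated AFs <= 1%
        assert kept is (max(pop_afs.values(), default=0.0) <= cfg.max_pop_af)

    def test_af_outside_unit_interval_is_an_error(self, cfg):
        bad = cs([rec(pop_afs={"global": 1.5})])
        with pytest.raises(ValueError, match="out of"):
            level1_population_filter(bad, cfg)


class TestLevel2:
    @pytest.mark.parametrize(
        "vaf,kept",
        [
            (0.05, False),   # low-VAF cut is inclusive
            (0.50, False),   # heterozygous centre
            (0.45, False),   # band closed at both ends
            (0.55, False),
            (0.30, True),
            (0.56, True),
            (0.98, True),    # hom cut disabled by default
        ],
    )
    def test_germline_vaf_bands(self, vaf, kept, cfg):
        out = level2_vaf_filter(cs([rec(vaf=vaf)]), cfg)
        assert (len(out.records) == 1) is kept

    def test_optional_homozygous_cut(self):
        cfg = FilterConfig(hom_vaf_cut=0.95)
        assert len(level2_vaf_filter(cs([rec(vaf=0.96)]), cfg).records) == 0
        assert len(level2_vaf_filter(cs([rec(vaf=0.94)]), cfg).records) == 1


class TestLevel3:
    def test_membership_rule(self, cfg):
        inside = rec(pos=100)
        outside = rec(pos=200)
        panel = BaselinePanel(keys={variant_key(inside)}, n_donors=2)
        out = level3_baseline_filter(cs([inside, outside]), panel)
        assert [r.pos for r in out.records] == [200]

    def test_no_overlap_is_identity(self, cfg):
        panel = BaselinePanel(keys={variant_key(rec(pos=999))}, n_donors=1)
        callset = cs([rec(pos=1), rec(pos=2)])
        out = level3_baseline_filter(callset, panel)
        assert [r.pos for r in out.records] == [1, 2]

    def test_indel_spelling_equivalence_respected(self, cfg):
        # panel stores the trimmed spelling; the callset carries a padded one
        padded = VariantRecord("chr1", 100, "ATT", "AT", 50, 100, 0.3,
                               "coding_nonsynonymous")
        panel = BaselinePanel(
            keys={variant_key(VariantRecord("chr1", 100, "AT", "A", 50, 100,
                                            0.3, "coding_nonsynonymous"))},
            n_donors=1,
        )
        assert len(level3_baseline_filter(cs([padded]), panel).records) == 0


def retain_oracle(r, cfg, panel):
    """Independent per-record evaluation of every retain-predicate."""
    if r.qual < cfg.min_qual or r.depth < cfg.min_depth:
        return False
    if cfg.drop_synonymous and r.consequence == "coding_synonymous":
        return False
    if cfg.drop_noncoding and r.consequence == "noncoding":
        return False
    if any(af > cfg.max_pop_af for af in r.pop_afs.values()):
        return False
    lo, hi = cfg.germ_het_band
    if r.vaf <= cfg.low_vaf_cut or lo <= r.vaf <= hi:
        return False
    if cfg.hom_vaf_cut is not None and r.vaf >= cfg.hom_vaf_cut:
        return False
    if variant_key(r) in panel.keys:
        return False
    return True


def panel_for(callset, rng):
    picks = [r for r in callset.records if rng.random() < 0.2]
    keys = {variant_key(r) for r in picks} or {variant_key(rec(pos=99999))}
    return BaselinePanel(keys=frozenset(keys), n_donors=2)


class TestComposition:
    def test_pipeline_equals_bruteforce_conjunction(self, cfg):
        """Over 120 random callsets the sequential pipeline output equals the
        set of records passing every retain-predicate independently."""
        rng = np.random.default_rng(11)
        for trial in range(120):
            callset = random_callset(rng, int(rng.integers(0, 500)))
            panel = panel_for(callset, rng)
            out, trace = tumor_only_somatic(callset, panel, cfg)
            expected = [r for r in callset.records if retain_oracle(r, cfg, panel)]
            assert out.records == expected
            assert trace.input == len(callset.records)
            assert trace.level3 == len(expected)

    def test_level_order_commutes(self, cfg):
        """Levels 1-3 are per-record predicates: any application order after
        stage 1 yields the same record set."""
        rng = np.random.default_rng(12)
        levels = {
            "l1": lambda c: level1_population_filter(c, cfg),
            "l2": lambda c: level2_vaf_filter(c, cfg),
            "l3": None,  # bound per-trial once the panel exists
        }
        for trial in range(20):
            callset = random_callset(rng, 300)
            panel = panel_for(callset, rng)
            levels["l3"] = lambda c: level3_baseline_filter(c, panel)
            reference = None
            for order in itertools.permutations(["l1", "l2", "l3"]):
                out = stage1_filter(callset, cfg)
                for name in order:
                    out = levels[name](out)
                keys = [variant_key(r) for r in out.records]
                if reference is None:
                    reference = keys
                assert keys == reference

    def test_each_filter_output_is_subset_and_trace_non_increasing(self, cfg):
        rng = np.random.default_rng(13)
        callset = random_callset(rng, 400)
        panel = panel_for(callset, rng)
        out, trace = tumor_only_somatic(callset, panel, cfg)
        assert {id(r) for r in out.records} <= {id(r) for r in callset.records}
        seq = (trace.input, trace.stage1, trace.level1, trace.level2, trace.level3)
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_empty_input_gives_empty_output_and_zero_trace(self, cfg, small_panel):
        out, trace = tumor_only_somatic(cs([]), small_panel, cfg)
        assert out.records == []
        assert trace == FilterTrace(0, 0, 0, 0, 0)

    def test_requires_tumor_source(self, cfg, small_panel):
        with pytest.raises(ValueError, match="tumor"):
            tumor_only_somatic(cs([], source="normal"), small_panel, cfg)

    def test_trace_rejects_increasing_counts(self):
        with pytest.raises(ValueError):
            FilterTrace(5, 6, 4, 3, 2)


IDEAL = SimParams(
    true_tmb=8.0, n_germline_het=400, n_germline_hom=200, n_noise=0,
    qual_low_frac=0.0, het_vaf_sd=0.02, recoverable_frac=1.0, seed=41,
)


class TestMatchedSubtraction:
    def test_tumor_private_kept_shared_removed(self, cfg):
        shared = rec(pos=10)
        private = rec(pos=20)
        tumor = cs([shared, private], source="tumor")
        normal = cs([rec(pos=10, vaf=0.48)], source="normal")
        out = matched_subtraction(tumor, normal, cfg)
        assert [r.pos for r in out.records] == [20]

    def test_requires_matching_sources(self, cfg):
        with pytest.raises(ValueError):
            matched_subtraction(cs([], "normal"), cs([], "normal"), cfg)
        with pytest.raises(ValueError):
            matched_subtraction(cs([], "tumor"), cs([], "tumor"), cfg)

    def test_recovers_ground_truth_on_synthetic_pair(self, cfg):
        """With every somatic record passing stage 1, subtraction returns
        exactly the simulated somatic keys."""
        tumor, normal, truth = generate_matched_pair(IDEAL)
        out = matched_subtraction(tumor, normal, cfg)
        assert out.keys() == set(truth.true_somatic_keys)

    def test_ideal_pair_both_workflows_agree_exactly(self, cfg):
        """Full panel coverage + recoverable VAFs + no noise: the tumor-only
        route returns the same key set as matched subtraction."""
        from tmbkit.simulate import GermlinePool

        pool_rng = np.random.default_rng(5)
        pool = GermlinePool.generate(2000, frac_common=0.7, rng=pool_rng)
        tumor, normal, truth = generate_matched_pair(IDEAL, pool=pool)
        only, _ = tumor_only_somatic(tumor, pool.to_panel(), cfg)
        sub = matched_subtraction(tumor, normal, cfg)
        assert only.keys() == sub.keys() == set(truth.true_somatic_keys)

    def test_all_germline_callset_filters_to_empty(self, cfg):
        """A callset of nothing but germline variants (ideal VAFs, full
        panel coverage) is emptied by the three-level strategy."""
        from tmbkit.simulate import GermlinePool

        params = SimParams(true_tmb=0.0, n_germline_het=300, n_germline_hom=150,
                           n_noise=0, qual_low_frac=0.0, seed=42)
        pool = GermlinePool.generate(1000, 0.7, np.random.default_rng(6))
        tumor, _, _ = generate_matched_pair(params, pool=pool)
        out, _ = tumor_only_somatic(tumor, pool.to_panel(), cfg)
        assert out.records == []
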