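"""Filtering cascade: per-stage rules, the hand-derived micro-cohort, and
order-independence of the set-filter stages."""

import itertools
import random
from math import comb

import pytest

from ctlong.config import FilterConfig
from ctlong.core_io import IntervalSet
from ctlong import filtering
from ctlong.filtering import (call_plasma_candidates, filter_base_quality,
                              filter_blacklist, filter_cp_controls,
                              filter_dbsnp_only, filter_exonic_function,
                              filter_germline, filter_multiallelic,
                              filter_strand_bias, flag_population_af,
                              record_key, run_cascade)
from conftest import make_variant


def fisher_two_sided_oracle(a, b, c, d):
    """Independent two-sided Fisher p by hypergeometric point-mass summation."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def pmf(x):
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


class TestCallRule:
    def test_three_reads_both_strands_called(self):
        rec = make_variant("chr1", 10, "A", "T", "P1", 2, 1)
        called, _ = call_plasma_candidates([rec])
        assert called == [rec]

    def test_one_strand_only_not_called(self):
        rec = make_variant("chr1", 10, "A", "T", "P1", 3, 0)
        called, dropped = call_plasma_candidates([rec])
        assert called == [] and record_key(rec) in dropped

    def test_tumour_rescue(self):
        rec = make_variant("chr1", 10, "A", "T", "P1", 1, 0)
        tum = make_variant("chr1", 10, "A", "T", "T1", 3, 2)
        called, _ = call_plasma_candidates([rec], [tum])
        assert called == [rec]

    def test_no_tumour_disables_rescue(self):
        rec = make_variant("chr1", 10, "A", "T", "P1", 1, 0)
        called, _ = call_plasma_candidates([rec], None)
        assert called == []


class TestSetFilters:
    def test_dbsnp_only_dropped(self):
        drop = make_variant("chr1", 1, "A", "T", "S", 3, 3, dbsnp_id="rs123")
        keep1 = make_variant("chr1", 2, "A", "T", "S", 3, 3,
                             cosmic_id="COSV1", dbsnp_id="rs123")
        keep2 = make_variant("chr1", 3, "A", "T", "S", 3, 3)
        kept, dropped = filter_dbsnp_only([drop, keep1, keep2])
        assert kept == [keep1, keep2] and record_key(drop) in dropped

    @pytest.mark.parametrize("fn,kept", [
        ("nonsynonymous", True), ("synonymous", False), ("unknown", False),
        ("stopgain", True), ("stoploss", True), (None, False)])
    def test_exonic_function(self, fn, kept):
        rec = make_variant("chr1", 1, "A", "T", "S", 3, 3, exonic_function=fn)
        out, _ = filter_exonic_function([rec])
        assert (out == [rec]) is kept

    @pytest.mark.parametrize("bq,kept", [(25.0, True), (24.9, False), (60.0, True)])
    def test_base_quality_boundary(self, bq, kept):
        rec = make_variant("chr1", 1, "A", "T", "S", 3, 3, bq=bq)
        out, _ = filter_base_quality([rec])
        assert (out == [rec]) is kept

    @pytest.mark.parametrize("depth,alt,kept,reason", [
        (25, 0, True, None),
        (25, 1, False, "alt read"),
        (19, 0, False, "undercovered"),
    ])
    def test_germline_rule(self, depth, alt, kept, reason):
        cand = make_variant("chr1", 100, "A", "T", "P1", 5, 5)
        germ = make_variant("chr1", 100, "A", "T", "GL", alt, 0,
                            ref_fwd=depth - alt, ref_rev=0)
        out, dropped = filter_germline([cand], [germ])
        assert (out == [cand]) is kept
        if reason:
            assert reason in dropped[record_key(cand)]

    def test_germline_missing_locus_dropped(self):
        cand = make_variant("chr1", 100, "A", "T", "P1", 5, 5)
        out, dropped = filter_germline([cand], [])
        assert out == [] and "depth 0" in dropped[record_key(cand)]

    def test_germline_undercovered_keep_switch(self):
        cand = make_variant("chr1", 100, "A", "T", "P1", 5, 5)
        cfg = FilterConfig(germline_undercovered="keep")
        out, _ = filter_germline([cand], [], cfg)
        assert out == [cand]

    def test_cp_controls(self):
        hit = make_variant("chr1", 1, "A", "T", "P1", 5, 5)
        clean = make_variant("chr1", 2, "A", "T", "P1", 5, 5)
        cp = [make_variant("chr1", 1, "A", "T", "CP1", 1, 0),
              make_variant("chr1", 2, "A", "T", "CP1", 0, 0,
                           ref_fwd=250, ref_rev=250)]
        kept, dropped = filter_cp_controls([hit, clean], cp)
        assert kept == [clean] and record_key(hit) in dropped

    def test_no_cp_samples_keeps_all(self):
        rec = make_variant("chr1", 1, "A", "T", "P1", 5, 5)
        kept, _ = filter_cp_controls([rec], [])
        assert kept == [rec]

    def test_multiallelic_across_serial_plasma(self):
        a = make_variant("chr1", 100, "A", "T", "P1", 5, 5)
        b = make_variant("chr1", 100, "A", "G", "P3", 5, 5)
        c = make_variant("chr2", 100, "A", "T", "P1", 5, 5)
        kept, dropped = filter_multiallelic([a, b, c])
        assert kept == [c]
        assert record_key(a) in dropped and record_key(b) in dropped

    def test_single_alt_across_timepoints_kept(self):
        recs = [make_variant("chr1", 100, "A", "T", s, 5, 5)
                for s in ("P1", "P2", "P4")]
        kept, _ = filter_multiallelic(recs)
        assert kept == recs

    @pytest.mark.parametrize("af,flagged", [(0.001, True), (0.0, False), (None, False)])
    def test_population_af_flag_not_drop(self, af, flagged):
        rec = make_variant("chr1", 1, "A", "T", "S", 5, 5, af_gnomad=af)
        kept, dropped = flag_population_af([rec])
        assert kept == [rec] and not dropped
        assert ("pop_af" in rec.flags) is flagged

    @pytest.mark.parametrize("pos,dropped", [(150, True), (100, False), (200, True)])
    def test_blacklist_bed_convention(self, pos, dropped):
        bl = IntervalSet([("chr1", 100, 200)])
        rec = make_variant("chr1", pos, "A", "T", "S", 5, 5)
        kept, _ = filter_blacklist([rec], bl)
        assert (kept == []) is dropped


class TestStrandBias:
    def test_biased_variant_dropped_fisher_oracle(self):
        rec = make_variant("chr1", 1, "A", "T", "S", 30, 0,
                           ref_fwd=100, ref_rev=100)
        p = fisher_two_sided_oracle(100, 100, 30, 0)
        assert p < 0.01  # the independent oracle agrees the table is extreme
        kept, dropped = filter_strand_bias([rec])
        assert kept == [] and record_key(rec) in dropped

    def test_balanced_variant_kept(self):
        rec = make_variant("chr1", 1, "A", "T", "S", 15, 15,
                           ref_fwd=100, ref_rev=100)
        kept, _ = filter_strand_bias([rec])
        assert kept == [rec]

    def test_low_depth_spared(self):
        rec = make_variant("chr1", 1, "A", "T", "S", 1, 0, ref_fwd=10, ref_rev=10)
        p = fisher_two_sided_oracle(10, 10, 1, 0)
        assert p > 0.01
        kept, _ = filter_strand_bias([rec])
        assert kept == [rec]

    def test_scipy_agrees_with_oracle(self):
        for table in [(100, 100, 30, 0), (10, 10, 1, 0), (50, 60, 7, 1),
                      (5, 5, 3, 3)]:
            rec = make_variant("chr1", 1, "A", "T", "S", table[2], table[3],
                               ref_fwd=table[0], ref_rev=table[1])
            assert filtering.strand_bias_test(rec) == \
                pytest.approx(fisher_two_sided_oracle(*table), rel=1e-9)


class TestCascade:
    def test_micro_cohort_survivors_and_stages(self, filter_fixture):
        f = filter_fixture
        report = run_cascade(f["plasma"], germline_records=f["germline"],
                             tumour_records=f["tumour"], cp_records=f["cp"],
                             blacklist=f["blacklist"], patient_id="TOY")
        assert {r.key for r in report.survivors} == f["expected_survivors"]
        for key, stage in f["designed_stage"].items():
            assert report.dropped_at(key) == stage, key
        # the rescue-eligible variant survived the call stage
        assert ("chr2", 20000, "A", "G", "TOY_P1") not in report.stage("call").dropped
        # the population-AF survivor is flagged but retained
        flagged = [r for r in report.survivors if "pop_af" in r.flags]
        assert [r.key for r in flagged] == [("chr4", 40000, "T", "A")]

    def test_monotonicity(self, filter_fixture):
        f = filter_fixture
        report = run_cascade(f["plasma"], germline_records=f["germline"],
                             tumour_records=f["tumour"], cp_records=f["cp"],
                             blacklist=f["blacklist"])
        for s in report.stages:
            assert s.n_out <= s.n_in
            assert s.n_out + len(s.dropped) == s.n_in

    def test_stage_permutation_leaves_final_set_unchanged(self, filter_fixture):
        """Stages 2-9 are per-variant predicates; their order cannot matter."""
        f = filter_fixture
        cfg = FilterConfig()
        called, _ = call_plasma_candidates(
            [r for r in f["plasma"] if r.is_snv], f["tumour"], cfg)
        universe = list(called)
        stages = [
            lambda recs: filter_dbsnp_only(recs, cfg)[0],
            lambda recs: filter_exonic_function(recs, cfg)[0],
            lambda recs: filter_base_quality(recs, cfg)[0],
            lambda recs: filter_germline(recs, f["germline"], cfg)[0],
            lambda recs: filter_cp_controls(recs, f["cp"], cfg)[0],
            lambda recs: filter_multiallelic(recs, universe, cfg)[0],
            lambda recs: filter_blacklist(recs, f["blacklist"], cfg)[0],
            lambda recs: filter_strand_bias(recs, cfg)[0],
        ]
        reference = None
        rng = random.Random(0)
        orders = [list(range(8))] + \
            [rng.sample(range(8), 8) for _ in range(10)]
        for order in orders:
            current = list(called)
            for i in order:
                current = stages[i](current)
            keys = {record_key(r) for r in current}
            if reference is None:
                reference = keys
            assert keys == reference

    def test_empty_input(self):
        report = run_cascade([])
        assert report.survivors == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)
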