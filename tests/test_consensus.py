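import itertools
import random

import numpy as np
import pytest

from cnvmeta import (
    BinDecision,
    CallerRole,
    CallerTrack,
    CnClass,
    ConsensusSegment,
    IntervalCall,
    PloidyModel,
    Thresholds,
    ValueScale,
    call_consensus,
    classify_cn,
    decide_bin,
    error_score,
    merge_segments,
    referee_class,
    round1,
    union_breakpoints,
)
from cnvmeta.core import validate_segments

TH = Thresholds(t1=1.85, t2=2.15, ploidy=2)


def track(intervals, role=CallerRole.COVERAGE, scale=ValueScale.ABSOLUTE_CN):
    calls = [IntervalCall("1", s, e, v) for s, e, v in intervals]
    return CallerTrack(role, scale, calls)


class TestUnionBreakpoints:
    def test_endpoint_union(self):
        cov = track([(0, 100, 2.0), (100, 200, 2.0)])
        hyb = track([(0, 150, 2.0)], CallerRole.HYBRID, ValueScale.RATIO_VS_NULL)
        part = union_breakpoints([cov, hyb]).chroms["1"]
        assert part.starts.tolist() == [0, 100, 150]
        assert part.ends.tolist() == [100, 150, 200]
        # hybrid covers the first two bins only
        assert not np.isnan(part.values[1][:2]).any()
        assert np.isnan(part.values[1][2])

    def test_union_is_idempotent_on_identical_tracks(self):
        cov = track([(0, 100, 2.0), (100, 250, 3.0)])
        part = union_breakpoints([cov, track([(0, 100, 1.0), (100, 250, 1.0)])])
        assert part.chroms["1"].starts.tolist() == [0, 100]

    def test_empty_second_track_leaves_first_partition(self):
        cov = track([(0, 100, 2.0), (100, 200, 2.5)])
        empty = CallerTrack(CallerRole.HYBRID, ValueScale.RATIO_VS_NULL, [])
        part = union_breakpoints([cov, empty]).chroms["1"]
        assert part.starts.tolist() == [0, 100]

    def test_uncovered_middle_bin_is_kept(self):
        cov = track([(0, 100, 2.0), (300, 400, 2.0)])
        part = union_breakpoints([cov]).chroms["1"]
        assert part.starts.tolist() == [0, 100, 300]
        assert np.isnan(part.values[0][1])  # the gap bin has no value


class TestClassification:
    @pytest.mark.parametrize(
        "cn, expected",
        [
            (1.5, CnClass.DELETION),
            (1.85, CnClass.NORMAL),   # boundary values are normal
            (2.0, CnClass.NORMAL),
            (2.15, CnClass.NORMAL),
            (2.4, CnClass.AMPLIFICATION),
        ],
    )
    def test_classify_cn(self, cn, expected):
        assert classify_cn(cn, TH) is expected

    @pytest.mark.parametrize(
        "value, expected",
        [
            (44084, CnClass.AMPLIFICATION),
            (0, CnClass.DELETION),
            (2, None),          # exactly ploidy: no evidence
            (None, None),
        ],
    )
    def test_referee_direction(self, value, expected):
        assert referee_class(value, ploidy=2) is expected

    def test_explicit_class_passes_through(self):
        assert referee_class(None, 2, explicit=CnClass.DELETION) is CnClass.DELETION


class TestErrorScore:
    @pytest.mark.parametrize(
        "rd, sv, expected",
        [
            (3.0, 3.0, 0.0),
            (1.0, 3.0, 4.0),
            (None, 2.0, 4.0),   # missing coverage counts as CN 0
            (3.0, None, 1.0),   # missing hybrid counts as the ploidy
            (None, None, 4.0),
        ],
    )
    def test_gap_conventions(self, rd, sv, expected):
        assert error_score(rd, sv, ploidy=2) == expected


# values representative of each class under TH
VAL = {CnClass.DELETION: 0.5, CnClass.NORMAL: 2.0, CnClass.AMPLIFICATION: 3.5}


def expected_rule_table(rd, sv, ref, P=2):
    """Independent restatement of the consensus rules (test oracle)."""
    if rd is None and sv is None:
        return float(P)
    if sv is None:
        return rd
    if rd is None:
        return sv
    crd, csv = classify_cn(rd, TH), classify_cn(sv, TH)
    if crd == csv:
        return sv if crd is CnClass.AMPLIFICATION else rd
    if ref is None:
        return float(P)
    if ref == crd:
        return rd
    if ref == csv:
        return sv
    return float(P)


class TestDecideBin:
    def test_exhaustive_rule_grid(self):
        """decide_bin is total and matches the rule table on all cells."""
        rd_opts = [None] + [VAL[c] for c in CnClass]
        sv_opts = [None] + [VAL[c] for c in CnClass]
        ref_opts = [None, CnClass.DELETION, CnClass.AMPLIFICATION]
        for rd, sv, ref in itertools.product(rd_opts, sv_opts, ref_opts):
            if rd is None and sv is None:
                continue
            d = decide_bin(rd, sv, ref, TH, 2)
            assert d.cn_meta == expected_rule_table(rd, sv, ref)
            assert d.error_score == error_score(rd, sv, 2)

    def test_no_evidence_bin(self):
        d = decide_bin(None, None, None, TH, 2)
        assert d.cn_meta == 2.0 and d.rule_id == "no_evidence"

    @pytest.mark.parametrize(
        "rd, sv, ref, expected_cn, rule",
        [
            (3.5, 3.8, None, 3.8, "agree_amplification"),   # amp value from hybrid
            (0.5, 0.8, None, 0.5, "agree_deletion"),        # del value from coverage
            (2.0, 2.1, None, 2.0, "agree_normal"),
            (3.5, None, None, 3.5, "coverage_only"),        # amp stands without hybrid
            (None, 3.8, None, 3.8, "hybrid_only"),
            (3.5, 2.0, CnClass.AMPLIFICATION, 3.5, "conflict_referee_coverage"),
            (2.0, 3.8, CnClass.AMPLIFICATION, 3.8, "conflict_referee_hybrid"),
            (3.5, 2.0, None, 2.0, "conflict_no_referee"),
            (2.0, 0.5, CnClass.AMPLIFICATION, 2.0, "conflict_referee_mismatch"),
        ],
    )
    def test_named_rules(self, rd, sv, ref, expected_cn, rule):
        d = decide_bin(rd, sv, ref, TH, 2)
        assert (d.cn_meta, d.rule_id) == (expected_cn, rule)


def bin_dec(start, end, cn, e=0.0, chrom="1", rule="agree_normal"):
    return BinDecision(chrom, start, end, cn, cn, None, cn, e, rule)


class TestMergeSegments:
    def test_weighted_means(self):
        segs = merge_segments([bin_dec(0, 100, 2.04, e=0.0), bin_dec(100, 400, 2.01, e=4.0)])
        assert len(segs) == 1
        assert segs[0].cn_meta == pytest.approx(0.25 * 2.04 + 0.75 * 2.01)
        assert segs[0].error_score == pytest.approx(3.0)

    def test_one_decimal_rule_blocks_merge(self):
        segs = merge_segments([bin_dec(0, 100, 2.04), bin_dec(100, 200, 2.16)])
        assert len(segs) == 2

    def test_single_bin_identity(self):
        segs = merge_segments([bin_dec(0, 100, 3.3, e=1.5)])
        assert segs == [ConsensusSegment("1", 0, 100, 3.3, 1.5, "agree_normal")]

    def test_non_adjacent_bins_do_not_merge(self):
        segs = merge_segments([bin_dec(0, 100, 2.0), bin_dec(200, 300, 2.0)])
        assert len(segs) == 2

    def _naive_merge(self, decisions):
        """Quadratic reference: repeatedly fuse any adjacent mergeable pair."""
        segs = [[d.chrom, d.start, d.end, d.cn_meta, d.error_score] for d in decisions]
        changed = True
        while changed:
            changed = False
            for i in range(len(segs) - 1):
                a, b = segs[i], segs[i + 1]
                if a[0] == b[0] and a[2] == b[1] and round1(a[3]) == round1(b[3]):
                    la, lb = a[2] - a[1], b[2] - b[1]
                    cn = (a[3] * la + b[3] * lb) / (la + lb)
                    e = (a[4] * la + b[4] * lb) / (la + lb)
                    segs[i:i + 2] = [[a[0], a[1], b[2], cn, e]]
                    changed = True
                    break
        return segs

    def test_agrees_with_naive_merge_on_random_runs(self):
        rng = random.Random(42)
        for _ in range(200):
            decisions, pos = [], 0
            for _ in range(rng.randint(1, 15)):
                if rng.random() < 0.2:
                    pos += rng.randint(1, 50)  # occasional gap
                length = rng.randint(10, 500)
                cn = rng.choice([0.5, 1.97, 2.0, 2.02, 2.11, 3.4])
                decisions.append(bin_dec(pos, pos + length, cn, e=rng.random()))
                pos += length
            got = merge_segments(decisions)
            want = self._naive_merge(decisions)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert (g.chrom, g.start, g.end) == (w[0], w[1], w[2])
                assert g.cn_meta == pytest.approx(w[3])
                assert g.error_score == pytest.approx(w[4])
            validate_segments(got)


class TestCallConsensus:
    def test_rule_reproduction_on_hand_built_scenario(self, arbitration_scenario):
        res = call_consensus(arbitration_scenario.coverage, arbitration_scenario.hybrid, arbitration_scenario.referee)
        by_bin = {s.start: s for s in res.segments}
        th = res.thresholds
        # b (conflict, referee silent) folded into the normal segment at CN 2
        assert by_bin[0].end == 200 and by_bin[0].cn_meta == pytest.approx(2.0)
        assert classify_cn(by_bin[200].cn_meta, th) is CnClass.AMPLIFICATION   # c
        assert classify_cn(by_bin[300].cn_meta, th) is CnClass.DELETION        # d
        assert classify_cn(by_bin[400].cn_meta, th) is CnClass.AMPLIFICATION   # e
        assert classify_cn(by_bin[500].cn_meta, th) is CnClass.AMPLIFICATION   # f
        assert classify_cn(by_bin[600].cn_meta, th) is CnClass.AMPLIFICATION   # g

    def test_removing_referee_flips_arbitrated_bins_to_ploidy(self, arbitration_scenario):
        res = call_consensus(arbitration_scenario.coverage, arbitration_scenario.hybrid, None)
        by_bin = {s.start: s for s in res.segments}
        assert by_bin[400].cn_meta == pytest.approx(2.0)
        assert by_bin[600].cn_meta == pytest.approx(2.0)

    def test_identical_constant_tracks_collapse_to_one_segment(self):
        vals = [(i * 100, (i + 1) * 100, 2.0) for i in range(20)]
        cov = track(vals)
        res = call_consensus(cov, None, None)
        assert len(res.segments) == 1
        seg = res.segments[0]
        assert seg.cn_meta == pytest.approx(2.0)
        # hybrid absent everywhere: error uses the ploidy convention -> 0
        assert seg.error_score == pytest.approx(0.0)

    def test_partition_conservation(self, small_scenario):
        sc = small_scenario
        res = call_consensus(sc.coverage, sc.hybrid, sc.referee)
        part = union_breakpoints([sc.coverage, sc.hybrid, sc.referee])
        assert sum(s.length for s in res.segments) == part.covered_length
        validate_segments(res.segments)
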