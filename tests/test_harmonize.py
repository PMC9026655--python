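"""Harmonization rules, filters and their conservation properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from conftest import brute_force_embedded, make_call
from svconcord.harmonize import (
    ASSEMBLY_DISCORDANCE,
    EMBEDDED,
    EXCLUDED_REGION,
    LOW_QUALITY,
    NO_CONFIDENCE,
    SIZE_LE_MIN,
    calls_to_frame,
    filter_bionano,
    filter_ont,
    frame_to_calls,
    harmonize_bionano,
    harmonize_ont,
    resolve_embedded,
)
from svconcord.io import BionanoVariant, DiffRecord


def gap(ref_gap, query_gap, start=1000, end=None, chrom="chr1"):
    end = end if end is not None else start + max(ref_gap, 1) - 1
    return DiffRecord(
        ref_seq=chrom, feature_type="GAP", ref_start=start, ref_end=end,
        ref_gap_len=ref_gap, query_gap_len=query_gap,
        gap_diff=ref_gap - query_gap,
    )


class TestHarmonizeOnt:
    @pytest.mark.parametrize(
        "ref_gap,query_gap,sv_type,size",
        [
            (101, 2101, "INS", 2101),   # query gap dominates -> insertion
            (5000, 40, "DEL", 5000),    # reference gap dominates -> deletion
            (300, 300, "DEL", 300),     # tie counts as deletion
            (-5, 900, "INS", 900),      # negative reference gap, real insertion
        ],
    )
    def test_gap_decision_rule(self, ref_gap, query_gap, sv_type, size):
        report = harmonize_ont([gap(ref_gap, query_gap)])
        (call,) = report.retained
        assert (call.sv_type, call.size) == (sv_type, size)

    def test_gap_rule_matches_sign_case_enumeration(self):
        # exhaustive check of the four sign quadrants against the stated rule
        for ref_gap in (-10, 0, 7, 40):
            for query_gap in (-10, 0, 7, 40):
                report = harmonize_ont([gap(ref_gap, query_gap)])
                if ref_gap <= 0 and query_gap <= 0:
                    assert report.removed[0][1] == ASSEMBLY_DISCORDANCE
                elif query_gap > ref_gap:
                    assert report.retained[0].sv_type == "INS"
                    assert report.retained[0].size == query_gap
                else:
                    assert report.retained[0].sv_type == "DEL"
                    assert report.retained[0].size == ref_gap

    @pytest.mark.parametrize("ftype", ["SEQ", "BRK", "JMP"])
    def test_discordance_types_removed(self, ftype):
        rec = DiffRecord(
            ref_seq="chr1", feature_type=ftype, ref_start=10, ref_end=20,
            ref_gap_len=11,
        )
        report = harmonize_ont([rec])
        assert report.retained == []
        assert report.removed == [(rec, ASSEMBLY_DISCORDANCE)]

    def test_inv_and_dup_sized_by_reference_span(self):
        recs = [
            DiffRecord("chr1", "INV", 100, 399, 300),
            DiffRecord("chr1", "DUP", 500, 599, 100),
        ]
        report = harmonize_ont(recs)
        assert [(c.sv_type, c.size) for c in report.retained] == [
            ("INV", 300), ("DUP", 100),
        ]

    def test_conservation(self):
        recs = [gap(10, 5), gap(-1, -1), DiffRecord("chr1", "SEQ", 1, 2, 2)]
        report = harmonize_ont(recs)
        assert report.input_count == len(recs)


class TestFilterOnt:
    def test_size_filter_is_strict(self, mk):
        calls = [mk("a", 1, 10, size=1000), mk("b", 20, 30, size=1001)]
        report = filter_ont(calls, min_size=1000)
        assert [c.call_id for c in report.retained] == ["b"]
        assert report.removed[0][1] == SIZE_LE_MIN

    def test_exclusion_regions(self, mk):
        calls = [mk("a", 100, 200, size=5000), mk("b", 900, 950, size=5000)]
        report = filter_ont(calls, exclusions=[("chr1", 150, 160)])
        assert [c.call_id for c in report.retained] == ["b"]
        assert report.removed[0][1] == EXCLUDED_REGION

    def test_identity_with_zero_threshold(self, mk):
        calls = [mk(f"c{i}", i * 10, i * 10 + 5, size=i + 1) for i in range(5)]
        report = filter_ont(calls, min_size=0)
        assert report.retained == calls

    def test_negative_min_size_rejected(self, mk):
        with pytest.raises(ValueError):
            filter_ont([], min_size=-1)

    @given(
        sizes=hst.lists(hst.integers(min_value=1, max_value=5000), max_size=50),
        t1=hst.integers(min_value=0, max_value=5000),
        t2=hst.integers(min_value=0, max_value=5000),
    )
    def test_conservation_monotonicity_idempotence(self, sizes, t1, t2):
        calls = [
            make_call(f"c{i}", 10 * i + 1, 10 * i + 5, size=s)
            for i, s in enumerate(sizes)
        ]
        lo, hi = sorted((t1, t2))
        rep_lo, rep_hi = filter_ont(calls, lo), filter_ont(calls, hi)
        assert rep_lo.input_count == len(calls)
        assert len(rep_hi.retained) <= len(rep_lo.retained)
        again = filter_ont(rep_lo.retained, lo)
        assert again.retained == rep_lo.retained and not again.removed


class TestHarmonizeBionano:
    def test_extended_interval_from_uncertainty(self):
        var = BionanoVariant(
            chrom="chr1", pos=1000, end=2000, sv_type="deletion", size=1001,
            cipos=(-50, 50), ciend=(-30, 30),
        )
        (call,) = harmonize_bionano([var])
        assert (call.ext_start, call.ext_end) == (950, 2030)
        assert (call.ref_start, call.ref_end) == (1000, 2000)

    def test_zero_uncertainty_is_identity(self):
        var = BionanoVariant("chr1", 1000, 2000, "deletion", 1001)
        (call,) = harmonize_bionano([var])
        assert (call.ext_start, call.ext_end) == (1000, 2000)

    def test_extended_start_clipped_to_one(self, caplog):
        var = BionanoVariant("chr1", 10, 400, "deletion", 391, cipos=(-50, 0))
        with caplog.at_level("WARNING"):
            (call,) = harmonize_bionano([var])
        assert call.ext_start == 1
        assert "clipping" in caplog.text


class TestFilterBionano:
    def test_small_low_quality_del_removed_as_size(self, mk):
        call = mk("d", 1, 900, sv_type="DEL", size=900, quality=8)
        report = filter_bionano([call])
        assert report.removed == [(call, SIZE_LE_MIN)]

    def test_low_quality_removed_when_large(self, mk):
        call = mk("d", 1, 2000, sv_type="DEL", size=2000, quality=8)
        report = filter_bionano([call])
        assert report.removed == [(call, LOW_QUALITY)]

    def test_absent_quality_does_not_remove_ins_del(self, mk):
        call = mk("d", 1, 2000, sv_type="INS", size=2000)
        assert filter_bionano([call]).retained == [call]

    def test_inv_without_confidence_discarded(self, mk):
        call = mk("i", 1, 60_000, sv_type="INV", size=60_000)
        report = filter_bionano([call])
        assert report.removed == [(call, NO_CONFIDENCE)]

    @pytest.mark.parametrize(
        "sv_type,confidence,kept",
        [
            ("TRA", 0.5, True), ("TRA", 0.05, False),
            ("INV", 0.02, True), ("INV", 0.005, False),
        ],
    )
    def test_confidence_cutoffs(self, mk, sv_type, confidence, kept):
        call = mk(
            "x", 1, 10_000, source="BIONANO", sv_type=sv_type, size=10_000,
            confidence=confidence,
        )
        report = filter_bionano([call])
        assert (len(report.retained) == 1) is kept


class TestResolveEmbedded:
    def test_smaller_of_nested_pair_removed(self, mk):
        outer = mk("a", 100, 10_000)
        inner = mk("b", 2000, 3000)
        report = resolve_embedded([outer, inner])
        assert report.retained == [outer]
        assert report.removed == [(inner, EMBEDDED)]

    def test_disjoint_calls_kept(self, mk):
        calls = [mk("a", 1, 10), mk("b", 20, 30)]
        assert resolve_embedded(calls).retained == calls

    def test_transitive_nesting_keeps_outermost(self, mk):
        calls = [mk("c", 40, 60), mk("b", 20, 80), mk("a", 1, 100)]
        report = resolve_embedded(calls)
        assert [c.call_id for c in report.retained] == ["a"]

    def test_identical_intervals_keep_first_id(self, mk):
        calls = [mk("b", 10, 20), mk("a", 10, 20)]
        report = resolve_embedded(calls)
        assert [c.call_id for c in report.retained] == ["a"]

    @given(
        spans=hst.lists(
            hst.tuples(
                hst.integers(min_value=1, max_value=300),
                hst.integers(min_value=0, max_value=100),
                hst.sampled_from(["chr1", "chr2"]),
            ),
            max_size=200,
        )
    )
    def test_matches_bruteforce_containment_oracle(self, spans):
        calls = [
            make_call(f"c{i:03d}", s, s + l, chrom=ch)
            for i, (s, l, ch) in enumerate(spans)
        ]
        report = resolve_embedded(calls)
        got = {item.call_id for item, _ in report.removed}
        assert got == brute_force_embedded(calls)


def test_call_frame_roundtrip(mk):
    calls = [
        mk("a", 1, 10, sv_type="INS", size=99, quality=12),
        mk("b", 5, 50, sv_type="TRA", source="BIONANO", confidence=0.25,
           ext=(1, 60)),
    ]
    assert frame_to_calls(calls_to_frame(calls)) == calls
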