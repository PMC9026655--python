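"""Summary tables, rank-sum test vs enumeration, bin tracks, labelling."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from conftest import exact_wilcoxon_less, make_call
from svconcord.concordance import classify
from svconcord.harmonize import BIONANO
from svconcord.stats import (
    bin_occurrences,
    compare_size_distributions,
    insilico_label_density,
    summarize_by_class,
    summarize_by_type,
)


class TestSummarizeByType:
    def test_single_type_arithmetic(self, mk):
        calls = [
            mk(f"c{i}", 1 + 10 * i, 5 + 10 * i, sv_type="DEL", size=s)
            for i, s in enumerate([2000, 3000, 4000])
        ]
        df = summarize_by_type(calls)
        row = df.loc["DEL"]
        assert row["count"] == 3
        assert row["cumulated_mb"] == 0.0  # 9000 bp rounds to 0.0 Mb
        assert row["median_bp"] == 3000
        assert row["average_bp"] == 3000
        assert df.loc["TOTAL", "percent"] == 100.0

    def test_one_call_is_hundred_percent(self, mk):
        df = summarize_by_type([mk("c", 1, 5, sv_type="INS", size=1001)])
        assert df.loc["INS", "percent"] == 100.0

    def test_even_count_median_is_midpoint(self, mk):
        calls = [
            mk(f"c{i}", 1 + 10 * i, 2 + 10 * i, sv_type="INS", size=s)
            for i, s in enumerate([1000, 2000, 4000, 9000])
        ]
        assert summarize_by_type(calls).loc["INS", "median_bp"] == 3000

    def test_empty_input(self):
        df = summarize_by_type([])
        assert df.loc["TOTAL", "count"] == 0
        assert np.isnan(df.loc["TOTAL", "median_bp"])

    def test_invariant_under_permutation(self, mk):
        calls = [
            mk(f"c{i}", 1 + 10 * i, 5 + 10 * i,
               sv_type="INS" if i % 2 else "DEL", size=100 + i)
            for i in range(9)
        ]
        a = summarize_by_type(calls).to_csv()
        b = summarize_by_type(calls[::-1]).to_csv()
        assert a == b


class TestSummarizeByClass:
    def _bn(self, call_id, start, end):
        return make_call(call_id, start, end, source=BIONANO)

    def test_toy_common_specific_split(self, mk):
        groups = classify(
            [mk("o1", 100, 200), mk("o2", 10_000, 10_100)],
            [self._bn("b1", 150, 250), self._bn("b2", 50_000, 50_100)],
        )
        df = summarize_by_class(groups)
        assert df.loc["ONT_common", "count"] == 1
        assert df.loc["ONT_specific", "count"] == 1
        assert df.loc["BIONANO_common", "count"] == 1
        assert df.loc["BIONANO_specific", "count"] == 1

    def test_mu_counts_members_and_locations(self, mk):
        groups = classify(
            [mk("o1", 100, 200), mk("o2", 300, 400), mk("o3", 500, 600)],
            [self._bn("b", 150, 550)],
        )
        df = summarize_by_class(groups)
        assert df.loc["MU_ONT", "locations"] == 1
        assert df.loc["MU_ONT", "count"] == 3
        assert df.loc["MU_BIONANO", "count"] == 1

    def test_planted_percentages(self, mk):
        # 10 UU + 5 UN: the ONT split must read 66.7 / 33.3
        ont = [mk(f"o{i}", 1000 * i, 1000 * i + 100) for i in range(1, 16)]
        bio = [self._bn(f"b{i}", 1000 * i, 1000 * i + 100) for i in range(1, 11)]
        df = summarize_by_class(classify(ont, bio))
        assert df.loc["ONT_common", "percent"] == 66.7
        assert df.loc["ONT_specific", "percent"] == 33.3


class TestSizeComparison:
    def test_exact_p_one_sixth(self):
        res = compare_size_distributions([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_samples_not_significant(self):
        res = compare_size_distributions([5, 1], [4, 2])
        assert res.p_value >= 0.5

    def test_reversed_singletons_p_one(self):
        res = compare_size_distributions([5], [1])
        assert res.p_value == pytest.approx(1.0)

    def test_large_event_cutoff_excludes_both_sides(self):
        res = compare_size_distributions(
            [1000, 2000, 60_000], [3000, 4000, 70_000],
            large_event_cutoff=50_000,
        )
        assert (res.n_ont, res.n_bionano) == (2, 2)

    def test_empty_after_cutoff_is_error(self):
        with pytest.raises(ValueError):
            compare_size_distributions([60_000], [1000], large_event_cutoff=50_000)

    @given(
        nx=hst.integers(min_value=1, max_value=4),
        data=hst.data(),
    )
    def test_exact_method_matches_enumeration_oracle(self, nx, data):
        pool = data.draw(
            hst.lists(
                hst.integers(min_value=1, max_value=10_000),
                min_size=nx + 1, max_size=8, unique=True,
            )
        )
        x, y = pool[:nx], pool[nx:]
        res = compare_size_distributions(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(exact_wilcoxon_less(x, y))

    def test_power_when_bionano_strictly_larger(self):
        rng = np.random.default_rng(5)
        ont = rng.lognormal(8.0, 0.5, size=40)
        bio = ont * rng.uniform(1.4, 2.0, size=40)
        res = compare_size_distributions(list(ont), list(bio))
        assert res.p_value < 0.05


class TestBinTracks:
    LENGTHS = {"chr1": 300_000}

    def test_spanning_call_hits_both_bins(self, mk):
        track = bin_occurrences([mk("c", 150_000, 250_000)], self.LENGTHS)
        assert track.values["chr1"].tolist() == [0, 1, 1, 0]

    def test_empty_callset_all_zero(self):
        track = bin_occurrences([], self.LENGTHS)
        assert not track.values["chr1"].any()

    def test_boundary_position_bin(self, mk):
        track = bin_occurrences([mk("c", 100_000, 100_000)], self.LENGTHS)
        assert track.values["chr1"].tolist() == [0, 1, 0, 0]

    def test_call_beyond_chromosome_is_error(self, mk):
        with pytest.raises(ValueError, match="beyond"):
            bin_occurrences([mk("c", 1, 400_000)], self.LENGTHS)

    def test_bedgraph_export(self, mk, tmp_path):
        track = bin_occurrences([mk("c", 1, 5)], {"chr1": 150_000})
        out = tmp_path / "t.bedgraph"
        track.to_bedgraph(out)
        first = out.read_text().splitlines()[0].split("\t")
        assert first == ["chr1", "0", "100000", "1"]


class TestLabelDensity:
    def test_planted_motifs_found_in_right_bins(self):
        rng = np.random.default_rng(11)
        seq = list("".join(rng.choice(list("AG"), size=300_000)))
        for pos in (5_000, 150_000, 250_000):  # 1-based planting
            seq[pos - 1 : pos + 5] = "CTTAAG"
        labels, track = insilico_label_density({"chr1": "".join(seq)})
        assert labels["chr1"].tolist() == [5_000, 150_000, 250_000]
        assert track.values["chr1"].tolist() == [1, 1, 1, 0]

    def test_no_motif_no_labels(self):
        labels, track = insilico_label_density({"chr1": "A" * 1000})
        assert labels["chr1"].size == 0

    def test_back_to_back_motifs_both_counted(self):
        labels, _ = insilico_label_density({"c": "CTTAAGCTTAAG"})
        assert labels["c"].tolist() == [1, 7]

    def test_density_conserves_label_count(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500_000))
        labels, track = insilico_label_density({"chr1": seq})
        assert track.values["chr1"].sum() == labels["chr1"].size

    def test_degenerate_motif_rejected(self):
        with pytest.raises(ValueError):
            insilico_label_density({"c": "ACGT"}, motif="CTNAAG")
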