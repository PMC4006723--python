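"""Interval algebra, coordinate conventions and BED I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriscan.intervals import (
    BedParseError,
    GenomeLayout,
    Interval,
    IntervalSet,
    MappabilityMask,
    distance_to_nearest,
    merge_within,
    merged_footprint,
    overlaps,
    overlaps_any,
    read_bed,
    subtract,
    write_bed,
)

from .conftest import random_intervals


class TestLayoutAndInterval:
    def test_layout_rejects_bad_lengths(self):
        with pytest.raises(ValueError):
            GenomeLayout.from_dict({"chr1": 0})

    def test_layout_chrom_sizes_roundtrip(self, tmp_path, layout_two_chroms):
        p = tmp_path / "g.sizes"
        layout_two_chroms.to_chrom_sizes(p)
        back = GenomeLayout.from_chrom_sizes(p)
        assert back == layout_two_chroms

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (10, 2)])
    def test_interval_invariants(self, start, end):
        with pytest.raises(ValueError):
            Interval("chr1", start, end)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval("chr1", 100, 200), Interval("chr1", 150, 250), True),
            (Interval("chr1", 100, 200), Interval("chr1", 200, 300), False),
            (Interval("chr1", 100, 200), Interval("chr2", 150, 250), False),
            (Interval("chr1", 100, 200), Interval("chr1", 199, 500), True),
        ],
    )
    def test_overlap_is_half_open_and_chrom_aware(self, a, b, expected):
        assert overlaps(a, b) is expected
        assert overlaps(b, a) is expected


class TestBedIO:
    def test_parse_simple_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        iset = read_bed(p)
        assert iset.to_intervals() == [Interval("chr1", 100, 200)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_inverted_coordinates_error_carries_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)

    def test_unknown_chromosome_is_named(self, tmp_path, layout_1mb):
        p = tmp_path / "a.bed"
        p.write_text("chrUn\t10\t20\n")
        with pytest.raises(ValueError, match="chrUn"):
            read_bed(p, layout=layout_1mb)

    def test_write_single_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed(IntervalSet.from_intervals([Interval("chr1", 0, 10)]), p)
        assert p.read_text() == "chr1\t0\t10\t.\n"

    def test_roundtrip_random_intervals(self, tmp_path, rng, layout_two_chroms):
        iset = random_intervals(rng, 1000, layout_two_chroms)
        p = tmp_path / "r.bed"
        write_bed(iset, p)
        back = read_bed(p)
        assert back.same_intervals(iset)
        pd.testing.assert_frame_equal(
            back.df[["chrom", "start", "end"]], iset.df[["chrom", "start", "end"]]
        )

    def test_roundtrip_preserves_name_and_score(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [5], "end": [25], "name": ["ori_1"], "score": [42]}
        )
        p = tmp_path / "n.bed"
        write_bed(IntervalSet(df), p)
        back = read_bed(p)
        assert back.df["name"].iloc[0] == "ori_1"
        assert int(back.df["score"].iloc[0]) == 42


class TestMergeWithin:
    def test_clusters_origins_closer_than_gap(self):
        s = IntervalSet.from_intervals(
            [Interval("chr1", 0, 1000), Interval("chr1", 1500, 2500)]
        )
        out = merge_within(s, 12000)
        assert out.to_intervals()[0] == Interval("chr1", 0, 2500, ".")
        assert len(out) == 1

    def test_leaves_distant_origins_alone(self):
        s = IntervalSet.from_intervals(
            [Interval("chr1", 0, 1000), Interval("chr1", 20000, 21000)]
        )
        assert len(merge_within(s, 12000)) == 2

    def test_gap_zero_merges_only_strict_overlaps(self):
        s = IntervalSet.from_intervals(
            [
                Interval("chr1", 0, 100),
                Interval("chr1", 100, 200),  # abutting: kept separate
                Interval("chr1", 150, 300),  # overlaps previous: merged
            ]
        )
        out = merge_within(s, 0)
        assert [(iv.start, iv.end) for iv in out.to_intervals()] == [(0, 100), (100, 300)]

    def test_annotations_summed_and_efficiency_recomputed(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 500],
                "end": [1000, 1500],
                "n_reads": [100, 50],
                "efficiency": [0.1, 0.05],
            }
        )
        out = merge_within(IntervalSet(df), 0)
        assert out.df["n_reads"].iloc[0] == 150
        assert out.df["efficiency"].iloc[0] == pytest.approx(150 / 1500)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 500)), min_size=1, max_size=30
        ),
        st.integers(0, 1000),
    )
    def test_idempotent(self, spans, gap):
        s = IntervalSet.from_intervals(
            [Interval("chr1", a, a + w) for a, w in spans]
        )
        once = merge_within(s, gap)
        twice = merge_within(once, gap)
        assert twice.same_intervals(once)


class TestDistanceAndOverlapQueries:
    def test_gap_distance(self):
        q = IntervalSet.from_intervals([Interval("chr1", 100, 200)])
        s = IntervalSet.from_intervals([Interval("chr1", 300, 400)])
        assert distance_to_nearest(q, s)[0] == 100

    def test_overlap_distance_is_zero(self):
        q = IntervalSet.from_intervals([Interval("chr1", 100, 200)])
        s = IntervalSet.from_intervals([Interval("chr1", 150, 400)])
        assert distance_to_nearest(q, s)[0] == 0

    def test_missing_chromosome_is_nan(self):
        q = IntervalSet.from_intervals([Interval("chr2", 100, 200)])
        s = IntervalSet.from_intervals([Interval("chr1", 300, 400)])
        assert np.isnan(distance_to_nearest(q, s)[0])

    def test_empty_subject_errors(self):
        q = IntervalSet.from_intervals([Interval("chr1", 100, 200)])
        with pytest.raises(ValueError):
            distance_to_nearest(q, IntervalSet.empty())

    def test_matches_brute_force_on_random_sets(self, rng, layout_two_chroms):
        q = random_intervals(rng, 500, layout_two_chroms)
        s = random_intervals(rng, 500, layout_two_chroms)
        got = distance_to_nearest(q, s)
        subj = list(s.to_intervals())
        for i, iv in enumerate(q.to_intervals()):
            best = np.inf
            for sv in subj:
                if sv.chrom != iv.chrom:
                    continue
                if overlaps(iv, sv):
                    best = 0
                    break
                best = min(best, max(sv.start - iv.end, iv.start - sv.end))
            if np.isinf(best):
                assert np.isnan(got[i])
            else:
                assert got[i] == best

    def test_overlaps_any_matches_brute_force(self, rng, layout_two_chroms):
        a = random_intervals(rng, 1000, layout_two_chroms)
        b = random_intervals(rng, 1000, layout_two_chroms)
        got = overlaps_any(a, b)
        bs = list(b.to_intervals())
        expected = np.array(
            [any(overlaps(iv, sv) for sv in bs) for iv in a.to_intervals()]
        )
        assert np.array_equal(got, expected)


class TestFootprintAlgebra:
    def test_subtract_carves_holes(self):
        a = IntervalSet.from_intervals([Interval("chr1", 0, 1000)])
        b = IntervalSet.from_intervals(
            [Interval("chr1", 100, 200), Interval("chr1", 500, 600)]
        )
        (starts, ends) = subtract(a, b)["chr1"]
        assert list(starts) == [0, 200, 600]
        assert list(ends) == [100, 500, 1000]

    def test_mask_normalizes_overlaps(self):
        m = MappabilityMask(
            IntervalSet.from_intervals(
                [Interval("chr1", 0, 500), Interval("chr1", 400, 900)]
            )
        )
        assert m.total_bp() == 900
        assert len(m.mappable) == 1

    def test_footprint_total(self, rng, layout_1mb):
        iset = random_intervals(rng, 200, layout_1mb)
        foot = merged_footprint(iset)
        manual = np.zeros(1_000_000, dtype=bool)
        for iv in iset.to_intervals():
            manual[iv.start : iv.end] = True
        assert iset.total_bp() == manual.sum()
        total = sum(int((e - s).sum()) for s, e in foot.values())
        assert total == manual.sum()
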