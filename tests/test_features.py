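"""G4 scanning, feature enrichment and stratified summaries."""

import numpy as np
import pytest

from oriscan.detection import Origin
from oriscan.features import (
    annotate_origins,
    compare_efficiency,
    enrichment_test,
    g4_density,
    mark_pair_class,
    revcomp,
    scan_g4_sequences,
    scan_g4_string,
)
from oriscan.intervals import GenomeLayout, Interval, IntervalSet, MappabilityMask


def oracle_scan(s, loop_max):
    """Backtracking enumerator of run/loop decompositions under the
    leftmost-greedy rule (quantifiers tried longest-first), independent
    of the regex engine used by the implementation."""
    n = len(s)

    def runlen(pos):
        j = pos
        while j < n and s[j] == "G":
            j += 1
        return j - pos

    def match_run(pos, remaining):
        m = runlen(pos)
        if m < 3:
            return None
        for r in range(m, 2, -1):
            res = match_rest(pos + r, remaining)
            if res is not None:
                return res
        return None

    def match_rest(pos, remaining):
        if remaining == 0:
            return pos
        for l in range(loop_max, 0, -1):
            if pos + l >= n:
                continue
            res = match_run(pos + l, remaining - 1)
            if res is not None:
                return res
        return None

    out = []
    pos = 0
    while pos < n:
        if s[pos] != "G":
            pos += 1
            continue
        e = match_run(pos, 3)
        if e is None:
            pos += 1
        else:
            out.append((pos, e))
            pos = e
    return out


class TestG4Scanner:
    def test_canonical_plus_motif(self):
        assert scan_g4_string("GGGAGGGAGGGAGGG", 7) == [(0, 15)]

    def test_canonical_minus_motif(self):
        out = scan_g4_sequences({"c": "CCCTCCCTCCCTCCC"}, 7)
        assert len(out) == 1
        row = out.df.iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (0, 15, "-")

    def test_loop_longer_than_max_rejected(self):
        seq = "GGG" + "A" * 8 + "GGG" + "A" * 8 + "GGG" + "A" * 8 + "GGG"
        assert scan_g4_string(seq, 7) == []
        assert len(scan_g4_string(seq, 15)) == 1

    def test_n_never_matches_a_g_run(self):
        # N in a loop is fine; N cannot substitute for a run G
        assert scan_g4_string("GGGNGGGNGGGNGGG", 7) == [(0, 15)]
        assert scan_g4_string("GGNAGGGAGGGAGGG", 7) == []

    def test_rejects_non_nucleotide_alphabet(self):
        with pytest.raises(ValueError):
            scan_g4_string("GGGAXGGAGGGAGGG", 7)

    @pytest.mark.parametrize("loop_max", [3, 7, 15])
    def test_agrees_with_backtracking_oracle(self, rng, loop_max):
        # G-rich alphabet so motifs and near-motifs are frequent
        letters = np.array(list("GGGACT"))
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=300))
            assert scan_g4_string(seq, loop_max) == oracle_scan(seq, loop_max)

    def test_strand_symmetry_under_reverse_complement(self, rng):
        letters = np.array(list("GGCCAT"))
        for _ in range(20):
            seq = "".join(rng.choice(letters, size=500))
            n = len(seq)
            fwd = scan_g4_sequences({"c": seq}, 7).df
            rev = scan_g4_sequences({"c": revcomp(seq)}, 7).df
            plus_fwd = sorted(
                (s, e) for s, e, st in zip(fwd["start"], fwd["end"], fwd["strand"]) if st == "+"
            )
            minus_rev_mapped = sorted(
                (n - e, n - s)
                for s, e, st in zip(rev["start"], rev["end"], rev["strand"])
                if st == "-"
            )
            assert plus_fwd == minus_rev_mapped


class TestG4Density:
    def _motifs(self, spans):
        return IntervalSet.from_intervals([Interval("chr1", a, b) for a, b in spans])

    def test_no_motifs_in_window(self):
        o = Origin("chr1", 10_000, 12_000, 10, 0.005, 1)
        assert g4_density([o], self._motifs([(50_000, 50_015)]), window=5000)[0] == 0

    def test_motif_at_midpoint(self):
        o = Origin("chr1", 10_000, 12_000, 10, 0.005, 1)
        assert g4_density([o], self._motifs([(11_000, 11_015)]), window=5000)[0] == 1

    def test_matches_brute_force_recount(self, rng):
        starts = rng.integers(0, 100_000, size=500)
        motifs = self._motifs([(int(s), int(s) + 15) for s in starts])
        origins = [
            Origin("chr1", int(s), int(s) + 2000, 10, 0.005, 1)
            for s in rng.integers(0, 98_000, size=100)
        ]
        got = g4_density(origins, motifs, window=5000)
        for i, o in enumerate(origins):
            ws = o.midpoint - 2500
            we = ws + 5000
            manual = sum(1 for s in starts if s < we and s + 15 > ws)
            assert got[i] == manual


class TestEnrichment:
    def _setup(self, rng, n_origins=50, n_feat=40, G=1_000_000):
        layout = GenomeLayout.from_dict({"chr1": G})
        mask = MappabilityMask.whole_genome(layout)
        starts = np.sort(rng.choice(G - 2000, size=n_origins, replace=False))
        origins = [Origin("chr1", int(s), int(s) + 2000, 10, 0.005, 1) for s in starts]
        fs = np.sort(rng.choice(G - 2000, size=n_feat, replace=False))
        feat = IntervalSet.from_intervals(
            [Interval("chr1", int(s), int(s) + 2000) for s in fs], label="F"
        )
        return origins, feat, mask

    def test_extreme_observation_gives_minimal_p(self, rng):
        origins, _, mask = self._setup(rng)
        # feature exactly covering all origins: observed 100%, null tiny
        feat = IntervalSet.from_intervals(
            [Interval("chr1", o.start, o.end) for o in origins], label="F"
        )
        (res,) = enrichment_test(origins, feat, mask, n_intervals=200, n_reps=99, seed=0)
        assert res.observed_pct == 100.0
        assert res.empirical_p == pytest.approx(1 / 100)
        assert res.direction == "enriched"

    def test_whole_mask_feature_is_ns(self, rng):
        origins, _, mask = self._setup(rng)
        feat = IntervalSet.from_intervals([Interval("chr1", 0, 1_000_000)], label="F")
        (res,) = enrichment_test(origins, feat, mask, n_intervals=100, n_reps=49, seed=0)
        assert res.observed_pct == 100.0 and res.expected_pct == 100.0
        assert res.direction == "ns"

    def test_null_mean_matches_analytic_hit_probability(self, rng):
        origins, feat, mask = self._setup(rng, n_origins=20, n_feat=50)
        results = enrichment_test(
            origins, feat, mask, n_intervals=2000, n_reps=50, seed=0
        )
        # analytic: uniform placement of a 2 kb interval on mask minus
        # origin footprint vs the feature footprint
        from oriscan.detection import origins_to_intervalset
        from oriscan.intervals import merged_footprint

        space = mask.allowed_space(exclude=origins_to_intervalset(origins))
        fs, fe = merged_footprint(feat)["chr1"]
        hit = tot = 0
        for s0, e0 in zip(*space["chr1"]):
            if e0 - s0 < 2000:
                continue
            starts = np.arange(s0, e0 - 2000 + 1)
            tot += len(starts)
            idx = np.searchsorted(fs, starts + 2000, side="left")
            hit += int(((idx > 0) & (fe[np.maximum(idx - 1, 0)] > starts)).sum())
        assert results[0].expected_pct / 100 == pytest.approx(hit / tot, abs=0.01)

    def test_empty_stratum_skipped_with_warning(self, rng):
        origins, feat, mask = self._setup(rng)
        strata = {"none": np.zeros(len(origins), dtype=bool)}
        with pytest.warns(UserWarning):
            out = enrichment_test(
                origins, feat, mask, strata=strata, n_intervals=50, n_reps=9, seed=0
            )
        assert out == []


class TestStratifiedSummary:
    def _origins(self):
        out = []
        for i, (cat, eff) in enumerate(
            [(1, 0.2), (1, 0.4), (4, 0.1), (4, 0.3), (6, 0.05), (6, 0.15)]
        ):
            o = Origin("chr1", i * 10_000, i * 10_000 + 2000, int(eff * 2000), eff, 1)
            o.labels["timing_category"] = cat
            from oriscan.timing import timing_group

            o.labels["timing_group"] = timing_group(cat)
            out.append(o)
        return out

    def test_mean_efficiency_per_stratum(self):
        marks = {"H2AZ": IntervalSet.from_intervals([Interval("chr1", 0, 2000)])}
        annotated = annotate_origins(self._origins(), marks)
        from oriscan.features import stratified_summary

        summary = stratified_summary(annotated, ["timing_category"])
        row = summary[summary["timing_category"] == 1].iloc[0]
        assert row["mean_efficiency"] == pytest.approx(0.3)
        assert row["n"] == 2

    def test_pair_partition_sums_to_total(self, rng, layout_1mb):
        from .conftest import random_intervals

        origins = [
            Origin("chr1", int(s), int(s) + 2000, 10, 0.005, 1)
            for s in rng.integers(0, 900_000, size=200)
        ]
        marks = {
            "H4K20me1": random_intervals(rng, 100, layout_1mb),
            "H3K27me3": random_intervals(rng, 100, layout_1mb),
        }
        annotated = annotate_origins(origins, marks)
        classes = mark_pair_class(annotated, "H4K20me1", "H3K27me3")
        assert classes.value_counts().sum() == len(origins)
        both = (annotated["H4K20me1"] & annotated["H3K27me3"]).sum()
        assert (classes == "both").sum() == both

    def test_open_marks_flag_is_any_of_configured(self, rng, layout_1mb):
        from .conftest import random_intervals

        origins = [
            Origin("chr1", int(s), int(s) + 2000, 10, 0.005, 1)
            for s in rng.integers(0, 900_000, size=50)
        ]
        marks = {
            m: random_intervals(rng, 50, layout_1mb) for m in ("H2AZ", "H3K9ac", "H3K4me3")
        }
        annotated = annotate_origins(origins, marks)
        expected = annotated[["H2AZ", "H3K9ac", "H3K4me3"]].any(axis=1)
        assert annotated["OpenMarks"].equals(expected)

    def test_t_test_matches_hand_calculation(self):
        # two-sample equal-variance t on a printed toy, n = 3 vs 3
        a = np.array([0.2, 0.3, 0.4])
        b = np.array([0.1, 0.15, 0.2])
        t, p = compare_efficiency(a, b)
        # hand calculation: means 0.3 / 0.15, pooled var = (0.02+0.005)/4
        sp2 = (0.02 + 0.005) / 4
        t_hand = (0.3 - 0.15) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, rel=1e-10)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df=4), rel=1e-10)
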