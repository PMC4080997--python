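"""Window construction, aggregation, filtering, flagging and merging."""

import numpy as np
import pandas as pd
import pytest

from dmrkit import (
    DmrConfig,
    SampleMethylome,
    aggregate_counts,
    call_candidate_windows,
    coverage_filter,
    make_windows,
    merge_windows_to_dmrs,
    methylation_level,
    compare_windows,
)
from dmrkit.dmr import HYPER, HYPO

from conftest import make_methylome_frame


def methylome(rows, sample_id="s"):
    return SampleMethylome(sample_id, records=make_methylome_frame(rows))


class TestMakeWindows:
    def test_truncated_final_tile(self):
        w = make_windows({"chr1": 250}, 100)
        assert list(zip(w["start"], w["end"])) == [(0, 100), (100, 200), (200, 250)]

    def test_exact_single_window(self):
        w = make_windows({"chr1": 100}, 100)
        assert list(zip(w["start"], w["end"])) == [(0, 100)]

    def test_zero_length_chromosome(self):
        assert len(make_windows({"chr1": 0}, 100)) == 0

    def test_tiles_are_gapless(self):
        w = make_windows({"chr1": 1234, "chr2": 50}, 100)
        for _, grp in w.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()


class TestAggregateCounts:
    def test_counts_pooled_within_window(self):
        m = methylome([("chr1", 10, "+", "CHH", 3, 5), ("chr1", 90, "-", "CHH", 1, 1)])
        agg = aggregate_counts(m, {"chr1": 200}, "CHH", DmrConfig())
        assert (agg.loc[0, "A"], agg.loc[0, "B"]) == (4, 6)
        assert (agg.loc[1, "A"], agg.loc[1, "B"]) == (0, 0)

    def test_position_at_window_end_goes_to_next_window(self):
        m = methylome([("chr1", 100, "+", "CHH", 2, 0)])
        agg = aggregate_counts(m, {"chr1": 200}, "CHH", DmrConfig())
        assert agg.loc[0, "A"] == 0 and agg.loc[1, "A"] == 2

    def test_other_contexts_excluded(self):
        m = methylome([("chr1", 10, "+", "CG", 9, 9), ("chr1", 11, "+", "CHH", 1, 0)])
        agg = aggregate_counts(m, {"chr1": 100}, "CHH", DmrConfig())
        assert (agg.loc[0, "A"], agg.loc[0, "B"]) == (1, 0)

    def test_count_conservation(self, small_methylome, small_sim):
        lengths = small_sim.analysis_chrom_lengths
        rec = small_methylome.records
        for ctx in ("CG", "CHG", "CHH"):
            agg = aggregate_counts(small_methylome, lengths, ctx, DmrConfig())
            sel = rec[(rec["context"] == ctx) & rec["chrom"].isin(lengths)]
            assert (agg["A"] + agg["B"]).sum() == (sel["n_meth"] + sel["n_unmeth"]).sum()


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "coverages, expected",
        [
            ([4, 4, 4, 4], True),    # boundary: exactly 4 cytosines at 4 reads
            ([50, 50, 50], False),   # too few cytosines, depth irrelevant
            ([4, 4, 4, 3], False),   # one cytosine below the depth floor
            ([4, 4, 4, 3, 4], True), # a 5th cytosine rescues the window
        ],
    )
    def test_boundaries(self, coverages, expected):
        rows = [
            ("chr1", 10 + i, "+", "CHH", c // 2, c - c // 2)
            for i, c in enumerate(coverages)
        ]
        agg = aggregate_counts(methylome(rows), {"chr1": 100}, "CHH", DmrConfig())
        assert coverage_filter(agg["n_cyt_cov"].to_numpy(), DmrConfig())[0] == expected


class TestMethylationLevel:
    @pytest.mark.parametrize("A, B, m", [(0, 12, 0.0), (7, 0, 1.0), (6, 6, 0.5)])
    def test_values(self, A, B, m):
        assert methylation_level(A, B) == pytest.approx(m)

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            methylation_level(0, 0)


def _results_frame(rows):
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "m_wt", "m_mut", "q",
                       "A_wt", "B_wt", "A_mut", "B_mut"]
    )
    df["context"] = "CHH"
    df["diff"] = df["m_wt"] - df["m_mut"]
    return df


class TestCallCandidateWindows:
    def test_flagging_rules(self):
        df = _results_frame([
            ("chr1", 0, 100, 0.25, 0.05, 0.001, 5, 15, 1, 19),   # flag, hypo
            ("chr1", 100, 200, 0.05, 0.55, 0.0001, 1, 19, 11, 9), # flag, hyper
            ("chr1", 200, 300, 0.25, 0.20, 0.001, 5, 15, 4, 16),  # diff too small
            ("chr1", 300, 400, 0.60, 0.10, 0.02, 12, 8, 2, 18),   # q too large
        ])
        out = call_candidate_windows(df, "CHH")
        assert out["passed"].tolist() == [True, True, False, False]
        assert out.loc[0, "direction"] == HYPO
        assert out.loc[1, "direction"] == HYPER

    def test_cg_threshold_stricter_than_chh(self):
        df = _results_frame([("chr1", 0, 100, 0.50, 0.20, 0.0001, 10, 10, 4, 16)])
        df["context"] = "CG"
        assert not call_candidate_windows(df, "CG")["passed"].any()
        df["context"] = "CHH"
        assert call_candidate_windows(df, "CHH")["passed"].all()

    def test_diff_boundary_inclusive(self):
        df = _results_frame([
            ("chr1", 0, 100, 0.20, 0.10, 0.001, 20, 80, 10, 90),
            ("chr1", 100, 200, 0.1999, 0.10, 0.001, 20, 80, 10, 90),
        ])
        out = call_candidate_windows(df, "CHH")
        assert out["passed"].tolist() == [True, False]

    def test_monotone_in_thresholds(self, rng):
        df = _results_frame([
            ("chr1", i * 100, (i + 1) * 100, w, m, q, 1, 1, 1, 1)
            for i, (w, m, q) in enumerate(
                zip(rng.random(200), rng.random(200), rng.random(200) * 0.05)
            )
        ])
        n_flagged = []
        for thr, qmax in [(0.3, 0.005), (0.1, 0.005), (0.1, 0.02)]:
            cfg = DmrConfig(diff_threshold={"CG": 0.4, "CHG": 0.2, "CHH": thr},
                            q_max=qmax)
            n_flagged.append(int(call_candidate_windows(df, "CHH", cfg)["passed"].sum()))
        assert n_flagged[0] <= n_flagged[1] <= n_flagged[2]


def _flagged(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])
    df["context"] = "CHH"
    for col, val in (("A_wt", 5), ("B_wt", 5), ("A_mut", 1), ("B_mut", 9), ("q", 1e-4)):
        df[col] = val
    df["passed"] = True
    return df


class TestMergeWindows:
    def test_gap_200_merges_gap_201_does_not(self):
        one = merge_windows_to_dmrs(_flagged([
            ("chr1", 0, 100, HYPO), ("chr1", 300, 400, HYPO)]))
        assert len(one) == 1 and (one.loc[0, "start"], one.loc[0, "end"]) == (0, 400)
        two = merge_windows_to_dmrs(_flagged([
            ("chr1", 0, 100, HYPO), ("chr1", 301, 401, HYPO)]))
        assert len(two) == 2

    def test_opposite_directions_never_merge(self):
        out = merge_windows_to_dmrs(_flagged([
            ("chr1", 0, 100, HYPO), ("chr1", 100, 200, HYPER)]))
        assert len(out) == 2
        assert set(out["direction"]) == {HYPO, HYPER}

    def test_summary_levels_from_pooled_counts(self):
        out = merge_windows_to_dmrs(_flagged([
            ("chr1", 0, 100, HYPO), ("chr1", 100, 200, HYPO)]))
        assert out.loc[0, "m_wt"] == pytest.approx(0.5)
        assert out.loc[0, "m_mut"] == pytest.approx(0.1)
        assert out.loc[0, "n_windows"] == 2

    def test_idempotent_and_separated(self, rng):
        starts = np.sort(rng.choice(20_000, size=60, replace=False)) * 100
        rows = [("chr1", int(s), int(s) + 100,
                 HYPO if rng.random() < 0.7 else HYPER) for s in starts]
        dmrs = merge_windows_to_dmrs(_flagged(rows))
        for direction, grp in dmrs.groupby("direction"):
            gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
            assert (gaps > 200).all()
        again = merge_windows_to_dmrs(
            dmrs.assign(passed=True, q=dmrs["score"].rsub(0).rpow(10.0))
        )
        assert len(again) == len(dmrs)
        assert (again["start"].to_numpy() == dmrs["start"].to_numpy()).all()
        assert (again["end"].to_numpy() == dmrs["end"].to_numpy()).all()


class TestCompareWindows:
    def test_zero_mutant_coverage_window_excluded(self):
        wt_rows = [("chr1", 10 + i, "+", "CHH", 5, 5) for i in range(4)]
        wt = methylome(wt_rows, "wt")
        mut = methylome([("chr1", 150, "+", "CHH", 1, 1)], "mut")
        out = compare_windows(wt, mut, "CHH", {"chr1": 200})
        assert len(out) == 0  # the only wt-eligible window has no mutant reads

    def test_fdr_family_is_all_tested_windows(self):
        rows_wt, rows_mut = [], []
        for w in range(6):
            for i in range(4):
                pos = w * 100 + 10 + i
                rows_wt.append(("chr1", pos, "+", "CHH", 8, 2))
                rows_mut.append(("chr1", pos, "+", "CHH", 1 if w == 0 else 8,
                                 9 if w == 0 else 2))
        out = compare_windows(
            methylome(rows_wt, "wt"), methylome(rows_mut, "mut"), "CHH", {"chr1": 600}
        )
        assert len(out) == 6
        expected_q = np.minimum(1.0, out["p"].to_numpy() * 6 /
                                (np.argsort(np.argsort(out["p"])) + 1))
        # BH with the step-up minimum; window 0 is the only real signal
        assert out.loc[0, "q"] <= expected_q[0] + 1e-12
        assert out.loc[0, "passed"]
        assert not out.loc[1:, "passed"].any()
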