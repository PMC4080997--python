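"""Interval algebra against a per-base bitmap oracle, plus BED/GFF3 I/O."""

import numpy as np
import pandas as pd
import pytest

from dmrkit import (
    classify_annotation,
    intersect_replicates,
    merge_intervals,
    overlap_fraction,
    read_bed,
    read_gff3,
    subtract_regions,
    write_bed,
)
from dmrkit.intervals import write_gff3

CHROM_LEN = 10_000


def iv(*triples, **extra):
    df = pd.DataFrame(list(triples), columns=["chrom", "start", "end"])
    for k, v in extra.items():
        df[k] = v
    return df


def bitmap(df, length=CHROM_LEN, chrom="chr1"):
    mask = np.zeros(length, dtype=bool)
    for r in df[df["chrom"] == chrom].itertuples(index=False):
        mask[r.start : r.end] = True
    return mask


def random_set(rng, n, max_size=400, chrom="chr1"):
    starts = rng.integers(0, CHROM_LEN - max_size, size=n)
    sizes = rng.integers(1, max_size, size=n)
    return iv(*[(chrom, int(s), int(s + z)) for s, z in zip(starts, sizes)])


class TestIntersectReplicates:
    def test_identical_sets_unchanged(self):
        a = iv(("chr1", 100, 300), ("chr1", 500, 700))
        out = intersect_replicates(a, a.copy())
        assert out[["chrom", "start", "end"]].values.tolist() == a.values.tolist()

    def test_one_bp_overlap_retained_with_union_span(self):
        out = intersect_replicates(iv(("chr1", 100, 300)), iv(("chr1", 299, 400)))
        assert out[["start", "end"]].values.tolist() == [[100, 400]]

    def test_touching_intervals_dropped(self):
        out = intersect_replicates(iv(("chr1", 100, 200)), iv(("chr1", 200, 300)))
        assert len(out) == 0

    def test_direction_must_match(self):
        a = iv(("chr1", 100, 300), direction="hypo_in_mutant")
        b = iv(("chr1", 200, 400), direction="hyper_in_mutant")
        assert len(intersect_replicates(a, b)) == 0

    def test_symmetric_membership_and_count_bound(self, rng):
        for _ in range(20):
            a, b = random_set(rng, 15), random_set(rng, 10)
            ab = intersect_replicates(a, b)
            ba = intersect_replicates(b, a)
            assert bitmap(ab).sum() == bitmap(ba).sum()
            assert len(ab) <= min(len(a), len(b))

    def test_span_modes(self):
        a, b = iv(("chr1", 100, 300)), iv(("chr1", 250, 400))
        assert intersect_replicates(a, b, span="union")[["start", "end"]].values.tolist() == [[100, 400]]
        assert intersect_replicates(a, b, span="intersection")[["start", "end"]].values.tolist() == [[250, 300]]
        assert intersect_replicates(a, b, span="first")[["start", "end"]].values.tolist() == [[100, 300]]


class TestSubtractRegions:
    def test_empty_blacklist_is_identity(self):
        a = iv(("chr1", 100, 200))
        assert subtract_regions(a, iv()).equals(a)

    def test_whole_interval_removal(self):
        out = subtract_regions(iv(("chr1", 100, 200)), iv(("chr1", 150, 160)))
        assert len(out) == 0

    def test_half_open_touching_kept(self):
        out = subtract_regions(iv(("chr1", 100, 200)), iv(("chr1", 200, 300)))
        assert len(out) == 1


class TestClassifyAnnotation:
    def test_te_priority_over_gene(self):
        dmrs = iv(("chr1", 100, 200))
        labels, fractions = classify_annotation(
            dmrs, genes=iv(("chr1", 150, 400)), tes=iv(("chr1", 50, 160))
        )
        assert labels.tolist() == ["TE"]

    def test_no_overlap_is_intergenic(self):
        labels, _ = classify_annotation(iv(("chr1", 100, 200)), iv(), iv())
        assert labels.tolist() == ["intergenic"]

    def test_fractions_sum_to_one(self):
        dmrs = iv(("chr1", 0, 10), ("chr1", 100, 110), ("chr1", 200, 210))
        labels, fractions = classify_annotation(
            dmrs, genes=iv(("chr1", 100, 120)), tes=iv(("chr1", 0, 5))
        )
        assert labels.tolist() == ["TE", "gene", "intergenic"]
        assert fractions.tolist() == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert fractions.sum() == pytest.approx(1.0, abs=1e-12)


class TestOverlapFraction:
    def test_subset_is_one(self):
        a = iv(("chr1", 10, 20), ("chr1", 30, 40))
        b = iv(("chr1", 0, 100))
        assert overlap_fraction(a, b) == 1.0

    def test_disjoint_is_zero(self):
        assert overlap_fraction(iv(("chr1", 0, 10)), iv(("chr1", 50, 60))) == 0.0

    def test_counting(self):
        a = iv(("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 40, 50))
        assert overlap_fraction(a, iv(("chr1", 25, 26))) == pytest.approx(1 / 3)

    def test_empty_query_is_zero(self):
        assert overlap_fraction(iv(), iv(("chr1", 0, 10))) == 0.0


class TestBitmapOracle:
    """merge / subtract / overlap / classify agree with per-base masks."""

    def test_merge_against_bitmap(self, rng):
        for _ in range(30):
            a = random_set(rng, int(rng.integers(1, 25)))
            merged = merge_intervals(a)
            assert (bitmap(merged) == bitmap(a)).all()
            # merged intervals are disjoint and sorted
            assert (merged["start"].to_numpy()[1:] >= merged["end"].to_numpy()[:-1]).all()

    def test_subtract_against_bitmap(self, rng):
        for _ in range(30):
            a, b = random_set(rng, 12), random_set(rng, 8)
            out = subtract_regions(a, b)
            mask_b = bitmap(b)
            expect = [
                (r.start, r.end)
                for r in a.itertuples(index=False)
                if not mask_b[r.start : r.end].any()
            ]
            assert sorted(zip(out["start"], out["end"])) == sorted(expect)
            assert not (bitmap(out) & mask_b).any()

    def test_overlap_fraction_against_bitmap(self, rng):
        for _ in range(30):
            a, b = random_set(rng, 10), random_set(rng, 6)
            mask_b = bitmap(b)
            expect = np.mean(
                [mask_b[r.start : r.end].any() for r in a.itertuples(index=False)]
            )
            assert overlap_fraction(a, b) == pytest.approx(expect)

    def test_intersect_membership_against_bitmap(self, rng):
        for _ in range(30):
            a, b = random_set(rng, 12), random_set(rng, 8)
            out = intersect_replicates(a, b)
            mask_out = bitmap(out)
            mask_a, mask_b = bitmap(a), bitmap(b)
            # every retained base of A's paired intervals is covered, and
            # nothing outside the union of paired intervals appears
            for r in a.itertuples(index=False):
                if mask_b[r.start : r.end].any():
                    assert mask_out[r.start : r.end].all()
            for r in b.itertuples(index=False):
                if mask_a[r.start : r.end].any():
                    assert mask_out[r.start : r.end].all()
            assert not (mask_out & ~(mask_a | mask_b)).any()


class TestIO:
    def test_bed_round_trip(self, tmp_path):
        df = iv(("chr1", 5, 50), ("chr2", 0, 9), name=["a", "b"], score=[1, 2],
                strand=["+", "-"])
        path = tmp_path / "x.bed"
        write_bed(df, path)
        back = read_bed(path)
        assert back[["chrom", "start", "end", "name"]].values.tolist() == \
            df[["chrom", "start", "end", "name"]].values.tolist()

    def test_gff3_round_trip_coordinates(self, tmp_path):
        feats = iv(("chr1", 100, 200), ("chr1", 300, 450),
                   type=["gene", "transposable_element"], strand=["+", "-"],
                   id=["g1", "te1"])
        path = tmp_path / "x.gff3"
        write_gff3(feats, path)
        genes, tes = read_gff3(path)
        assert genes[["start", "end"]].values.tolist() == [[100, 200]]
        assert tes[["start", "end"]].values.tolist() == [[300, 450]]
        assert tes["id"].tolist() == ["te1"]
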