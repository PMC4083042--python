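"""Window counting, RPM normalization and differential calling invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_genome
from smrnapipe.io_formats import CollapsedRead, GenomeSequence, Interval
from smrnapipe.read_mapping import ReadPlacement
from smrnapipe.smrna_clusters import (
    call_differential,
    chromosome_track,
    count_windows,
    normalize_rpm,
    subset_by_size,
)


def placement(seq_len, chrom, start, strand="+", count=1):
    return ReadPlacement(
        CollapsedRead("A" * seq_len, count),
        [Interval(chrom, start, start + seq_len, strand)],
    )


GENOME = [GenomeSequence("chr1", "A" * 1000)]


class TestCountWindows:
    def test_window_boundary_assignment(self):
        p1 = placement(20, "chr1", 199)  # 5' at 199 -> window [100,200)
        p2 = placement(20, "chr1", 200)  # 5' at 200 -> window [200,300)
        counts = count_windows([p1, p2], GENOME)
        assert counts.loc[counts.start == 100, "raw_count"].item() == 1
        assert counts.loc[counts.start == 200, "raw_count"].item() == 1

    def test_minus_strand_uses_five_prime_end(self):
        # minus-strand hit [180, 204): its 5' end is base 203 -> window [200,300)
        p = ReadPlacement(CollapsedRead("A" * 24, 1), [Interval("chr1", 180, 204, "-")])
        counts = count_windows([p], GENOME)
        assert counts.loc[counts.start == 200, "raw_count"].item() == 1
        assert counts.loc[counts.start == 100, "raw_count"].item() == 0

    def test_multihit_multiplicity(self):
        p = ReadPlacement(
            CollapsedRead("A" * 20, 3),
            [Interval("chr1", 10, 30, "+"), Interval("chr1", 510, 530, "+")],
        )
        counts = count_windows([p], GENOME)
        assert counts["raw_count"].sum() == 6

    def test_tiling_covers_every_base_once(self):
        genome = [GenomeSequence("chr1", "A" * 1050)]  # last window short
        counts = count_windows([], genome)
        assert list(counts["start"]) == list(range(0, 1050, 100))
        assert counts["end"].iloc[-1] == 1050
        spans = (counts["end"] - counts["start"]).sum()
        assert spans == 1050

    def test_brute_force_oracle_on_random_reads(self):
        """Per-position brute-force assignment equals count_windows."""
        rng = np.random.default_rng(17)
        genome = random_genome(rng, [5_000])
        placements = []
        for _ in range(40):
            n = int(rng.integers(18, 27))
            s = int(rng.integers(0, 5_000 - n))
            strand = "+" if rng.integers(2) else "-"
            placements.append(
                ReadPlacement(
                    CollapsedRead("A" * n, int(rng.integers(1, 5))),
                    [Interval("chr1", s, s + n, strand)],
                )
            )
        counts = count_windows(placements, genome)
        expected = np.zeros(50, dtype=int)
        for p in placements:
            for h in p.hits:
                five = h.start if h.strand == "+" else h.end - 1
                expected[five // 100] += p.read.count
        assert list(counts["raw_count"]) == list(expected)

    def test_size_range_validation(self):
        with pytest.raises(ValueError):
            count_windows([], GENOME, size_range=(10, 26))


class TestNormalizeRPM:
    def test_per_million_identity(self):
        counts = count_windows([placement(20, "chr1", 0, count=10)], GENOME)
        rpm = normalize_rpm(counts, 1_000_000)
        assert rpm.loc[0, "rpm"] == 10.0

    def test_scaling_arithmetic(self):
        counts = count_windows([placement(20, "chr1", 0, count=10)], GENOME)
        rpm = normalize_rpm(counts, 200_000)
        assert rpm.loc[0, "rpm"] == 50.0

    def test_zero_total_errors(self):
        counts = count_windows([], GENOME)
        with pytest.raises(ValueError):
            normalize_rpm(counts, 0)


def profiles_from_rpm(rpm_values):
    n = len(rpm_values)
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": range(0, 100 * n, 100),
            "end": range(100, 100 * n + 100, 100),
            "raw_count": [0] * n,
            "rpm": rpm_values,
        }
    )


class TestCallDifferential:
    def test_fourfold_boundary_inclusive(self):
        """X=8, Y=2 with no pseudocount gives exactly 2.0 and passes."""
        out = call_differential(
            [profiles_from_rpm([8.0])], [profiles_from_rpm([2.0])], pseudocount=0.0
        )
        assert out.loc[0, "fold_value"] == 2.0
        assert bool(out.loc[0, "passes"])
        assert out.loc[0, "direction"] == "up"

    def test_equal_is_zero_and_fails(self):
        out = call_differential(
            [profiles_from_rpm([5.0])], [profiles_from_rpm([5.0])]
        )
        assert out.loc[0, "fold_value"] == 0.0
        assert not bool(out.loc[0, "passes"])

    def test_empty_windows_never_called(self):
        out = call_differential(
            [profiles_from_rpm([0.0])], [profiles_from_rpm([0.0])]
        )
        assert out.loc[0, "fold_value"] == 0.0
        assert not bool(out.loc[0, "passes"])

    def test_swap_negates_fold_values(self):
        rng = np.random.default_rng(3)
        a = profiles_from_rpm(list(rng.gamma(1.0, 50.0, size=30)))
        b = profiles_from_rpm(list(rng.gamma(1.0, 50.0, size=30)))
        fwd = call_differential([a], [b])
        rev = call_differential([b], [a])
        assert np.allclose(fwd["fold_value"], -rev["fold_value"])

    def test_scale_invariance_with_zero_pseudocount(self):
        rng = np.random.default_rng(4)
        vals_a = list(rng.integers(1, 100, size=20).astype(float))
        vals_b = list(rng.integers(1, 100, size=20).astype(float))
        base = call_differential(
            [profiles_from_rpm(vals_a)], [profiles_from_rpm(vals_b)], pseudocount=0.0
        )
        scaled = call_differential(
            [profiles_from_rpm([v * 7 for v in vals_a])],
            [profiles_from_rpm([v * 7 for v in vals_b])],
            pseudocount=0.0,
        )
        assert np.allclose(base["fold_value"], scaled["fold_value"])

    def test_median_across_libraries(self):
        mut = [profiles_from_rpm([2.0]), profiles_from_rpm([8.0]), profiles_from_rpm([10.0])]
        wt = [profiles_from_rpm([1.0]), profiles_from_rpm([2.0])]
        out = call_differential(mut, wt, pseudocount=0.0)
        assert out.loc[0, "X"] == 8.0  # median of 2, 8, 10
        assert out.loc[0, "Y"] == 1.5

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError, match="grids"):
            call_differential(
                [profiles_from_rpm([1.0, 2.0])], [profiles_from_rpm([1.0])]
            )

    def test_passes_iff_abs_fold_at_least_two(self):
        rng = np.random.default_rng(9)
        a = profiles_from_rpm(list(rng.gamma(1.0, 20.0, size=200)))
        b = profiles_from_rpm(list(rng.gamma(1.0, 20.0, size=200)))
        out = call_differential([a], [b])
        nonzero = (out["X"] > 0) | (out["Y"] > 0)
        expected = (out["fold_value"].abs() >= math.log2(4.0)) & nonzero
        assert (out["passes"] == expected).all()


class TestSubsetAndTrack:
    def test_subset_closed_range(self):
        ps = [placement(19, "chr1", 0), placement(20, "chr1", 0), placement(24, "chr1", 0)]
        sub = subset_by_size(ps, (20, 24))
        assert [p.read.length for p in sub] == [20, 24]

    def test_subset_counts_are_monotone(self):
        ps = [placement(n, "chr1", n * 10) for n in range(18, 27)]
        full = count_windows(ps, GENOME, (18, 26))
        sub = count_windows(subset_by_size(ps, (20, 24)), GENOME, (20, 24))
        assert (sub["raw_count"] <= full["raw_count"]).all()

    def test_track_is_ordered_and_complete(self):
        a = profiles_from_rpm(list(np.arange(10, dtype=float)))
        out = call_differential([a], [a])
        tracks = chromosome_track(out)
        assert set(tracks) == {"chr1"}
        assert len(tracks["chr1"]) == 10
        assert (np.diff(tracks["chr1"]["position"]) > 0).all()
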