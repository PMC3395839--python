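import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import baccgh as b
from baccgh.errors import InvalidInputError
from baccgh.segmentation import (Segment, read_segments, segments_to_frame,
                                 write_segments)


def brute_force_max_arc(values):
    """Exhaustive double-loop oracle over all circular arcs.

    Independently recomputes the pooled two-sample t with plain slicing
    and scalar numpy calls on each arc/complement split.
    """
    x = np.asarray(values, dtype=float)
    m = len(x)
    best = (1, 2, 0.0)
    for i in range(1, m + 1):
        for j in range(i + 1, m + 1):
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            ss = (((arc - arc.mean()) ** 2).sum()
                  + ((rest - rest.mean()) ** 2).sum())
            diff = abs(arc.mean() - rest.mean())
            denom = np.sqrt(ss / max(m - 2, 1)
                            * (1 / len(arc) + 1 / len(rest)))
            if denom == 0.0:
                t = 0.0 if diff == 0.0 else np.inf
            else:
                t = diff / denom
            if t > best[2]:
                best = (i, j, t)
    return best


def pieces_of(i, j, m):
    """Normalized partition induced by arc boundaries (i, j) on 0..m."""
    cuts = sorted({0, i, j, m})
    return tuple((a, c) for a, c in zip(cuts, cuts[1:]))


def chrom_frame(values, chrom="1"):
    n = len(values)
    return pd.DataFrame(
        {
            "clone_id": [f"c{k}" for k in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 1_000_000 + 1,
            "end": np.arange(n) * 1_000_000 + 150_000,
            "mean_log2": values,
            "sd_log2": 0.0,
            "n_spots": 3,
            "qc_pass": True,
        }
    )


class TestMaxArcStatistic:
    def test_perfect_step_isolated(self):
        i, j, T = b.max_arc_statistic([0, 0, 0, 1, 1, 1])
        assert pieces_of(i, j, 6) == ((0, 3), (3, 6))
        assert T > 0

    def test_constant_vector_gives_zero(self):
        i, j, T = b.max_arc_statistic([0.5] * 8)
        assert T == 0.0
        assert (i, j) == (1, 2)  # first admissible pair

    def test_matches_brute_force_on_gaussian(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(size=30)
            assert b.max_arc_statistic(x) == pytest.approx(
                brute_force_max_arc(x), abs=1e-9)

    def test_rejects_short_input(self):
        with pytest.raises(InvalidInputError):
            b.max_arc_statistic([1.0])


class TestPermutationPvalue:
    def test_constant_null_floor(self):
        config = b.SegmentationConfig(n_permutations=200, seed=1)
        p = b.permutation_pvalue([0.0] * 10, T_obs=3.0, config=config)
        assert p == pytest.approx(1 / 201)

    def test_zero_statistic_gives_one(self):
        config = b.SegmentationConfig(n_permutations=200, seed=1)
        assert b.permutation_pvalue([1.0, 2.0, 3.0], 0.0, config) == 1.0

    def test_strong_step_reaches_floor(self):
        x = [0.0] * 10 + [1.0] * 10
        config = b.SegmentationConfig(n_permutations=200, seed=3)
        _, _, T = b.max_arc_statistic(x)
        assert b.permutation_pvalue(x, T, config) <= 0.01

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        _, _, T = b.max_arc_statistic(x)
        config = b.SegmentationConfig(n_permutations=300, seed=9)
        p1 = b.permutation_pvalue(x, T, config,
                                  np.random.default_rng(9))
        p2 = b.permutation_pvalue(x, T, config,
                                  np.random.default_rng(9))
        assert p1 == p2


class TestSegmentChromosome:
    def test_perfect_step_two_segments(self):
        clones = chrom_frame([0.0] * 10 + [1.0] * 10)
        segments = b.segment_chromosome(clones, b.SegmentationConfig(seed=0))
        assert len(segments) == 2
        assert segments[0].mean_log2 == pytest.approx(0.0)
        assert segments[1].mean_log2 == pytest.approx(1.0)
        assert segments[0].end_index == 9
        assert segments[1].start_index == 10

    def test_constant_chromosome_single_segment(self):
        clones = chrom_frame([0.1] * 30)
        segments = b.segment_chromosome(clones, b.SegmentationConfig(seed=0))
        assert len(segments) == 1
        assert segments[0].n_clones == 30

    def test_breakpoints_match_least_squares_oracle(self):
        """Noisy 3-level chromosome vs exhaustive 2-changepoint SSE fit."""
        rng = np.random.default_rng(21)
        levels = np.concatenate([np.zeros(30), np.full(15, 0.8),
                                 np.full(25, -0.6)])
        x = levels + rng.normal(0, 0.05, len(levels))
        best, best_sse = None, np.inf
        for a in range(2, len(x) - 3):
            for c in range(a + 2, len(x) - 1):
                sse = sum(((x[lo:hi] - x[lo:hi].mean()) ** 2).sum()
                          for lo, hi in ((0, a), (a, c), (c, len(x))))
                if sse < best_sse:
                    best, best_sse = (a, c), sse
        segments = b.segment_chromosome(chrom_frame(x),
                                        b.SegmentationConfig(seed=2))
        breaks = sorted(s.start_index for s in segments[1:])
        assert len(breaks) == 2
        assert all(min(abs(bk - o) for bk in breaks) <= 1 for o in best)

    def test_partition_invariant(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.05, 20),
                            rng.normal(1.0, 0.05, 12)])
        segments = b.segment_chromosome(chrom_frame(x),
                                        b.SegmentationConfig(seed=4))
        covered = []
        for s in segments:
            covered.extend(range(s.start_index, s.end_index + 1))
        assert covered == list(range(len(x)))

    @given(st.sampled_from([np.exp, np.tanh, lambda v: v ** 3 + 2 * v]))
    def test_monotone_transform_leaves_boundaries(self, f):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 0.3, 15),
                            rng.normal(2.0, 0.3, 15)])
        cfg = b.SegmentationConfig(seed=5)
        raw = b.segment_chromosome(chrom_frame(x), cfg)
        transformed = b.segment_chromosome(chrom_frame(f(x)), cfg)
        assert ([(s.start_index, s.end_index) for s in raw]
                == [(s.start_index, s.end_index) for s in transformed])

    def test_short_window_single_segment(self):
        clones = chrom_frame([0.0, 5.0, 0.1])
        segments = b.segment_chromosome(
            clones, b.SegmentationConfig(min_width=2, seed=0))
        assert len(segments) == 1

    def test_empty_input(self):
        assert b.segment_chromosome(chrom_frame([]),
                                    b.SegmentationConfig()) == []


class TestSegmentProfile:
    def test_neutral_profile_one_segment_per_chromosome(self, design_small,
                                                        zero_noise):
        truth = b.preset_truth("normal_male_leukocyte")
        spots = b.simulate_spot_table(design_small, truth, zero_noise, 0)
        profile = b.drop_chromosome(
            b.qc_filter(b.summarize_replicates(spots, design_small)), "Y")
        segments = b.segment_profile(profile, b.SegmentationConfig(seed=0))
        assert len(segments) == profile.clones["chrom"].nunique()

    def test_zero_noise_boundaries_match_truth(self, design_full,
                                               zero_noise):
        truth = b.preset_truth("vcap_like")
        spots = b.simulate_spot_table(design_full, truth, zero_noise, 0)
        profile = b.drop_chromosome(
            b.qc_filter(b.summarize_replicates(spots, design_full)), "Y")
        segments = b.segment_profile(profile, b.SegmentationConfig(seed=0))
        for ab in truth.aberrations:
            members = [c.id for c in design_full.clones
                       if c.chromosome == ab.chromosome
                       and ab.start <= c.midpoint <= ab.end]
            matching = [s for s in segments
                        if s.chromosome == ab.chromosome
                        and set(members) == set(s.clone_ids)]
            assert matching, f"no segment matches aberration {ab}"

    def test_seeded_reproducibility(self, design_small):
        truth = b.preset_truth("pc3_like")
        spots = b.simulate_spot_table(design_small, truth, b.NoiseParams(), 6)
        profile = b.drop_chromosome(
            b.qc_filter(b.summarize_replicates(spots, design_small)), "Y")
        cfg = b.SegmentationConfig(seed=77)
        s1 = b.segment_profile(profile, cfg)
        s2 = b.segment_profile(profile, cfg)
        assert s1 == s2


class TestSegmentIO:
    def test_bed_round_trip(self, tmp_path):
        segments = [
            Segment("1", 0, 9, 1, 10_000_000, 0.25, 10, ("a", "b")),
            Segment("2", 0, 4, 500, 2_000_000, -0.7, 5),
        ]
        path = tmp_path / "segments.bed"
        write_segments(segments, path)
        frame = segments_to_frame(segments)
        assert list(frame["start"]) == [0, 499]  # 0-based half-open
        back = read_segments(path)
        assert [(s.chromosome, s.start_bp, s.end_bp, s.n_clones)
                for s in back] == [("1", 1, 10_000_000, 10),
                                   ("2", 500, 2_000_000, 5)]
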