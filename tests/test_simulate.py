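"""Synthetic benchmark generators and the overlap-based evaluation."""

import numpy as np
import pytest

from trackmatch import (
    GenomeLayout,
    MatchedRegionSpec,
    NoiseSpec,
    Region,
    ScoredRegion,
    SearchConfig,
    SignalTrack,
    TruthSet,
    build_index,
    default_genome,
    derive_positives_by_self_search,
    evaluate,
    replace_with_noise,
    simulate_matched_pair,
    write_bedgraph,
)


@pytest.fixture
def small_genome():
    return default_genome(n_chromosomes=2, chrom_length=400_000)


class TestSimulateMatchedPair:
    def test_deterministic_given_seed(self, small_genome):
        spec = MatchedRegionSpec(n_regions=10, genome=small_genome)
        out1 = simulate_matched_pair(spec, 5, 0, np.random.default_rng(9))
        out2 = simulate_matched_pair(spec, 5, 0, np.random.default_rng(9))
        for chrom in small_genome.names:
            for a, b in ((out1[0], out2[0]), (out1[1], out2[1])):
                s1, e1, v1 = a.intervals(chrom)
                s2, e2, v2 = b.intervals(chrom)
                assert np.array_equal(s1, s2) and np.allclose(v1, v2)
        assert out1[2].regions == out2[2].regions

    def test_segment_counts_and_lengths_in_range(self, small_genome):
        spec = MatchedRegionSpec(n_regions=15, genome=small_genome)
        query, _, truth = simulate_matched_pair(
            spec, 0, 0, np.random.default_rng(10)
        )
        for region in truth.regions:
            starts, ends, _ = query.intervals(region.chrom)
            inside = [
                (s, e)
                for s, e in zip(starts, ends)
                if s >= region.start and e <= region.end
            ]
            n_inside = len(inside)
            assert 1 <= n_inside <= 10
            for s, e in inside:
                assert 100 <= e - s <= 2000

    def test_noiseless_pair_identical_inside_truth_zero_outside(self, small_genome):
        spec = MatchedRegionSpec(n_regions=8, genome=small_genome)
        query, target, truth = simulate_matched_pair(
            spec, 0, 0, np.random.default_rng(11)
        )
        for chrom in small_genome.names:
            qs, qe, qv = query.intervals(chrom)
            ts, te, tv = target.intervals(chrom)
            assert np.array_equal(qs, ts) and np.allclose(qv, tv)
        covered = sum(r.length for r in truth.regions)
        q_mass_extent = sum(
            (e - s).sum() for s, e, _ in
            (query.intervals(c) for c in small_genome.names)
        )
        assert q_mass_extent <= covered  # signal only inside truth regions

    def test_truth_and_extras_never_overlap(self, small_genome):
        spec = MatchedRegionSpec(n_regions=10, genome=small_genome)
        _, target, truth = simulate_matched_pair(spec, 30, 0, np.random.default_rng(12))
        for chrom in small_genome.names:
            starts, ends, _ = target.intervals(chrom)
            for a, b in zip(ends[:-1], starts[1:]):
                assert b >= a  # placement produced disjoint intervals

    def test_placement_failure_suggests_remedy(self):
        cramped = GenomeLayout([("c1", 30_000)])
        spec = MatchedRegionSpec(n_regions=50, genome=cramped)
        with pytest.raises(RuntimeError, match="larger genome"):
            simulate_matched_pair(spec, 0, 0, np.random.default_rng(13))


class TestReplaceWithNoise:
    def test_positives_covering_everything_is_identity(self, small_genome):
        spec = MatchedRegionSpec(n_regions=5, genome=small_genome)
        track, _, _ = simulate_matched_pair(spec, 0, 0, np.random.default_rng(14))
        positives = TruthSet(
            [Region(c, 0, l) for c, l in small_genome], "noise_replacement"
        )
        out = replace_with_noise(
            track, positives, NoiseSpec(), small_genome, np.random.default_rng(1)
        )
        for chrom in small_genome.names:
            s1, e1, v1 = track.intervals(chrom)
            s2, e2, v2 = out.intervals(chrom)
            assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
            assert np.array_equal(v1, v2)  # bitwise conservation inside positives

    def test_signal_conserved_inside_positives(self, small_genome):
        spec = MatchedRegionSpec(n_regions=6, genome=small_genome)
        track, _, truth = simulate_matched_pair(spec, 0, 0, np.random.default_rng(15))
        out = replace_with_noise(
            track, truth, NoiseSpec(), small_genome, np.random.default_rng(2)
        )
        for r in truth.regions:
            a = track.values_per_base(r.chrom, r.start, r.end)
            b = out.values_per_base(r.chrom, r.start, r.end)
            assert np.array_equal(a, b)

    def test_noise_location_count_matches_poisson_rate(self):
        # expected count ~ N * lambda; allow 5 standard deviations
        layout = GenomeLayout([("c1", 1_000_000)])
        track = SignalTrack(layout, {})
        positives = TruthSet([Region("c1", 0, 1000)], "noise_replacement")
        lam = 0.01
        out = replace_with_noise(
            track,
            positives,
            NoiseSpec(lam=lam, mu=5.0, sigma2=1.0),
            layout,
            np.random.default_rng(3),
            point_width=1,
        )
        starts, _, _ = out.intervals("c1")
        n = len(starts)
        expected = 1_000_000 * lam
        assert abs(n - expected) < 5 * np.sqrt(expected)

    def test_mean_gap_is_inverse_rate(self):
        layout = GenomeLayout([("c1", 2_000_000)])
        track = SignalTrack(layout, {})
        positives = TruthSet([Region("c1", 0, 100)], "noise_replacement")
        out = replace_with_noise(
            track,
            positives,
            NoiseSpec(lam=0.01, mu=5.0, sigma2=1.0),
            layout,
            np.random.default_rng(4),
            point_width=1,
        )
        starts, _, _ = out.intervals("c1")
        gaps = np.diff(starts)
        assert np.mean(gaps) == pytest.approx(100, rel=0.05)

    def test_values_never_negative(self):
        layout = GenomeLayout([("c1", 200_000)])
        track = SignalTrack(
            layout, {"c1": (np.array([0]), np.array([1000]), np.array([3.0]))}
        )
        positives = TruthSet([Region("c1", 0, 1000)], "noise_replacement")
        out = replace_with_noise(
            track,
            positives,
            NoiseSpec(mu=0.1, sigma2=4.0),
            layout,
            np.random.default_rng(5),
        )
        _, _, values = out.intervals("c1")
        assert np.all(values >= 0)


class TestDerivePositives:
    def _self_index(self, tmp_path, genome, n_regions, rng):
        spec = MatchedRegionSpec(n_regions=n_regions, genome=genome)
        track, _, _ = simulate_matched_pair(spec, 0, 0, rng)
        path = tmp_path / "self.bedGraph"
        write_bedgraph(track, str(path))
        index = build_index([{"target_id": "self", "path": str(path)}], genome)
        return track, index

    def test_topk_self_search(self, tmp_path, small_genome):
        track, index = self._self_index(
            tmp_path, small_genome, 30, np.random.default_rng(16)
        )
        cfg = SearchConfig(rng_seed=8)
        positives = derive_positives_by_self_search(track, index, 20, cfg)
        assert len(positives) == 20

    def test_k_beyond_available_returns_all_found(self, tmp_path, small_genome):
        track, index = self._self_index(
            tmp_path, small_genome, 5, np.random.default_rng(18)
        )
        cfg = SearchConfig(rng_seed=8)
        positives = derive_positives_by_self_search(track, index, 50, cfg)
        assert 0 < len(positives) <= 50


class TestEvaluate:
    truth = TruthSet(
        [Region("c1", 100, 200), Region("c1", 500, 700), Region("c2", 0, 50)]
    )

    @staticmethod
    def _result(chrom, start, end, target="T"):
        return ScoredRegion(Region(chrom, start, end), 1.0, 0.7, target)

    def test_perfect_results(self):
        results = [self._result(r.chrom, r.start, r.end) for r in self.truth.regions]
        rep = evaluate(results, self.truth)
        assert rep.sensitivity == 1.0 and rep.precision == 1.0

    def test_empty_results(self):
        rep = evaluate([], self.truth)
        assert rep.sensitivity == 0.0 and rep.precision is None

    def test_hand_counted_case(self):
        # 3 truth regions, 4 results of which 3 overlap distinct truths
        results = [
            self._result("c1", 150, 250),
            self._result("c1", 600, 800),
            self._result("c2", 40, 90),
            self._result("c2", 5000, 6000),  # off-truth
        ]
        rep = evaluate(results, self.truth)
        assert rep.sensitivity == 1.0
        assert rep.precision == pytest.approx(0.75)

    def test_wrong_target_not_credited(self):
        results = [self._result("c1", 100, 200, target="other")]
        rep = evaluate(results, self.truth, expected_target="T")
        assert rep.sensitivity == 0.0 and rep.precision == 0.0

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError):
            evaluate([], TruthSet([]))
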