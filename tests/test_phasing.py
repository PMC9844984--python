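"""Windowed clustering, voting, stitching, and window-size prediction."""

import numpy as np
import pytest

import meioscan as ms
from meioscan.matrix import NA
from meioscan.phasing import phase_window, stitch_haplotypes

from conftest import make_matrix


class TestMakeWindows:
    def test_hand_constructed_overlapping_windows(self):
        spec = ms.make_windows(10, window_length=6, overlap=3)
        assert spec.bounds == [(0, 6), (3, 9), (6, 10)]

    def test_short_chromosome_gets_single_window(self):
        assert ms.make_windows(5, window_length=6, overlap=3).bounds == [(0, 5)]

    def test_single_snp(self):
        assert ms.make_windows(1, window_length=6, overlap=3).bounds == [(0, 1)]

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            ms.make_windows(10, window_length=6, overlap=6)

    @pytest.mark.parametrize("n,w,o", [(10, 6, 3), (100, 7, 2), (17, 5, 4), (3000, 1000, 500)])
    def test_windows_cover_everything_with_exact_overlap(self, n, w, o):
        spec = ms.make_windows(n, window_length=w, overlap=o)
        covered = np.zeros(n, dtype=int)
        for s, e in spec.bounds:
            covered[s:e] += 1
        assert (covered >= 1).all()
        if o <= w // 2:  # beyond half-overlap an index can sit in >2 windows
            assert covered.max() <= 2
        for (s1, e1), (s2, e2) in zip(spec.bounds, spec.bounds[1:]):
            assert e1 - s2 == o


class TestJaccardDistances:
    def test_hand_worked_pair(self):
        # g1=[1,1,0,NA], g2=[1,0,0,1]: complete sites 1-3; sites with a one:
        # {1,2}; discordant among them: {2}  ->  d = 1/2
        g = np.array([[1, 1], [1, 0], [0, 0], [NA, 1]], dtype=np.int8)
        d = ms.jaccard_distances(g)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 0] == 0.0

    def test_pair_without_usable_sites_gets_distance_one(self):
        g = np.array([[0, 0], [NA, 1]], dtype=np.int8)  # only shared site is 0/0
        assert ms.jaccard_distances(g)[0, 1] == 1.0

    def test_identical_and_complementary_gametes(self):
        g = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0]], dtype=np.int8)
        d = ms.jaccard_distances(g)
        assert d[0, 1] == 0.0 and d[0, 2] == 1.0


class TestPhaseWindow:
    def test_noiseless_complementary_clusters(self):
        h1, h2 = [0, 1, 0], [1, 0, 1]
        g = np.array([h1, h2, h1, h2], dtype=np.int8).T
        out = phase_window(g)
        assert out.tolist() in ([0, 1, 0], [1, 0, 1])

    def test_tied_votes_in_both_clusters_become_na(self):
        # sites 0-1 define the clusters {g0,g1} vs {g2,g3}; at site 2 both
        # clusters split their votes 1:1
        g = np.array(
            [[1, 1, 0, 0],
             [0, 0, 1, 1],
             [0, 1, 0, 1]], dtype=np.int8)
        out = phase_window(g)
        assert out[2] == NA and NA not in (out[0], out[1])

    def test_one_sided_vote_filled_as_complement(self):
        g = np.array(
            [[1, 1, 0, 0],
             [0, 0, 1, 1],
             [NA, NA, 1, 1]], dtype=np.int8)
        out = phase_window(g)
        # site 2 only voted in cluster {g2,g3}, whose votes at sites 1 and 2
        # are identical; the complement fill must keep them consistent
        assert out[2] != NA
        assert out[2] == out[1]

    def test_identical_gametes_yield_all_na(self):
        g = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        assert (phase_window(g) == NA).all()


class TestStitching:
    def _spec(self, n=6, w=4, o=2):
        return ms.make_windows(n, window_length=w, overlap=o)

    def test_identical_overlap_keeps_orientation(self):
        spec = self._spec()
        w1 = np.array([0, 1, 0, 1], dtype=np.int8)
        w2 = np.array([0, 1, 1, 0], dtype=np.int8)
        haps, report = stitch_haplotypes([w1, w2], spec, np.arange(1, 7))
        assert report.action == ["keep"]
        assert haps.h1.tolist() == [0, 1, 0, 1, 1, 0]

    def test_complementary_overlap_flips_right_window(self):
        spec = self._spec()
        w1 = np.array([0, 1, 0, 1], dtype=np.int8)
        w2 = np.array([1, 0, 0, 1], dtype=np.int8)
        haps, report = stitch_haplotypes([w1, w2], spec, np.arange(1, 7))
        assert report.action == ["flip"]
        assert report.consensus == [0.0]
        assert haps.h1.tolist() == [0, 1, 0, 1, 1, 0]

    def test_ambiguous_consensus_errors_in_stringent_mode(self):
        spec = self._spec()
        w1 = np.array([0, 1, 0, 1], dtype=np.int8)
        w2 = np.array([0, 0, 1, 1], dtype=np.int8)  # consensus 0.5
        with pytest.raises(ms.DiscordantWindowsError, match="junction 1"):
            stitch_haplotypes([w1, w2], spec, np.arange(1, 7), threshold=0.9)

    def test_lenient_mode_takes_higher_consensus_orientation(self):
        spec = self._spec(n=8, w=6, o=4)
        w1 = np.array([0, 1, 0, 1, 0, 1], dtype=np.int8)
        w2 = np.array([0, 1, 0, 0, 1, 1], dtype=np.int8)  # consensus 0.75
        haps, report = stitch_haplotypes([w1, w2], spec, np.arange(1, 9), mode="lenient")
        assert report.action == ["keep"]
        # overlap sites keep the left window's calls
        assert haps.h1[:6].tolist() == w1.tolist()

    def test_left_window_wins_at_overlap_unless_na(self):
        spec = self._spec()
        w1 = np.array([0, 1, NA, 1], dtype=np.int8)
        w2 = np.array([0, 1, 1, 0], dtype=np.int8)
        haps, _ = stitch_haplotypes([w1, w2], spec, np.arange(1, 7), mode="lenient")
        assert haps.h1[2] == 0  # NA in left filled from right window
        assert haps.h1[3] == 1


class TestPhaseEndToEnd:
    def test_complementarity_wherever_both_phased(self, moderate_run):
        *_, result = moderate_run
        haps = result.haplotypes
        both = (haps.h1 != NA) & (haps.h2 != NA)
        assert np.array_equal(haps.h2[both], 1 - haps.h1[both])

    def test_noiseless_recovery_up_to_global_swap(self, noiseless_run):
        _, _, truth, result = noiseless_run
        metrics = ms.evaluate_phasing(result.haplotypes, truth)
        assert metrics.accuracy == 1.0
        assert metrics.completeness == 1.0
        assert metrics.switch_error_rate == 0.0


@pytest.fixture(scope="module")
def window_model():
    return ms.fit_window_model(seed=5)


class TestWindowSizeModel:
    def test_coefficient_signs_match_known_effects(self, window_model):
        # more gametes and coverage favour larger windows; faster
        # recombination favours smaller ones
        assert window_model.coefficient("n_gametes") > 0
        assert window_model.coefficient("coverage") > 0
        assert window_model.coefficient("recomb_rate") < 0

    def test_proportion_monotone_in_gamete_count(self, window_model):
        small = window_model.predict_proportion(100, 0.4, 0.005, 1.0)
        large = window_model.predict_proportion(1000, 0.4, 0.005, 1.0)
        assert small <= large

    def test_proportion_decreasing_in_recombination_rate(self, window_model):
        slow = window_model.predict_proportion(100, 0.4, 0.005, 0.6)
        fast = window_model.predict_proportion(100, 0.4, 0.005, 3.0)
        assert fast <= slow

    def test_predictions_stay_in_unit_interval(self, window_model):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = window_model.predict_proportion(
                rng.uniform(1, 10_000), rng.uniform(0, 5),
                rng.uniform(0, 0.2), rng.uniform(0, 10),
            )
            assert 0.0 < p < 1.0

    def test_window_length_has_floor_of_two(self, window_model):
        assert window_model.predict_window_length(
            2, n_gametes=20, coverage=0.15, error_rate=0.005, recomb_rate=4.0) >= 2

    def test_missing_model_falls_back_to_default(self, caplog):
        with caplog.at_level("WARNING"):
            w = ms.auto_window_length(50_000, 100, 0.01, 0.005, 1.0, model=None)
        assert w == 3000
        assert "falling back" in caplog.text
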