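"""Gaussian match statistic, delay scanning, and the state-shuffle null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statebound.match import (
    MatchConfig,
    choose_seed,
    delay_scan,
    gaussian_match,
    gaussian_weight,
    relative_match,
    shuffle_states,
)
from statebound.timelines import shift_timeline

from conftest import neural_timeline


class TestGaussianWeight:
    def test_zero_distance_is_one(self):
        assert gaussian_weight(0.0) == 1.0

    def test_one_sigma_is_exp_minus_half(self):
        assert gaussian_weight(0.332, 0.332) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self, rng):
        d = rng.uniform(0, 2, 50)
        assert np.allclose(gaussian_weight(d), gaussian_weight(-d))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_weight(0.1, sigma_s=0.0)


class TestGaussianMatch:
    def test_identical_timelines_match_one(self):
        t = neural_timeline({1: [64, 300, 1900], 3: [5]})
        assert gaussian_match(t, t) == 1.0

    def test_single_pair_closed_form(self):
        # 21-sample offset at 64 Hz = 0.328125 s
        v = gaussian_match(neural_timeline({1: [64]}), neural_timeline({1: [85]}))
        assert v == pytest.approx(np.exp(-0.328125**2 / (2 * 0.332**2)), abs=1e-12)

    def test_mean_over_seed_marks(self):
        v = gaussian_match(neural_timeline({1: [10, 100]}),
                           neural_timeline({1: [10]}))
        far = np.exp(-((90 / 64) ** 2) / (2 * 0.332**2))
        assert v == pytest.approx((1.0 + far) / 2, abs=1e-12)

    def test_non_commutative_on_asymmetric_pair(self):
        a = neural_timeline({1: [100]})
        b = neural_timeline({1: [100, 500]})
        assert gaussian_match(a, b) == 1.0
        assert gaussian_match(b, a) < 1.0

    def test_closest_search_does_not_cross_blocks(self):
        # seed mark in block 3 must not see the near-in-time mark of block 1
        seed = neural_timeline({1: [], 3: [0]})
        other = neural_timeline({1: [1919], 3: [640]})
        assert gaussian_match(seed, other) == pytest.approx(
            gaussian_weight(640 / 64), abs=1e-15)

    def test_blocks_with_empty_other_excluded_from_mean(self):
        seed = neural_timeline({1: [10], 3: [10]})
        other = neural_timeline({1: [10], 3: []})
        assert gaussian_match(seed, other) == 1.0

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            gaussian_match(neural_timeline({1: []}), neural_timeline({1: [5]}))

    def test_per_block_pooling_differs_when_block_counts_differ(self):
        seed = neural_timeline({1: [10, 20, 30], 3: [40]})
        other = neural_timeline({1: [10, 20, 30], 3: [48]})
        pooled = gaussian_match(seed, other, MatchConfig(pooling="pooled"))
        per_block = gaussian_match(seed, other, MatchConfig(pooling="per_block"))
        w = gaussian_weight(8 / 64)
        assert pooled == pytest.approx((3 + w) / 4)
        assert per_block == pytest.approx((1 + w) / 2)


class TestChooseSeed:
    def test_stimulus_timeline_always_seeds(self, schedule):
        stim = neural_timeline({1: list(range(0, 1900, 20))})
        stim.provenance = "stimulus_feature"
        neural = neural_timeline({1: [5]})
        assert choose_seed(neural, stim, "stimulus_vs_neural")[0] is stim

    def test_neural_mode_seeds_fewer_marks(self):
        a = neural_timeline({1: list(range(0, 200, 10))})
        b = neural_timeline({1: [4, 8]})
        assert choose_seed(a, b, "neural_vs_neural")[0] is b

    def test_tie_keeps_first_argument(self):
        a = neural_timeline({1: [1, 2]})
        b = neural_timeline({1: [3, 4]})
        assert choose_seed(a, b, "neural_vs_neural")[0] is a


class TestDelayScan:
    def test_grid_endpoints_truncate_600ms(self):
        cfg = MatchConfig()
        stim = cfg.delay_grid("stimulus_vs_neural")
        neur = cfg.delay_grid("neural_vs_neural")
        assert stim[0] == 0 and stim[-1] == 38   # 38/64 s = 593.75 ms
        assert neur[0] == -38 and neur[-1] == 38

    def test_shifted_copy_recovers_exact_delay(self):
        seed = neural_timeline({1: list(range(50, 1800, 97))})
        other = shift_timeline(seed, 8)
        curve = delay_scan(seed, other, mode="stimulus_vs_neural")
        assert curve.optimal_delay == 8
        assert curve.max_match == 1.0

    def test_argmax_at_least_value_at_zero(self, rng):
        seed = neural_timeline({1: np.sort(rng.choice(1920, 30, replace=False))})
        other = neural_timeline({1: np.sort(rng.choice(1920, 40, replace=False))})
        curve = delay_scan(seed, other, mode="neural_vs_neural")
        zero = int(np.flatnonzero(curve.delays_samples == 0)[0])
        assert curve.max_match >= curve.values[zero]

    def test_tie_prefers_smallest_absolute_delay(self):
        curve = delay_scan(neural_timeline({1: [960]}),
                           neural_timeline({1: [960]}),
                           mode="neural_vs_neural")
        assert curve.optimal_delay == 0  # many delays tie at w(±k); 0 wins

    def test_monotone_degradation_with_jitter(self):
        base = np.arange(60, 1860, 60)
        cfg = MatchConfig()
        means = []
        for sd in (0, 2, 5, 10):
            vals = []
            for s in range(20):
                r = np.random.default_rng(1000 + s)
                jit = np.clip(base + r.normal(0, sd, base.size), 0, 1919)
                vals.append(gaussian_match(
                    neural_timeline({1: base}),
                    neural_timeline({1: np.unique(np.round(jit))}), cfg))
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestShuffleStates:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 1918), min_size=0, max_size=40, unique=True),
           st.integers(0, 2**31 - 1))
    def test_conservation_of_marks_and_durations(self, marks, seed):
        t = neural_timeline({1: sorted(marks)})
        s = shuffle_states(t, np.random.default_rng(seed))
        assert s.n_marks == t.n_marks
        before = sorted(np.diff(np.concatenate(([0], t.blocks[1], [1920]))))
        after = sorted(np.diff(np.concatenate(([0], s.blocks[1], [1920]))))
        assert before == after

    def test_single_state_block_unchanged(self, rng):
        t = neural_timeline({1: []})
        assert shuffle_states(t, rng).n_marks == 0


class TestRelativeMatch:
    def test_perfect_alignment_gives_relative_one(self):
        t = neural_timeline({1: [100, 600, 1100, 1600]})
        res = relative_match(t, t, MatchConfig(n_perm=50), rng=0)
        assert res.match_data == 1.0
        assert res.relative == pytest.approx(1.0)

    def test_relative_zero_when_data_equals_null(self):
        t = neural_timeline({1: [100, 600, 1100, 1600]})
        res = relative_match(t, shift_timeline(t, 3), MatchConfig(n_perm=50),
                             rng=0)
        fake = (res.match_null - res.match_null) / (1 - res.match_null)
        assert fake == 0.0  # the normalization formula itself

    def test_permutation_maxima_retained_and_reproducible(self):
        a = neural_timeline({1: np.arange(100, 1900, 111)})
        b = neural_timeline({1: np.arange(140, 1900, 97)})
        cfg = MatchConfig(n_perm=25)
        r1 = relative_match(a, b, cfg, rng=42)
        r2 = relative_match(a, b, cfg, rng=42)
        assert r1.perm_maxima.shape == (25,)
        assert np.array_equal(r1.perm_maxima, r2.perm_maxima)
        assert r1.relative == r2.relative

    def test_invalid_n_perm(self):
        t = neural_timeline({1: [5, 500]})
        with pytest.raises(ValueError):
            relative_match(t, t, MatchConfig(n_perm=0))
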