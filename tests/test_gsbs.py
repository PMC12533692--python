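"""Greedy state-boundary search against brute-force oracles, and model selection."""

import numpy as np
import pytest
from scipy import stats as sps

from statebound.gsbs import (
    GreedyStateSegmentation,
    find_peaks,
    greedy_segment,
    select_nstates_block,
    select_nstates_global,
    tdistance,
    timepoint_correlation_matrix,
)


# ----------------------------------------------------------------- oracles
def naive_fit(X, boundaries):
    """Mean over timepoints of Pearson r between pattern and its state mean."""
    edges = [0, *sorted(boundaries), len(X)]
    total = 0.0
    for a, b in zip(edges, edges[1:]):
        m = X[a:b].mean(axis=0)
        for t in range(a, b):
            if np.std(X[t]) == 0 or np.std(m) == 0:
                continue
            total += sps.pearsonr(X[t], m).statistic
    return total / len(X)


def brute_force_first_boundary(X):
    scores = [naive_fit(X, [b]) for b in range(1, len(X))]
    return 1 + int(np.argmax(scores))


def brute_force_best_pair(X):
    T = len(X)
    best, best_pair = -np.inf, None
    for p in range(1, T - 1):
        for q in range(p + 1, T):
            f = naive_fit(X, [p, q])
            if f > best + 1e-12:
                best, best_pair = f, (p, q)
    return best, best_pair


def naive_tdistance(boundaries, corr):
    T = corr.shape[0]
    labels = np.zeros(T, dtype=int)
    for b in boundaries:
        labels[b:] += 1
    iu = np.triu_indices(T, 1)
    vals = corr[iu]
    same = labels[iu[0]] == labels[iu[1]]
    consec = np.abs(labels[iu[0]] - labels[iu[1]]) == 1
    return sps.ttest_ind(vals[same], vals[consec], equal_var=True).statistic


def piecewise(patterns, lengths, noise_sd, rng):
    X = np.concatenate([np.tile(p, (n, 1)) for p, n in zip(patterns, lengths)])
    return X + noise_sd * rng.standard_normal(X.shape)


# ------------------------------------------------------------------- tests
class TestCorrelationMatrix:
    def test_block_structure_and_unit_diagonal(self, rng):
        A, B = rng.standard_normal(6), rng.standard_normal(6)
        X = piecewise([A, B], [2, 2], 0.0, rng)
        C = timepoint_correlation_matrix(X)
        assert np.allclose(np.diag(C), 1.0)
        assert C[0, 1] == pytest.approx(1.0)
        assert abs(C[0, 2]) < 1.0  # across states not perfectly correlated
        assert np.allclose(C, C.T)

    def test_invariant_to_rescoring_of_prepared_data(self, rng):
        # pipeline blocks arrive z-scored per channel; re-standardizing them
        # is a no-op, so the correlation matrix must not change
        X = rng.standard_normal((15, 6))
        X = (X - X.mean(0)) / X.std(0)
        Z = (X - X.mean(0)) / X.std(0)
        assert np.allclose(timepoint_correlation_matrix(X),
                           timepoint_correlation_matrix(Z), atol=1e-10)

    def test_zero_variance_pattern_rejected(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="zero-variance"):
            timepoint_correlation_matrix(X)


class TestGreedySearch:
    def test_first_boundary_on_clean_two_state_signal(self, rng):
        A, B = rng.standard_normal(4), rng.standard_normal(4)
        X = piecewise([A, B], [4, 4], 0.01, rng)
        est = GreedyStateSegmentation(k_max=4, compute_tdistance=False).fit(X)
        assert list(est.path_[2]) == [4]

    @pytest.mark.parametrize("mode", ["two_stage", "exhaustive"])
    def test_embedded_state_placed_as_pair(self, rng, mode):
        A, B = rng.standard_normal(4), rng.standard_normal(4)
        X = piecewise([A, B, A], [2, 4, 2], 0.0, rng)
        est = GreedyStateSegmentation(k_max=4, pair_search=mode,
                                      compute_tdistance=False).fit(X)
        assert list(est.path_[3]) == [2, 6]
        _, oracle_pair = brute_force_best_pair(X)
        assert naive_fit(X, est.path_[3]) == pytest.approx(
            naive_fit(X, oracle_pair), abs=1e-9)

    def test_k1_is_empty_boundary_set(self, rng):
        est = GreedyStateSegmentation(k_max=3, compute_tdistance=False).fit(
            rng.standard_normal((10, 4)))
        assert est.path_[1].size == 0

    def test_determinism(self, rng):
        X = rng.standard_normal((40, 5))
        a = greedy_segment(X, k_max=8)
        b = greedy_segment(X.copy(), k_max=8)
        assert sorted(a) == sorted(b)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_path_plumbing_invariants(self, rng):
        X = rng.standard_normal((60, 5))
        path = greedy_segment(X, k_max=15)
        for k, bounds in path.items():
            assert len(bounds) == k - 1
            assert np.all(np.diff(bounds) > 0)
            assert np.all((bounds > 0) & (bounds < 60))
            durations = np.diff(np.concatenate(([0], bounds, [60])))
            assert durations.sum() == 60

    def test_state_labels_and_predict(self, rng):
        A, B = rng.standard_normal(5), rng.standard_normal(5)
        X = piecewise([A, B], [5, 5], 0.05, rng)
        est = GreedyStateSegmentation(k_max=4).fit(X)
        labels = est.state_labels(k=2)
        assert np.array_equal(labels, np.repeat([0, 1], 5))

    def test_sklearn_params_round_trip(self):
        est = GreedyStateSegmentation(k_max=7, finetune=0)
        assert est.get_params()["k_max"] == 7
        est.set_params(finetune=1)
        assert est.finetune == 1


class TestTDistance:
    def test_matches_naive_reimplementation_on_random_instances(self, rng):
        for _ in range(10):
            X = rng.standard_normal((20, 5))
            corr = timepoint_correlation_matrix(X)
            n_b = int(rng.integers(1, 5))
            bounds = np.sort(rng.choice(np.arange(1, 20), n_b, replace=False))
            assert tdistance(bounds, corr) == pytest.approx(
                naive_tdistance(bounds, corr), rel=1e-9)

    def test_true_segmentation_beats_perturbed_on_block_diagonal(self, rng):
        A, B, C = np.eye(6)[:3]
        X = piecewise([A, B, C], [6, 6, 6], 0.15, rng)
        corr = timepoint_correlation_matrix(X)
        t_true = tdistance([6, 12], corr)
        assert t_true > tdistance([8, 12], corr)
        assert t_true > tdistance([6, 14], corr)

    def test_identical_pools_give_zero(self):
        corr = np.full((6, 6), 0.5)
        np.fill_diagonal(corr, 1.0)
        assert tdistance([3], corr) == 0.0


class TestModelSelection:
    def test_single_curve_selects_its_argmax(self):
        curve = {2: 1.0, 3: 5.0, 4: 2.0}
        assert select_nstates_global([curve]) == 3

    def test_mean_of_two_shifted_curves_peaks_between(self):
        def bump(center):
            return {k: -((k - center) ** 2) for k in range(2, 50)}
        k = select_nstates_global([bump(20), bump(30)])
        assert 20 <= k <= 30
        assert k == 25

    def test_tie_in_mean_curve_takes_smallest_k(self):
        curve = {2: 1.0, 3: 4.0, 4: 4.0, 5: 0.0}
        assert select_nstates_global([curve]) == 3

    def test_peak_enumeration_with_plateau_pairs(self):
        curve = dict(zip(range(1, 7), [1, 3, 2, 2, 4, 1]))
        assert find_peaks(curve) == [2, 5]
        plateau = dict(zip(range(1, 5), [1, 2, 2, 1]))
        assert find_peaks(plateau) == [2]

    def test_block_selection_takes_nearest_peak(self):
        curve = dict(zip(range(1, 7), [1, 3, 2, 2, 4, 1]))
        assert select_nstates_block(curve, k_star=3) == 2  # distance 1 beats 2
        assert select_nstates_block(curve, k_star=5) == 5

    def test_monotone_curve_falls_back_to_argmax_with_warning(self):
        curve = {k: float(k) for k in range(2, 8)}
        with pytest.warns(UserWarning, match="no peak"):
            assert select_nstates_block(curve, k_star=4) == 7

    def test_selection_requires_input(self):
        with pytest.raises(ValueError):
            select_nstates_global([])
        with pytest.raises(ValueError):
            select_nstates_block({2: 1.0}, 2)
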