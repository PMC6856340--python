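"""Invariant density analysis: discretization, chain estimation, measures."""

import numpy as np
import pytest

from swaymetrics import ida
from swaymetrics.errors import DataError, NumericalError, ParameterError
from swaymetrics.ida import (
    BinGeometry,
    MarkovModel,
    discretize,
    entropy,
    estimate_transition_matrix,
    ida_summary,
    make_bins,
    second_eigenvector_zero_crossing,
    second_left_eigenvector,
    stationary_density,
    transition_counts,
)

from conftest import make_series

# Hand-solved 2-state chain: pi P = pi gives pi = [5/6, 1/6];
# eigenvalues of a 2x2 stochastic matrix are {1, trace - 1} = {1, 0.4}.
P_HAND = np.array([[0.9, 0.1], [0.5, 0.5]])
PI_HAND = np.array([5.0 / 6.0, 1.0 / 6.0])


def random_chain(n_states, rng):
    P = rng.uniform(0.01, 1.0, size=(n_states, n_states))
    return P / P.sum(axis=1, keepdims=True)


def two_state_model(P=P_HAND):
    return MarkovModel(states=np.array([0, 1]), P=P)


class TestBins:
    def test_uniform_width_from_pooled_max(self):
        s = make_series([0.0, 6.0])
        bins = make_bins(s, n_states=60)
        np.testing.assert_allclose(bins.width, 0.1)
        assert bins.n_states == 60
        np.testing.assert_allclose(bins.centers[0], 0.05)

    def test_pooled_conditions_share_edges(self):
        a = make_series([0.0, 2.0])
        b = make_series([0.0, 6.0])
        pooled = make_bins([a, b], n_states=10)
        only_b = make_bins(b, n_states=10)
        np.testing.assert_allclose(pooled.edges, only_b.edges)

    def test_single_state_rejected(self):
        with pytest.raises(ParameterError):
            make_bins(make_series([0.0, 1.0]), n_states=1)

    def test_all_zero_pool_rejected(self):
        with pytest.raises(DataError):
            make_bins(make_series(np.zeros(10)), n_states=10)


class TestDiscretize:
    BINS = BinGeometry(edges=np.arange(0.0, 0.61, 0.1))

    def test_basic_assignment(self):
        states = discretize(make_series([0.05, 0.15]), self.BINS)
        np.testing.assert_array_equal(states, [0, 1])

    def test_interior_edge_goes_to_upper_bin(self):
        states = discretize(make_series([0.1]), self.BINS)
        np.testing.assert_array_equal(states, [1])

    def test_max_value_falls_in_last_bin(self):
        states = discretize(make_series([0.6]), self.BINS)
        np.testing.assert_array_equal(states, [5])

    def test_signed_series_folded_to_distance(self):
        states = discretize(make_series([-0.25, 0.25]), self.BINS)
        np.testing.assert_array_equal(states, [2, 2])

    def test_beyond_last_edge_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            states = discretize(make_series([0.7]), self.BINS)
        np.testing.assert_array_equal(states, [5])


class TestTransitionMatrix:
    def test_alternating_sequence_counts(self):
        counts = transition_counts(np.array([0, 1, 0, 1, 0]), 2)
        np.testing.assert_allclose(counts, [[0, 2], [2, 0]])

    def test_rows_sum_to_one(self, rng):
        bins = BinGeometry(edges=np.linspace(0, 1, 11))
        states = rng.integers(0, 10, size=500)
        model = estimate_transition_matrix(states, bins)
        np.testing.assert_allclose(model.P.sum(axis=1), 1.0, atol=1e-12)

    def test_regularization_makes_all_entries_positive(self):
        bins = BinGeometry(edges=np.linspace(0, 1, 11))
        # visits only two of ten states
        model = estimate_transition_matrix(np.array([0, 1, 0, 1]), bins)
        assert model.P.min() > 0

    def test_empty_sequence_rejected(self):
        bins = BinGeometry(edges=np.linspace(0, 1, 11))
        with pytest.raises(DataError):
            estimate_transition_matrix(np.array([], dtype=int), bins)


class TestStationaryDensity:
    def test_hand_solved_two_state_chain(self):
        pi = stationary_density(two_state_model())
        np.testing.assert_allclose(pi, PI_HAND, atol=1e-12)

    def test_uniform_chain_gives_uniform_density(self):
        P = np.full((4, 4), 0.25)
        pi = stationary_density(MarkovModel(states=np.zeros(1, int), P=P))
        np.testing.assert_allclose(pi, 0.25, atol=1e-12)

    def test_matches_power_iteration_on_random_chains(self, rng):
        from swaymetrics.ida import _power_iteration_pi

        for n in (20, 60):
            P = random_chain(n, rng)
            pi = stationary_density(P, cross_check=False)
            np.testing.assert_allclose(pi, _power_iteration_pi(P), atol=1e-8)

    def test_cross_check_is_part_of_default_path(self, rng):
        P = random_chain(20, rng)
        pi = stationary_density(P)  # raises NumericalError on disagreement
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pi @ P, pi, atol=1e-12)

    def test_leading_eigenvalue_is_one(self, rng):
        P = random_chain(30, rng)
        w = np.abs(np.linalg.eigvals(P))
        w.sort()
        assert w[-1] == pytest.approx(1.0, abs=1e-10)
        assert w[-2] < 1.0


class TestEntropy:
    def test_delta_density_zero_bits(self):
        pi = np.zeros(60)
        pi[7] = 1.0
        assert entropy(pi) == 0.0

    def test_uniform_64_states_six_bits(self):
        assert entropy(np.full(64, 1 / 64)) == pytest.approx(6.0, abs=1e-12)

    def test_worked_three_state_value(self):
        assert entropy(np.array([0.5, 0.25, 0.25])) == pytest.approx(1.5, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ParameterError):
            entropy(np.array([1.5, -0.5]))

    def test_mixing_toward_uniform_never_decreases_entropy(self, rng):
        for _ in range(5):
            pi = rng.dirichlet(np.ones(20) * 0.3)
            u = np.full(20, 1 / 20)
            h = [entropy(a * pi + (1 - a) * u) for a in np.linspace(1, 0, 11)]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(h, h[1:]))

    def test_added_noise_increases_series_entropy(self, rng):
        """More measurement noise spreads the invariant density (on a state
        space shared across noise levels)."""
        t = np.arange(3000) / 100.0
        base = 3.0 * np.sin(2 * np.pi * 0.3 * t)
        noise = rng.normal(size=3000)
        sigmas = (0.1, 0.5, 1.0, 2.0, 4.0)
        series = [make_series(base + sg * noise) for sg in sigmas]
        bins = make_bins(series, 60)
        hs = [ida.analyze_series(s, bins).H for s in series]
        assert hs[-1] > hs[0]
        assert all(b >= a - 0.05 for a, b in zip(hs, hs[1:]))


class TestSummary:
    def test_delta_density_summary(self):
        # chain that sticks in state 2 almost surely
        n = 5
        P = np.full((n, n), 1e-9)
        P[:, 2] = 1.0
        P /= P.sum(axis=1, keepdims=True)
        bins = BinGeometry(edges=np.linspace(0, 1, n + 1))
        res = ida_summary(MarkovModel(states=np.zeros(1, int), P=P), bins)
        assert res.P_peak == pytest.approx(1.0, abs=1e-6)
        assert res.D_bar == pytest.approx(bins.centers[2], abs=1e-6)
        assert res.D95 == pytest.approx(bins.centers[2], abs=1e-6)

    def test_two_state_lambda2(self):
        bins = BinGeometry(edges=np.array([0.0, 1.0, 2.0]))
        res = ida_summary(two_state_model(), bins)
        assert res.lambda2 == pytest.approx(0.4, abs=1e-12)

    def test_d95_from_hand_cumulative_sum(self):
        # pi = [0.5, 0.3, 0.15, 0.05] -> cumulative reaches 0.95 at state 2
        pi = np.array([0.5, 0.3, 0.15, 0.05])
        P = np.tile(pi, (4, 1))  # iid chain with invariant density pi
        bins = BinGeometry(edges=np.linspace(0, 4, 5))
        res = ida_summary(MarkovModel(states=np.zeros(1, int), P=P), bins)
        assert res.D95 == pytest.approx(bins.centers[2])

    def test_dbar_never_exceeds_d95(self, rng):
        for _ in range(5):
            P = random_chain(12, rng)
            bins = BinGeometry(edges=np.linspace(0, 1, 13))
            res = ida_summary(MarkovModel(states=np.zeros(1, int), P=P), bins)
            assert res.D_bar <= res.D95 + 1e-12


class TestSecondEigenvector:
    def test_two_state_left_eigenvector_and_crossing(self):
        lam2, v = second_left_eigenvector(P_HAND)
        assert lam2 == pytest.approx(0.4, abs=1e-12)
        np.testing.assert_allclose(v / v[0], [1.0, -1.0], atol=1e-12)
        bins = BinGeometry(edges=np.array([0.0, 1.0, 2.0]))
        z = second_eigenvector_zero_crossing(two_state_model(), bins)
        assert z == pytest.approx(1.0)  # midpoint of centers 0.5 and 1.5

    def test_components_sum_to_zero(self, rng):
        for n in (10, 30, 60):
            _, v = second_left_eigenvector(random_chain(n, rng))
            assert abs(v.sum()) < 1e-9 * np.max(np.abs(v))

    def test_no_crossing_returns_nan_with_warning(self, monkeypatch):
        model = two_state_model()
        monkeypatch.setattr(
            ida, "second_left_eigenvector", lambda P: (0.4, np.array([1.0, 2.0]))
        )
        bins = BinGeometry(edges=np.array([0.0, 1.0, 2.0]))
        with pytest.warns(UserWarning, match="no sign change"):
            z = second_eigenvector_zero_crossing(model, bins)
        assert np.isnan(z)


class TestOrderingOnSimulatedSway:
    def test_dbar_below_crossing_below_d95(self):
        """On simulated sway the crossing sits between D_bar and D95."""
        from swaymetrics.signal import directional_series, preprocess
        from swaymetrics.simulate import PendulumConfig, simulate_quiet_standing

        cfg = PendulumConfig()
        series = []
        for seed in range(6):
            tr = preprocess(simulate_quiet_standing(cfg, 7000 + seed))
            series.append(directional_series(tr, "AP"))
        bins = make_bins(series, 60)
        hold = 0
        for s in series:
            res = ida.analyze_series(s, bins)
            if res.D_bar < res.z_lambda2 < res.D95:
                hold += 1
        assert hold > len(series) / 2
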