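import numpy as np
import pytest

from bekinet import (
    RateSet,
    build_editing_network,
    outcomes_from_rates,
    rates_from_reduced,
    simulate_gillespie,
    splitting_probabilities,
)
from bekinet.errors import SingularModelError, ValidationError
from bekinet.network import ABSORBING_STATES, N_STATES, network_to_dot, network_to_edge_table

from conftest import random_rate_set

OUTCOME_KEYS = {"CTC": "p_ctc", "CTT": "p_ctt", "TTC": "p_ttc", "TTT": "p_ttt"}


@pytest.fixture
def calib_network(calib_params):
    return build_editing_network(rates_from_reduced(calib_params))


class TestBuildEditingNetwork:
    def test_fifteen_states_22_edges(self, calib_network):
        assert len(calib_network.states) == N_STATES == 15
        assert len(calib_network.edges) == 22
        assert dict(calib_network.absorbing) == ABSORBING_STATES

    def test_absorbing_states_have_no_exits(self, calib_network):
        sources = {src for src, _, _ in calib_network.edges}
        assert sources.isdisjoint(calib_network.absorbing)

    def test_zero_rate_rebinding_edges_retained(self, calib_params):
        net = build_editing_network(rates_from_reduced(calib_params.replace(m=0.0)))
        rebind = {(s, d): r for s, d, r in net.edges if (s, d) in {(7, 5), (8, 6)}}
        assert rebind == {(7, 5): 0.0, (8, 6): 0.0}

    def test_edge_rates_match_rate_set(self):
        r = RateSet(u0=1.0, u1=2.0, u2=3.0, u3=4.0, u4=5.0, w0=6.0, w1=7.0, w2=8.0, m=0.5)
        net = build_editing_network(r)
        rates = {(s, d): v for s, d, v in net.edges}
        assert rates[(0, 2)] == 1.0 and rates[(0, 1)] == 5.0
        assert rates[(2, 3)] == 2.0 and rates[(2, 4)] == 3.0 and rates[(2, 0)] == 6.0
        assert rates[(3, 5)] == 4.0 and rates[(3, 2)] == 7.0
        assert rates[(4, 6)] == 4.0 and rates[(4, 2)] == 8.0
        assert rates[(7, 5)] == 0.5 and rates[(9, 5)] == 8.0
        assert rates[(11, 12)] == 6.0


class TestSplittingProbabilities:
    def test_matches_closed_form_at_calibration(self, calib_params, calib_network):
        probs = splitting_probabilities(calib_network)
        o = outcomes_from_rates(rates_from_reduced(calib_params))
        for label, attr in OUTCOME_KEYS.items():
            assert probs[label] == pytest.approx(getattr(o, attr), abs=1e-10)

    def test_matches_closed_form_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            r = random_rate_set(rng)
            probs = splitting_probabilities(build_editing_network(r))
            o = outcomes_from_rates(r)
            for label, attr in OUTCOME_KEYS.items():
                assert probs[label] == pytest.approx(getattr(o, attr), abs=1e-10)

    def test_matches_closed_form_extreme_energies(self, calib_params):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = calib_params.replace(
                ddEm=float(rng.uniform(-20, 20)), ddE0=float(rng.uniform(-20, 20))
            )
            probs = splitting_probabilities(build_editing_network(rates_from_reduced(p)))
            o = outcomes_from_rates(rates_from_reduced(p))
            for label, attr in OUTCOME_KEYS.items():
                assert probs[label] == pytest.approx(getattr(o, attr), abs=1e-10)

    def test_normalization_random(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            probs = splitting_probabilities(build_editing_network(random_rate_set(rng)))
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_reachable_outcome(self):
        # u4 -> 0 never commits to CTC/CTT/TTC; w0 > 0 needed to reach TTT.
        r = RateSet(u0=1, u1=1, u2=1, u3=1, u4=0.0, w0=1.0, w1=1, w2=1, m=1.0)
        probs = splitting_probabilities(build_editing_network(r))
        assert probs["TTT"] == pytest.approx(1.0, abs=1e-12)

    def test_r2_equals_splitting_ratio_from_state_5(self, calib_params):
        from bekinet import ratio_r2

        net = build_editing_network(rates_from_reduced(calib_params))
        probs = splitting_probabilities(net, start=5)
        assert probs["CTT"] / probs["TTT"] == pytest.approx(
            ratio_r2(calib_params), rel=1e-10
        )

    def test_absorbing_start_rejected(self, calib_network):
        with pytest.raises(ValidationError):
            splitting_probabilities(calib_network, start=1)

    def test_unreachable_absorption_raises(self):
        # u4=0 and m=0: state 7/8 (reachable when w0>0) have no exit.
        r = RateSet(u0=1, u1=1, u2=1, u3=1, u4=0.0, w0=1.0, w1=1, w2=1, m=0.0)
        with pytest.raises(SingularModelError):
            splitting_probabilities(build_editing_network(r))

    def test_m0_pruning_equals_m0_rates(self, calib_params):
        # Removing the rebinding edges equals carrying them at rate 0.
        net = build_editing_network(rates_from_reduced(calib_params.replace(m=0.0)))
        pruned = net.__class__(
            edges=tuple(e for e in net.edges if e[2] > 0.0),
            states=net.states,
            absorbing=net.absorbing,
        )
        a = splitting_probabilities(net)
        b = splitting_probabilities(pruned)
        assert a == pytest.approx(b, abs=0)


class TestGillespie:
    def test_zero_trajectories(self, calib_network):
        sim = simulate_gillespie(calib_network, n_traj=0, seed=1)
        assert sum(sim.counts.values()) == 0

    def test_same_seed_identical(self, calib_network):
        a = simulate_gillespie(calib_network, n_traj=2000, seed=7)
        b = simulate_gillespie(calib_network, n_traj=2000, seed=7)
        assert a == b

    def test_different_seed_differs(self, calib_network):
        a = simulate_gillespie(calib_network, n_traj=2000, seed=7)
        b = simulate_gillespie(calib_network, n_traj=2000, seed=8)
        assert a.counts != b.counts

    @pytest.mark.parametrize("n_traj", [1000, 10_000])
    def test_frequencies_converge_to_linear_solve(self, calib_network, n_traj):
        exact = splitting_probabilities(calib_network)
        sim = simulate_gillespie(calib_network, n_traj=n_traj, seed=123)
        for label, freq in sim.frequencies.items():
            se = max(np.sqrt(exact[label] * (1 - exact[label]) / n_traj), 1e-12)
            assert abs(freq - exact[label]) <= 4 * se + 2.0 / n_traj

    def test_counts_sum_and_standard_errors(self, calib_network):
        sim = simulate_gillespie(calib_network, n_traj=500, seed=2)
        assert sum(sim.counts.values()) == 500
        for label, se in sim.standard_errors.items():
            f = sim.frequencies[label]
            assert se == pytest.approx(np.sqrt(f * (1 - f) / 500))

    def test_event_cap(self, calib_network):
        with pytest.raises(SingularModelError, match="events"):
            simulate_gillespie(calib_network, n_traj=50, seed=3, max_events=5)

    def test_negative_n_traj_rejected(self, calib_network):
        with pytest.raises(ValidationError):
            simulate_gillespie(calib_network, n_traj=-1, seed=0)


class TestExports:
    def test_dot_export(self, calib_network):
        dot = network_to_dot(calib_network)
        assert dot.startswith("digraph")
        assert dot.count("->") == 22

    def test_edge_table(self, calib_network):
        frame = network_to_edge_table(calib_network)
        assert len(frame) == 22
        assert set(frame.columns) >= {"source", "target", "rate"}
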