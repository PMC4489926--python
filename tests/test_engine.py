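"""Langevin engine: initial states, stepping, adhesion, full runs."""

import numpy as np
import pytest

from knotloop import forcefield as ff
from knotloop.engine import (
    adhesion_event,
    bond_minimum,
    initial_conformation,
    langevin_step,
    run_until_circularization,
)
from knotloop.params import ModelParams, RunProtocol
from knotloop.state import ChainState, RunOutcome


class TestInitialConformation:
    def test_end_to_end_matches_bond_minimum(self):
        params = ModelParams.chain(500)
        protocol = RunProtocol(seed=11)
        state = initial_conformation(params, protocol)
        d0 = bond_minimum(params)
        ree = np.linalg.norm(state.positions[-1] - state.positions[0])
        assert ree == pytest.approx(499 * d0, rel=0.01)
        # the numerically minimized bond length is the known ~0.96 sigma
        assert d0 == pytest.approx(0.97, abs=0.015)

    def test_deterministic_given_seed(self):
        params = ModelParams.chain(50)
        protocol = RunProtocol(seed=3)
        a = initial_conformation(params, protocol)
        b = initial_conformation(params, protocol)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_nearly_straight_and_unbonded(self):
        params = ModelParams.chain(80)
        state = initial_conformation(params, RunProtocol(seed=1))
        b = state.positions[1:] - state.positions[:-1]
        u = b / np.linalg.norm(b, axis=1, keepdims=True)
        cos_bond = (u[:-1] * u[1:]).sum(axis=1)
        theta = np.pi - np.arccos(np.clip(cos_bond, -1, 1))
        assert np.all(np.abs(theta - np.pi) < 1e-2)
        assert not state.bonded_termini and not state.bonded_internal


class TestLangevinStep:
    def test_gamma_zero_reduces_to_velocity_verlet(self):
        params = ModelParams.chain(10, regime="S", internal_pair=(3, 6))
        protocol = RunProtocol(gamma=0.0, seed=4)
        rng = np.random.default_rng(4)
        state = initial_conformation(params, protocol, rng)
        state.positions += rng.normal(0, 0.03, state.positions.shape)

        manual = state.copy()
        f0 = ff.forces(manual, params)
        manual.velocities += 0.5 * protocol.dt * f0 / params.mass
        manual.positions += protocol.dt * manual.velocities
        f1 = ff.forces(manual, params)
        manual.velocities += 0.5 * protocol.dt * f1 / params.mass

        langevin_step(state, params, protocol)
        np.testing.assert_allclose(state.positions, manual.positions, atol=1e-13)
        np.testing.assert_allclose(state.velocities, manual.velocities, atol=1e-12)

    def test_fixed_seed_reproducible(self):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.5, seed=9)
        s1 = initial_conformation(params, protocol)
        s2 = initial_conformation(params, protocol)
        rng1 = np.random.default_rng(42)
        rng2 = np.random.default_rng(42)
        for _ in range(50):
            langevin_step(s1, params, protocol, rng1)
            langevin_step(s2, params, protocol, rng2)
        np.testing.assert_array_equal(s1.positions, s2.positions)


class TestAdhesion:
    def _state(self, d_term: float) -> ChainState:
        pos = np.zeros((6, 3))
        pos[:, 0] = np.linspace(0.0, d_term, 6)
        return ChainState(pos, np.zeros_like(pos))

    def test_capture_sets_flag(self):
        protocol = RunProtocol(capture_distance=1.5)
        state = self._state(1.49)
        adhesion_event(state, (0, 5), protocol)
        assert state.bonded_termini

    def test_far_pair_unchanged(self):
        protocol = RunProtocol(capture_distance=1.5)
        state = self._state(3.0)
        adhesion_event(state, (0, 5), protocol)
        assert not state.bonded_termini

    def test_idempotent_permanence(self):
        protocol = RunProtocol(capture_distance=1.5)
        state = self._state(10.0)
        state.bonded_termini = True
        adhesion_event(state, (0, 5), protocol)
        assert state.bonded_termini  # never unset, regardless of distance


class TestRunUntilCircularization:
    def test_tiny_cap_censors(self):
        params = ModelParams.chain(60)
        protocol = RunProtocol(max_steps=200, seed=5)
        out = run_until_circularization(params, protocol)
        assert out.censored and not out.circularized
        assert out.steps_elapsed == 200

    def test_short_chain_circularizes_and_satisfies_capture(self):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.1, max_steps=3_000_000, seed=8)
        out = run_until_circularization(params, protocol)
        assert out.circularized
        d = np.linalg.norm(out.final_positions[0] - out.final_positions[-1])
        assert d <= protocol.capture_distance + 1e-9

    def test_same_seed_identical_outcome(self):
        params = ModelParams.chain(20)
        protocol = RunProtocol(gamma=0.1, max_steps=3_000_000, seed=12)
        a = run_until_circularization(params, protocol)
        b = run_until_circularization(params, protocol)
        assert a.steps_elapsed == b.steps_elapsed
        np.testing.assert_array_equal(a.final_positions, b.final_positions)

    def test_reference_chain_has_no_internal_flag(self):
        params = ModelParams.chain(20)  # no internal pair
        protocol = RunProtocol(gamma=0.1, max_steps=3_000_000, seed=13)
        out = run_until_circularization(params, protocol)
        assert out.circularized and not out.internal_loop_closed_at_end

    def test_terminal_pair_required(self):
        params = ModelParams(n_beads=20)  # no sticky pairs at all
        with pytest.raises(ValueError):
            run_until_circularization(params, RunProtocol())

    def test_internal_flag_consistent_with_final_distance(self):
        """The loop-closed flag agrees with the final-frame pair distance.

        The flag is permanent while the distance can in principle
        re-open; with the deep well and the added bond the two stay
        consistent, which is the internal-consistency contract of the
        loop_closed observable.
        """
        params = ModelParams.chain(30, internal_pair=(8, 21))
        n_checked = 0
        for seed in range(10):
            protocol = RunProtocol(gamma=0.1, max_steps=4_000_000, seed=seed)
            out = run_until_circularization(params, protocol)
            if not out.circularized:
                continue
            n_checked += 1
            d = np.linalg.norm(out.final_positions[8] - out.final_positions[21])
            if out.internal_loop_closed_at_end:
                assert d <= protocol.capture_distance * 1.05
            else:
                assert d > protocol.capture_distance
        assert n_checked >= 5
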