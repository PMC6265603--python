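import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oglcnet.core import Arc, Marking, PetriNet, Place, Transition, p_invariants
from oglcnet.dynamics import (
    SimulationSettings,
    euler_simulate,
    ode_rhs,
    readout,
    simulate,
    transition_rate,
)
from oglcnet.errors import UnknownElementError
from oglcnet.models import random_net


def _net(places, transitions, arcs, name="toy"):
    return PetriNet(places=places, transitions=transitions, arcs=arcs, name=name)


class TestTransitionRate:
    def test_source_fires_at_its_rate_constant(self):
        net = _net([Place("a")], [Transition("src", rate_constant=2.0, kind="source")],
                   [Arc("src", "a")])
        assert transition_rate(net, net.initial_marking(), "src") == 2.0

    def test_empty_input_place_gives_zero_rate(self):
        net = _net([Place("a", initial_tokens=0.0)],
                   [Transition("t", kind="sink")], [Arc("a", "t")])
        assert transition_rate(net, net.initial_marking(), "t") == 0.0

    def test_hard_gate_closes_at_weight(self):
        net = _net(
            [Place("a", initial_tokens=1.0), Place("q", initial_tokens=5.0)],
            [Transition("t", kind="sink")],
            [Arc("a", "t"), Arc("q", "t", weight=1.0, arc_type="inhibitory")],
        )
        hard = SimulationSettings(hard_gate=True)
        assert transition_rate(net, net.initial_marking(), "t", hard) == 0.0

    def test_kinetic_order_equals_arc_weight(self):
        net = _net([Place("a", initial_tokens=2.0)],
                   [Transition("t", rate_constant=0.5, kind="sink")],
                   [Arc("a", "t", weight=2.0)])
        assert transition_rate(net, net.initial_marking(), "t") == pytest.approx(2.0)

    def test_unknown_transition_raises(self):
        net = _net([Place("a")], [Transition("t", kind="sink")], [Arc("a", "t")])
        with pytest.raises(UnknownElementError):
            transition_rate(net, net.initial_marking(), "ghost")

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(derandomize=True, max_examples=30)
    def test_smooth_gate_monotone_in_inhibitor_level(self, level):
        """Raising the inhibitor marking never raises the gated rate."""
        net = _net(
            [Place("a", initial_tokens=1.0), Place("q")],
            [Transition("t", kind="sink")],
            [Arc("a", "t"), Arc("q", "t", weight=3.0, arc_type="inhibitory")],
        )
        lo = transition_rate(net, Marking({"a": 1.0, "q": level}), "t")
        hi = transition_rate(net, Marking({"a": 1.0, "q": level + 1.0}), "t")
        assert hi <= lo


class TestOdeRhs:
    def test_unit_transfer(self):
        net = _net([Place("a", initial_tokens=1.0), Place("b")],
                   [Transition("t")], [Arc("a", "t"), Arc("t", "b")])
        assert ode_rhs(net, net.initial_marking()).tolist() == [-1.0, 1.0]

    def test_invariant_annihilates_rhs(self, two_place_cycle):
        rhs = ode_rhs(two_place_cycle, two_place_cycle.initial_marking())
        for x in p_invariants(two_place_cycle):
            assert abs(x @ rhs) < 1e-12

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_matches_euler_finite_difference(self, seed):
        """(m(h) - m(0))/h converges to the reported derivative."""
        net = random_net(4, 4, seed)
        m0 = net.initial_marking()
        rhs = ode_rhs(net, m0)
        h = 1e-6
        m_h = euler_simulate(net, h, h)
        fd = (m_h - m0.as_vector(net)) / h
        assert np.allclose(fd, rhs, atol=1e-4)


class TestSimulate:
    def test_first_row_is_initial_marking(self, decay_net):
        traj = simulate(decay_net, SimulationSettings(t_end=1.0, n_points=5))
        assert traj.markings[0].tolist() == [1.0]

    def test_short_horizon_first_order_step(self, two_place_cycle):
        t_end = 1e-5
        traj = simulate(two_place_cycle, SimulationSettings(t_end=t_end, n_points=2))
        rhs = ode_rhs(two_place_cycle, two_place_cycle.initial_marking())
        expected = two_place_cycle.initial_marking().as_vector(two_place_cycle)
        assert np.allclose(traj.markings[-1], expected + t_end * rhs, atol=1e-9)

    def test_exponential_decay_closed_form(self, decay_net):
        s = SimulationSettings(t_end=10.0, n_points=101,
                               rel_tol=1e-10, abs_tol=1e-13)
        traj = simulate(decay_net, s)
        for t_query in (1.0, 5.0, 10.0):
            i = int(np.argmin(np.abs(traj.times - t_query)))
            assert traj.markings[i, 0] == pytest.approx(np.exp(-t_query), abs=1e-6)

    def test_conservation_along_trajectory(self, two_place_cycle):
        traj = simulate(two_place_cycle)
        for x in p_invariants(two_place_cycle):
            sums = traj.markings @ x
            assert np.abs(sums - sums[0]).max() < 1e-6

    def test_determinism_bitwise(self, variant_nets):
        net = variant_nets["cancer_hyperglycemia"]
        a = simulate(net)
        b = simulate(net)
        assert np.array_equal(a.markings, b.markings)

    def test_no_negative_marking_reported(self, variant_trajectories):
        for traj in variant_trajectories.values():
            assert (traj.markings >= 0).all()

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_agrees_with_fixed_step_euler(self, seed):
        net = random_net(5, 5, seed)
        adaptive = simulate(net, SimulationSettings(t_end=1.0, n_points=2)).markings[-1]
        euler = euler_simulate(net, 1.0, 1e-4)
        assert np.abs(adaptive - euler).max() < 1e-3


class TestReadout:
    def _traj(self, values):
        from oglcnet.dynamics import Trajectory

        values = np.asarray(values, dtype=float)
        return Trajectory(times=np.arange(len(values), dtype=float),
                          markings=values[:, None], place_ids=("a",))

    @pytest.mark.parametrize("mode", ["final", "mean_tail", "max"])
    def test_constant_trajectory(self, mode):
        assert readout(self._traj([3.0] * 10), "a", mode=mode) == 3.0

    def test_monotone_increasing_max_equals_final(self):
        traj = self._traj(np.linspace(0, 4, 21))
        assert readout(traj, "a", "max") == readout(traj, "a", "final")

    def test_decaying_exponential_tail_below_threshold(self, decay_net):
        traj = simulate(decay_net, SimulationSettings(t_end=10.0, n_points=101))
        tail = readout(traj, "a", "mean_tail")
        final = readout(traj, "a", "final")
        assert tail < final + 1e-3
        assert tail < 1e-3 and final < 1e-3

    def test_unknown_place_raises(self, decay_net):
        traj = simulate(decay_net, SimulationSettings(t_end=1.0, n_points=5))
        with pytest.raises(UnknownElementError):
            readout(traj, "ghost")

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown readout mode"):
            readout(self._traj([1.0, 2.0]), "a", mode="median")


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(t_end=0), dict(t_end=-1), dict(n_points=1), dict(rel_tol=0),
         dict(abs_tol=-1e-9), dict(inhibition_steepness=0)],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationSettings(**kwargs)


def test_trajectory_csv_round_trip(tmp_path, decay_net):
    import pandas as pd

    traj = simulate(decay_net, SimulationSettings(t_end=1.0, n_points=11))
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["time", "a"]
    assert np.allclose(df["a"].to_numpy(), traj.column("a"))
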