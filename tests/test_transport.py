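"""Transport stepper: conservation, positivity, oracle equivalence."""

import numpy as np
import pytest

import lungdep as ld
from lungdep.discretize import discretize
from lungdep.particles import GasProperties, ParticleProperties
from lungdep.transport import TransportStepper, _bernoulli, run_breath
from lungdep.ventilation import BreathingWaveform, VentilationSolution

from conftest import build_network


def make_tube_net(length=0.02, radius=0.002):
    return build_network(
        parent=[-1], generation=[1], length=[length], radius=[radius],
        proximal=[[0, 0, 0]], distal=[[0, 0, -length]], lobe=["TR"])


def constant_flow_vent(net, q=0.0, n_steps=50, dt=0.01):
    """Hand-built ventilation solution with constant flows (for stepper
    unit tests; the acinus absorbs the flow)."""
    nt = n_steps + 1
    vol = net.acinus_V0[None, :] + q * dt * np.arange(nt)[:, None]
    return VentilationSolution(
        net=net, waveform=BreathingWaveform(), dt=dt,
        times=np.arange(nt) * dt,
        airway_flow=np.full((nt, net.n_airways), q),
        acinus_volume=vol,
        acinus_flow=np.full((nt, net.n_acini), q),
        pleural_pressure=np.zeros(nt), q0=np.full(nt, q))


def test_identity_step_at_rest():
    """Zero flow, zero sinks: a gas field in equilibrium is unchanged."""
    net = make_tube_net()
    vent = constant_flow_vent(net, q=0.0)
    stepper = TransportStepper(discretize(net, acinar_mode="compartment"),
                               vent, gas=GasProperties(), c_inlet=0.0)
    state = stepper.initial_state(1.0)
    c0 = state.concentration.copy()
    stepper.step(state)
    assert np.allclose(state.concentration, c0, rtol=1e-12)
    assert state.deposited.sum() == 0.0


def test_closed_system_conserves_mass(small_net, small_vent):
    """Washout-mode transport (no sinks) conserves total tracer up to
    what leaves through the trachea."""
    d = discretize(small_net, acinar_mode="compartment")
    stepper = TransportStepper(d, small_vent, gas=GasProperties(),
                               c_inlet=0.0)
    state = stepper.initial_state(1.0)
    total0 = state.airborne
    stepper.run_breath(state)
    closure = abs(state.airborne + state.exhaled - total0) / total0
    assert closure < 1e-8


def test_concentrations_stay_nonnegative(small_net, small_vent):
    res = ld.run_breath(small_net, small_vent)
    d = discretize(small_net)
    stepper = TransportStepper(d, small_vent,
                               particle=ParticleProperties(), c_inlet=1.0)
    state = stepper.initial_state()
    for _ in range(60):
        stepper.step(state)
        assert np.all(state.concentration >= 0.0)
    assert np.all(res.per_edge >= 0.0)


def test_bernoulli_weighting_limits():
    x = np.array([-1e3, -1.0, -1e-14, 0.0, 1e-14, 1.0, 1e3])
    b = _bernoulli(x)
    assert b[3] == 1.0
    assert b[0] == pytest.approx(1e3)     # strong upwind limit
    assert b[-1] == pytest.approx(0.0, abs=1e-200)
    assert np.all(np.isfinite(b))


class TestSingleTubeDenseOracle:
    """The tree solve on one discretized tube must match an independent
    dense solver for the same backward-Euler system to 1e-10."""

    def dense_step(self, d, c, v_old, v_new, q, d_eff_mol, dt, q0, c_in):
        n = d.n_nodes
        A = np.zeros((n, n))
        rhs = v_old * c / dt
        for i in range(1, n):
            p = d.parent_node[i]
            area, h, r = d.edge_area[i], d.edge_h[i], d.edge_radius[i]
            de = d_eff_mol + 1.08 * abs(q / area) * 2 * r \
                if area > 0 else 0.0
            g = de * area / h
            pe = q / g if g > 0 else np.inf
            if g > 0:
                a_in = g * _bernoulli(-pe)
                a_out = g * _bernoulli(pe)
            else:
                a_in, a_out = max(q, 0.0), max(-q, 0.0)
            A[i, i] += a_out
            A[i, p] -= a_in
            A[p, p] += a_in
            A[p, i] -= a_out
        A[np.arange(n), np.arange(n)] += v_new / dt
        if q0 > 0:
            rhs[0] += q0 * c_in
        elif q0 < 0:
            A[0, 0] += -q0
        return np.linalg.solve(A, rhs)

    @pytest.mark.parametrize("q", [2e-5, -2e-5])
    def test_tree_solver_matches_dense(self, q):
        net = make_tube_net()
        vent = constant_flow_vent(net, q=q, n_steps=10)
        d = discretize(net, acinar_mode="compartment")
        gas = GasProperties()
        stepper = TransportStepper(d, vent, gas=gas, c_inlet=1.0)
        state = stepper.initial_state(0.5)
        c_dense = state.concentration.copy()
        v = state.node_volume.copy()
        for k in range(5):
            stepper.step(state)
            v_new = d.node_volumes(vent.acinus_volume[k + 1])
            c_dense = self.dense_step(d, c_dense, v, v_new, q,
                                      gas.diffusivity, vent.dt, q, 1.0)
            v = v_new
            assert np.allclose(state.concentration, c_dense,
                               rtol=1e-10, atol=1e-14)

    def test_bicgstab_path_agrees_with_tree_solver(self):
        net = make_tube_net()
        vent = constant_flow_vent(net, q=1e-5, n_steps=10)
        d = discretize(net, acinar_mode="compartment")
        s1 = TransportStepper(d, vent, gas=GasProperties(), c_inlet=1.0)
        s2 = TransportStepper(d, vent, gas=GasProperties(), c_inlet=1.0,
                              solver="bicgstab")
        st1, st2 = s1.initial_state(0.2), s2.initial_state(0.2)
        for _ in range(5):
            s1.step(st1)
            s2.step(st2)
        # iterative residual tolerance 1e-10 times the conditioning of the
        # diffusion-dominated system bounds the achievable agreement
        assert np.allclose(st1.concentration, st2.concentration,
                           rtol=1e-5, atol=1e-9)

    def test_front_advects_at_mean_velocity(self):
        """Pure advection (zero diffusivity, zero sinks): the centre of
        mass of an injected pulse moves at the mean velocity."""
        net = make_tube_net(length=0.1, radius=0.002)
        area = np.pi * 0.002**2
        u = 0.05
        vent = constant_flow_vent(net, q=u * area, n_steps=60, dt=0.01)
        d = discretize(net, acinar_mode="compartment")
        stepper = TransportStepper(d, vent, gas=GasProperties(1e-300),
                                   c_inlet=0.0, dispersion_coeff=0.0)
        state = stepper.initial_state(0.0)
        # pulse near the tube entrance
        z = np.array([np.sum(d.edge_h[1:i + 1]) for i in range(d.n_nodes)])
        cond = d.node_acinus < 0
        state.concentration[cond & (z < 0.02)] = 1.0
        m0 = state.airborne

        def centre():
            w = state.concentration[cond] * state.node_volume[cond]
            return np.sum(z[cond] * w) / np.sum(w)

        c_start = centre()
        n_steps, dt = 40, vent.dt
        for _ in range(n_steps):
            stepper.step(state)
        assert centre() - c_start == pytest.approx(u * n_steps * dt,
                                                   rel=0.02)
        assert state.airborne == pytest.approx(m0, rel=1e-10)


class TestRunBreath:
    def test_conservation_closure(self, small_deposition):
        assert small_deposition.conservation_error() < 1e-6

    def test_zero_sinks_means_zero_deposition(self, small_net, small_vent):
        from lungdep.transport import MechanismSet

        mech = MechanismSet(impaction=lambda *a: 0.0,
                            sedimentation=lambda *a: 0.0,
                            diffusion=lambda *a: 0.0)
        res = ld.run_breath(small_net, small_vent, mechanisms=mech)
        assert res.deposited == 0.0
        assert res.exhaled_fraction + res.residual_fraction == \
            pytest.approx(1.0, rel=1e-9)

    def test_rollups_sum_to_total(self, small_deposition):
        res = small_deposition
        s = res.splits()
        assert s["central"] + s["distal"] + s["acinar"] == pytest.approx(
            res.deposited_fraction, rel=1e-10)
        assert res.per_airway().sum() + res.per_acinus().sum() == \
            pytest.approx(res.deposited, rel=1e-10)
        lobes = res.by_lobe()
        total = sum(v["conducting_fraction"] + v["acinar_fraction"]
                    for v in lobes.values())
        assert total == pytest.approx(res.deposited_fraction, rel=1e-10)

    def test_central_deposition_exceeds_distal_per_airway(
            self, small_net, small_deposition):
        """In an unconstricted asymmetric tree at 4 um, mean per-airway
        deposition is higher in central than distal conducting airways."""
        aw = small_deposition.per_airway()
        central = ld.classify_airways(small_net) == "central"
        assert aw[central].mean() > aw[~central].mean()

    def test_halving_dt_changes_total_deposition_below_one_percent(
            self, small_net, small_vent):
        res1 = ld.run_breath(small_net, small_vent)
        vent2 = ld.assemble_and_solve(small_net, dt=0.005)
        res2 = ld.run_breath(small_net, vent2)
        rel = abs(res2.deposited_fraction - res1.deposited_fraction) \
            / res1.deposited_fraction
        assert rel < 0.01
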