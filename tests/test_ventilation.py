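"""Ventilation solver: resistance laws, conservation, closed forms."""

import numpy as np
import pytest

import lungdep as ld
from lungdep import units
from lungdep.ventilation import (BreathingWaveform, ResistanceModel,
                                 airway_resistance, assemble_and_solve,
                                 distribute_acinar_mechanics,
                                 rescale_elastance)

from conftest import build_network


class TestAirwayResistance:
    def test_poiseuille_arithmetic(self):
        r = airway_resistance(0.01, 0.001,
                              ResistanceModel(viscosity=1.9e-5))
        assert r == pytest.approx(8 * 1.9e-5 * 0.01 / (np.pi * 0.001**4),
                                  rel=1e-12)
        assert r == pytest.approx(4.84e5, rel=1e-2)

    def test_severity_multiplies_by_inverse_fourth_power(self):
        base = airway_resistance(0.01, 0.001)
        assert airway_resistance(0.01, 0.001, severity=0.5) == \
            pytest.approx(base * 16.0, rel=1e-12)
        assert airway_resistance(0.01, 0.001, severity=0.0) == \
            pytest.approx(base, rel=1e-14)

    def test_pedley_never_below_poiseuille(self):
        model = ResistanceModel(mode="pedley")
        base = airway_resistance(0.01, 0.004)
        for q in [0.0, 1e-6, 1e-4, 1e-3]:
            assert airway_resistance(0.01, 0.004, model, flow=q) >= base

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            airway_resistance(0.01, 0.001, severity=1.0)


class TestAcinarMechanics:
    def test_parallel_elastances(self, symmetric_net):
        e_a = distribute_acinar_mechanics(symmetric_net, 6.82)
        assert symmetric_net.n_acini == 8
        assert np.allclose(e_a, 8 * 6.82)
        combined = 1.0 / np.sum(1.0 / symmetric_net.acinus_E)
        assert units.elastance_si_to_cmh2o_per_l(combined) == \
            pytest.approx(6.82, rel=1e-10)

    def test_single_acinus(self, single_compartment_net):
        e_a = distribute_acinar_mechanics(single_compartment_net, 6.82)
        assert e_a[0] == pytest.approx(6.82)

    def test_elastance_volume_rescaling(self):
        assert rescale_elastance(5.0, 4.5, 3.3) == pytest.approx(
            6.82, abs=0.005)


def test_waveform_integrates_to_tidal_volume():
    w = BreathingWaveform(tb=5.0, vt_l=0.625)
    t = np.linspace(0, 2.5, 100001)
    vol = np.trapezoid(w.tracheal_flow(t), t)
    assert vol == pytest.approx(w.vt, rel=1e-8)
    assert w.tracheal_flow(0.0) == pytest.approx(0.0, abs=1e-18)
    assert w.tracheal_flow(2.5) == pytest.approx(0.0, abs=1e-18)


class TestAssembleAndSolve:
    def test_flow_conservation_at_bifurcations(self, small_vent):
        assert small_vent.conservation_residual() < 1e-8

    def test_tidal_volume_delivered(self, small_vent):
        assert small_vent.tidal_volume_delivered() == pytest.approx(
            small_vent.waveform.vt, rel=1e-3)

    def test_symmetric_tree_sister_flows_equal(self, symmetric_net):
        vent = assemble_and_solve(symmetric_net)
        net = symmetric_net
        children = net.children()
        for ch in children:
            if len(ch) == 2:
                assert np.allclose(vent.airway_flow[:, ch[0]],
                                   vent.airway_flow[:, ch[1]],
                                   rtol=1e-9, atol=1e-16)

    def test_two_branch_resistive_divider(self, two_branch_factory):
        """With negligible acinar impedance, the instantaneous flow split
        between an open and a sigma=0.5 branch is the Poiseuille
        (1-sigma)^-4 = 16 closed form."""
        net = two_branch_factory(sigma=0.5, e_total=1e-10)
        vent = assemble_and_solve(net, n_breaths=1)
        k = len(vent.times) // 4  # mid-inhalation
        ratio = vent.airway_flow[k, 1] / vent.airway_flow[k, 2]
        assert ratio == pytest.approx(16.0, rel=1e-8)

    def test_linearity_in_tidal_volume(self, small_net):
        v1 = assemble_and_solve(small_net, BreathingWaveform(vt_l=0.3))
        v2 = assemble_and_solve(small_net, BreathingWaveform(vt_l=0.6))
        assert np.allclose(v2.airway_flow, 2.0 * v1.airway_flow,
                           rtol=1e-9, atol=1e-15)
        assert np.allclose(v2.acinus_volume - small_net.acinus_V0,
                           2.0 * (v1.acinus_volume - small_net.acinus_V0),
                           rtol=1e-9, atol=1e-15)

    def test_flows_periodic_after_conditioning(self, small_net):
        vent = assemble_and_solve(small_net, n_breaths=3)
        drift = np.abs(vent.acinus_volume[-1] - vent.acinus_volume[0])
        assert drift.max() < 1e-9 * small_net.acinus_V0[0]

    def test_lobar_ventilation_proportional_to_acini(self, symmetric_net):
        """Equal-resistance symmetric tree: each subtree's flow share is
        its share of subtended acini (the uniform-ventilation limit)."""
        vent = assemble_and_solve(symmetric_net)
        net = symmetric_net
        counts = net.subtended_acinus_count()
        k = len(vent.times) // 4
        q0 = vent.airway_flow[k, net.root]
        for i in range(net.n_airways):
            share = counts[i] / net.n_acini
            assert vent.airway_flow[k, i] / q0 == pytest.approx(
                share, rel=1e-9)

    def test_blocked_network_reported(self, two_branch_factory):
        net = two_branch_factory()
        net.radius[:] = [0.004, 1e-12, 1e-12]  # effectively fully blocked
        with pytest.raises(RuntimeError):
            assemble_and_solve(net, n_breaths=1)


class TestMonotonicityVsDenseOracle:
    """Constricting one terminal branch never increases time-averaged flow
    through it; flows match an independent dense linear-algebra oracle."""

    def dense_oracle(self, net, waveform, dt, n_steps):
        """Quasi-static dense solve, built from first principles."""
        n = net.n_airways
        res = 8 * units.AIR_VISCOSITY * net.length / (np.pi * net.radius**4)
        pnode = np.where(net.parent_index >= 0, net.parent_index, n)
        g = 1.0 / (net.acinus_E * dt + net.acinus_eta)
        term = net.acinus_terminal_airway
        nun = n + 2
        A = np.zeros((nun, nun))
        for i in range(n):
            A[i, pnode[i]] += 1 / res[i]
            A[i, i] -= 1 / res[i]
        for i, p in enumerate(net.parent_index):
            if p >= 0:
                A[p, p] -= 1 / res[i]
                A[p, i] += 1 / res[i]
        for b, t_aw in enumerate(term):
            A[t_aw, t_aw] -= g[b]
            A[t_aw, n + 1] += g[b]
            A[n + 1, t_aw] += g[b]
        A[n + 1, n + 1] -= g.sum()
        A[n, n] = 1.0
        vol = net.acinus_V0.copy()
        flows = np.zeros((n_steps + 1, n))
        for s in range(n_steps):
            q0 = waveform.tracheal_flow((s + 1) * dt)
            rhs = np.zeros(nun)
            dv = vol - net.acinus_V0
            rhs[term] = -g * net.acinus_E * dv
            rhs[n + 1] = q0 + np.sum(g * net.acinus_E * dv)
            p = np.linalg.solve(A, rhs)
            q = (p[pnode] - p[:n]) / res
            flows[s + 1] = q
            vol += dt * g * (p[term] - p[n + 1] - net.acinus_E * dv)
        return flows

    def test_solver_matches_dense_oracle(self, two_branch_factory):
        net = two_branch_factory(sigma=0.3)
        wf = BreathingWaveform()
        vent = assemble_and_solve(net, wf, n_breaths=1)
        flows = self.dense_oracle(net, wf, vent.dt, vent.n_steps)
        assert np.allclose(vent.airway_flow[1:], flows[1:],
                           rtol=1e-8, atol=1e-14)

    def test_constriction_never_increases_branch_flow(self,
                                                      two_branch_factory):
        wf = BreathingWaveform()
        prev = np.inf
        for sigma in [0.0, 0.2, 0.4, 0.6, 0.8]:
            net = two_branch_factory(sigma=sigma)
            flows = self.dense_oracle(net, wf, 0.01, 250)
            mean_q = np.abs(flows[:, 2]).mean()
            assert mean_q <= prev + 1e-15
            prev = mean_q
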