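"""Network ventilation: per-airway flows from resistance and acinar mechanics.

Air flow is driven by a prescribed sinusoidal tracheal flow rate
``Q0(t) = (pi VT / Tb) sin(2 pi t / Tb)`` (positive = inhalation; the
integral over the inhalation half-cycle is exactly VT). Each conducting
airway is a rigid Poiseuille resistor ``R = 8 mu L / (pi r^4)`` (optionally
with the Pedley entrance-flow correction); each acinus is a linear
viscoelastic (Kelvin-Voigt) bag,

    P_a - P_pl = E_a (V_a - V0) + eta_a dV_a/dt,

with the spatially uniform pleural pressure P_pl entering as an extra
unknown whose equation enforces that the summed acinar volume rate equals
Q0(t). Time stepping is backward Euler; with linear resistances the system
matrix is constant in time and is factorized once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import units
from .network import AirwayNetwork

AIR_DENSITY = 1.12  # kg/m3 at body temperature


@dataclass(frozen=True)
class BreathingWaveform:
    """Sinusoidal tidal breathing."""

    tb: float = 5.0       # breath period, s
    vt_l: float = 0.625   # tidal volume, litres

    def __post_init__(self):
        if self.tb <= 0 or self.vt_l <= 0:
            raise ValueError("breath period and tidal volume must be positive")

    @property
    def vt(self) -> float:
        """Tidal volume, m3."""
        return self.vt_l * units.M3_PER_L

    def tracheal_flow(self, t) -> np.ndarray:
        """Q0(t), m3/s, positive during inhalation."""
        return (math.pi * self.vt / self.tb) * np.sin(
            2.0 * math.pi * np.asarray(t, dtype=float) / self.tb)


@dataclass(frozen=True)
class ResistanceModel:
    """Airway resistance law."""

    mode: str = "poiseuille"      # or "pedley"
    viscosity: float = units.AIR_VISCOSITY
    density: float = AIR_DENSITY
    pedley_c: float = 1.85

    def __post_init__(self):
        if self.mode not in ("poiseuille", "pedley"):
            raise ValueError("mode must be 'poiseuille' or 'pedley'")


def airway_resistance(length, radius, model: ResistanceModel =
                      ResistanceModel(), flow=0.0, severity=0.0):
    """Resistance of an airway, Pa s m^-3.

    ``severity`` is a radius-constriction fraction; it multiplies the
    Poiseuille resistance by ``(1 - severity)^-4``. In ``pedley`` mode the
    resistance is additionally scaled by the entrance-flow dissipation
    factor ``Z = (C/4) sqrt(Re 2r / L)`` whenever Z > 1, which makes it
    flow-dependent and never smaller than the Poiseuille value.
    """
    length = np.asarray(length, dtype=float)
    radius = np.asarray(radius, dtype=float) * (1.0 - np.asarray(severity))
    if np.any(radius <= 0):
        raise ValueError("airway radius must be positive (severity < 1)")
    r_pois = 8.0 * model.viscosity * length / (np.pi * radius**4)
    if model.mode == "poiseuille":
        return r_pois
    q = np.abs(np.asarray(flow, dtype=float))
    reynolds = 2.0 * model.density * q / (np.pi * radius * model.viscosity)
    z = 0.25 * model.pedley_c * np.sqrt(
        np.maximum(reynolds * 2.0 * radius / length, 0.0))
    return r_pois * np.maximum(z, 1.0)


def rescale_elastance(e_ref: float, frc_ref_l: float, frc_l: float) -> float:
    """Rescale a total lung elastance inversely with lung volume
    (e.g. 5 cmH2O/l at FRC 4.5 l -> 6.82 cmH2O/l at 3.3 l)."""
    return e_ref * frc_ref_l / frc_l


def distribute_acinar_mechanics(net: AirwayNetwork,
                                e_total_cmh2o_per_l: float,
                                eta_total_cmh2o_s_per_l: float = 0.0,
                                ) -> np.ndarray:
    """Assign identical per-acinus elastance from a total lung elastance.

    N identical acini in parallel combine as ``E_total = E_a / N``, so each
    acinus receives ``E_a = N * E_total``. Returns the per-acinus elastance
    in cmH2O/l and updates the network in place.
    """
    n = net.n_acini
    if n == 0:
        raise ValueError("network has no acini")
    e_a = n * e_total_cmh2o_per_l
    net.acinus_E = np.full(n, units.elastance_cmh2o_per_l_to_si(e_a))
    net.acinus_eta = np.full(
        n, n * eta_total_cmh2o_s_per_l * units.PA_PER_CMH2O / units.M3_PER_L)
    return np.full(n, e_a)


@dataclass
class VentilationSolution:
    """Flows and acinar volumes over one recorded breath.

    Arrays are sampled on the time grid ``times`` (t=0 is end-exhalation at
    the start of the recorded breath); ``airway_flow[k, i]`` is the flow
    through airway i at ``times[k]``, positive towards the periphery.
    """

    net: AirwayNetwork
    waveform: BreathingWaveform
    dt: float
    times: np.ndarray
    airway_flow: np.ndarray      # (nt, n_airways), m3/s
    acinus_volume: np.ndarray    # (nt, n_acini), m3
    acinus_flow: np.ndarray      # (nt, n_acini), m3/s
    pleural_pressure: np.ndarray  # (nt,), Pa
    q0: np.ndarray               # (nt,), m3/s

    @property
    def n_steps(self) -> int:
        return self.times.size - 1

    def conservation_residual(self) -> float:
        """Worst relative flow imbalance over all bifurcations and times."""
        net = self.net
        inflow = self.airway_flow.copy()
        out = np.zeros_like(inflow)
        for i, p in enumerate(net.parent_index):
            if p >= 0:
                out[:, p] += self.airway_flow[:, i]
        a = net.acinus_index
        term = a >= 0
        out[:, term] += self.acinus_flow[:, a[term]]
        scale = max(np.abs(self.q0).max(), 1e-300)
        return float(np.abs(inflow - out).max() / scale)

    def tidal_volume_delivered(self) -> float:
        """Summed acinar volume change over the inhalation half-cycle, m3."""
        k = int(round(self.waveform.tb / 2.0 / self.dt))
        return float(np.sum(self.acinus_volume[k] - self.acinus_volume[0]))


def assemble_and_solve(net: AirwayNetwork,
                       waveform: BreathingWaveform = BreathingWaveform(),
                       model: ResistanceModel = ResistanceModel(),
                       dt: float = 0.01,
                       n_breaths: int = 2,
                       pedley_iterations: int = 4) -> VentilationSolution:
    """Solve the coupled airway/acinus system over ``n_breaths`` breaths.

    The first ``n_breaths - 1`` breaths condition away the initial
    transient (acini start at V0, end-exhalation); the last breath is
    recorded and returned. Raises if the system is singular (e.g. an
    acinus whose every path is fully blocked).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.any(~np.isfinite(net.acinus_E)) or np.any(net.acinus_E <= 0):
        raise ValueError("acinar elastances must be set and positive")
    n_aw = net.n_airways
    n_ac = net.n_acini
    inlet = n_aw
    ipl = n_aw + 1
    nun = n_aw + 2

    resistance = airway_resistance(net.length, net.radius, model)
    parent = net.parent_index
    pnode = np.where(parent >= 0, parent, inlet)
    term_aw = net.acinus_terminal_airway
    g_ac = 1.0 / (net.acinus_E * dt + net.acinus_eta)

    def build_matrix(res):
        cond = 1.0 / res
        rows, cols, vals = [], [], []
        # conservation at each airway's distal node
        rows += [np.arange(n_aw), np.arange(n_aw)]
        cols += [pnode, np.arange(n_aw)]
        vals += [cond, -cond]
        ch = parent >= 0
        rows += [parent[ch], parent[ch]]
        cols += [parent[ch], np.flatnonzero(ch)]
        vals += [-cond[ch], cond[ch]]
        # NOTE: flows out of the inlet node are not conserved here; the
        # inlet has a Dirichlet row instead.
        rows += [term_aw, term_aw]
        cols += [term_aw, np.full(n_ac, ipl)]
        vals += [-g_ac, g_ac]
        # inlet Dirichlet
        rows += [np.array([inlet])]
        cols += [np.array([inlet])]
        vals += [np.array([1.0])]
        # pleural constraint: sum of acinar flows = Q0
        rows += [np.full(n_ac, ipl), np.array([ipl])]
        cols += [term_aw, np.array([ipl])]
        vals += [g_ac, np.array([-g_ac.sum()])]
        mat = sparse.csc_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(nun, nun))
        try:
            return splu(mat)
        except RuntimeError as exc:
            raise RuntimeError(
                "ventilation system is singular (fully blocked acinus?): "
                f"{exc}") from exc

    lu = build_matrix(resistance)

    steps_per_breath = int(round(waveform.tb / dt))
    total_steps = steps_per_breath * n_breaths
    rec0 = total_steps - steps_per_breath

    vol = net.acinus_V0.copy()
    dv = np.zeros(n_ac)
    flow = np.zeros(n_aw)

    nt = steps_per_breath + 1
    out_t = np.arange(nt) * dt
    out_flow = np.zeros((nt, n_aw))
    out_vol = np.zeros((nt, n_ac))
    out_q = np.zeros((nt, n_ac))
    out_ppl = np.zeros(nt)
    out_q0 = np.zeros(nt)

    rhs = np.zeros(nun)
    for step in range(total_steps):
        t1 = (step + 1) * dt
        q0 = float(waveform.tracheal_flow(t1))
        dvn = vol - net.acinus_V0
        rhs[:] = 0.0
        rhs[term_aw] = -g_ac * net.acinus_E * dvn
        rhs[ipl] = q0 + np.sum(g_ac * net.acinus_E * dvn)
        if model.mode == "pedley":
            for _ in range(pedley_iterations):
                res = airway_resistance(net.length, net.radius, model,
                                        flow=flow)
                lu = build_matrix(res)
                pr = lu.solve(rhs)
                flow = (pr[pnode] - pr[:n_aw]) / res
        else:
            pr = lu.solve(rhs)
            flow = (pr[pnode] - pr[:n_aw]) / resistance
        q_ac = g_ac * (pr[term_aw] - pr[ipl] - net.acinus_E * dvn)
        vol = vol + dt * q_ac

        if step >= rec0:
            k = step - rec0 + 1
            out_flow[k] = flow
            out_vol[k] = vol
            out_q[k] = q_ac
            out_ppl[k] = pr[ipl]
            out_q0[k] = q0
        if step == rec0 - 1:
            out_vol[0] = vol
            out_flow[0] = flow
            out_q[0] = q_ac
            out_ppl[0] = pr[ipl]
            out_q0[0] = q0

    if rec0 == 0:
        out_vol[0] = net.acinus_V0
        # flows at t=0 are zero (end-exhalation, Q0(0)=0)

    return VentilationSolution(
        net=net, waveform=waveform, dt=dt, times=out_t,
        airway_flow=out_flow, acinus_volume=out_vol, acinus_flow=out_q,
        pleural_pressure=out_ppl, q0=out_q0)
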