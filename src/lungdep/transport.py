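"""Advection-diffusion-deposition transport on the discretized network.

The cross-sectionally averaged concentration obeys

    dc/dt = d/dz ( -u c + D_eff dc/dz ) - s

on every airway, with mass conservation at bifurcations. The discrete
form is a finite-volume scheme on the node tree with exponential-fitted
(Scharfetter-Gummel) advection-diffusion edge fluxes -- exact for steady
transport on each edge, reducing to central diffusion at zero flow and to
first-order upwinding at vanishing diffusivity -- stepped with backward
Euler. The scheme is an M-matrix, so concentrations stay non-negative,
and the per-step linear system is solved exactly by the O(N) tree solver. The deposition sink s is a first-order
rate per edge obtained from the impaction/sedimentation/diffusion transit
efficiencies; mechanism probabilities are evaluated on whole airways (and
whole acinar-duct generations) so that deposition does not depend on how
many edges discretize an airway. Impaction acts at each airway's entrance
edge and its tally is assigned to the parent airway, mirroring how
bifurcation deposition is attributed in scintigraphy-style summaries.

Boundary condition at the tracheal inlet: prescribed concentration flux
``Q0(t) * c_in`` during inhalation, advective outflow during exhalation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import deposition as dep
from .discretize import DiscretizedNetwork
from .network import AirwayNetwork, classify_airways
from .particles import GasProperties, ParticleProperties
from .treesolve import solve_bicgstab, solve_tree
from .ventilation import VentilationSolution


def _bernoulli(x):
    """B(x) = x / (e^x - 1), the Scharfetter-Gummel weighting function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-10
    out[small] = 1.0 - 0.5 * x[small]
    xs = x[~small]
    with np.errstate(over="ignore"):
        out[~small] = xs / np.expm1(xs)
    return out


@dataclass
class MechanismSet:
    """Pluggable deposition-efficiency correlations."""

    impaction: Callable = dep.impaction_probability
    sedimentation: Callable = dep.sedimentation_probability
    diffusion: Callable = dep.diffusion_probability


@dataclass
class TransportState:
    """Concentration field and deposition tallies."""

    concentration: np.ndarray          # (N,) particles / m3
    node_volume: np.ndarray            # (N,) m3 at the current time
    deposited_imp: np.ndarray          # (N,) particles, per edge
    deposited_sed: np.ndarray
    deposited_dif: np.ndarray
    inhaled: float = 0.0
    exhaled: float = 0.0
    step_index: int = 0

    @property
    def deposited(self) -> np.ndarray:
        return self.deposited_imp + self.deposited_sed + self.deposited_dif

    @property
    def airborne(self) -> float:
        return float(np.dot(self.node_volume, self.concentration))


class TransportStepper:
    """Backward-Euler stepper bound to a discretization and a ventilation
    solution. The ventilation breath is reused cyclically for multi-breath
    runs (washout)."""

    def __init__(self, disc: DiscretizedNetwork, vent: VentilationSolution,
                 particle: Optional[ParticleProperties] = None,
                 gas: Optional[GasProperties] = None,
                 c_inlet: float = 1.0,
                 mechanisms: Optional[MechanismSet] = None,
                 solver: str = "tree",
                 dispersion_coeff: float = dep.DISPERSION_COEFF):
        if (particle is None) == (gas is None):
            raise ValueError("specify exactly one of particle or gas")
        if solver not in ("tree", "bicgstab"):
            raise ValueError("solver must be 'tree' or 'bicgstab'")
        self.disc = disc
        self.vent = vent
        self.particle = particle
        self.gas = gas
        self.c_inlet = float(c_inlet)
        self.mech = mechanisms or MechanismSet()
        self.solver = solver
        self.dispersion_coeff = dispersion_coeff
        self.dt = vent.dt
        self._prepare_static()

    # ------------------------------------------------------------------
    def _prepare_static(self):
        d = self.disc
        net = d.net
        self.molecular_d = (self.gas.diffusivity if self.gas is not None
                            else self.particle.diffusivity)
        self.deposit = self.particle is not None
        # conducting per-airway geometry
        self.aw_area = np.pi * net.radius**2
        axis = net.distal - net.proximal
        an = np.maximum(np.linalg.norm(axis, axis=1), 1e-300)
        self.aw_cosphi = np.sqrt(axis[:, 0]**2 + axis[:, 1]**2) / an
        first = d.edge_is_first
        self.first_nodes = np.flatnonzero(first)
        self.first_airway = d.edge_airway[self.first_nodes]
        self.first_h = d.edge_h[self.first_nodes]
        self.branch_angle = d.edge_branch_angle[self.first_nodes]
        if d.acinar_mode == "tree" and self.deposit:
            m = d.acinar_model
            ng = m.n_generations
            # mean sleeve fraction distal to each generation's midpoint
            w = m.sleeve_fraction
            tail = np.concatenate([w[::-1].cumsum()[::-1][1:], [0.0]])
            self.ac_wmid = tail + 0.5 * w
            self.ac_area = (m.scale_for(net.acinus_V0)[:, None]
                            * m.duct_area[None, :])
            self.ac_len = m.lengths
            self.ac_rad = m.radii
            self.ac_cos = m.cos_incline
            flat = d.edge_acinus * ng + d.edge_acinar_gen
            self.ac_edge_flat = np.where(d.edge_acinus >= 0, flat, 0)
        self.is_acinar_edge = d.edge_acinus >= 0

    # ------------------------------------------------------------------
    def initial_state(self, concentration: float = 0.0) -> TransportState:
        d = self.disc
        v = d.node_volumes(self.vent.acinus_volume[0])
        c = np.full(d.n_nodes, float(concentration))
        z = np.zeros(d.n_nodes)
        return TransportState(concentration=c, node_volume=v,
                              deposited_imp=z.copy(), deposited_sed=z.copy(),
                              deposited_dif=z.copy())

    def _edge_rates(self, q_edge):
        """Per-edge deposition rates (imp, sed, dif), s^-1."""
        d = self.disc
        net = d.net
        n = d.n_nodes
        lam_imp = np.zeros(n)
        lam_sed = np.zeros(n)
        lam_dif = np.zeros(n)
        if not self.deposit:
            return lam_imp, lam_sed, lam_dif
        p = self.particle
        # conducting airways: probabilities on the whole airway
        q_aw = q_edge[d.airway_last_node]
        u_aw = q_aw / self.aw_area
        p_sed = self.mech.sedimentation(p, net.length, net.radius,
                                        self.aw_cosphi, u_aw)
        p_dif = self.mech.diffusion(p.diffusivity, net.length, net.radius,
                                    u_aw)
        lam_sed_aw = dep.rate_from_probability(p_sed, u_aw, net.length)
        lam_dif_aw = dep.rate_from_probability(p_dif, u_aw, net.length)
        cond = d.edge_airway >= 0
        lam_sed[cond] = lam_sed_aw[d.edge_airway[cond]]
        lam_dif[cond] = lam_dif_aw[d.edge_airway[cond]]
        # impaction on each airway's entrance edge
        p_imp = self.mech.impaction(p, u_aw[self.first_airway],
                                    net.radius[self.first_airway],
                                    self.branch_angle)
        lam_imp[self.first_nodes] = dep.rate_from_probability(
            p_imp, u_aw[self.first_airway], self.first_h)
        # acinar ducts: probabilities per generation (impaction neglected;
        # velocities there are far below the impaction range)
        if d.acinar_mode == "tree":
            q_ac = self.vent_acinus_flow_current
            u_gen = (q_ac[:, None] * self.ac_wmid[None, :]) / self.ac_area
            ps = self.mech.sedimentation(p, self.ac_len[None, :],
                                         self.ac_rad[None, :],
                                         self.ac_cos, u_gen)
            pd_ = self.mech.diffusion(p.diffusivity, self.ac_len[None, :],
                                      self.ac_rad[None, :], u_gen)
            ls = dep.rate_from_probability(ps, u_gen, self.ac_len[None, :])
            ld = dep.rate_from_probability(pd_, u_gen, self.ac_len[None, :])
            m = self.is_acinar_edge
            lam_sed[m] = ls.ravel()[self.ac_edge_flat[m]]
            lam_dif[m] = ld.ravel()[self.ac_edge_flat[m]]
        return lam_imp, lam_sed, lam_dif

    def step(self, state: TransportState) -> TransportState:
        """Advance one backward-Euler step (in place) and return state."""
        d = self.disc
        dt = self.dt
        ns = self.vent.n_steps
        k1 = (state.step_index % ns) + 1
        q0 = float(self.vent.q0[k1])
        q_ac = self.vent.acinus_flow[k1]
        self.vent_acinus_flow_current = q_ac
        q_edge = d.edge_flows(self.vent.airway_flow[k1], q_ac)
        v_new = d.node_volumes(self.vent.acinus_volume[k1])

        with np.errstate(divide="ignore", invalid="ignore"):
            u_edge = np.where(d.edge_area > 0, q_edge / d.edge_area, 0.0)
        d_eff = dep.effective_diffusivity(self.molecular_d, d.edge_radius,
                                          u_edge, self.dispersion_coeff)
        g = d_eff * d.edge_area / d.edge_h
        g[0] = 0.0
        # Scharfetter-Gummel edge flux F(parent->child) =
        #   a_in * c_parent - a_out * c_child, with Peclet number q/g;
        # reduces to pure upwinding where the edge diffusivity is zero.
        with np.errstate(divide="ignore", invalid="ignore"):
            pe = np.where(g > 0.0, q_edge / np.where(g > 0.0, g, 1.0), 0.0)
        a_in = np.where(g > 0.0, g * _bernoulli(-pe),
                        np.maximum(q_edge, 0.0))
        a_out = np.where(g > 0.0, g * _bernoulli(pe),
                         np.maximum(-q_edge, 0.0))
        a_in[0] = a_out[0] = 0.0

        lam_imp, lam_sed, lam_dif = self._edge_rates(q_edge)
        lam = lam_imp + lam_sed + lam_dif
        vol_e = d.edge_area * d.edge_h
        # each edge's sink acts half on each endpoint node (midpoint
        # quadrature over the half-edge volumes the nodes own)
        sink_half = 0.5 * lam * vol_e

        parent = d.parent_node
        diag = v_new / dt
        diag += a_out
        diag += np.bincount(np.maximum(parent, 0), weights=a_in,
                            minlength=d.n_nodes)
        diag += sink_half
        diag += np.bincount(np.maximum(parent, 0), weights=sink_half,
                            minlength=d.n_nodes)
        lower = -a_out
        upper = -a_in
        rhs = state.node_volume * state.concentration / dt
        if q0 > 0.0:
            rhs[0] += q0 * self.c_inlet
        elif q0 < 0.0:
            diag[0] += -q0

        if self.solver == "tree":
            c = solve_tree(parent, diag, lower, upper, rhs)
        else:
            c = solve_bicgstab(parent, diag, lower, upper, rhs,
                               x0=state.concentration)

        c_pair = c + c[np.maximum(parent, 0)]
        dep_base = 0.5 * vol_e * c_pair * dt
        state.deposited_imp += lam_imp * dep_base
        state.deposited_sed += lam_sed * dep_base
        state.deposited_dif += lam_dif * dep_base
        if q0 > 0.0:
            state.inhaled += q0 * self.c_inlet * dt
        elif q0 < 0.0:
            state.exhaled += -q0 * c[0] * dt
        state.concentration = c
        state.node_volume = v_new
        state.step_index += 1
        return state

    def run_breath(self, state: Optional[TransportState] = None,
                   ) -> TransportState:
        """Advance one full breath (inhalation + exhalation)."""
        if state is None:
            state = self.initial_state()
        for _ in range(self.vent.n_steps):
            self.step(state)
        return state


def step_transport(stepper: TransportStepper,
                   state: TransportState) -> TransportState:
    """Functional wrapper around :meth:`TransportStepper.step`."""
    return stepper.step(state)


# ----------------------------------------------------------------------
@dataclass
class DepositionResult:
    """Deposition of one breath, with rollups.

    All ``*_fraction`` quantities are fractions of the inhaled amount.
    """

    net: AirwayNetwork
    disc: DiscretizedNetwork
    per_edge_imp: np.ndarray
    per_edge_sed: np.ndarray
    per_edge_dif: np.ndarray
    inhaled: float
    exhaled: float
    residual: float

    @property
    def per_edge(self) -> np.ndarray:
        return self.per_edge_imp + self.per_edge_sed + self.per_edge_dif

    @property
    def deposited(self) -> float:
        return float(self.per_edge.sum())

    @property
    def deposited_fraction(self) -> float:
        return self.deposited / self.inhaled

    @property
    def exhaled_fraction(self) -> float:
        return self.exhaled / self.inhaled

    @property
    def residual_fraction(self) -> float:
        return self.residual / self.inhaled

    def conservation_error(self) -> float:
        """Relative closure error of deposited + exhaled + residual."""
        tot = self.deposited + self.exhaled + self.residual
        return abs(tot - self.inhaled) / self.inhaled

    # ---- rollups ------------------------------------------------------
    def per_airway(self) -> np.ndarray:
        """Deposited amount per conducting airway; entrance-edge impaction
        is assigned to the parent airway."""
        d = self.disc
        net = self.net
        cond = d.edge_airway >= 0
        out = np.zeros(net.n_airways)
        np.add.at(out, d.edge_airway[cond],
                  (self.per_edge_sed + self.per_edge_dif)[cond])
        first = d.edge_is_first
        aw = d.edge_airway[first]
        target = np.where(net.parent_index[aw] >= 0,
                          net.parent_index[aw], aw)
        np.add.at(out, target, self.per_edge_imp[first])
        return out

    def per_acinus(self) -> np.ndarray:
        d = self.disc
        out = np.zeros(self.net.n_acini)
        m = d.edge_acinus >= 0
        np.add.at(out, d.edge_acinus[m], self.per_edge[m])
        return out

    def splits(self) -> dict:
        """Deposited fractions in central conducting (generation < 10),
        distal conducting and acinar regions."""
        aw = self.per_airway()
        central = classify_airways(self.net) == "central"
        return {
            "central": float(aw[central].sum() / self.inhaled),
            "distal": float(aw[~central].sum() / self.inhaled),
            "acinar": float(self.per_acinus().sum() / self.inhaled),
        }

    def by_lobe(self) -> dict:
        aw = self.per_airway()
        ac = self.per_acinus()
        lobes = {}
        term_lobe = self.net.lobe[self.net.acinus_terminal_airway]
        for lobe in np.unique(self.net.lobe):
            conducting = float(aw[self.net.lobe == lobe].sum())
            acinar = float(ac[term_lobe == lobe].sum())
            lobes[str(lobe)] = {
                "conducting_fraction": conducting / self.inhaled,
                "acinar_fraction": acinar / self.inhaled,
            }
        return lobes

    def by_generation(self) -> "pd.DataFrame":
        import pandas as pd

        aw = self.per_airway() / self.inhaled
        frame = pd.DataFrame({"generation": self.net.generation,
                              "fraction": aw})
        return frame.groupby("generation", as_index=False).sum()

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        aw = self.per_airway()
        return pd.DataFrame({
            "id": self.net.ids,
            "generation": self.net.generation,
            "lobe": self.net.lobe,
            "deposited_fraction": aw / self.inhaled,
        })


def run_breath(net: AirwayNetwork, vent: VentilationSolution,
               particle: ParticleProperties = ParticleProperties(),
               disc: Optional[DiscretizedNetwork] = None,
               c_inlet: float = 1.0,
               mechanisms: Optional[MechanismSet] = None,
               solver: str = "tree") -> DepositionResult:
    """Simulate particle deposition over a single breath.

    Starts from zero concentration everywhere, applies the fixed inlet
    concentration flux during inhalation and returns the deposition
    tallies and closure fractions.
    """
    from .discretize import discretize

    if disc is None:
        disc = discretize(net, acinar_mode="tree")
    stepper = TransportStepper(disc, vent, particle=particle,
                               c_inlet=c_inlet, mechanisms=mechanisms,
                               solver=solver)
    state = stepper.run_breath()
    return DepositionResult(
        net=net, disc=disc,
        per_edge_imp=state.deposited_imp,
        per_edge_sed=state.deposited_sed,
        per_edge_dif=state.deposited_dif,
        inhaled=state.inhaled, exhaled=state.exhaled,
        residual=state.airborne)
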