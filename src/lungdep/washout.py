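"""Multiple-breath nitrogen washout and the lung clearance index.

The transport machinery is reused with deposition switched off, the
diffusivity set to that of nitrogen in oxygen at body temperature, a
uniform initial tracer concentration, acini treated as well-mixed
compartments and pure oxygen (zero tracer) inhaled at the trachea. The
end-exhalation tracheal concentration c0(n Tb) falls breath by breath;
the washout ends at the first breath n_L with c0 < c0(0)/40, and

    LCI = V_ce [c0(0) - c0(n_L Tb)] / V_tr,

where V_ce is the cumulative expired volume and V_tr the total exhaled
tracer volume, i.e. the cumulative expired volume normalized by the
washout-derived FRC estimate. For an ideal well-mixed lung of volume FRC
this reduces to n_L VT / FRC, the classic turnover count at the 1/40
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .discretize import DiscretizedNetwork, discretize
from .network import AirwayNetwork
from .particles import GasProperties
from .transport import TransportStepper
from .ventilation import VentilationSolution

WASHOUT_THRESHOLD = 1.0 / 40.0


@dataclass
class WashoutResult:
    """Per-breath washout trace and derived LCI."""

    c0: np.ndarray          # end-exhalation tracheal concentration / c0(0)
    v_ce: np.ndarray        # cumulative expired volume after each breath, m3
    v_tr: np.ndarray        # cumulative exhaled tracer volume, m3
    n_threshold: Optional[int]   # breath count n_L (1-based), None if not hit
    lci: Optional[float]
    converged: bool
    degenerate: bool = False
    conservation_error: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "breath": np.arange(1, self.c0.size + 1),
            "c0": self.c0,
            "cumulative_expired_l": self.v_ce * 1e3,
            "cumulative_tracer_l": self.v_tr * 1e3,
        })


def compute_lci(v_ce: float, v_tr: float, c0_initial: float,
                c0_end: float) -> float:
    """LCI from cumulative expired volume, exhaled tracer volume and the
    initial/final end-exhalation concentrations."""
    if v_tr <= 0:
        raise ValueError("no tracer was exhaled; LCI undefined")
    return v_ce * (c0_initial - c0_end) / v_tr


def run_washout(net: AirwayNetwork, vent: VentilationSolution,
                gas: GasProperties = GasProperties(),
                max_breaths: int = 60,
                threshold: float = WASHOUT_THRESHOLD,
                disc: Optional[DiscretizedNetwork] = None,
                initial_concentration: float = 1.0,
                solver: str = "tree") -> WashoutResult:
    """Simulate a nitrogen multiple-breath washout.

    Terminates at the first breath whose end-exhalation tracheal
    concentration is below ``threshold`` of the initial value (and the
    previous breath's was not), or at ``max_breaths`` with
    ``converged=False``.
    """
    if disc is None:
        disc = discretize(net, acinar_mode="compartment")
    stepper = TransportStepper(disc, vent, gas=gas, c_inlet=0.0,
                               solver=solver)
    state = stepper.initial_state(initial_concentration)
    tracer0 = state.airborne
    c_init = float(initial_concentration)
    if c_init <= 0:
        return WashoutResult(c0=np.zeros(1), v_ce=np.zeros(1),
                             v_tr=np.zeros(1), n_threshold=1, lci=None,
                             converged=True, degenerate=True)

    dt = vent.dt
    ns = vent.n_steps
    c0_hist, vce_hist, vtr_hist = [], [], []
    v_ce = 0.0
    n_threshold = None
    cons_err = 0.0
    for breath in range(1, max_breaths + 1):
        for _ in range(ns):
            k1 = (state.step_index % ns) + 1
            q0 = float(vent.q0[k1])
            stepper.step(state)
            if q0 < 0.0:
                v_ce += -q0 * dt
        c_end = float(state.concentration[0])
        c0_hist.append(c_end)
        vce_hist.append(v_ce)
        vtr_hist.append(state.exhaled)
        cons_err = max(cons_err,
                       abs(state.exhaled + state.airborne - tracer0)
                       / tracer0)
        if c_end < threshold * c_init:
            n_threshold = breath
            break

    c0 = np.asarray(c0_hist) / c_init
    v_ce_arr = np.asarray(vce_hist)
    v_tr_arr = np.asarray(vtr_hist)
    lci = None
    if n_threshold is not None:
        lci = compute_lci(v_ce_arr[-1], v_tr_arr[-1], c_init,
                          c0_hist[-1])
    return WashoutResult(
        c0=c0, v_ce=v_ce_arr, v_tr=v_tr_arr,
        n_threshold=n_threshold, lci=lci,
        converged=n_threshold is not None,
        conservation_error=cons_err)
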