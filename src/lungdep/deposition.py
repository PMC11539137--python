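"""Deposition mechanism efficiencies and their conversion to sink rates.

Three mechanisms act on particles in transit through an airway segment:
inertial impaction at bifurcations, gravitational sedimentation across the
lumen of an inclined tube, and Brownian diffusion to the walls. Each is
expressed as a transit deposition probability P in [0, 1]; the mechanisms
are assumed independent, so the combined transit efficiency is
``1 - (1-P_imp)(1-P_sed)(1-P_dif)``, and is converted to a first-order
volumetric sink rate so that deposition along an airway does not depend on
how many edges discretize it.

All functions are vectorized over numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .particles import ParticleProperties

#: probabilities are capped at 1 - P_CAP_EPS before taking logs
P_CAP_EPS = 1e-12

#: default dispersion coefficient in the effective-diffusivity closure
DISPERSION_COEFF = 1.08


def stokes_number(particle: ParticleProperties, u, radius):
    """Stokes number tau * |u| / (2 r), diameter-based."""
    u = np.abs(np.asarray(u, dtype=float))
    radius = np.asarray(radius, dtype=float)
    return particle.relaxation_time * u / (2.0 * radius)


def impaction_probability(particle: ParticleProperties, u, radius,
                          branching_angle):
    """Inertial impaction efficiency at a bifurcation entrance.

    Angle-weighted Stokes-number efficiency (Yeh-Schum form):
    with ``x = theta * St``,

        P = 1 - (2/pi) arccos(x) + (1/pi) sin(2 arccos(x))   for x < 1
        P = 1                                                 for x >= 1

    Parameters
    ----------
    u : array_like
        Mean axial air velocity in the daughter entrance, m/s (sign ignored).
    radius : array_like
        Daughter airway radius, m.
    branching_angle : array_like
        Angle between the daughter axis and its parent's axis, radians.
    """
    st = stokes_number(particle, u, radius)
    x = np.clip(np.asarray(branching_angle, dtype=float) * st, 0.0, 1.0)
    acos = np.arccos(x)
    p = 1.0 - 2.0 / np.pi * acos + np.sin(2.0 * acos) / np.pi
    p = np.where(x == 0.0, 0.0, p)  # exact limit (roundoff-free)
    return np.clip(p, 0.0, 1.0)


def sedimentation_probability(particle: ParticleProperties, length, radius,
                              cos_incline, u):
    """Gravitational sedimentation in an inclined tube with Poiseuille flow.

    Pich-type inclined-tube efficiency. With settling velocity v_s,
    residence parameter

        kappa = 3 L v_s cos(phi) / (8 r |u|),

    where phi is the tube inclination to the horizontal (``cos_incline`` is
    cos(phi); 1 for a horizontal tube, 0 for one parallel to gravity):

        P = (2/pi) [ 2 kappa sqrt(1 - kappa^(2/3))
                     - kappa^(1/3) sqrt(1 - kappa^(2/3))
                     + arcsin(kappa^(1/3)) ],  capped at 1 for kappa >= 1.
    """
    length = np.asarray(length, dtype=float)
    radius = np.asarray(radius, dtype=float)
    cos_incline = np.asarray(cos_incline, dtype=float)
    u = np.abs(np.asarray(u, dtype=float))
    vs = particle.settling_velocity
    with np.errstate(divide="ignore", over="ignore"):
        kappa = np.where(
            u > 0.0,
            3.0 * length * vs * cos_incline / (8.0 * radius * u),
            np.where(vs * cos_incline > 0.0, np.inf, 0.0),
        )
    kappa = np.clip(kappa, 0.0, 1.0)
    k13 = kappa ** (1.0 / 3.0)
    root = np.sqrt(np.clip(1.0 - k13**2, 0.0, 1.0))
    p = 2.0 / np.pi * (2.0 * kappa * root - k13 * root + np.arcsin(k13))
    return np.clip(p, 0.0, 1.0)


def diffusion_probability(diffusivity, length, radius, u):
    """Brownian wall deposition in laminar tube flow (Ingham formula).

    With the dimensionless residence parameter
    ``delta = D L / (4 |u| r^2)``:

        P = 1 - 0.819 e^(-14.63 d) - 0.0976 e^(-89.22 d)
              - 0.0325 e^(-228 d) - 0.0509 e^(-125.9 d^(2/3))
    """
    diffusivity = np.asarray(diffusivity, dtype=float)
    length = np.asarray(length, dtype=float)
    radius = np.asarray(radius, dtype=float)
    u = np.abs(np.asarray(u, dtype=float))
    with np.errstate(divide="ignore", over="ignore"):
        delta = np.where(
            u > 0.0,
            diffusivity * length / (4.0 * u * radius**2),
            np.where(diffusivity > 0.0, np.inf, 0.0),
        )
    p = (
        1.0
        - 0.819 * np.exp(-14.63 * delta)
        - 0.0976 * np.exp(-89.22 * delta)
        - 0.0325 * np.exp(-228.0 * delta)
        - 0.0509 * np.exp(-125.9 * delta ** (2.0 / 3.0))
    )
    return np.clip(p, 0.0, 1.0)


def combine_mechanisms(p_imp, p_sed, p_dif, u, length):
    """Combine independent mechanism probabilities into a sink rate.

    Returns ``(p_tot, lam)`` where ``p_tot = 1 - (1-P_i)(1-P_s)(1-P_d)`` and
    ``lam`` is the first-order volumetric deposition rate (s^-1)

        lam = -ln(1 - p_tot) |u| / L,

    linearized to ``p_tot |u| / L`` for p_tot < 1e-6 and capped via
    ``p_tot <= 1 - 1e-12`` so that a certain-deposition transit stays finite.
    """
    for name, p in (("impaction", p_imp), ("sedimentation", p_sed),
                    ("diffusion", p_dif)):
        arr = np.asarray(p, dtype=float)
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError(f"{name} probability outside [0, 1]")
    p_imp = np.asarray(p_imp, dtype=float)
    p_sed = np.asarray(p_sed, dtype=float)
    p_dif = np.asarray(p_dif, dtype=float)
    p_tot = 1.0 - (1.0 - p_imp) * (1.0 - p_sed) * (1.0 - p_dif)
    lam = rate_from_probability(p_tot, u, length)
    return p_tot, lam


def rate_from_probability(p, u, length):
    """First-order rate lambda for a transit deposition probability."""
    p = np.asarray(p, dtype=float)
    u = np.abs(np.asarray(u, dtype=float))
    length = np.asarray(length, dtype=float)
    p_c = np.minimum(p, 1.0 - P_CAP_EPS)
    small = p_c < 1e-6
    lam = np.where(small, p_c, -np.log1p(-np.where(small, 0.0, p_c)))
    return lam * u / length


def effective_diffusivity(molecular_diffusivity, radius, u,
                          dispersion_coeff: float = DISPERSION_COEFF):
    """Axial effective diffusivity including shear-augmented dispersion.

    Additive closure ``D_eff = D_mol + k |u| (2 r)`` (Scherer-type). It
    reduces to the molecular value at rest and is non-decreasing in |u|.
    """
    radius = np.asarray(radius, dtype=float)
    u = np.abs(np.asarray(u, dtype=float))
    return np.asarray(molecular_diffusivity, dtype=float) + \
        dispersion_coeff * u * 2.0 * radius
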