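"""Parametric stochastic airway-tree generator.

Builds bifurcating conducting trees with five lobar subtrees hanging off a
fixed central skeleton (trachea, main bronchi, bronchus intermedius, lobar
roots). Within each lobe the tree grows by recursive splitting of a
terminal-airway budget: at each bifurcation the budget splits
asymmetrically, the child supplying more acini takes the major radius
homothety ratio and the other the minor ratio, and growth stops when a
branch's budget reaches one (that branch becomes a terminal bronchiole
with one acinus). This reproduces the gross properties of anatomically
derived trees: asymmetric path lengths (terminal generations spanning
roughly 8-20+), five lobes, radii strictly decreasing towards the
periphery, and a conducting dead space of order 100-150 ml at FRC 3.3 l.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import units
from .network import AirwayNetwork, LOBES, PRELOBAR, attach_default_acini


@dataclass(frozen=True)
class GeneratorParams:
    """Settings for :func:`generate_tree`.

    Radii in metres; the default scale is an adult lung at FRC 3.3 l.
    """

    n_terminal_target: int = 30000
    #: fraction of terminal airways assigned to each lobe
    lobe_fractions: tuple = (("RU", 0.20), ("RM", 0.10), ("RL", 0.25),
                             ("LU", 0.20), ("LL", 0.25))
    #: mean/sd of the major-side terminal-count split fraction
    split_fraction: float = 0.65
    split_fraction_sd: float = 0.10
    #: radius homothety ratios applied to the major/minor daughter
    ratio_major: float = 0.85
    ratio_minor: float = 0.78
    #: airway length as a multiple of its radius
    length_radius_ratio: float = 3.0
    #: branching half-angle, radians, and its jitter
    branching_angle: float = 0.61
    branching_angle_sd: float = 0.10
    #: rotation of the branching plane per generation, radians
    plane_rotation: float = np.pi / 2.0
    plane_rotation_sd: float = 0.35
    frc_l: float = 3.3
    e_total_cmh2o_per_l: float = 6.82
    #: fixed central-skeleton geometry (radius, length), metres
    trachea_radius: float = 0.008
    trachea_length: float = 0.10
    symmetric: bool = False
    n_generations: Optional[int] = None  # symmetric mode only


def _validate_params(p: GeneratorParams) -> None:
    if not p.symmetric and p.n_terminal_target != 1 and p.n_terminal_target < 5:
        raise ValueError(
            "n_terminal_target must be 1 (degenerate) or >= 5 (one per lobe)")
    for name, ratio in (("ratio_major", p.ratio_major),
                        ("ratio_minor", p.ratio_minor)):
        if not 0.0 < ratio < 1.0:
            raise ValueError(f"{name} must lie in (0, 1); got {ratio}")
    if p.length_radius_ratio <= 0:
        raise ValueError("length_radius_ratio must be positive")
    if not 0.5 <= p.split_fraction < 1.0:
        raise ValueError("split_fraction must lie in [0.5, 1)")
    if p.frc_l <= 0:
        raise ValueError("FRC must be positive")


class _Builder:
    def __init__(self):
        self.parent: list[int] = []
        self.generation: list[int] = []
        self.length: list[float] = []
        self.radius: list[float] = []
        self.proximal: list[np.ndarray] = []
        self.distal: list[np.ndarray] = []
        self.lobe: list[str] = []
        self.terminal: list[bool] = []

    def add(self, parent: int, generation: int, length: float, radius: float,
            proximal: np.ndarray, direction: np.ndarray, lobe: str,
            terminal: bool = False) -> int:
        idx = len(self.parent)
        self.parent.append(parent)
        self.generation.append(generation)
        self.length.append(length)
        self.radius.append(radius)
        self.proximal.append(np.asarray(proximal, dtype=float))
        self.distal.append(np.asarray(proximal, dtype=float)
                           + length * np.asarray(direction, dtype=float))
        self.lobe.append(lobe)
        self.terminal.append(terminal)
        return idx

    def to_network(self, frc_l: float,
                   e_total_cmh2o_per_l: float) -> AirwayNetwork:
        n = len(self.parent)
        acinus_index = np.full(n, -1, dtype=np.int64)
        term = np.flatnonzero(np.asarray(self.terminal))
        acinus_index[term] = np.arange(term.size)
        net = AirwayNetwork(
            ids=np.arange(n, dtype=np.int64),
            parent_index=np.asarray(self.parent, dtype=np.int64),
            generation=np.asarray(self.generation, dtype=np.int64),
            length=np.asarray(self.length, dtype=float),
            radius=np.asarray(self.radius, dtype=float),
            proximal=np.vstack(self.proximal),
            distal=np.vstack(self.distal),
            lobe=np.asarray(self.lobe, dtype=object),
            acinus_index=acinus_index,
            frc=frc_l * units.M3_PER_L,
        )
        attach_default_acini(net, e_total_cmh2o_per_l)
        return net


def _orthonormal(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction``."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _child_direction(direction: np.ndarray, theta: float,
                     psi: float, sign: float) -> np.ndarray:
    e1, e2 = _orthonormal(direction)
    lateral = np.cos(psi) * e1 + np.sin(psi) * e2
    child = np.cos(theta) * direction + sign * np.sin(theta) * lateral
    return child / np.linalg.norm(child)


def _grow_lobe(builder: _Builder, rng: np.random.Generator,
               p: GeneratorParams, root_idx: int, n_terminals: int,
               direction: np.ndarray, psi0: float) -> None:
    """Grow an asymmetric subtree below an existing lobar-root airway."""
    # stack entries: (parent_idx, budget, radius, direction, psi)
    stack = [(root_idx, n_terminals, builder.radius[root_idx],
              np.asarray(direction, float), psi0)]
    while stack:
        parent, n, r_parent, d_parent, psi = stack.pop()
        if n == 1:
            builder.terminal[parent] = True
            continue
        f = np.clip(rng.normal(p.split_fraction, p.split_fraction_sd),
                    0.52, 0.80)
        n_major = int(np.clip(round(n * f), 1, n - 1))
        n_minor = n - n_major
        theta = abs(rng.normal(p.branching_angle, p.branching_angle_sd))
        psi_child = psi + rng.normal(p.plane_rotation, p.plane_rotation_sd)
        gen = builder.generation[parent] + 1
        prox = builder.distal[parent]
        sides = [(n_major, p.ratio_major, +1.0), (n_minor, p.ratio_minor, -1.0)]
        if rng.random() < 0.5:
            sides[0], sides[1] = ((sides[0][0], sides[0][1], -1.0),
                                  (sides[1][0], sides[1][1], +1.0))
        for n_child, ratio, sign in sides:
            r = r_parent * ratio
            d = _child_direction(d_parent, theta, psi, sign)
            idx = builder.add(parent, gen, p.length_radius_ratio * r, r,
                              prox, d, builder.lobe[parent])
            stack.append((idx, n_child, r, d, psi_child))


def _grow_symmetric(builder: _Builder, rng: np.random.Generator,
                    p: GeneratorParams, root_idx: int, n_generations: int,
                    direction: np.ndarray) -> None:
    ratio = p.ratio_major
    stack = [(root_idx, 1, builder.radius[root_idx],
              np.asarray(direction, float), 0.0)]
    while stack:
        parent, gen, r_parent, d_parent, psi = stack.pop()
        if gen == n_generations:
            builder.terminal[parent] = True
            continue
        r = r_parent * ratio
        prox = builder.distal[parent]
        lobe = builder.lobe[parent]
        for k, sign in enumerate((+1.0, -1.0)):
            d = _child_direction(d_parent, p.branching_angle, psi, sign)
            child_lobe = lobe
            if lobe == PRELOBAR:  # label the two gen-2 subtrees
                child_lobe = "RU" if sign > 0 else "LU"
            idx = builder.add(parent, gen + 1, p.length_radius_ratio * r, r,
                              prox, d, child_lobe)
            stack.append((idx, gen + 1, r, d, psi + p.plane_rotation))


def generate_tree(params: GeneratorParams = GeneratorParams(), *,
                  seed: int) -> AirwayNetwork:
    """Generate a stochastic bifurcating airway network.

    Deterministic for a fixed ``seed``. Degenerate cases: a
    ``n_terminal_target`` of 1 yields a single trachea with one acinus;
    ``symmetric=True`` with ``n_generations=g`` yields the complete
    symmetric tree with ``2**(g-1)`` terminal airways.
    """
    p = params
    _validate_params(p)
    rng = np.random.default_rng(seed)
    b = _Builder()
    down = np.array([0.0, 0.0, -1.0])

    trachea = b.add(-1, 1, p.trachea_length, p.trachea_radius,
                    np.zeros(3), down, PRELOBAR)

    if p.symmetric:
        g = p.n_generations or 4
        if g < 1:
            raise ValueError("n_generations must be >= 1")
        if g == 1:
            b.terminal[trachea] = True
        else:
            _grow_symmetric(b, rng, p, trachea, g, down)
        return b.to_network(p.frc_l, p.e_total_cmh2o_per_l)

    if p.n_terminal_target == 1:
        b.terminal[trachea] = True
        return b.to_network(p.frc_l, p.e_total_cmh2o_per_l)

    carina = b.distal[trachea]

    def skel(parent, gen, radius, length, direction, lobe):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        return b.add(parent, gen, length, radius, b.distal[parent], d, lobe), d

    # main bronchi (generation 2)
    r_main, _ = skel(trachea, 2, 0.0065, 0.022, [0.55, 0.1, -0.84], PRELOBAR)
    l_main, _ = skel(trachea, 2, 0.0055, 0.045, [-0.6, -0.1, -0.8], PRELOBAR)
    # right: upper-lobe root + bronchus intermedius (generation 3)
    ru_root, ru_d = skel(r_main, 3, 0.0045, 0.0135, [0.7, 0.15, 0.4], "RU")
    interm, _ = skel(r_main, 3, 0.0055, 0.025, [0.35, 0.0, -0.94], PRELOBAR)
    # right middle + lower lobar roots (generation 4)
    rm_root, rm_d = skel(interm, 4, 0.0035, 0.0105, [0.75, -0.6, -0.2], "RM")
    rl_root, rl_d = skel(interm, 4, 0.0045, 0.0135, [0.4, 0.35, -0.85], "RL")
    # left upper + lower lobar roots (generation 3)
    lu_root, lu_d = skel(l_main, 3, 0.0045, 0.0135, [-0.7, -0.1, 0.35], "LU")
    ll_root, ll_d = skel(l_main, 3, 0.0045, 0.0135, [-0.45, 0.3, -0.85], "LL")

    roots = {"RU": (ru_root, ru_d), "RM": (rm_root, rm_d),
             "RL": (rl_root, rl_d), "LU": (lu_root, lu_d),
             "LL": (ll_root, ll_d)}

    fractions = dict(p.lobe_fractions)
    total = sum(fractions.values())
    budgets = {}
    for lobe in LOBES:
        budgets[lobe] = max(1, round(p.n_terminal_target
                                     * fractions[lobe] / total))
    for lobe in LOBES:
        root_idx, d = roots[lobe]
        _grow_lobe(b, rng, p, root_idx, budgets[lobe], d,
                   psi0=rng.uniform(0, 2 * np.pi))

    return b.to_network(p.frc_l, p.e_total_cmh2o_per_l)
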