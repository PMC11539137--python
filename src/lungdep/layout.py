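"""Schematic planar-graph layout of an airway tree.

The distal end of every generation-g airway is placed on a circle of
radius (g-1)*R0 around the trachea's distal end; the daughters of an
airway whose distal end sits at polar angle theta are placed at
theta +/- 2^-g * pi (g the parent's generation). Angular intervals of
sibling subtrees are therefore disjoint, so the drawing never
self-intersects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import AirwayNetwork


@dataclass
class PlanarLayout:
    """Polar coordinates of every airway's distal end."""

    radius: np.ndarray  # (n,) = (generation - 1) * R0
    theta: np.ndarray   # (n,) radians
    R0: float

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.radius * np.cos(self.theta),
                                self.radius * np.sin(self.theta)])


def planar_layout(net: AirwayNetwork, R0: float = 1.0) -> PlanarLayout:
    """Compute the planar layout for a network (deterministic)."""
    n = net.n_airways
    theta = np.zeros(n)
    radius = (net.generation - 1).astype(float) * R0
    order = net.topological_order()
    children = net.children()
    theta[net.root] = 0.0
    for i in order:
        ch = children[i]
        if not ch:
            continue
        g = int(net.generation[i])
        offs = 2.0 ** (-g) * np.pi
        if len(ch) == 1:
            theta[ch[0]] = theta[i]
        else:
            theta[ch[0]] = theta[i] + offs
            theta[ch[1]] = theta[i] - offs
    return PlanarLayout(radius=radius, theta=theta, R0=R0)
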