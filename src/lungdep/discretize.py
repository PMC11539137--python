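"""Sub-airway discretization of a network for transport solves.

Every conducting airway is split into ``n = max(min_edges,
ceil(L / max_edge_len))`` equal-length edges (defaults: at least eight
edges per airway, none longer than 200 um). The resulting node graph is a
tree: node 0 is the tracheal inlet, each airway contributes a chain of
nodes, and bifurcation nodes are shared between a parent's last node and
its daughters' first edges. Acini are appended either as discretized
representative acinar paths (``acinar_mode="tree"``, used for particle
deposition) or as single well-mixed compartment nodes
(``acinar_mode="compartment"``, used for gas washout).

Nodes are indexed in topological order (every parent node has a smaller
index than its children), which the tree linear solver relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acinar import AcinarModel
from .network import AirwayNetwork

DEFAULT_MAX_EDGE_LEN = 200e-6
DEFAULT_MIN_EDGES = 8
#: acinar ducts are sub-millimetre but hold most of the deposition; they
#: need a finer grid than the conducting minimum for a converged total
DEFAULT_ACINAR_MIN_EDGES = 32
DEFAULT_BRANCH_ANGLE = 0.611  # ~35 degrees, used when geometry is degenerate


def edges_per_airway(length, max_edge_len=DEFAULT_MAX_EDGE_LEN,
                     min_edges=DEFAULT_MIN_EDGES) -> np.ndarray:
    """Edge count rule: max(min_edges, ceil(L / max_edge_len))."""
    n = np.ceil(np.asarray(length, dtype=float) / max_edge_len -
                1e-12).astype(np.int64)
    return np.maximum(n, min_edges)


@dataclass
class DiscretizedNetwork:
    """Edge-level tree carrying the transport state.

    Per-node arrays describe the edge joining each node to its parent
    (node 0, the inlet, has no edge; its entries are placeholders).
    """

    net: AirwayNetwork
    acinar_mode: str
    acinar_model: AcinarModel

    parent_node: np.ndarray        # (N,) int64, -1 for the inlet
    edge_h: np.ndarray             # (N,) edge length, m
    edge_area: np.ndarray          # (N,) summed cross-section, m2
    edge_radius: np.ndarray        # (N,) tube radius for deposition, m
    edge_airway: np.ndarray        # (N,) owning airway index, -1 if acinar
    edge_acinus: np.ndarray        # (N,) owning acinus index, -1 otherwise
    edge_acinar_gen: np.ndarray    # (N,) intra-acinar generation, -1
    edge_is_first: np.ndarray      # (N,) bool, first edge of an airway
    edge_cos_incline: np.ndarray   # (N,) cos(inclination to horizontal)
    edge_branch_angle: np.ndarray  # (N,) radians (first edges only)
    edge_distal_sleeve: np.ndarray  # (N,) sleeve fraction distal to edge
    edge_midpoint: np.ndarray      # (N,3) for imaging
    v_static: np.ndarray           # (N,) rigid node volume, m3
    node_sleeve_weight: np.ndarray  # (N,) share of acinus sleeve volume
    node_acinus: np.ndarray        # (N,) int64
    airway_last_node: np.ndarray   # (n_airways,)
    airway_first_node: np.ndarray  # (n_airways,) first interior node
    n_conducting_nodes: int
    acinus_duct_volume: np.ndarray  # (n_acini,) scaled duct volume
    max_edge_len: float
    min_edges: int

    @property
    def n_nodes(self) -> int:
        return self.parent_node.size

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def node_volumes(self, acinus_volume: np.ndarray) -> np.ndarray:
        """Node volumes for given per-acinus volumes (m3)."""
        sleeve = acinus_volume - self.acinus_duct_volume
        if np.any(sleeve <= 0):
            raise ValueError("acinus volume fell below its duct volume")
        v = self.v_static.copy()
        m = self.node_acinus >= 0
        v[m] += self.node_sleeve_weight[m] * sleeve[self.node_acinus[m]]
        return v

    def edge_flows(self, airway_flow: np.ndarray,
                   acinus_flow: np.ndarray) -> np.ndarray:
        """Per-edge volumetric flow (m3/s, positive towards the periphery)
        from per-airway and per-acinus (dV/dt) flows."""
        q = np.zeros(self.n_nodes)
        mc = self.edge_airway >= 0
        q[mc] = airway_flow[self.edge_airway[mc]]
        ma = self.edge_acinus >= 0
        q[ma] = (acinus_flow[self.edge_acinus[ma]]
                 * self.edge_distal_sleeve[ma])
        return q


def _branching_angles(net: AirwayNetwork) -> np.ndarray:
    axis = net.distal - net.proximal
    norm = np.linalg.norm(axis, axis=1)
    ok = norm > 0
    unit = np.zeros_like(axis)
    unit[ok] = axis[ok] / norm[ok, None]
    ang = np.full(net.n_airways, DEFAULT_BRANCH_ANGLE)
    p = net.parent_index
    has_p = p >= 0
    dots = np.einsum("ij,ij->i", unit[has_p], unit[p[has_p]])
    good = ok[has_p] & ok[p[has_p]]
    a = np.arccos(np.clip(dots, -1.0, 1.0))
    ang[np.flatnonzero(has_p)[good]] = a[good]
    ang[~has_p] = 0.0  # trachea: no bifurcation upstream
    return ang


def discretize(net: AirwayNetwork,
               max_edge_len: float = DEFAULT_MAX_EDGE_LEN,
               min_edges: int = DEFAULT_MIN_EDGES,
               acinar_mode: str = "tree",
               acinar_model: Optional[AcinarModel] = None,
               acinar_max_edge_len: Optional[float] = None,
               acinar_min_edges: int = DEFAULT_ACINAR_MIN_EDGES,
               ) -> DiscretizedNetwork:
    """Discretize a network for transport solves.

    ``acinar_max_edge_len`` / ``acinar_min_edges`` control the edge rule
    inside acinar ducts; the acinar default is finer than the conducting
    minimum because the expanding alveolar sleeves dominate deposition and
    converge more slowly with edge count.
    """
    if acinar_mode not in ("tree", "compartment"):
        raise ValueError("acinar_mode must be 'tree' or 'compartment'")
    model = acinar_model or AcinarModel()

    n_aw = net.n_airways
    order = net.topological_order()
    ne = edges_per_airway(net.length, max_edge_len, min_edges)

    # node bases assigned in topological order so parents precede children
    base = np.zeros(n_aw, dtype=np.int64)
    nxt = 1  # node 0 = inlet
    for i in order:
        base[i] = nxt
        nxt += ne[i]
    n_cond = nxt

    parent_node = np.full(n_cond, -1, dtype=np.int64)
    edge_h = np.ones(n_cond)
    edge_area = np.zeros(n_cond)
    edge_radius = np.ones(n_cond)
    edge_airway = np.full(n_cond, -1, dtype=np.int64)
    edge_is_first = np.zeros(n_cond, dtype=bool)
    edge_cosphi = np.zeros(n_cond)
    edge_midpoint = np.zeros((n_cond, 3))

    axis = net.distal - net.proximal
    axis_norm = np.maximum(np.linalg.norm(axis, axis=1), 1e-300)
    cosphi_aw = np.sqrt(np.maximum(
        axis[:, 0] ** 2 + axis[:, 1] ** 2, 0.0)) / axis_norm
    angles = _branching_angles(net)

    for i in order:
        k = int(ne[i])
        nodes = np.arange(base[i], base[i] + k)
        p = net.parent_index[i]
        first_parent = 0 if p < 0 else base[p] + ne[p] - 1
        parent_node[nodes[0]] = first_parent
        parent_node[nodes[1:]] = nodes[:-1]
        h = net.length[i] / k
        edge_h[nodes] = h
        edge_area[nodes] = np.pi * net.radius[i] ** 2
        edge_radius[nodes] = net.radius[i]
        edge_airway[nodes] = i
        edge_is_first[nodes[0]] = True
        edge_cosphi[nodes] = cosphi_aw[i]
        frac = (np.arange(k) + 0.5) / k
        edge_midpoint[nodes] = net.proximal[i] + frac[:, None] * axis[i]

    edge_branch_angle = np.zeros(n_cond)
    fmask = edge_is_first
    edge_branch_angle[fmask] = angles[edge_airway[fmask]]

    # rigid node volumes: half of each adjacent edge's volume
    evol = edge_area * edge_h
    v_static = np.zeros(n_cond)
    v_static[1:] += 0.5 * evol[1:]
    np.add.at(v_static, parent_node[1:], 0.5 * evol[1:])

    n_ac = net.n_acini
    term_nodes = base[net.acinus_terminal_airway] + \
        ne[net.acinus_terminal_airway] - 1
    scale = model.scale_for(net.acinus_V0)

    if acinar_mode == "compartment":
        n_per = 1
        n_total = n_cond + n_ac
        pn = np.concatenate([parent_node, term_nodes])
        r0 = model.radii[0]
        eh = np.concatenate([edge_h, np.full(n_ac, model.lengths[0])])
        ea = np.concatenate([edge_area, scale * np.pi * r0**2])
        er = np.concatenate([edge_radius, np.full(n_ac, r0)])
        eaw = np.concatenate([edge_airway, np.full(n_ac, -1, np.int64)])
        eac = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.arange(n_ac, dtype=np.int64)])
        eag = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.zeros(n_ac, np.int64)])
        efirst = np.concatenate([edge_is_first, np.zeros(n_ac, bool)])
        ecos = np.concatenate([edge_cosphi, np.full(n_ac, model.cos_incline)])
        eang = np.concatenate([edge_branch_angle, np.zeros(n_ac)])
        edist = np.concatenate([np.zeros(n_cond), np.ones(n_ac)])
        emid = np.vstack([edge_midpoint,
                          net.distal[net.acinus_terminal_airway]])
        vs = np.concatenate([v_static, np.zeros(n_ac)])
        sw = np.concatenate([np.zeros(n_cond), np.ones(n_ac)])
        nac = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.arange(n_ac, dtype=np.int64)])
        duct_vol = np.zeros(n_ac)
    else:
        ne_ac = edges_per_airway(
            model.lengths,
            acinar_max_edge_len if acinar_max_edge_len is not None
            else max_edge_len,
            acinar_min_edges)
        k_per = int(ne_ac.sum())         # nodes per acinus
        gen_of = np.repeat(np.arange(model.n_generations), ne_ac)
        h_of = np.repeat(model.lengths / ne_ac, ne_ac)
        area_of = np.repeat(model.duct_area, ne_ac)      # unscaled
        rad_of = np.repeat(model.radii, ne_ac)
        # sleeve weight per node: generation weight split over its nodes
        w_of = np.repeat(model.sleeve_fraction / ne_ac, ne_ac)
        # sleeve fraction at-or-distal-to each node's edge
        distal_of = w_of[::-1].cumsum()[::-1]

        n_total = n_cond + n_ac * k_per
        local = np.arange(k_per)
        pn_local = local - 1  # chains; first node fixed below
        pn_block = (n_cond + (np.arange(n_ac)[:, None] * k_per
                              + pn_local[None, :]))
        pn_block[:, 0] = term_nodes
        pn = np.concatenate([parent_node, pn_block.ravel()])
        eh = np.concatenate([edge_h, np.tile(h_of, n_ac)])
        ea = np.concatenate([edge_area,
                             (scale[:, None] * area_of[None, :]).ravel()])
        er = np.concatenate([edge_radius, np.tile(rad_of, n_ac)])
        eaw = np.concatenate([edge_airway,
                              np.full(n_ac * k_per, -1, np.int64)])
        eac = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.repeat(np.arange(n_ac, dtype=np.int64),
                                        k_per)])
        eag = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.tile(gen_of, n_ac)])
        efirst = np.concatenate([edge_is_first, np.zeros(n_ac * k_per, bool)])
        ecos = np.concatenate([edge_cosphi,
                               np.full(n_ac * k_per, model.cos_incline)])
        eang = np.concatenate([edge_branch_angle, np.zeros(n_ac * k_per)])
        edist = np.concatenate([np.zeros(n_cond), np.tile(distal_of, n_ac)])
        emid = np.vstack([
            edge_midpoint,
            np.repeat(net.distal[net.acinus_terminal_airway], k_per, axis=0)])
        ev_ac = (scale[:, None] * (area_of * h_of)[None, :])
        vs_block = 0.5 * ev_ac.copy()
        vs_block[:, :-1] += 0.5 * ev_ac[:, 1:]
        # half of each acinus's first duct edge also loads the terminal
        # conducting node
        vs = np.concatenate([v_static, vs_block.ravel()])
        np.add.at(vs, term_nodes, 0.5 * ev_ac[:, 0])
        sw = np.concatenate([np.zeros(n_cond), np.tile(w_of, n_ac)])
        nac = np.concatenate([np.full(n_cond, -1, np.int64),
                              np.repeat(np.arange(n_ac, dtype=np.int64),
                                        k_per)])
        duct_vol = scale * model.duct_volume

    return DiscretizedNetwork(
        net=net, acinar_mode=acinar_mode, acinar_model=model,
        parent_node=pn, edge_h=eh, edge_area=ea, edge_radius=er,
        edge_airway=eaw, edge_acinus=eac, edge_acinar_gen=eag,
        edge_is_first=efirst, edge_cos_incline=ecos,
        edge_branch_angle=eang, edge_distal_sleeve=edist,
        edge_midpoint=emid, v_static=vs, node_sleeve_weight=sw,
        node_acinus=nac,
        airway_last_node=base + ne - 1, airway_first_node=base,
        n_conducting_nodes=n_cond, acinus_duct_volume=duct_vol,
        max_edge_len=max_edge_len, min_edges=min_edges,
    )
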