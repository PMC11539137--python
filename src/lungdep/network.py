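"""Airway-tree networks: the simulator's central data structure.

An :class:`AirwayNetwork` is a bifurcating tree of conducting airways
(rigid tubes, each with a length, radius and 3-D position; gravity acts
along -z) plus one acinus attached to every terminal airway. Generations
are counted from the trachea = generation 1, incrementing at each
bifurcation. Central conducting airways are those with generation < 10,
the rest are distal.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import units

#: the five lobes; ``TR`` labels pre-lobar airways (trachea and main bronchi)
LOBES = ("RU", "RM", "RL", "LU", "LL")
PRELOBAR = "TR"

CENTRAL_MAX_GENERATION = 9  # generation < 10 is central

NETWORK_COLUMNS = [
    "id", "parent_id", "generation", "length_m", "radius_m",
    "x0", "y0", "z0", "x1", "y1", "z1", "lobe", "acinus_id",
]


@dataclass
class Airway:
    """Single-airway view (a row of the network arrays)."""

    id: int
    parent_id: Optional[int]
    generation: int
    length: float
    radius: float
    proximal_xyz: np.ndarray
    distal_xyz: np.ndarray
    lobe: str
    acinus_id: Optional[int]


class AirwayNetwork:
    """Bifurcating conducting-airway tree with attached acini.

    Arrays are positionally indexed; ``parent_index`` holds positional
    indices (-1 for the trachea). ``acinus_index`` maps terminal airways to
    positions in the acinus arrays (-1 otherwise).
    """

    def __init__(self, *, ids, parent_index, generation, length, radius,
                 proximal, distal, lobe, acinus_index,
                 frc, acinus_V0=None, acinus_E=None, acinus_eta=None,
                 validate=True):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.parent_index = np.asarray(parent_index, dtype=np.int64)
        self.generation = np.asarray(generation, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.radius = np.asarray(radius, dtype=float)
        self.proximal = np.asarray(proximal, dtype=float).reshape(-1, 3)
        self.distal = np.asarray(distal, dtype=float).reshape(-1, 3)
        self.lobe = np.asarray(lobe, dtype=object)
        self.acinus_index = np.asarray(acinus_index, dtype=np.int64)
        self.frc = float(frc)  # m3

        n_acini = int(np.sum(self.acinus_index >= 0))
        if acinus_V0 is None:
            acinus_V0 = np.full(n_acini, np.nan)
        self.acinus_V0 = np.asarray(acinus_V0, dtype=float)   # m3
        if acinus_E is None:
            acinus_E = np.full(n_acini, np.nan)
        self.acinus_E = np.asarray(acinus_E, dtype=float)     # Pa / m3
        if acinus_eta is None:
            acinus_eta = np.zeros(n_acini)
        self.acinus_eta = np.asarray(acinus_eta, dtype=float)  # Pa s / m3

        # terminal airway position for each acinus
        order = np.argsort(self.acinus_index[self.acinus_index >= 0])
        self.acinus_terminal_airway = np.flatnonzero(
            self.acinus_index >= 0)[order]

        if validate:
            self.validate()

    # ------------------------------------------------------------------
    @property
    def n_airways(self) -> int:
        return self.ids.size

    @property
    def n_acini(self) -> int:
        return self.acinus_terminal_airway.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent_index < 0)[0])

    @property
    def is_terminal(self) -> np.ndarray:
        return self.acinus_index >= 0

    @property
    def dead_space(self) -> float:
        """Total conducting-airway volume sum(pi r^2 L), m3."""
        return float(np.sum(np.pi * self.radius**2 * self.length))

    @property
    def airway_volume(self) -> np.ndarray:
        return np.pi * self.radius**2 * self.length

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_airways)]
        for i, p in enumerate(self.parent_index):
            if p >= 0:
                ch[p].append(i)
        return ch

    def topological_order(self) -> np.ndarray:
        """Airway indices ordered root-first (parents before children)."""
        return np.argsort(self.generation, kind="stable")

    def airway(self, index: int) -> Airway:
        p = int(self.parent_index[index])
        a = int(self.acinus_index[index])
        return Airway(
            id=int(self.ids[index]),
            parent_id=int(self.ids[p]) if p >= 0 else None,
            generation=int(self.generation[index]),
            length=float(self.length[index]),
            radius=float(self.radius[index]),
            proximal_xyz=self.proximal[index].copy(),
            distal_xyz=self.distal[index].copy(),
            lobe=str(self.lobe[index]),
            acinus_id=a if a >= 0 else None,
        )

    def copy(self) -> "AirwayNetwork":
        return AirwayNetwork(
            ids=self.ids.copy(), parent_index=self.parent_index.copy(),
            generation=self.generation.copy(), length=self.length.copy(),
            radius=self.radius.copy(), proximal=self.proximal.copy(),
            distal=self.distal.copy(), lobe=self.lobe.copy(),
            acinus_index=self.acinus_index.copy(), frc=self.frc,
            acinus_V0=self.acinus_V0.copy(), acinus_E=self.acinus_E.copy(),
            acinus_eta=self.acinus_eta.copy(), validate=False,
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check tree topology and geometric invariants."""
        n = self.n_airways
        roots = np.flatnonzero(self.parent_index < 0)
        if roots.size == 0:
            raise ValueError("network has no root (trachea)")
        if roots.size > 1:
            raise ValueError(
                "network has multiple roots: airway ids "
                f"{self.ids[roots].tolist()}")
        if np.any(self.parent_index >= n):
            bad = self.ids[self.parent_index >= n]
            raise ValueError(f"airways with out-of-range parents: {bad.tolist()}")
        if np.any(self.length <= 0) or np.any(self.radius <= 0):
            bad = self.ids[(self.length <= 0) | (self.radius <= 0)]
            raise ValueError(
                f"non-positive length/radius on airways {bad.tolist()}")
        # generation bookkeeping + cycle check via parent walk counts
        p = self.parent_index
        gen_ok = np.ones(n, dtype=bool)
        gen_ok[p >= 0] = (
            self.generation[p >= 0] == self.generation[p[p >= 0]] + 1)
        if not np.all(gen_ok):
            raise ValueError(
                "generation must equal parent generation + 1 for airways "
                f"{self.ids[~gen_ok].tolist()}")
        if int(self.generation[roots[0]]) != 1:
            raise ValueError("trachea must be generation 1")
        # generation+parent consistency excludes cycles; still verify
        # connectivity by depth walk
        depth = self.generation - 1
        if np.any(depth < 0):
            raise ValueError("generations must be >= 1")
        # acinus attachment
        ch_count = np.bincount(p[p >= 0], minlength=n)
        terminal = ch_count == 0
        bad = terminal & (self.acinus_index < 0)
        if np.any(bad):
            raise ValueError(
                f"terminal airways without an acinus: {self.ids[bad].tolist()}")
        bad = (~terminal) & (self.acinus_index >= 0)
        if np.any(bad):
            raise ValueError(
                f"non-terminal airways with an acinus: {self.ids[bad].tolist()}")
        if self.frc <= 0:
            raise ValueError("FRC must be positive")

    # ------------------------------------------------------------------
    def subtended_acinus_count(self) -> np.ndarray:
        """Number of acini fed through each airway."""
        count = np.where(self.is_terminal, 1, 0).astype(np.int64)
        order = self.topological_order()
        for i in order[::-1]:
            p = self.parent_index[i]
            if p >= 0:
                count[p] += count[i]
        return count

    def to_frame(self) -> pd.DataFrame:
        parent_id = np.where(
            self.parent_index >= 0,
            self.ids[np.clip(self.parent_index, 0, None)], -1)
        acinus_id = np.where(self.acinus_index >= 0, self.acinus_index, -1)
        return pd.DataFrame({
            "id": self.ids,
            "parent_id": parent_id,
            "generation": self.generation,
            "length_m": self.length,
            "radius_m": self.radius,
            "x0": self.proximal[:, 0], "y0": self.proximal[:, 1],
            "z0": self.proximal[:, 2],
            "x1": self.distal[:, 0], "y1": self.distal[:, 1],
            "z1": self.distal[:, 2],
            "lobe": self.lobe,
            "acinus_id": acinus_id,
        })


# ----------------------------------------------------------------------
def classify_airways(net: AirwayNetwork) -> np.ndarray:
    """Label every airway ``central`` (generation < 10) or ``distal``."""
    return np.where(net.generation <= CENTRAL_MAX_GENERATION,
                    "central", "distal")


def rescale_to_frc(net: AirwayNetwork, target_frc_l: float) -> AirwayNetwork:
    """Isotropically rescale a network to a target FRC (litres).

    Every airway length, radius and coordinate is multiplied by
    ``(target_FRC / FRC)^(1/3)``; the dead space and acinar volumes scale by
    the cube of that factor.
    """
    if target_frc_l <= 0:
        raise ValueError("target FRC must be positive")
    target = target_frc_l * units.M3_PER_L
    factor = (target / net.frc) ** (1.0 / 3.0)
    out = net.copy()
    out.length *= factor
    out.radius *= factor
    out.proximal *= factor
    out.distal *= factor
    out.frc = target
    out.acinus_V0 = net.acinus_V0 * factor**3
    # elastance scales inversely with volume (same pressure swing over
    # a volume excursion that scales with lung size)
    with np.errstate(invalid="ignore"):
        out.acinus_E = net.acinus_E / factor**3
        out.acinus_eta = net.acinus_eta / factor**3
    return out


def attach_default_acini(net: AirwayNetwork,
                         e_total_cmh2o_per_l: float = 6.82,
                         eta_cmh2o_s_per_l: float = 0.0) -> None:
    """Give every acinus the same V0 (equal split of FRC minus dead space)
    and elastance consistent with a total lung elastance (cmH2O/l)."""
    n = net.n_acini
    if n == 0:
        raise ValueError("network has no acini")
    v0 = (net.frc - net.dead_space) / n
    if v0 <= 0:
        raise ValueError("dead space exceeds FRC; cannot assign acinar V0")
    net.acinus_V0 = np.full(n, v0)
    e_tot_si = units.elastance_cmh2o_per_l_to_si(e_total_cmh2o_per_l)
    net.acinus_E = np.full(n, n * e_tot_si)
    net.acinus_eta = np.full(
        n, n * eta_cmh2o_s_per_l * units.PA_PER_CMH2O / units.M3_PER_L)


# ----------------------------------------------------------------------
# tabular I/O (comma-separated, header row, SI units)

def write_network(path, net: AirwayNetwork) -> None:
    """Write a network to the documented CSV dialect.

    The FRC is carried in a ``# frc_m3=...`` comment line so that
    write-then-read is the identity.
    """
    frame = net.to_frame()
    with open(path, "w") as fh:
        fh.write(f"# frc_m3={net.frc!r}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_network(path, frc_l: Optional[float] = None,
                 e_total_cmh2o_per_l: float = 6.82) -> AirwayNetwork:
    """Read a network from the CSV dialect written by :func:`write_network`.

    Missing columns, duplicate roots, orphan airways and cyclic topology are
    reported with the offending airway ids. Acinar mechanics are
    reconstructed from the stored FRC (or ``frc_l``) and ``e_total``.
    """
    frc_m3 = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "frc_m3=" in first:
                frc_m3 = float(first.split("frc_m3=")[1])
            text = fh.read()
        else:
            text = first + fh.read()
    frame = pd.read_csv(io.StringIO(text))
    missing = [c for c in NETWORK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"network file missing columns: {missing}")
    if frc_l is not None:
        frc_m3 = frc_l * units.M3_PER_L
    if frc_m3 is None:
        raise ValueError("network file has no FRC metadata; pass frc_l")

    ids = frame["id"].to_numpy(np.int64)
    if np.unique(ids).size != ids.size:
        raise ValueError("duplicate airway ids in network file")
    pos = {int(i): k for k, i in enumerate(ids)}
    parent_raw = frame["parent_id"].to_numpy()
    parent_index = np.empty(ids.size, dtype=np.int64)
    orphans = []
    for k, praw in enumerate(parent_raw):
        if pd.isna(praw) or int(praw) < 0:
            parent_index[k] = -1
        else:
            p = pos.get(int(praw))
            if p is None:
                orphans.append(int(ids[k]))
                parent_index[k] = -1
            else:
                parent_index[k] = p
    if orphans:
        raise ValueError(
            f"airways referencing absent parents: {orphans}")

    acinus_raw = frame["acinus_id"].to_numpy()
    acinus_index = np.where(pd.isna(acinus_raw), -1,
                            np.nan_to_num(acinus_raw, nan=-1)).astype(np.int64)

    net = AirwayNetwork(
        ids=ids, parent_index=parent_index,
        generation=frame["generation"].to_numpy(np.int64),
        length=frame["length_m"].to_numpy(float),
        radius=frame["radius_m"].to_numpy(float),
        proximal=frame[["x0", "y0", "z0"]].to_numpy(float),
        distal=frame[["x1", "y1", "z1"]].to_numpy(float),
        lobe=frame["lobe"].to_numpy(object),
        acinus_index=acinus_index,
        frc=frc_m3,
    )
    attach_default_acini(net, e_total_cmh2o_per_l)
    return net
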