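"""Distal-airway constriction patterns representative of CF disease.

All patterns target generation 12-15 conducting airways and apply one
shared severity sigma in [0, 1): the fraction by which targeted radii are
reduced (Poiseuille resistance grows by (1 - sigma)^-4). Three pattern
families are provided: every generation 12-15 airway of one lobe, spatial
clusters grown around randomly chosen generation-12 seed airways, and a
uniform random sample of generation-12 airways; cluster and random
patterns always include the targeted airways' descendants down to
generation 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .network import AirwayNetwork

TARGET_GENERATIONS = (12, 15)
MAX_PLACEMENT_ATTEMPTS = 500


@dataclass
class ConstrictionPattern:
    """A set of airway indices constricted with one severity."""

    airway_index: np.ndarray   # positional indices into the network
    severity: float
    descriptor: str            # lobar | clustered | random
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.severity < 1.0:
            raise ValueError("severity must lie in [0, 1)")
        self.airway_index = np.unique(
            np.asarray(self.airway_index, dtype=np.int64))

    @property
    def airway_ids(self) -> np.ndarray:
        return self.airway_index

    def __len__(self) -> int:
        return self.airway_index.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"airway_id": self.airway_index,
                             "severity": self.severity})


def _check_target_generations(net: AirwayNetwork, idx: np.ndarray) -> None:
    g = net.generation[idx]
    lo, hi = TARGET_GENERATIONS
    if idx.size and (g.min() < lo or g.max() > hi):
        raise ValueError("constriction targets must be generation 12-15")


def _descendants_to_gen15(net: AirwayNetwork,
                          roots: np.ndarray) -> np.ndarray:
    """Roots plus all descendants with generation <= 15."""
    children = net.children()
    out = set(int(i) for i in roots)
    stack = list(roots)
    hi = TARGET_GENERATIONS[1]
    while stack:
        i = stack.pop()
        for c in children[int(i)]:
            if net.generation[c] <= hi:
                out.add(c)
                stack.append(c)
    return np.asarray(sorted(out), dtype=np.int64)


def lobar_pattern(net: AirwayNetwork, lobe: str,
                  severity: float) -> ConstrictionPattern:
    """Constrict every generation 12-15 airway of one lobe."""
    in_lobe = net.lobe == lobe
    if not np.any(in_lobe):
        raise ValueError(f"lobe {lobe!r} not present in network")
    lo, hi = TARGET_GENERATIONS
    idx = np.flatnonzero(in_lobe & (net.generation >= lo)
                         & (net.generation <= hi))
    return ConstrictionPattern(idx, severity, "lobar", {"lobe": lobe})


def clustered_pattern(net: AirwayNetwork, n_clusters: int,
                      cluster_radius: float, severity: float, *,
                      seed: int,
                      restrict_lobes: Optional[Sequence[str]] = None,
                      ) -> ConstrictionPattern:
    """Constrict clusters of generation-12 airways and their descendants.

    ``n_clusters`` generation-12 seed airways are drawn at random; every
    generation-12 airway whose distal end lies within ``cluster_radius``
    (metres) of a seed's joins that seed's cluster, and all descendants
    down to generation 15 are added. No two clusters may share a
    generation-12 airway; offending seeds are re-drawn (bounded attempts).
    """
    rng = np.random.default_rng(seed)
    g12 = np.flatnonzero(net.generation == TARGET_GENERATIONS[0])
    if restrict_lobes is not None:
        g12 = g12[np.isin(net.lobe[g12], list(restrict_lobes))]
    if g12.size < n_clusters:
        raise ValueError(
            f"only {g12.size} candidate generation-12 airways for "
            f"{n_clusters} clusters")
    pos = net.distal[g12]

    def members_of(seed_pos):
        return np.linalg.norm(pos - seed_pos, axis=1) <= cluster_radius

    chosen: list[int] = []          # indices into g12
    member_sets: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n_clusters:
        cand = int(rng.integers(g12.size))
        attempts += 1
        if attempts > MAX_PLACEMENT_ATTEMPTS * n_clusters:
            raise RuntimeError(
                "could not place non-overlapping clusters within the "
                "attempt budget; reduce n_clusters or cluster_radius")
        if cand in chosen:
            continue
        mem = members_of(pos[cand])
        if any(np.any(mem & m) for m in member_sets):
            continue
        chosen.append(cand)
        member_sets.append(mem)

    members = np.zeros(g12.size, dtype=bool)
    for m in member_sets:
        members |= m
    idx = _descendants_to_gen15(net, g12[members])
    _check_target_generations(net, idx)
    return ConstrictionPattern(
        idx, severity, "clustered",
        {"n_clusters": n_clusters, "cluster_radius": cluster_radius,
         "seed": seed, "seeds": g12[np.asarray(chosen)].tolist(),
         "restrict_lobes": list(restrict_lobes) if restrict_lobes else None})


def random_pattern(net: AirwayNetwork, count: int, severity: float, *,
                   seed: int) -> ConstrictionPattern:
    """Constrict ``count`` uniformly sampled generation-12 airways and
    their descendants down to generation 15."""
    g12 = np.flatnonzero(net.generation == TARGET_GENERATIONS[0])
    if count > g12.size:
        raise ValueError(
            f"requested {count} airways but only {g12.size} at "
            f"generation {TARGET_GENERATIONS[0]}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(g12, size=count, replace=False)
    idx = _descendants_to_gen15(net, pick)
    _check_target_generations(net, idx)
    return ConstrictionPattern(idx, severity, "random",
                               {"count": count, "seed": seed})


def apply(net: AirwayNetwork,
          pattern: ConstrictionPattern) -> AirwayNetwork:
    """Return a copy of the network with targeted radii reduced by the
    pattern severity; lengths, topology and acini are untouched."""
    if not 0.0 <= pattern.severity < 1.0:
        raise ValueError("severity must lie in [0, 1)")
    out = net.copy()
    out.radius[pattern.airway_index] *= (1.0 - pattern.severity)
    return out
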