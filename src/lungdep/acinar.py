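"""Intra-acinar symmetric-tree model.

Each acinus is a symmetric bifurcating tree of alveolated ducts. Because
the tree is symmetric, all ducts of one intra-acinar generation behave
identically, so the whole acinus is represented by a single path of
generations with a multiplicity (2^k ducts at generation k) carried in the
cross-sectional area and volumes. Each generation has a duct of fixed
radius plus an alveolar sleeve whose volume follows the acinus volume from
the ventilation solution; the sleeve is treated as radially well mixed
with its duct.

Duct dimensions and the distal-weighted volume distribution are
literature-typical adult acinar morphometry (transitional bronchiole
through alveolar sacs); the alveolar volume fraction rises steeply towards
the terminal generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcinarModel:
    """Representative-path description of a symmetric acinar tree."""

    #: duct length per intra-acinar generation, m
    lengths: np.ndarray = field(default_factory=lambda: np.array(
        [1.40, 1.33, 1.12, 0.93, 0.83, 0.70, 0.70, 0.70, 0.70]) * 1e-3)
    #: duct radius per generation, m
    radii: np.ndarray = field(default_factory=lambda: np.array(
        [0.250, 0.245, 0.200, 0.190, 0.180, 0.170, 0.155, 0.145, 0.125])
        * 1e-3)
    #: per-generation alveolarization factor (relative sleeve volume per
    #: unit duct volume); most alveolar volume sits in the terminal sacs
    alveolar_factor: np.ndarray = field(default_factory=lambda: np.array(
        [0.15, 0.30, 0.50, 0.80, 1.20, 1.80, 2.50, 3.50, 5.00]))
    #: reference acinus volume at FRC used to scale duct areas, m3
    reference_volume: float = 1.06e-7
    #: effective cosine of duct inclination to the horizontal (mean over
    #: isotropic orientations, pi/4)
    cos_incline: float = np.pi / 4.0

    @property
    def n_generations(self) -> int:
        return self.lengths.size

    @property
    def multiplicity(self) -> np.ndarray:
        return 2.0 ** np.arange(self.n_generations)

    @property
    def duct_area(self) -> np.ndarray:
        """Summed duct cross-section per generation (unscaled), m2."""
        return self.multiplicity * np.pi * self.radii**2

    @property
    def duct_volume(self) -> float:
        """Total duct volume of the reference acinus, m3."""
        return float(np.sum(self.duct_area * self.lengths))

    @property
    def sleeve_fraction(self) -> np.ndarray:
        """Fraction of the acinus's alveolar (sleeve) volume per
        generation; sums to one."""
        w = self.duct_area * self.lengths * self.alveolar_factor
        return w / w.sum()

    def scale_for(self, v0: np.ndarray) -> np.ndarray:
        """Area/volume scale factor for acini of FRC volume ``v0`` (m3)."""
        return np.asarray(v0, dtype=float) / self.reference_volume
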