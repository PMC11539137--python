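"""Visual summaries: simulated gamma scintigraphy and planar-graph maps.

Scintigraphy is simulated by summing deposition into coronal (x, z)
pixels across the whole depth (y) of the lungs and smoothing the binned
image with a Gaussian kernel (a kernel-density estimate of the deposition
distribution). The raw pixel sum equals total lung deposition exactly;
only the smoothed field is for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .layout import PlanarLayout
from .transport import DepositionResult

DEFAULT_PIXEL = 5e-3       # m
DEFAULT_BANDWIDTH = 8e-3   # m


@dataclass
class ScintigraphyImage:
    """Coronal-projection deposition image."""

    raw: np.ndarray        # (nx, nz) summed deposition per pixel
    smoothed: np.ndarray   # kernel-density-estimated intensity
    x_edges: np.ndarray
    z_edges: np.ndarray
    pixel_size: float
    bandwidth: float

    @property
    def total(self) -> float:
        return float(self.raw.sum())

    def to_frame(self):
        import pandas as pd

        xs = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        zs = 0.5 * (self.z_edges[:-1] + self.z_edges[1:])
        xx, zz = np.meshgrid(xs, zs, indexing="ij")
        return pd.DataFrame({"x_m": xx.ravel(), "z_m": zz.ravel(),
                             "raw": self.raw.ravel(),
                             "smoothed": self.smoothed.ravel()})


def project_scintigraphy(result: DepositionResult,
                         pixel_size: float = DEFAULT_PIXEL,
                         bandwidth: float = DEFAULT_BANDWIDTH,
                         extent: Optional[tuple] = None,
                         ) -> ScintigraphyImage:
    """Project per-edge deposition onto the coronal (x, z) plane.

    ``extent`` is ((xmin, xmax), (zmin, zmax)); by default it is the
    network bounding box padded by two pixels.
    """
    from scipy.ndimage import gaussian_filter

    mid = result.disc.edge_midpoint
    w = result.per_edge
    x, z = mid[:, 0], mid[:, 2]
    if extent is None:
        pad = 2 * pixel_size
        extent = ((x.min() - pad, x.max() + pad),
                  (z.min() - pad, z.max() + pad))
    (x0, x1), (z0, z1) = extent
    nx = max(int(np.ceil((x1 - x0) / pixel_size)), 1)
    nz = max(int(np.ceil((z1 - z0) / pixel_size)), 1)
    if nx <= 0 or nz <= 0:
        raise ValueError("empty scintigraphy grid")
    x_edges = x0 + np.arange(nx + 1) * pixel_size
    z_edges = z0 + np.arange(nz + 1) * pixel_size
    raw, _, _ = np.histogram2d(x, z, bins=[x_edges, z_edges], weights=w)
    sigma = bandwidth / pixel_size
    smoothed = gaussian_filter(raw, sigma=sigma, mode="constant")
    return ScintigraphyImage(raw=raw, smoothed=smoothed,
                             x_edges=x_edges, z_edges=z_edges,
                             pixel_size=pixel_size, bandwidth=bandwidth)


def change_map(baseline: DepositionResult,
               perturbed: DepositionResult) -> np.ndarray:
    """Per-airway fractional deposition change (perturbed - baseline) /
    baseline. Airways with zero baseline deposition are flagged NaN
    rather than divided."""
    if baseline.net.n_airways != perturbed.net.n_airways or \
            not np.array_equal(baseline.net.ids, perturbed.net.ids):
        raise ValueError("deposition results are from different networks")
    b = baseline.per_airway() / baseline.inhaled
    p = perturbed.per_airway() / perturbed.inhaled
    out = np.full(b.shape, np.nan)
    ok = b > 0
    out[ok] = (p[ok] - b[ok]) / b[ok]
    return out


def render_planar(values: np.ndarray, layout: PlanarLayout, net,
                  ax=None, cmap: str = "viridis", vmin=None, vmax=None,
                  linewidth: float = 0.6):
    """Draw per-airway values on the planar-graph layout.

    Each airway is a radial segment from its parent's distal position to
    its own, coloured by ``values``. Returns the matplotlib axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    xy = layout.xy
    p = net.parent_index
    start = np.where((p >= 0)[:, None], xy[np.maximum(p, 0)], 0.0)
    segs = np.stack([start, xy], axis=1)
    vals = np.asarray(values, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    lc = LineCollection(segs, cmap=cmap, linewidths=linewidth)
    lc.set_array(vals)
    if vmin is not None or vmax is not None:
        lc.set_clim(vmin, vmax)
    ax.add_collection(lc)
    lim = layout.radius.max() * 1.05 + layout.R0
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax
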