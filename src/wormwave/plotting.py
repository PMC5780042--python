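"""Plotting helpers for kymograms and entrainment maps (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .kinematics import CurvatureMap
from .spectral import EntrainmentMap


def plot_kymogram(cmap: CurvatureMap, ax=None, vlim: float | None = None):
    """Render a curvature map with time on the y axis, head at the left.

    Blue/red encode the two bending directions (the dorso-ventral
    assignment of tracked data is arbitrary).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    if vlim is None:
        vlim = float(np.percentile(np.abs(cmap.values), 99)) or 1.0
    im = ax.imshow(
        cmap.values,
        aspect="auto",
        origin="upper",
        cmap="RdBu",
        vmin=-vlim,
        vmax=vlim,
        extent=[cmap.body_coords[0], cmap.body_coords[-1],
                cmap.times[-1], cmap.times[0]],
    )
    ax.set_xlabel("body coordinate (head = 0, tail = 100)")
    ax.set_ylabel("time (s)")
    ax.figure.colorbar(im, ax=ax, label=r"curvature $\kappa \cdot L$")
    return ax


def plot_entrainment_map(emap: EntrainmentMap, ax=None, band=(0.0, 2.5)):
    """Heat map of response spectra vs imposed pulse frequency, with the
    y = x and y = x/2 locking guides overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sel = (emap.response_freqs >= band[0]) & (emap.response_freqs <= band[1])
    im = ax.pcolormesh(
        emap.imposed_freqs,
        emap.response_freqs[sel],
        emap.power[:, sel].T,
        shading="auto",
        cmap="magma",
    )
    x = emap.imposed_freqs
    ax.plot(x, x, "w--", lw=0.8, label="1:1")
    ax.plot(x, x / 2, "w:", lw=0.8, label="2:1")
    ax.set_xlabel("imposed pulse frequency (Hz)")
    ax.set_ylabel("response frequency (Hz)")
    ax.set_ylim(band)
    ax.legend(loc="upper left", frameon=False)
    ax.figure.colorbar(im, ax=ax, label="mean spectral amplitude (1/s)")
    return ax
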