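"""Polar plots of grid-orientation coherence and cross-run stability.

Orientations live in [0, 360/fold) degrees; for display they are mapped
onto the full circle by multiplying by the fold, the convention used in
grid-code polar histograms.
"""

from __future__ import annotations

import numpy as np

from .design import check_fold

__all__ = ["polar_orientation_histogram", "stability_rings"]


def polar_orientation_histogram(phis, fold: int = 6, n_bins: int = 36,
                                mean_phi: float | None = None, ax=None):
    """Polar histogram of voxel orientations, with optional mean-phi arrow."""
    import matplotlib.pyplot as plt

    fold = check_fold(fold)
    phis = np.asarray(phis, dtype=float)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    theta = np.deg2rad(phis * fold)
    counts, edges = np.histogram(np.mod(theta, 2 * np.pi), bins=n_bins,
                                 range=(0, 2 * np.pi))
    centers = (edges[:-1] + edges[1:]) / 2
    ax.bar(centers, counts, width=2 * np.pi / n_bins, alpha=0.7,
           edgecolor="black", linewidth=0.5)
    if mean_phi is not None:
        ax.annotate("", xy=(np.deg2rad(mean_phi * fold), counts.max() or 1),
                    xytext=(0, 0), arrowprops=dict(color="red", width=1.5))
    ax.set_title(f"voxel grid orientations (x{fold})")
    return ax


def stability_rings(phi_a, phi_b, fold: int = 6, threshold: float = 15.0, ax=None):
    """Two-ring polar plot connecting each voxel's orientation across runs.

    Inner ring: first map; outer ring: second map. Stable voxels (circular
    distance <= threshold) are drawn green, unstable red-dotted.
    """
    import matplotlib.pyplot as plt

    from .stability import circular_distance

    fold = check_fold(fold)
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    r_in, r_out = 1.0, 1.5
    delta = circular_distance(phi_a, phi_b, fold)
    for a, b, d in zip(phi_a, phi_b, delta):
        stable = d <= threshold
        ax.plot([np.deg2rad(a * fold), np.deg2rad(b * fold)], [r_in, r_out],
                color="green" if stable else "red",
                linestyle="-" if stable else ":", linewidth=0.8)
        ax.plot(np.deg2rad(a * fold), r_in, "o", color="k", markersize=2)
        ax.plot(np.deg2rad(b * fold), r_out, "o", color="k", markersize=2)
    ax.set_yticks([])
    ax.set_ylim(0, r_out + 0.2)
    ax.set_title(f"within-voxel stability (+/-{threshold:.0f} deg)")
    return ax
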