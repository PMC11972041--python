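"""Quick-look plots for depth profiles and voxel difference maps.

CT underlays are out of scope; these are diagnostic views of the package's
own outputs.
"""

from __future__ import annotations

import numpy as np

from .compare import DepthProfile, DifferenceMap


def plot_depth_profiles(p_ref: DepthProfile, p_test: DepthProfile, ax=None):
    """Overlay two depth-fragment distributions and shade the z regions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (p_ref.bin_edges[:-1] + p_ref.bin_edges[1:])
    ax.step(centers, p_ref.counts, where="mid", label="reference")
    ax.step(centers, p_test.counts, where="mid", label="test")
    colors = iter(["tab:blue", "tab:red", "tab:gray", "tab:green"])
    for name, (z0, z1) in p_ref.regions.items():
        ax.axvspan(z0, z1, alpha=0.15, color=next(colors, "tab:gray"), label=name)
    ax.set_xlabel("z along beam axis [mm]")
    ax.set_ylabel(f"fragment vertices / {p_ref.bin_size:g} mm")
    ax.legend(fontsize="small")
    return ax


def plot_difference_slice(dmap: DifferenceMap, iy: int | None = None, ax=None):
    """Axial (x-z) slice of the voxel difference map; significant voxels marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if iy is None:
        iy = dmap.grid.shape[1] // 2
    delta = np.where(dmap.eligible[:, iy, :], dmap.delta[:, iy, :], np.nan)
    ox, _, oz = dmap.grid.origin
    dx, _, dz = dmap.grid.voxel_size
    nx, _, nz = dmap.grid.shape
    vmax = np.nanmax(np.abs(delta)) if np.isfinite(delta).any() else 1.0
    im = ax.imshow(
        delta,
        origin="lower",
        aspect="auto",
        extent=(oz, oz + nz * dz, ox, ox + nx * dx),
        cmap="coolwarm",
        vmin=-vmax,
        vmax=vmax,
    )
    sig = np.argwhere(dmap.significant[:, iy, :])
    if len(sig):
        ax.plot(
            oz + (sig[:, 1] + 0.5) * dz,
            ox + (sig[:, 0] + 0.5) * dx,
            "k*",
            ms=8,
            label="significant",
        )
        ax.legend(fontsize="small")
    ax.set_xlabel("z along beam axis [mm]")
    ax.set_ylabel("x [mm]")
    plt.colorbar(im, ax=ax, label="N2 - N1 per voxel")
    return ax
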