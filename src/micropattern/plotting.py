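"""Figure-style plots: radial profile line charts, density-colored
coexpression scatters, height profiles and distance box plots.

PNG metadata is fixed so identical data yields identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coexpression import GateResult, VoxelPairs
from .morphometrics import HeightProfile
from .radial import RadialProfile

_PNG_META = {"Software": "micropattern"}


def _save(fig, path):
    path = Path(path)
    fig.savefig(path, dpi=120, metadata=_PNG_META)
    plt.close(fig)
    return path


def plot_radial_profile(profile: RadialProfile, path, title: Optional[str] = None,
                        channels: Optional[Sequence[str]] = None) -> Path:
    """Mean intensity vs distance from colony center, one line per channel."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = profile.bin_centers_um
    for ch in channels or profile.channels:
        ax.plot(x, profile.means[ch], label=ch)
    ax.set_xlabel("distance from colony center (μm)")
    ylabel = {
        "raw": "mean voxel intensity (a.u.)",
        "hoechst_relative": "intensity / Hoechst",
    }.get(profile.normalization, "relative intensity (max = 100)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return _save(fig, path)


def plot_height_profile(hp: HeightProfile, path, title: Optional[str] = None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(hp.bin_centers_um, hp.height_um)
    ax.set_xlabel("distance from colony center (μm)")
    ax.set_ylabel("colony height (μm)")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    return _save(fig, path)


def plot_density_scatter(pairs: VoxelPairs, path,
                         gate: Optional[GateResult] = None) -> Path:
    """Per-voxel paired intensities colored by local density, with gate
    thresholds and quadrant percentages overlaid when supplied."""
    fig, ax = plt.subplots(figsize=(4, 4))
    la, lb = np.log1p(pairs.a), np.log1p(pairs.b)
    ai = np.clip(np.searchsorted(pairs.a_edges, la) - 1, 0, pairs.density.shape[0] - 1)
    bi = np.clip(np.searchsorted(pairs.b_edges, lb) - 1, 0, pairs.density.shape[1] - 1)
    dens = pairs.density[ai, bi]
    order = np.argsort(dens)
    ax.scatter(la[order], lb[order], c=dens[order], s=2, cmap="viridis", rasterized=True)
    if gate is not None:
        ax.axvline(np.log1p(gate.threshold_a), color="r", lw=0.8)
        ax.axhline(np.log1p(gate.threshold_b), color="r", lw=0.8)
        xmax, ymax = float(la.max()), float(lb.max())
        gx, gy = np.log1p(gate.threshold_a), np.log1p(gate.threshold_b)
        for quad, (px, py) in {
            "--": (gx / 2, gy / 2), "+-": ((gx + xmax) / 2, gy / 2),
            "-+": (gx / 2, (gy + ymax) / 2), "++": ((gx + xmax) / 2, (gy + ymax) / 2),
        }.items():
            ax.text(px, py, f"{gate.percentages[quad]:.1f}%", color="r", fontsize=7,
                    ha="center")
    ax.set_xlabel(f"log(1 + {pairs.channel_a})")
    ax.set_ylabel(f"log(1 + {pairs.channel_b})")
    fig.tight_layout()
    return _save(fig, path)


def plot_distance_box(groups: dict, path, ylabel: str = "distance (μm)") -> Path:
    """Box plot of measurement groups (e.g. inter-nuclear distances)."""
    fig, ax = plt.subplots(figsize=(1 + len(groups), 3.2))
    labels = list(groups)
    ax.boxplot([np.asarray(groups[k]) for k in labels], tick_labels=labels)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return _save(fig, path)
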