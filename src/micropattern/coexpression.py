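"""Voxel-level two-marker coexpression analysis.

Each masked voxel contributes one paired intensity (a, b); gates are
drawn from the 0 hr reference distribution (markers absent or low at the
start of differentiation) and the four threshold-defined quadrants are
reported as percentages of total masked voxels.  Positivity is a strict
inequality, so ties at the threshold count as negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .grids import NuclearMask, VoxelGrid

QUADRANTS = ("--", "+-", "-+", "++")  # (A, B) negativity/positivity


@dataclass
class VoxelPairs:
    """Paired per-voxel intensities for two channels, with a 2D density
    histogram (log1p-scaled axes) for density-colored scatter plots."""

    channel_a: str
    channel_b: str
    a: np.ndarray
    b: np.ndarray
    density: np.ndarray
    a_edges: np.ndarray  # log1p-scale bin edges
    b_edges: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.a)


@dataclass
class GateResult:
    """Quadrant percentages of masked voxels for one channel pair."""

    channel_a: str
    channel_b: str
    threshold_a: float
    threshold_b: float
    percentages: dict = field(default_factory=dict)  # quadrant -> % of voxels
    n_voxels: int = 0
    reference: str = ""

    def __post_init__(self):
        if self.threshold_a < 0 or self.threshold_b < 0:
            raise InputError("thresholds must be >= 0")
        if self.percentages:
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 0.01:
                raise InputError(f"quadrant percentages sum to {total}, not 100")

    def to_dict(self) -> dict:
        return {
            "channel_a": self.channel_a,
            "channel_b": self.channel_b,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "percentages": dict(self.percentages),
            "n_voxels": self.n_voxels,
            "reference": self.reference,
        }


def voxel_pairs(
    grid: VoxelGrid,
    mask: NuclearMask,
    channel_a: str,
    channel_b: str,
    density_bins: int = 128,
) -> VoxelPairs:
    """One (a, b) intensity pair per masked voxel, plus a fixed-grid 2D
    histogram on log1p-scaled axes for plotting."""
    mask.check_matches(grid)
    for ch in (channel_a, channel_b):
        if not grid.has_channel(ch):
            raise InputError(f"channel {ch!r} missing from grid")
    binary = mask.binary
    a = grid.channel(channel_a)[binary].astype(np.float64)
    b = grid.channel(channel_b)[binary].astype(np.float64)
    la, lb = np.log1p(a), np.log1p(b)
    a_edges = np.linspace(0.0, max(float(la.max()), 1e-6) if la.size else 1.0, density_bins + 1)
    b_edges = np.linspace(0.0, max(float(lb.max()), 1e-6) if lb.size else 1.0, density_bins + 1)
    density, _, _ = np.histogram2d(la, lb, bins=(a_edges, b_edges))
    return VoxelPairs(channel_a, channel_b, a, b, density, a_edges, b_edges)


def gate_from_reference(
    reference_grid: VoxelGrid,
    reference_mask: NuclearMask,
    channel: str,
    quantile: float = 0.99,
) -> float:
    """Gate threshold: the given quantile of the 0 hr reference masked
    voxel intensities for the channel."""
    if not (0.0 < quantile < 1.0):
        raise InputError(f"quantile must be in (0, 1): {quantile}")
    reference_mask.check_matches(reference_grid)
    binary = reference_mask.binary
    if not binary.any():
        raise InputError("empty reference mask")
    vals = reference_grid.channel(channel)[binary]
    return float(np.quantile(vals.astype(np.float64), quantile))


def quadrant_percentages(
    pairs: VoxelPairs,
    threshold_a: float,
    threshold_b: float,
    reference: str = "",
) -> GateResult:
    """Classify each voxel pair into the four gate quadrants.

    'Positive' means strictly greater than the threshold. Percentages
    are of all pairs and sum to 100 exactly.
    """
    if pairs.n_voxels == 0:
        raise InputError("empty pair list")
    if not (np.isfinite(threshold_a) and np.isfinite(threshold_b)):
        raise InputError("thresholds must be finite")
    pos_a = pairs.a > threshold_a
    pos_b = pairs.b > threshold_b
    n = pairs.n_voxels
    counts = {
        "--": int(np.sum(~pos_a & ~pos_b)),
        "+-": int(np.sum(pos_a & ~pos_b)),
        "-+": int(np.sum(~pos_a & pos_b)),
        "++": int(np.sum(pos_a & pos_b)),
    }
    return GateResult(
        channel_a=pairs.channel_a,
        channel_b=pairs.channel_b,
        threshold_a=float(threshold_a),
        threshold_b=float(threshold_b),
        percentages={q: 100.0 * c / n for q, c in counts.items()},
        n_voxels=n,
        reference=reference,
    )
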