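"""Colony and tissue morphometrics: height vs radius, nuclear counts per
100 μm, and inter-nuclear distances.

Height is the robust z-extent of the nuclear mask per radial bin
(2.5th–97.5th percentile of z, so stray voxels cannot set the colony
height).  Linear nuclear density supports two counting conventions:
``strip`` counts centroids inside a fixed-width band around a line
segment (scales linearly with areal density), while ``transect`` counts
the distinct nearest nuclei encountered walking along the segment — the
chain of nuclei one would count by eye in a side view, which scales with
the square root of areal density for 2D packing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError
from .grids import NuclearMask
from .masking import CellRecord
from .radial import ColonyGeometry


@dataclass
class HeightProfile:
    """z-extent of the nuclear mask per radial bin, in μm."""

    bin_edges_um: np.ndarray
    height_um: np.ndarray
    colony_id: str = "colony"

    def __post_init__(self):
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.height_um = np.asarray(self.height_um, dtype=float)
        if np.any(self.height_um < 0):
            raise InputError("heights must be >= 0")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def peak_radius_um(self) -> float:
        """Bin-center radius of the height maximum."""
        return float(self.bin_centers_um[int(np.argmax(self.height_um))])


@dataclass
class DensityMeasurement:
    """Mean nuclei per 100 μm over a set of counting positions."""

    nuclei_per_100um: float
    positions_sampled: int
    context: str = "colony_sideview"  # or "epiblast_section"
    per_segment: list = field(default_factory=list)

    def __post_init__(self):
        if self.nuclei_per_100um < 0:
            raise InputError("density must be >= 0")


def height_profile(
    mask: NuclearMask,
    geometry: ColonyGeometry,
    bin_width_um: float = 10.0,
    z_percentiles: tuple[float, float] = (2.5, 97.5),
    colony_id: str = "colony",
) -> HeightProfile:
    """Colony height from center to edge.

    Per radial bin, height = (z_hi − z_lo + 1) × dz where z_lo/z_hi are
    the given percentiles of the masked voxels' z indices in that bin.
    Empty bins have height 0.
    """
    if bin_width_um <= 0:
        raise InputError("bin width must be > 0")
    dx, dy, dz = mask.voxel_spacing_um
    binary = mask.binary
    n_bins = int(np.ceil(geometry.radius_um / bin_width_um))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    heights = np.zeros(n_bins)
    if binary.any():
        cx, cy = geometry.center_um
        zc, yc, xc = np.nonzero(binary)
        r = np.hypot((xc + 0.5) * dx - cx, (yc + 0.5) * dy - cy)
        keep = r <= edges[-1]
        zc, r = zc[keep], r[keep]
        idx = np.minimum((r / bin_width_um).astype(int), n_bins - 1)
        for b in range(n_bins):
            zb = zc[idx == b]
            if zb.size:
                lo, hi = np.percentile(zb, z_percentiles)
                heights[b] = (hi - lo + 1) * dz
    return HeightProfile(edges, heights, colony_id=colony_id)


def _segment_frame(segment) -> tuple[np.ndarray, np.ndarray, float]:
    p0 = np.asarray(segment[0], dtype=float)
    p1 = np.asarray(segment[1], dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length <= 0:
        raise InputError(f"zero-length segment {segment}")
    return p0, (p1 - p0) / length, length


def nuclei_per_100um(
    cells: Sequence[CellRecord],
    segments: Sequence,
    strip_width_um: float = 12.0,
    mode: str = "strip",
    context: str = "colony_sideview",
    transect_step_um: float = 1.0,
) -> DensityMeasurement:
    """Average number of nuclei per 100 μm along counting line segments.

    ``segments`` are ``((x0, y0), (x1, y1))`` pairs in μm (xy
    projection).  In ``strip`` mode, centroids within
    ``strip_width_um / 2`` of the segment and projecting onto it are
    counted.  In ``transect`` mode, the distinct nearest centroids along
    the segment are counted (see module docstring).
    """
    if len(segments) < 1:
        raise InputError("at least one counting segment required")
    if mode not in ("strip", "transect"):
        raise InputError(f"unknown mode {mode!r}")
    xy = np.array([[c.centroid_um[0], c.centroid_um[1]] for c in cells]) \
        if cells else np.empty((0, 2))
    per_segment = []
    tree = cKDTree(xy) if len(xy) else None
    for seg in segments:
        p0, u, length = _segment_frame(seg)
        if len(xy) == 0:
            per_segment.append(0.0)
            continue
        if mode == "strip":
            rel = xy - p0
            t = rel @ u
            perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
            count = int(np.sum((t >= 0) & (t <= length) & (perp <= strip_width_um / 2)))
        else:
            ts = np.arange(0.0, length + transect_step_um / 2, transect_step_um)
            pts = p0[None, :] + ts[:, None] * u[None, :]
            _, nearest = tree.query(pts)
            count = len(np.unique(nearest))
        per_segment.append(count / length * 100.0)
    return DensityMeasurement(
        nuclei_per_100um=float(np.mean(per_segment)),
        positions_sampled=len(segments),
        context=context,
        per_segment=per_segment,
    )


def internuclear_distances(
    cells: Sequence[CellRecord],
    mode: str = "nearest_neighbor",
    pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> np.ndarray:
    """Center-to-center distances between adjacent nuclei, in μm.

    nearest_neighbor : per cell, the 3D Euclidean distance to its
        nearest other centroid.
    sampled_pairs : distances for explicitly supplied adjacent index
        pairs (emulating manual adjacent-nucleus measurements).
    """
    if len(cells) < 2:
        raise InputError("need at least 2 cells")
    pts = np.array([c.centroid_um for c in cells], dtype=float)
    if mode == "nearest_neighbor":
        d, _ = cKDTree(pts).query(pts, k=2)
        return d[:, 1]
    if mode == "sampled_pairs":
        if not pairs:
            raise InputError("sampled_pairs mode requires pairs")
        pairs_arr = np.asarray(pairs, dtype=int)
        return np.linalg.norm(pts[pairs_arr[:, 0]] - pts[pairs_arr[:, 1]], axis=1)
    raise InputError(f"unknown mode {mode!r}")
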