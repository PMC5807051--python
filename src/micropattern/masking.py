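"""Background subtraction, nuclear probability masking, centroid detection.

The probability mask stands in for an interactively trained pixel
classifier: the nuclear channel is smoothed with an anisotropic Gaussian,
thresholded automatically (Otsu), and mapped through a logistic centered
on the threshold to give a soft per-voxel nuclear probability.  The
binarized mask defines the in-colony voxel set used by every voxel-based
quantification.  Centroid detection serves only dot plots and
morphometrics — intensity quantification stays voxel-based throughout,
because dense colonies defeat reliable per-cell segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball
from skimage.transform import resize

from .errors import DegenerateImageError, InputError
from .grids import DEFAULT_NUCLEAR_CHANNEL, NuclearMask, VoxelGrid


@dataclass
class CellRecord:
    """One detected cell: centroid and per-channel mean intensity."""

    centroid_um: tuple[float, float, float]  # (x, y, z)
    intensities: dict = field(default_factory=dict)
    radius_from_center_um: Optional[float] = None

    def __post_init__(self):
        if any(v < 0 for v in self.intensities.values()):
            raise InputError("cell intensities must be >= 0")


# ---------------------------------------------------------------------------
# background subtraction


def _slice_background(img2d: np.ndarray, radius_px: float) -> np.ndarray:
    """Rolling-ball background of one slice, downscaled for large radii."""
    factor = max(1, int(radius_px // 8))
    if factor == 1:
        return rolling_ball(img2d, radius=radius_px)
    small = resize(img2d, (img2d.shape[0] // factor, img2d.shape[1] // factor),
                   order=1, anti_aliasing=True, preserve_range=True)
    bg_small = rolling_ball(small, radius=radius_px / factor)
    return resize(bg_small, img2d.shape, order=1, preserve_range=True)


def subtract_background(grid: VoxelGrid, ball_radius_um: float) -> VoxelGrid:
    """Rolling-ball background subtraction, per z-slice, per channel.

    ``ball_radius_um`` should comfortably exceed a nucleus diameter so
    nuclei are not flattened into the background. Output is clipped at 0;
    a flat background maps to ~0 everywhere.
    """
    if ball_radius_um <= 0:
        raise InputError("ball radius must be > 0")
    dx, dy, _ = grid.voxel_spacing_um
    radius_px = ball_radius_um / (0.5 * (dx + dy))
    out = np.empty_like(grid.intensities, dtype=np.float32)
    for c in range(grid.n_channels):
        for z in range(grid.spatial_shape[0]):
            img = grid.intensities[c, z].astype(float)
            out[c, z] = np.clip(img - _slice_background(img, radius_px), 0.0, None)
    return grid.with_intensities(out)


def estimate_background(grid: VoxelGrid, mask: NuclearMask) -> dict[str, float]:
    """Per-channel constant background: median intensity outside the mask."""
    mask.check_matches(grid)
    outside = ~mask.binary
    if not outside.any():
        raise InputError("mask covers the whole grid; no background voxels")
    return {
        ch: float(np.median(grid.channel(ch)[outside]))
        for ch in grid.channel_names
    }


def subtract_constant_background(grid: VoxelGrid, levels: dict[str, float]) -> VoxelGrid:
    """Subtract a per-channel constant (clipped at 0)."""
    out = grid.intensities.astype(np.float32).copy()
    for ch, level in levels.items():
        idx = grid.channel_names.index(ch)
        out[idx] = np.clip(out[idx] - float(level), 0.0, None)
    return grid.with_intensities(out)


# ---------------------------------------------------------------------------
# nuclear probability mask


def _smooth(img: np.ndarray, sigma_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    dx, dy, dz = spacing
    return ndimage.gaussian_filter(img.astype(float), sigma=(sigma_um / dz, sigma_um / dy, sigma_um / dx))


def classify_nuclei(
    grid: VoxelGrid,
    nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL,
    smooth_sigma_um: float = 1.0,
    softness: float = 0.1,
    ball_radius_um: Optional[float] = None,
    foreground_floor: float = 0.05,
) -> NuclearMask:
    """Produce the 3D nuclear probability mask from the nuclear channel.

    Pipeline: optional rolling-ball subtraction → anisotropic Gaussian
    smoothing (σ in μm, scaled per axis by voxel spacing) → Otsu
    threshold t on the smoothed channel → logistic soft assignment
    ``p = σ((I − t)/(softness·t))``.  Otsu is computed over voxels above
    ``foreground_floor`` × the smoothed maximum: colony stacks are
    mostly empty background, which would otherwise dominate the
    histogram and pull the threshold far below the nuclear boundary.
    The binarization ``p > 0.5`` is exactly ``I > t`` and is invariant
    to rescaling the nuclear channel by any k > 0.
    """
    if ball_radius_um is not None:
        grid = subtract_background(grid, ball_radius_um)
    img = grid.channel(nuclear_channel)
    smoothed = _smooth(img, smooth_sigma_um, grid.voxel_spacing_um)
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi <= 0 or hi == lo:
        raise DegenerateImageError(
            "nuclear channel is empty or uniform; no threshold definable"
        )
    fg = smoothed[smoothed > foreground_floor * hi]
    if fg.size < 2 or float(fg.min()) == float(fg.max()):
        raise DegenerateImageError("degenerate foreground; no threshold definable")
    t = float(threshold_otsu(fg))
    if t <= 0:
        raise DegenerateImageError("degenerate Otsu threshold")
    z = (smoothed - t) / (softness * t)
    prob = 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))
    return NuclearMask(prob, threshold=0.5, source="builtin",
                       voxel_spacing_um=grid.voxel_spacing_um)


# ---------------------------------------------------------------------------
# centroid detection


def _ellipsoid_footprint(radii_vox: tuple[float, float, float]) -> np.ndarray:
    half = [max(1, int(math.ceil(r))) for r in radii_vox]
    zz, yy, xx = np.mgrid[-half[0]:half[0] + 1, -half[1]:half[1] + 1, -half[2]:half[2] + 1]
    return (
        (zz / max(radii_vox[0], 1e-9)) ** 2
        + (yy / max(radii_vox[1], 1e-9)) ** 2
        + (xx / max(radii_vox[2], 1e-9)) ** 2
    ) <= 1.0


def detect_cell_centroids(
    mask: NuclearMask,
    grid: VoxelGrid,
    nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL,
    min_separation_um: float = 8.8,
    smooth_sigma_um: float = 2.0,
    measure_radius_um: float = 3.0,
) -> list[CellRecord]:
    """Detect per-cell centroids as 3D local maxima of the smoothed
    nuclear channel inside the mask.

    Maxima closer than ``min_separation_um`` are merged (the brighter
    survives). Each record carries per-channel mean intensity over an
    ellipsoidal neighborhood of ``measure_radius_um``.  An empty mask
    yields an empty list.
    """
    mask.check_matches(grid)
    binary = mask.binary
    if not binary.any():
        return []
    dx, dy, dz = grid.voxel_spacing_um
    smoothed = _smooth(grid.channel(nuclear_channel), smooth_sigma_um, grid.voxel_spacing_um)
    inside = np.where(binary, smoothed, 0.0)
    fp = _ellipsoid_footprint(
        (min_separation_um / 2 / dz, min_separation_um / 2 / dy, min_separation_um / 2 / dx)
    )
    peaks = peak_local_max(inside, footprint=fp, threshold_abs=1e-12, exclude_border=False)
    if peaks.shape[0] == 0:
        return []

    # anisotropy-aware merge in physical coordinates: keep brighter peaks
    spacing = np.array([dz, dy, dx])
    pos_um = (peaks + 0.5) * spacing  # (n, 3) in z, y, x order
    order = np.argsort(-inside[tuple(peaks.T)])
    kept: list[int] = []
    tree_pts: list[np.ndarray] = []
    for i in order:
        if tree_pts:
            d, _ = cKDTree(np.asarray(tree_pts)).query(pos_um[i])
            if d < min_separation_um:
                continue
        kept.append(i)
        tree_pts.append(pos_um[i])

    nz, ny, nx = grid.spatial_shape
    meas_fp = _ellipsoid_footprint(
        (measure_radius_um / dz, measure_radius_um / dy, measure_radius_um / dx)
    )
    offs = np.argwhere(meas_fp) - (np.array(meas_fp.shape) // 2)
    records = []
    for i in kept:
        vz, vy, vx = peaks[i]
        vox = offs + np.array([vz, vy, vx])
        ok = (
            (vox[:, 0] >= 0) & (vox[:, 0] < nz)
            & (vox[:, 1] >= 0) & (vox[:, 1] < ny)
            & (vox[:, 2] >= 0) & (vox[:, 2] < nx)
        )
        vox = vox[ok]
        intensities = {
            ch: float(grid.channel(ch)[vox[:, 0], vox[:, 1], vox[:, 2]].mean())
            for ch in grid.channel_names
        }
        records.append(CellRecord(
            centroid_um=((vx + 0.5) * dx, (vy + 0.5) * dy, (vz + 0.5) * dz),
            intensities=intensities,
        ))
    return records
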