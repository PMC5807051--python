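"""Voxel-based radial fluorescence profiling.

Every in-colony voxel is assigned its in-plane (xy) distance from the
colony center; voxels are binned into discrete radial bands and the mean
intensity per band is computed per channel and per colony, then averaged
across colonies with equal colony weight.  Profiles can be normalized to
the highest level of expression (shown as 100) within a timepoint or
across a time course, or expressed relative to the Hoechst nuclear stain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateImageError, GeometryError, InputError, NoCrossingError
from .grids import DEFAULT_NUCLEAR_CHANNEL, NuclearMask, VoxelGrid
from .masking import CellRecord

NORMALIZATIONS = ("raw", "hoechst_relative", "max100_per_timepoint", "max100_across_timecourse")


@dataclass
class ColonyGeometry:
    """Colony center and radius estimates in μm."""

    center_um: tuple[float, float]
    fitted_radius_um: float
    nominal_radius_um: Optional[float] = None

    def __post_init__(self):
        if self.fitted_radius_um <= 0:
            raise InputError("fitted radius must be > 0")
        if self.nominal_radius_um is not None:
            rel = abs(self.fitted_radius_um - self.nominal_radius_um) / self.nominal_radius_um
            if rel > 0.15:
                raise GeometryError(
                    f"fitted radius {self.fitted_radius_um:.1f} μm deviates "
                    f"{100 * rel:.0f}% from nominal {self.nominal_radius_um:.1f} μm"
                )

    @property
    def radius_um(self) -> float:
        return self.nominal_radius_um if self.nominal_radius_um is not None else self.fitted_radius_um


@dataclass
class RadialProfile:
    """Per-radial-bin mean intensities for one colony (or a colony average).

    ``means[channel]`` is NaN wherever ``n_voxels`` is 0.  ``n_colonies``
    is populated for averaged profiles and counts, per bin, the colonies
    that contributed data.
    """

    bin_edges_um: np.ndarray
    means: dict
    n_voxels: np.ndarray
    colony_id: str = "colony"
    normalization: str = "raw"
    n_colonies: Optional[np.ndarray] = None

    def __post_init__(self):
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels)
        nb = len(self.bin_edges_um) - 1
        if nb < 0 or np.any(np.diff(self.bin_edges_um) <= 0):
            raise InputError("bin edges must strictly increase")
        if len(self.n_voxels) != nb:
            raise InputError("n_voxels length must match bin count")
        for ch, m in self.means.items():
            self.means[ch] = np.asarray(m, dtype=float)
            if len(self.means[ch]) != nb:
                raise InputError(f"channel {ch!r}: wrong number of bin means")
        if self.normalization not in NORMALIZATIONS:
            raise InputError(f"unknown normalization {self.normalization!r}")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_um) - 1

    @property
    def channels(self) -> list[str]:
        return list(self.means)

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: colony_id, channel, bin_start_um, bin_end_um,
        mean_intensity, n_voxels (and n_colonies for averages)."""
        rows = []
        for ch in self.channels:
            for i in range(self.n_bins):
                row = {
                    "colony_id": self.colony_id,
                    "channel": ch,
                    "bin_start_um": self.bin_edges_um[i],
                    "bin_end_um": self.bin_edges_um[i + 1],
                    "mean_intensity": self.means[ch][i],
                    "n_voxels": int(self.n_voxels[i]),
                    "normalization": self.normalization,
                }
                if self.n_colonies is not None:
                    row["n_colonies"] = int(self.n_colonies[i])
                rows.append(row)
        columns = ["colony_id", "channel", "bin_start_um", "bin_end_um",
                   "mean_intensity", "n_voxels", "normalization"]
        if self.n_colonies is not None:
            columns.append("n_colonies")
        return pd.DataFrame(rows, columns=columns)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RadialProfile":
        if df.empty:
            raise InputError("empty profile table")
        channels = list(dict.fromkeys(df["channel"]))
        first = df[df["channel"] == channels[0]].sort_values("bin_start_um")
        edges = np.append(first["bin_start_um"].to_numpy(), first["bin_end_um"].to_numpy()[-1])
        means = {}
        for ch in channels:
            sub = df[df["channel"] == ch].sort_values("bin_start_um")
            means[ch] = sub["mean_intensity"].to_numpy(dtype=float)
        n_colonies = None
        if "n_colonies" in df.columns:
            n_colonies = first["n_colonies"].to_numpy(dtype=int)
        return cls(
            bin_edges_um=edges,
            means=means,
            n_voxels=first["n_voxels"].to_numpy(dtype=int),
            colony_id=str(df["colony_id"].iloc[0]),
            normalization=str(df["normalization"].iloc[0]) if "normalization" in df.columns else "raw",
            n_colonies=n_colonies,
        )


# ---------------------------------------------------------------------------
# center estimation


def estimate_center(mask: NuclearMask,
                    nominal_radius_um: Optional[float] = None) -> ColonyGeometry:
    """Colony center = probability-weighted centroid of the thresholded
    mask projected to xy; fitted radius encloses 99% of mask voxels."""
    binary = mask.binary
    if not binary.any():
        raise DegenerateImageError("empty mask: no in-colony voxels")
    dx, dy, dz = mask.voxel_spacing_um
    w = np.where(binary, mask.probability, 0.0).sum(axis=0)  # project to (y, x)
    total = w.sum()
    ys = (np.arange(w.shape[0]) + 0.5) * dy
    xs = (np.arange(w.shape[1]) + 0.5) * dx
    cy = float((w.sum(axis=1) * ys).sum() / total)
    cx = float((w.sum(axis=0) * xs).sum() / total)
    zc, yc, xc = np.nonzero(binary)
    r = np.hypot((xc + 0.5) * dx - cx, (yc + 0.5) * dy - cy)
    fitted = float(np.quantile(r, 0.99))
    return ColonyGeometry(center_um=(cx, cy), fitted_radius_um=fitted,
                          nominal_radius_um=nominal_radius_um)


# ---------------------------------------------------------------------------
# profiling


def radial_profile(
    grid: VoxelGrid,
    mask: NuclearMask,
    geometry: ColonyGeometry,
    bin_width_um: float = 10.0,
    colony_id: str = "colony",
) -> RadialProfile:
    """Bin masked voxels by xy-distance from the colony center.

    Bins are half-open ``[a, b)`` with the final bin closed; all z-planes
    contribute to their xy radius; voxels beyond the fitted radius are
    excluded.  Σ n_voxels over bins equals the number of masked voxels
    within the fitted radius, exactly.
    """
    mask.check_matches(grid)
    if bin_width_um <= 0:
        raise InputError("bin width must be > 0")
    cx, cy = geometry.center_um
    dx, dy, dz = grid.voxel_spacing_um
    nz, ny, nx = grid.spatial_shape
    if not (0 <= cx <= nx * dx and 0 <= cy <= ny * dy):
        raise GeometryError(f"center {geometry.center_um} outside grid")
    edge_radius = geometry.radius_um
    if bin_width_um > edge_radius:
        raise InputError(
            f"bin width {bin_width_um} μm exceeds colony radius {edge_radius} μm"
        )
    n_bins = int(math.ceil(edge_radius / bin_width_um))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um

    binary = mask.binary
    r_map = grid.xy_radius_map_um((cx, cy))
    cutoff = min(geometry.fitted_radius_um, edges[-1])
    zc, yc, xc = np.nonzero(binary)
    r = r_map[yc, xc]
    keep = r <= cutoff
    zc, yc, xc, r = zc[keep], yc[keep], xc[keep], r[keep]
    idx = np.minimum((r / bin_width_um).astype(int), n_bins - 1)
    n_vox = np.bincount(idx, minlength=n_bins)
    means = {}
    with np.errstate(invalid="ignore"):
        for ch in grid.channel_names:
            vals = grid.channel(ch)[zc, yc, xc].astype(np.float64)
            sums = np.bincount(idx, weights=vals, minlength=n_bins)
            means[ch] = np.where(n_vox > 0, sums / np.maximum(n_vox, 1), np.nan)
    return RadialProfile(edges, means, n_vox, colony_id=colony_id)


def average_profiles(profiles: Sequence[RadialProfile]) -> RadialProfile:
    """Colony-weighted average: per bin, the unweighted mean of per-colony
    means over colonies with data in that bin.  n_voxels are summed for
    bookkeeping; n_colonies counts contributors per bin."""
    if not profiles:
        raise InputError("no profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.allclose(p.bin_edges_um, ref.bin_edges_um):
            raise InputError("profiles have mismatched bin edges")
        if set(p.channels) != set(ref.channels):
            raise InputError("profiles have mismatched channels")
        if p.normalization != ref.normalization:
            raise InputError("profiles have mismatched normalization")
    valid = np.stack([p.n_voxels > 0 for p in profiles])  # (n_colonies, n_bins)
    n_colonies = valid.sum(axis=0)
    means = {}
    for ch in ref.channels:
        stack = np.stack([p.means[ch] for p in profiles])
        stack = np.where(valid, stack, np.nan)
        with np.errstate(invalid="ignore"):
            means[ch] = np.where(n_colonies > 0, np.nanmean(stack, axis=0), np.nan)
    return RadialProfile(
        bin_edges_um=ref.bin_edges_um.copy(),
        means=means,
        n_voxels=np.sum([p.n_voxels for p in profiles], axis=0),
        colony_id="average",
        normalization=ref.normalization,
        n_colonies=n_colonies,
    )


def normalize_profile(
    profile: RadialProfile,
    mode: str,
    profile_set: Optional[Sequence[RadialProfile]] = None,
    hoechst_channel: str = DEFAULT_NUCLEAR_CHANNEL,
) -> RadialProfile:
    """Normalize bin means for display.

    max100_per_timepoint : each channel scaled so its own maximum bin
        mean is 100.
    max100_across_timecourse : each channel scaled by its maximum over
        ``profile_set`` (the whole time course), so only the peak
        timepoint reaches 100.
    hoechst_relative : each channel divided, bin by bin, by the Hoechst
        channel's bin means.
    """
    if mode not in ("max100_per_timepoint", "max100_across_timecourse", "hoechst_relative"):
        raise InputError(f"unknown normalization mode {mode!r}")
    means = {ch: m.copy() for ch, m in profile.means.items()}
    if mode == "hoechst_relative":
        if hoechst_channel not in means:
            raise InputError(f"missing Hoechst channel {hoechst_channel!r}")
        hoechst = profile.means[hoechst_channel]
        populated = profile.n_voxels > 0
        if np.any(hoechst[populated] == 0):
            raise DegenerateImageError("zero Hoechst mean in a populated bin")
        for ch in means:
            means[ch] = means[ch] / hoechst
    else:
        for ch in means:
            if mode == "max100_across_timecourse":
                if profile_set is None:
                    raise InputError("across-timecourse mode needs profile_set")
                pool = list(profile_set)
                if not any(p is profile for p in pool):
                    pool.append(profile)
            else:
                pool = [profile]
            peak = np.nanmax([
                np.nanmax(p.means[ch]) if np.any(p.n_voxels > 0) else np.nan
                for p in pool
            ])
            if not np.isfinite(peak) or peak <= 0:
                raise DegenerateImageError(f"channel {ch!r}: zero maximum, cannot normalize")
            means[ch] = means[ch] * (100.0 / peak)
    return replace(profile, means=means, normalization=mode)


# ---------------------------------------------------------------------------
# dot summaries and boundary recovery


def dot_summary(cells: Sequence[CellRecord], geometry: ColonyGeometry) -> pd.DataFrame:
    """Annotate each detected cell with its radius and angle for the
    pooled 'average positional marker expression' dot display."""
    cx, cy = geometry.center_um
    rows = []
    for i, cell in enumerate(cells):
        x, y, z = cell.centroid_um
        radius = math.hypot(x - cx, y - cy)
        cell.radius_from_center_um = radius
        row = {
            "cell_id": i,
            "x_um": x, "y_um": y, "z_um": z,
            "radius_um": radius,
            "angle_rad": math.atan2(y - cy, x - cx),
        }
        row.update(cell.intensities)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["cell_id", "x_um", "y_um", "z_um", "radius_um", "angle_rad"])
    return pd.DataFrame(rows)


def recover_boundary(profile: RadialProfile, channel: str, which: str = "first") -> float:
    """Radius of the half-maximum crossing of a channel's radial profile.

    Half-maximum is the midpoint of the channel's min and max bin means;
    the crossing radius is linearly interpolated between bin centers.
    Raises :class:`NoCrossingError` on flat profiles or when no crossing
    exists.
    """
    if channel not in profile.means:
        raise InputError(f"channel {channel!r} not in profile")
    populated = profile.n_voxels > 0
    x = profile.bin_centers_um[populated]
    y = profile.means[channel][populated]
    if len(y) < 2:
        raise NoCrossingError("fewer than two populated bins")
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi == lo:
        raise NoCrossingError(f"flat profile for channel {channel!r}")
    half = 0.5 * (lo + hi)
    crossings = []
    d = y - half
    for i in range(len(y) - 1):
        if d[i] == 0.0:
            crossings.append(float(x[i]))
        elif d[i] * d[i + 1] < 0:
            frac = d[i] / (d[i] - d[i + 1])
            crossings.append(float(x[i] + frac * (x[i + 1] - x[i])))
    if d[-1] == 0.0:
        crossings.append(float(x[-1]))
    if not crossings:
        raise NoCrossingError(f"no half-maximum crossing for channel {channel!r}")
    return crossings[0] if which == "first" else crossings[-1]
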