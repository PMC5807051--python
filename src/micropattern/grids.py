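"""Core in-memory containers: multi-channel voxel grids and nuclear masks.

Conventions
-----------
Arrays are indexed ``(channel, z, y, x)``; voxel indices are 0-based and
the physical coordinate of voxel ``i`` along an axis with spacing ``d``
is its center, ``(i + 0.5) * d`` micrometres.  All downstream radius and
distance computations use these voxel-center coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import GeometryError, InputError

#: Channel name used as the nuclear (Hoechst) channel unless overridden.
DEFAULT_NUCLEAR_CHANNEL = "hoechst"


@dataclass
class VoxelGrid:
    """A multi-channel 3D fluorescence stack with physical voxel spacing.

    Parameters
    ----------
    intensities
        Non-negative float array of shape ``(n_channels, nz, ny, nx)``.
        2D section images are represented with ``nz == 1``.
    channel_names
        Unique channel labels, one per leading-axis entry.
    voxel_spacing_um
        ``(dx, dy, dz)`` spacing in micrometres, all positive.
    """

    intensities: np.ndarray
    channel_names: list[str]
    voxel_spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise GeometryError(
                f"intensities must be (channel, z, y, x); got ndim={self.intensities.ndim}"
            )
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.intensities.shape[0]:
            raise GeometryError(
                f"{len(self.channel_names)} channel names for "
                f"{self.intensities.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InputError(f"duplicate channel names: {self.channel_names}")
        self.voxel_spacing_um = tuple(float(s) for s in self.voxel_spacing_um)
        if len(self.voxel_spacing_um) != 3 or any(s <= 0 for s in self.voxel_spacing_um):
            raise GeometryError(f"spacings must be positive: {self.voxel_spacing_um}")
        if self.intensities.size and float(self.intensities.min()) < 0:
            raise InputError("negative intensities are not allowed")

    # -- basic accessors -------------------------------------------------

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx)."""
        return self.intensities.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) array for one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise InputError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.intensities[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names

    def with_intensities(self, intensities: np.ndarray) -> "VoxelGrid":
        """Copy of this grid with replaced intensity data (same geometry)."""
        return replace(self, intensities=intensities)

    # -- physical coordinates --------------------------------------------

    def axis_coords_um(self, axis: str) -> np.ndarray:
        """Voxel-center coordinates in μm along 'x', 'y' or 'z'."""
        dx, dy, dz = self.voxel_spacing_um
        nz, ny, nx = self.spatial_shape
        n, d = {"x": (nx, dx), "y": (ny, dy), "z": (nz, dz)}[axis]
        return (np.arange(n) + 0.5) * d

    def xy_radius_map_um(self, center_um: Sequence[float]) -> np.ndarray:
        """(ny, nx) map of in-plane distance from ``center_um`` = (cx, cy)."""
        cx, cy = float(center_um[0]), float(center_um[1])
        x = self.axis_coords_um("x") - cx
        y = self.axis_coords_um("y") - cy
        return np.hypot(y[:, None], x[None, :])


@dataclass
class NuclearMask:
    """Per-voxel nuclear probability aligned with a :class:`VoxelGrid`.

    ``probability`` is a (nz, ny, nx) array in [0, 1]; ``threshold``
    binarizes it into the in-colony / in-nuclei voxel set used by every
    downstream voxel selection.
    """

    probability: np.ndarray
    threshold: float = 0.5
    source: str = "builtin"  # {"external", "builtin"}
    voxel_spacing_um: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self):
        self.probability = np.asarray(self.probability)
        if self.probability.ndim != 3:
            raise GeometryError(
                f"mask must be (z, y, x); got ndim={self.probability.ndim}"
            )
        pmin = float(self.probability.min()) if self.probability.size else 0.0
        pmax = float(self.probability.max()) if self.probability.size else 0.0
        if pmin < 0.0 or pmax > 1.0:
            raise InputError(
                f"mask probabilities outside [0, 1]: range [{pmin}, {pmax}]"
            )
        if not (0.0 <= self.threshold <= 1.0):
            raise InputError(f"threshold must be in [0, 1]: {self.threshold}")
        self.voxel_spacing_um = tuple(float(s) for s in self.voxel_spacing_um)

    @property
    def binary(self) -> np.ndarray:
        """Boolean in-nuclei voxels at the stored threshold."""
        return self.probability > self.threshold

    def check_matches(self, grid: VoxelGrid) -> None:
        """Raise unless this mask shares the grid's spatial geometry."""
        if self.probability.shape != grid.spatial_shape:
            raise GeometryError(
                f"mask shape {self.probability.shape} != grid spatial shape "
                f"{grid.spatial_shape}"
            )
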