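"""Synthetic micropattern colony z-stacks with known ground truth.

This module emulates confocal stacks of circular micropatterned colonies
(80–1000 μm diameter) immunostained for nuclear markers: nuclei are
placed by Poisson-disc sampling at a prescribed areal density, each cell
receives a per-channel marker level drawn from a radially organized
domain model (central / mid / outer concentric territories, optionally
shifting and rescaling over a time course), and microscopy-like noise
(additive background, optional planar tilt, signal-dependent shot noise,
Gaussian read noise) is applied last.  Everything the generator decides
— centroids, per-cell levels, domain boundaries, the pre-noise stack —
is recorded in a :class:`GroundTruth` twin so downstream quantification
can be validated voxel-for-voxel.

Nuclei are rendered as flat-core ellipsoids (default half-axes 4 μm in
xy, 3 μm in z) with a Gaussian shoulder: inside the core every channel
equals its model-assigned level *exactly*, which makes noise-free stacks
an exact oracle for masking and profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .errors import GeometryError, InfeasibleSpecError, InputError
from .grids import DEFAULT_NUCLEAR_CHANNEL, VoxelGrid

#: Profile kinds a marker domain model may take.
PROFILE_KINDS = ("uniform", "center_high", "edge_high", "annulus")

#: Colony diameters used in the study design (μm).
STUDY_DIAMETERS_UM = (80.0, 140.0, 225.0, 500.0, 1000.0)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


@dataclass
class MarkerDomainModel:
    """Radial expression domain for one immunostained marker.

    ``level_inside`` is the level within the domain (center disc, outer
    ring, or annulus depending on ``profile_kind``), ``level_outside``
    elsewhere; the transition is a logistic of width
    ``boundary_sharpness_um`` (0 gives a hard step).
    ``positive_fraction_noise`` is the probability that a cell swaps its
    inside/outside level (salt-type spontaneous misexpression).
    """

    channel_name: str
    profile_kind: str = "uniform"
    boundary_radii_um: tuple[float, ...] = ()
    boundary_sharpness_um: float = 0.0
    level_inside: float = 10000.0
    level_outside: float = 200.0
    positive_fraction_noise: float = 0.0

    def __post_init__(self):
        if self.profile_kind not in PROFILE_KINDS:
            raise InputError(
                f"profile_kind {self.profile_kind!r} not in {PROFILE_KINDS}"
            )
        self.boundary_radii_um = tuple(float(b) for b in self.boundary_radii_um)
        expected = {"uniform": 0, "center_high": 1, "edge_high": 1, "annulus": 2}
        if len(self.boundary_radii_um) != expected[self.profile_kind]:
            raise InputError(
                f"{self.profile_kind} needs {expected[self.profile_kind]} "
                f"boundary radii, got {self.boundary_radii_um}"
            )
        if any(b2 <= b1 for b1, b2 in zip(self.boundary_radii_um, self.boundary_radii_um[1:])):
            raise InputError(f"boundary radii must strictly increase: {self.boundary_radii_um}")
        if self.level_inside < 0 or self.level_outside < 0:
            raise InputError("intensity levels must be >= 0")
        if self.boundary_sharpness_um < 0:
            raise InputError("boundary sharpness must be >= 0")
        if not (0.0 <= self.positive_fraction_noise <= 1.0):
            raise InputError("positive_fraction_noise must be a probability")

    def level_at(self, r_um: np.ndarray) -> np.ndarray:
        """True (noise-free) marker level at radius ``r_um`` from center."""
        r = np.asarray(r_um, dtype=float)
        lo, hi = self.level_outside, self.level_inside
        s = self.boundary_sharpness_um
        if self.profile_kind == "uniform":
            return np.full_like(r, hi)
        if s <= 0:
            def sig(x):
                return (x >= 0).astype(float)
        else:
            def sig(x):
                return _logistic(x / s)
        if self.profile_kind == "center_high":
            (b,) = self.boundary_radii_um
            w = sig(b - r)
        elif self.profile_kind == "edge_high":
            (b,) = self.boundary_radii_um
            w = sig(r - b)
        else:  # annulus
            b0, b1 = self.boundary_radii_um
            w = sig(r - b0) * sig(b1 - r)
        return lo + (hi - lo) * w


@dataclass
class NoiseModel:
    """Additive + signal-dependent acquisition noise.

    background_level : flat additive offset (a.u.)
    background_gradient : planar tilt along x (a.u. per μm)
    shot_scale : variance-to-mean ratio of signal-dependent noise
    read_sigma : standard deviation of additive Gaussian read noise (a.u.)
    """

    background_level: float = 500.0
    background_gradient: float = 0.05
    shot_scale: float = 2.0
    read_sigma: float = 50.0

    def __post_init__(self):
        for name in ("background_level", "background_gradient", "shot_scale", "read_sigma"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)

    @property
    def is_off(self) -> bool:
        return (
            self.background_level == 0
            and self.background_gradient == 0
            and self.shot_scale == 0
            and self.read_sigma == 0
        )


@dataclass
class RidgeModel:
    """Multi-layered annular ridge ('volcano' morphology).

    Cells within ``[inner_radius_um, outer_radius_um]`` are stacked in up
    to ``n_layers`` layers spaced ``layer_dz_um`` apart; the layer count
    tapers triangularly from the annulus center so the colony height has
    a well-defined peak at ``peak_radius_um``.
    """

    inner_radius_um: float
    outer_radius_um: float
    n_layers: int = 3
    layer_dz_um: float = 4.0

    def __post_init__(self):
        if self.outer_radius_um <= self.inner_radius_um:
            raise InputError("ridge outer radius must exceed inner radius")
        if self.n_layers < 1:
            raise InputError("ridge needs >= 1 layers")

    @property
    def peak_radius_um(self) -> float:
        return 0.5 * (self.inner_radius_um + self.outer_radius_um)

    def layers_at(self, r_um: float) -> int:
        half = 0.5 * (self.outer_radius_um - self.inner_radius_um)
        tri = max(0.0, 1.0 - abs(r_um - self.peak_radius_um) / half)
        return 1 + int(round((self.n_layers - 1) * tri))


@dataclass
class SyntheticColonySpec:
    """Full generative description of one synthetic colony stack.

    ``cell_density`` is in cells per 1000 μm² of colony area (a confluent
    epithelium at ~11 μm center spacing corresponds to ~4/1000 μm²).
    Intensities are on a 16-bit a.u. scale (0–65535).
    """

    diameter_um: float = 1000.0
    cell_density: float = 4.0
    n_z_layers: int = 16
    marker_models: list[MarkerDomainModel] = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    voxel_spacing_um: tuple[float, float, float] = (2.0, 2.0, 1.0)
    seed: int = 0
    nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL
    nuclear_level: float = 20000.0
    nuclear_core_xy_um: float = 4.0
    nuclear_core_z_um: float = 3.0
    nuclear_rolloff_um: float = 1.5
    z_jitter_um: float = 1.0
    field_margin_um: float = 10.0
    min_spacing_um: Optional[float] = None
    ridge: Optional[RidgeModel] = None

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise InputError("diameter_um must be > 0")
        if self.cell_density <= 0:
            raise InputError("cell_density must be > 0")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise InputError("voxel spacings must be > 0")
        if self.n_z_layers < 1:
            raise InputError("n_z_layers must be >= 1")
        names = [m.channel_name for m in self.marker_models]
        if self.nuclear_channel in names or len(set(names)) != len(names):
            raise InputError(f"channel names must be unique and distinct "
                             f"from {self.nuclear_channel!r}: {names}")
        radius = self.diameter_um / 2.0
        for m in self.marker_models:
            if any(b > radius for b in m.boundary_radii_um):
                raise InputError(
                    f"boundary radii of {m.channel_name!r} exceed colony radius {radius}"
                )
        if self.ridge is not None and self.ridge.outer_radius_um > radius:
            raise InputError("ridge extends beyond colony radius")

    # -- derived geometry ------------------------------------------------

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def areal_density_per_um2(self) -> float:
        return self.cell_density / 1000.0

    @property
    def spacing_um(self) -> float:
        """Minimum inter-nuclear spacing for Poisson-disc placement."""
        if self.min_spacing_um is not None:
            return self.min_spacing_um
        return 0.7 / math.sqrt(self.areal_density_per_um2)

    @property
    def n_cells(self) -> int:
        return int(round(self.areal_density_per_um2 * math.pi * self.radius_um**2))

    def field_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) of the generated stack."""
        dx, dy, dz = self.voxel_spacing_um
        width = self.diameter_um + 2 * self.field_margin_um
        return (self.n_z_layers, int(math.ceil(width / dy)), int(math.ceil(width / dx)))

    def center_um(self) -> tuple[float, float]:
        dx, dy, _ = self.voxel_spacing_um
        nz, ny, nx = self.field_shape()
        return (nx * dx / 2.0, ny * dy / 2.0)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "diameter_um": self.diameter_um,
            "cell_density": self.cell_density,
            "n_z_layers": self.n_z_layers,
            "voxel_spacing_um": list(self.voxel_spacing_um),
            "seed": self.seed,
            "nuclear_channel": self.nuclear_channel,
            "nuclear_level": self.nuclear_level,
            "nuclear_core_xy_um": self.nuclear_core_xy_um,
            "nuclear_core_z_um": self.nuclear_core_z_um,
            "nuclear_rolloff_um": self.nuclear_rolloff_um,
            "z_jitter_um": self.z_jitter_um,
            "field_margin_um": self.field_margin_um,
            "min_spacing_um": self.min_spacing_um,
            "noise": vars(self.noise).copy(),
            "marker_models": [
                {
                    "channel_name": m.channel_name,
                    "profile_kind": m.profile_kind,
                    "boundary_radii_um": list(m.boundary_radii_um),
                    "boundary_sharpness_um": m.boundary_sharpness_um,
                    "level_inside": m.level_inside,
                    "level_outside": m.level_outside,
                    "positive_fraction_noise": m.positive_fraction_noise,
                }
                for m in self.marker_models
            ],
        }
        if self.ridge is not None:
            d["ridge"] = vars(self.ridge).copy()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticColonySpec":
        d = dict(d)
        markers = [MarkerDomainModel(**m) for m in d.pop("marker_models", [])]
        noise = NoiseModel(**d.pop("noise", {}))
        ridge = d.pop("ridge", None)
        if ridge is not None:
            ridge = RidgeModel(**ridge)
        if "voxel_spacing_um" in d:
            d["voxel_spacing_um"] = tuple(d["voxel_spacing_um"])
        return cls(marker_models=markers, noise=noise, ridge=ridge, **d)


@dataclass
class GroundTruth:
    """Everything the generator decided, recorded before noise."""

    centroids_um: np.ndarray              # (n_cells, 3): x, y, z
    marker_levels: dict                   # channel -> (n_cells,) true level
    boundary_radii_um: dict               # channel -> list of true radii
    center_um: tuple[float, float]
    colony_radius_um: float
    clean: Optional[np.ndarray] = None    # pre-noise (C, nz, ny, nx) stack
    channel_names: list[str] = field(default_factory=list)
    cell_layers: Optional[np.ndarray] = None
    ridge: Optional[RidgeModel] = None
    min_spacing_um: float = 0.0
    transitions_applied: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.centroids_um.shape[0]

    def cell_radii_um(self) -> np.ndarray:
        cx, cy = self.center_um
        return np.hypot(self.centroids_um[:, 0] - cx, self.centroids_um[:, 1] - cy)

    def nuclear_core_mask(self, nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL,
                          nuclear_level: float = 20000.0) -> np.ndarray:
        """Boolean voxels inside any nucleus core (exact-level region)."""
        if self.clean is None:
            raise InputError("ground truth was generated without the clean stack")
        idx = self.channel_names.index(nuclear_channel)
        return self.clean[idx] == np.float32(nuclear_level)

    def nuclear_footprint_mask(self, nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL,
                               nuclear_level: float = 20000.0,
                               fraction: float = 0.5) -> np.ndarray:
        """Voxels where the clean nuclear signal exceeds ``fraction`` of
        the nuclear level — the half-maximum object footprint by default."""
        if self.clean is None:
            raise InputError("ground truth was generated without the clean stack")
        idx = self.channel_names.index(nuclear_channel)
        return self.clean[idx] >= fraction * nuclear_level

    def to_json_dict(self) -> dict:
        """Sidecar-serializable summary (volumetric arrays omitted)."""
        return {
            "n_cells": int(self.n_cells),
            "centroids_um": np.asarray(self.centroids_um).tolist(),
            "marker_levels": {k: np.asarray(v).tolist() for k, v in self.marker_levels.items()},
            "boundary_radii_um": {k: list(map(float, v)) for k, v in self.boundary_radii_um.items()},
            "center_um": list(map(float, self.center_um)),
            "colony_radius_um": float(self.colony_radius_um),
            "min_spacing_um": float(self.min_spacing_um),
            "ridge": (vars(self.ridge).copy() if self.ridge is not None else None),
            "transitions_applied": self.transitions_applied,
        }


# ---------------------------------------------------------------------------
# cell placement


def _poisson_disc(rng: np.random.Generator, radius: float, min_spacing: float,
                  n_target: int, attempts_per_cell: int = 400) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of ``n_target`` points in a disc.

    Points are relative to the disc center. Raises
    :class:`InfeasibleSpecError` if saturation prevents placement.
    """
    if n_target == 0:
        return np.empty((0, 2))
    lam = n_target / (math.pi * radius**2)
    if lam * min_spacing**2 > 0.65:  # random sequential adsorption saturation
        raise InfeasibleSpecError(
            f"density {lam:.4g}/μm² infeasible at min spacing {min_spacing:.3g} μm"
        )
    from scipy.spatial import cKDTree

    accepted = np.empty((n_target, 2))
    n_placed = 0
    attempts = 0
    limit = attempts_per_cell * n_target
    while n_placed < n_target and attempts < limit:
        batch = min(max(4 * (n_target - n_placed), 1024), limit - attempts)
        attempts += batch
        rr = radius * np.sqrt(rng.random(batch))
        th = 2 * math.pi * rng.random(batch)
        cand = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        if n_placed:
            d, _ = cKDTree(accepted[:n_placed]).query(cand, workers=1)
            cand = cand[d >= min_spacing]
        if cand.shape[0] == 0:
            continue
        # resolve within-batch conflicts sequentially (earlier dart wins)
        alive = np.ones(cand.shape[0], dtype=bool)
        for i, j in sorted(cKDTree(cand).query_pairs(min_spacing)):
            if alive[i] and alive[j]:
                alive[j] = False
        survivors = cand[alive]
        take = min(len(survivors), n_target - n_placed)
        accepted[n_placed:n_placed + take] = survivors[:take]
        n_placed += take
    if n_placed < n_target:
        raise InfeasibleSpecError(
            f"placed only {n_placed}/{n_target} cells after {attempts} attempts"
        )
    return accepted


# ---------------------------------------------------------------------------
# rendering


def _paint_cells(shape: tuple[int, int, int], spacing: tuple[float, float, float],
                 centroids_um: np.ndarray, levels: np.ndarray,
                 core_xy: float, core_z: float, rolloff: float) -> np.ndarray:
    """Render per-cell flat-core ellipsoids with a Gaussian shoulder.

    ``levels`` is (n_channels, n_cells); output is (n_channels, *shape).
    Overlapping supports combine by maximum, so single-cell core voxels
    hold the cell's level exactly.
    """
    dx, dy, dz = spacing
    nz, ny, nx = shape
    levels = np.atleast_2d(levels)
    out = np.zeros((levels.shape[0],) + shape, dtype=np.float32)
    w = rolloff / core_xy  # shoulder width in normalized ellipsoid units
    dmax = 1.0 + (3.0 * w if w > 0 else 0.0)
    # support half-extents in voxels
    hx = int(math.ceil(core_xy * dmax / dx))
    hy = int(math.ceil(core_xy * dmax / dy))
    hz = int(math.ceil(core_z * dmax / dz))
    for k, (cx, cy, cz) in enumerate(centroids_um):
        ix = int(cx / dx - 0.5)
        iy = int(cy / dy - 0.5)
        iz = int(cz / dz - 0.5)
        x0, x1 = max(0, ix - hx), min(nx, ix + hx + 2)
        y0, y1 = max(0, iy - hy), min(ny, iy + hy + 2)
        z0, z1 = max(0, iz - hz), min(nz, iz + hz + 2)
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        xs = ((np.arange(x0, x1) + 0.5) * dx - cx) / core_xy
        ys = ((np.arange(y0, y1) + 0.5) * dy - cy) / core_xy
        zs = ((np.arange(z0, z1) + 0.5) * dz - cz) / core_z
        d = np.sqrt(zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2)
        if w > 0:
            f = np.where(d <= 1.0, 1.0, np.exp(-0.5 * ((d - 1.0) / w) ** 2))
            f[d > dmax] = 0.0
        else:
            f = (d <= 1.0).astype(float)
        f = f.astype(np.float32)
        for c in range(levels.shape[0]):
            if levels[c, k] <= 0:
                continue
            sub = out[c, z0:z1, y0:y1, x0:x1]
            np.maximum(sub, levels[c, k] * f, out=sub)
    return out


def _apply_noise(clean: np.ndarray, noise: NoiseModel, spacing, rng) -> np.ndarray:
    """Background + shot-like + read noise, clipped to the 16-bit range."""
    if noise.is_off:
        return clean.copy()
    dx = spacing[0]
    nx = clean.shape[-1]
    x_um = (np.arange(nx) + 0.5) * dx
    bg = noise.background_level + noise.background_gradient * x_um
    mean = clean + bg.astype(np.float32)[None, None, None, :]
    sigma = np.sqrt(noise.shot_scale * mean + noise.read_sigma**2, dtype=np.float32)
    noisy = mean + rng.standard_normal(mean.shape, dtype=np.float32) * sigma
    return np.clip(noisy, 0.0, 65535.0)


# ---------------------------------------------------------------------------
# public generators


def generate_colony(spec: SyntheticColonySpec,
                    keep_clean: bool = True) -> tuple[VoxelGrid, GroundTruth]:
    """Generate one synthetic colony stack and its ground truth.

    The same spec (including seed) always yields bit-identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    place_rng, level_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    shape = spec.field_shape()
    dx, dy, dz = spec.voxel_spacing_um
    cx0, cy0 = spec.center_um()

    place_radius = spec.radius_um - spec.nuclear_core_xy_um
    if place_radius <= 0:
        raise InfeasibleSpecError("colony too small for a single nucleus")
    pts = _poisson_disc(place_rng, place_radius, spec.spacing_um, spec.n_cells)
    radii = np.hypot(pts[:, 0], pts[:, 1])

    # z placement: monolayer plane, optionally stacked within a ridge annulus
    support_z = spec.nuclear_core_z_um + 3.0 * spec.nuclear_rolloff_um
    if spec.ridge is None:
        z_base = shape[0] * dz / 2.0
        layers = np.zeros(len(pts), dtype=int)
    else:
        z_base = support_z + spec.z_jitter_um
        n_layers = np.array([
            spec.ridge.layers_at(r)
            if spec.ridge.inner_radius_um <= r <= spec.ridge.outer_radius_um else 1
            for r in radii
        ])
        layers = np.array([place_rng.integers(0, n) for n in n_layers])
        z_top = z_base + (spec.ridge.n_layers - 1) * spec.ridge.layer_dz_um
        if z_top + support_z + spec.z_jitter_um > shape[0] * dz:
            raise GeometryError(
                f"stack depth {shape[0] * dz} μm too shallow for ridge (needs "
                f"{z_top + support_z + spec.z_jitter_um:.1f} μm)"
            )
    layer_dz = spec.ridge.layer_dz_um if spec.ridge is not None else 0.0
    z_jit = place_rng.uniform(-spec.z_jitter_um, spec.z_jitter_um, size=len(pts))
    zs = z_base + layers * layer_dz + z_jit

    centroids = np.column_stack([pts[:, 0] + cx0, pts[:, 1] + cy0, zs])

    # per-cell marker levels from the domain models
    marker_levels: dict[str, np.ndarray] = {}
    boundary_radii: dict[str, list[float]] = {}
    for m in spec.marker_models:
        levels = m.level_at(radii)
        if m.positive_fraction_noise > 0:
            flip = level_rng.random(len(levels)) < m.positive_fraction_noise
            swapped = np.where(
                np.isclose(levels, m.level_inside), m.level_outside, m.level_inside
            )
            levels = np.where(flip, swapped, levels)
        marker_levels[m.channel_name] = levels
        boundary_radii[m.channel_name] = list(m.boundary_radii_um)

    channel_names = [spec.nuclear_channel] + [m.channel_name for m in spec.marker_models]
    level_matrix = np.vstack(
        [np.full(len(centroids), spec.nuclear_level)]
        + [marker_levels[m.channel_name] for m in spec.marker_models]
    )
    clean = _paint_cells(shape, spec.voxel_spacing_um, centroids, level_matrix,
                         spec.nuclear_core_xy_um, spec.nuclear_core_z_um,
                         spec.nuclear_rolloff_um)

    noisy = _apply_noise(clean, spec.noise, spec.voxel_spacing_um, noise_rng)

    grid = VoxelGrid(noisy, channel_names, spec.voxel_spacing_um)
    truth = GroundTruth(
        centroids_um=centroids,
        marker_levels=marker_levels,
        boundary_radii_um=boundary_radii,
        center_um=(cx0, cy0),
        colony_radius_um=spec.radius_um,
        clean=clean if keep_clean else None,
        channel_names=channel_names,
        cell_layers=layers,
        ridge=spec.ridge,
        min_spacing_um=spec.spacing_um,
    )
    return grid, truth


@dataclass
class ChannelTransition:
    """Per-timepoint changes applied to one marker over a time course.

    ``level_multipliers[i]`` scales both domain levels at timepoint i;
    ``boundary_radii_um[i]`` (optional) replaces the domain boundaries.
    """

    level_multipliers: Sequence[float]
    boundary_radii_um: Optional[Sequence[Sequence[float]]] = None


def generate_timecourse(
    spec_0hr: SyntheticColonySpec,
    transitions: dict[str, ChannelTransition],
    timepoints_hr: Sequence[float],
) -> list[tuple[VoxelGrid, GroundTruth]]:
    """Generate one colony per timepoint, sharing the cell placement.

    All timepoints use the 0 hr spec's seed, so identity transitions
    reproduce the 0 hr stack exactly. Ground truth records the applied
    multipliers and boundaries per channel.
    """
    tp = [float(t) for t in timepoints_hr]
    if any(b <= a for a, b in zip(tp, tp[1:])):
        raise InputError(f"timepoints must strictly increase: {tp}")
    known = {m.channel_name for m in spec_0hr.marker_models}
    for ch, tr in transitions.items():
        if ch not in known:
            raise InputError(f"transition for unknown channel {ch!r}")
        if len(tr.level_multipliers) != len(tp):
            raise InputError(
                f"{ch!r}: {len(tr.level_multipliers)} multipliers for {len(tp)} timepoints"
            )
        if tr.boundary_radii_um is not None and len(tr.boundary_radii_um) != len(tp):
            raise InputError(f"{ch!r}: boundary list length != number of timepoints")

    out = []
    for i, t in enumerate(tp):
        models = []
        applied = {}
        for m in spec_0hr.marker_models:
            tr = transitions.get(m.channel_name)
            if tr is None:
                models.append(m)
                continue
            mult = float(tr.level_multipliers[i])
            radii = (
                tuple(float(b) for b in tr.boundary_radii_um[i])
                if tr.boundary_radii_um is not None
                else m.boundary_radii_um
            )
            models.append(replace(
                m,
                level_inside=m.level_inside * mult,
                level_outside=m.level_outside * mult,
                boundary_radii_um=radii,
            ))
            applied[m.channel_name] = {
                "level_multiplier": mult,
                "boundary_radii_um": list(radii),
            }
        spec_t = replace(spec_0hr, marker_models=models)
        grid, truth = generate_colony(spec_t)
        truth.transitions_applied = {"timepoint_hr": t, "channels": applied}
        out.append((grid, truth))
    return out


# ---------------------------------------------------------------------------
# 2D section fixtures


def generate_section_fixture(
    regions: Sequence[dict],
    seed: int,
    image_size_um: tuple[float, float] = (200.0, 200.0),
    pixel_size_um: float = 1.0,
    noise_sigma: float = 0.0,
    nuclear_channel: str = DEFAULT_NUCLEAR_CHANNEL,
) -> tuple[VoxelGrid, dict]:
    """Synthesize a 2D multi-channel section image from polygonal regions.

    Each region is ``{"region_id": str, "polygon_um": [(x, y), ...],
    "channel_means": {channel: level}}``; every region must include the
    nuclear channel. Regions may not overlap. Returns the image (a
    single-z :class:`VoxelGrid`) and a ground-truth dict with per-region
    true means and pixel masks.
    """
    if not regions:
        raise InputError("at least one region required")
    channels: list[str] = []
    for reg in regions:
        for ch in reg["channel_means"]:
            if ch not in channels:
                channels.append(ch)
        if nuclear_channel not in reg["channel_means"]:
            raise InputError(
                f"region {reg.get('region_id')!r} lacks the nuclear channel "
                f"{nuclear_channel!r}"
            )
    nx = int(math.ceil(image_size_um[0] / pixel_size_um))
    ny = int(math.ceil(image_size_um[1] / pixel_size_um))
    xs = (np.arange(nx) + 0.5) * pixel_size_um
    ys = (np.arange(ny) + 0.5) * pixel_size_um
    centers = np.column_stack([np.tile(xs, ny), np.repeat(ys, nx)])

    masks = []
    for reg in regions:
        poly = np.asarray(reg["polygon_um"], dtype=float)
        if poly.shape[0] < 3:
            raise InputError(f"region {reg.get('region_id')!r}: polygon needs >= 3 vertices")
        inside = MplPath(poly).contains_points(centers).reshape(ny, nx)
        if not inside.any():
            raise InputError(f"region {reg.get('region_id')!r} lies outside the image")
        masks.append(inside)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise InputError(
                    f"regions {regions[i].get('region_id')!r} and "
                    f"{regions[j].get('region_id')!r} overlap"
                )

    img = np.zeros((len(channels), 1, ny, nx), dtype=np.float32)
    for reg, mask in zip(regions, masks):
        for ch, level in reg["channel_means"].items():
            img[channels.index(ch), 0][mask] = level
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(
            img + rng.standard_normal(img.shape).astype(np.float32) * noise_sigma,
            0.0, 65535.0,
        )
    grid = VoxelGrid(img, channels, (pixel_size_um, pixel_size_um, 1.0))
    truth = {
        "regions": [
            {
                "region_id": reg.get("region_id", f"region_{i}"),
                "true_means": dict(reg["channel_means"]),
                "n_pixels": int(mask.sum()),
            }
            for i, (reg, mask) in enumerate(zip(regions, masks))
        ],
        "masks": masks,
        "channels": channels,
    }
    return grid, truth
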