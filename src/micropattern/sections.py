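"""ROI- and point-based quantification of 2D section images.

Implements the embryo-side quantifications: mean fluorescence within
manually recorded regions of interest (anterior vs posterior epiblast)
and small discs around manually selected cells, all normalized to the
Hoechst nuclear stain over the identical pixel set — which makes the
normalized values invariant to any global intensity rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .errors import DegenerateImageError, InputError
from .grids import DEFAULT_NUCLEAR_CHANNEL, VoxelGrid


@dataclass
class RoiQuantResult:
    """Per-ROI channel means and their Hoechst-normalized values."""

    roi_id: str
    means: dict
    hoechst_normalized: dict
    n_pixels: int
    group: str = ""

    def __post_init__(self):
        if self.n_pixels <= 0:
            raise InputError("ROI covers no pixels")


def _section_image(section: VoxelGrid) -> None:
    if section.spatial_shape[0] != 1:
        raise InputError(
            f"section quantification expects a single-z image; got nz={section.spatial_shape[0]}"
        )


def _pixel_centers_um(section: VoxelGrid) -> np.ndarray:
    xs = section.axis_coords_um("x")
    ys = section.axis_coords_um("y")
    ny, nx = len(ys), len(xs)
    return np.column_stack([np.tile(xs, ny), np.repeat(ys, nx)])


def _quantify_mask(
    section: VoxelGrid,
    pix_mask: np.ndarray,
    roi_id: str,
    group: str,
    channels: Optional[Sequence[str]],
    hoechst_channel: str,
) -> RoiQuantResult:
    if not pix_mask.any():
        raise InputError(f"ROI {roi_id!r} covers no pixel centers")
    if hoechst_channel not in section.channel_names:
        raise InputError(f"missing Hoechst channel {hoechst_channel!r}")
    chans = list(channels) if channels is not None else list(section.channel_names)
    hoechst_mean = float(section.channel(hoechst_channel)[0][pix_mask].mean())
    if hoechst_mean == 0:
        raise DegenerateImageError(f"ROI {roi_id!r}: zero Hoechst mean")
    means = {ch: float(section.channel(ch)[0][pix_mask].mean()) for ch in chans}
    return RoiQuantResult(
        roi_id=roi_id,
        means=means,
        hoechst_normalized={ch: m / hoechst_mean for ch, m in means.items()},
        n_pixels=int(pix_mask.sum()),
        group=group,
    )


def roi_mean(
    section: VoxelGrid,
    polygon_um: Sequence[Sequence[float]],
    channels: Optional[Sequence[str]] = None,
    hoechst_channel: str = DEFAULT_NUCLEAR_CHANNEL,
    roi_id: str = "roi",
    group: str = "",
) -> RoiQuantResult:
    """Mean intensity over pixels whose centers fall inside the polygon.

    The polygon is a closed, non-self-intersecting sequence of (x, y)
    vertices in μm.  Hoechst normalization uses the identical pixel set.
    """
    _section_image(section)
    poly = np.asarray(polygon_um, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise InputError("polygon needs >= 3 (x, y) vertices")
    ny, nx = section.spatial_shape[1:]
    inside = MplPath(poly).contains_points(_pixel_centers_um(section)).reshape(ny, nx)
    if not inside.any():
        raise InputError(f"ROI {roi_id!r} lies outside the image")
    return _quantify_mask(section, inside, roi_id, group, channels, hoechst_channel)


def point_cell_quant(
    section: VoxelGrid,
    points: Sequence[dict],
    radius_um: float = 5.0,
    channels: Optional[Sequence[str]] = None,
    hoechst_channel: str = DEFAULT_NUCLEAR_CHANNEL,
) -> list[RoiQuantResult]:
    """Quantify a disc of ``radius_um`` around each manually selected cell.

    ``points`` are ``{"roi_id": ..., "group": ..., "coordinates_um": (x, y)}``.
    """
    _section_image(section)
    if radius_um <= 0:
        raise InputError("radius_um must be > 0")
    ny, nx = section.spatial_shape[1:]
    centers = _pixel_centers_um(section)
    results = []
    for pt in points:
        x, y = (float(v) for v in pt["coordinates_um"])
        disc = (np.hypot(centers[:, 0] - x, centers[:, 1] - y) <= radius_um).reshape(ny, nx)
        results.append(_quantify_mask(
            section, disc, str(pt.get("roi_id", "cell")), str(pt.get("group", "")),
            channels, hoechst_channel,
        ))
    return results


def group_summary(results: Sequence[RoiQuantResult]) -> pd.DataFrame:
    """Mean ± SD (n−1 denominator) of Hoechst-normalized values per group
    and channel; groups with a single member report SD as NaN."""
    rows = []
    for res in results:
        for ch, val in res.hoechst_normalized.items():
            rows.append({"group": res.group, "channel": ch, "value": val})
    if not rows:
        return pd.DataFrame(columns=["group", "channel", "mean", "sd", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "channel"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# ROI file format


def load_rois(path) -> list[dict]:
    """Read an ROI JSON file.

    Schema: ``{"rois": [{"roi_id", "group", "type": "polygon"|"point",
    "coordinates_um": [[x, y], ...] | [x, y]}, ...]}``.
    """
    with open(Path(path)) as fh:
        data = json.load(fh)
    rois = data.get("rois")
    if not isinstance(rois, list):
        raise InputError(f"{path}: expected top-level 'rois' list")
    for roi in rois:
        if roi.get("type") not in ("polygon", "point"):
            raise InputError(f"{path}: ROI type must be 'polygon' or 'point': {roi}")
        if "coordinates_um" not in roi:
            raise InputError(f"{path}: ROI missing coordinates_um: {roi}")
    return rois


def quantify_rois(
    section: VoxelGrid,
    rois: Sequence[dict],
    point_radius_um: float = 5.0,
    channels: Optional[Sequence[str]] = None,
    hoechst_channel: str = DEFAULT_NUCLEAR_CHANNEL,
) -> list[RoiQuantResult]:
    """Dispatch a mixed list of polygon and point ROIs."""
    results = []
    for roi in rois:
        if roi["type"] == "polygon":
            results.append(roi_mean(
                section, roi["coordinates_um"], channels=channels,
                hoechst_channel=hoechst_channel,
                roi_id=str(roi.get("roi_id", "roi")), group=str(roi.get("group", "")),
            ))
        else:
            results.extend(point_cell_quant(
                section, [roi], radius_um=point_radius_um,
                channels=channels, hoechst_channel=hoechst_channel,
            ))
    return results
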