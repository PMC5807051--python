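"""Reading and writing stacks, masks, profiles and tables.

Stacks follow the acquisition convention of one multi-page TIFF per
channel (z as pages) plus a small JSON sidecar holding channel names and
voxel spacing; masks persist as HDF5 (float probability + threshold
attributes) or float TIFF; profiles and tables are CSV with a
self-describing column schema so results are joinable across colonies.
All writers avoid embedded timestamps so identical data produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import GeometryError, InputError
from .grids import NuclearMask, VoxelGrid
from .radial import RadialProfile
from .synthetic import GroundTruth, SyntheticColonySpec

PathLike = Union[str, Path]

_META_SUFFIX = "_meta.json"


# ---------------------------------------------------------------------------
# stacks


def write_stack(grid: VoxelGrid, directory: PathLike, basename: str = "stack") -> list[Path]:
    """Write one multi-page TIFF per channel plus a JSON metadata sidecar.

    Float data is stored as float32; integer data as uint16.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch in grid.channel_names:
        data = grid.channel(ch)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.uint16)
        else:
            data = data.astype(np.float32)
        path = directory / f"{basename}_{ch}.tif"
        tifffile.imwrite(path, data, photometric="minisblack")
        paths.append(path)
    meta = {
        "basename": basename,
        "channel_names": list(grid.channel_names),
        "voxel_spacing_um": list(grid.voxel_spacing_um),
    }
    meta_path = directory / f"{basename}{_META_SUFFIX}"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths.append(meta_path)
    return paths


def read_stack(
    source: Union[PathLike, dict],
    voxel_spacing_um: Optional[Sequence[float]] = None,
    channel_names: Optional[Sequence[str]] = None,
) -> VoxelGrid:
    """Assemble a multi-channel grid from per-channel TIFF stacks.

    ``source`` is either a metadata JSON path written by
    :func:`write_stack`, or a mapping ``{channel_name: tiff_path}`` (in
    which case ``voxel_spacing_um`` is required).  Channel page counts
    and shapes must agree.
    """
    if isinstance(source, (str, Path)):
        meta_path = Path(source)
        if not meta_path.exists():
            raise InputError(f"no such stack metadata file: {meta_path}")
        meta = json.loads(meta_path.read_text())
        names = channel_names or meta["channel_names"]
        spacing = voxel_spacing_um or meta.get("voxel_spacing_um")
        files = {
            ch: meta_path.parent / f"{meta['basename']}_{ch}.tif" for ch in names
        }
    else:
        files = {ch: Path(p) for ch, p in source.items()}
        names = channel_names or list(files)
        spacing = voxel_spacing_um
    if spacing is None:
        raise InputError("voxel spacing unknown: not in metadata and not supplied")
    arrays = []
    for ch in names:
        path = files[ch]
        if not path.exists():
            raise InputError(f"channel {ch!r}: no such file {path}")
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        arrays.append(arr)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(
            f"channel stacks disagree in shape/page count: "
            f"{ {ch: a.shape for ch, a in zip(names, arrays)} }"
        )
    return VoxelGrid(np.stack(arrays).astype(np.float32), list(names), tuple(spacing))


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: NuclearMask, path: PathLike) -> Path:
    """Persist a nuclear mask as HDF5 (.h5/.hdf5) or float TIFF (.tif)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(
                "probability", data=mask.probability.astype(np.float32),
                track_times=False,
            )
            ds.attrs["threshold"] = mask.threshold
            ds.attrs["source"] = mask.source
            ds.attrs["voxel_spacing_um"] = list(mask.voxel_spacing_um)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.probability.astype(np.float32), photometric="minisblack")
    else:
        raise InputError(f"unsupported mask format: {path.suffix!r}")
    return path


def read_mask(
    path: PathLike,
    voxel_spacing_um: Optional[Sequence[float]] = None,
    threshold: float = 0.5,
) -> NuclearMask:
    """Read a probability mask; values outside [0, 1] are rejected."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask file: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["probability"]
            prob = ds[...]
            threshold = float(ds.attrs.get("threshold", threshold))
            source = str(ds.attrs.get("source", "external"))
            spacing = tuple(ds.attrs.get("voxel_spacing_um", voxel_spacing_um or (1, 1, 1)))
    else:
        prob = tifffile.imread(path)
        source = "external"
        spacing = tuple(voxel_spacing_um) if voxel_spacing_um else (1.0, 1.0, 1.0)
    if prob.ndim == 2:
        prob = prob[None, :, :]
    return NuclearMask(prob.astype(np.float64), threshold=threshold,
                       source=source, voxel_spacing_um=spacing)


# ---------------------------------------------------------------------------
# profiles and tables


def write_profile(profile: RadialProfile, path: PathLike) -> Path:
    """Radial profile as long-format CSV (header always written)."""
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    return path


def read_profile(path: PathLike) -> RadialProfile:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such profile file: {path}")
    df = pd.read_csv(path)
    return RadialProfile.from_frame(df)


def write_table(rows: Union[pd.DataFrame, Sequence[dict]], path: PathLike) -> Path:
    """Write a table of records as CSV."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    return path


def write_cells(cells: Sequence, path: PathLike) -> Path:
    """Detected-cell table: cell_id, centroid, per-channel intensities."""
    rows = []
    for i, c in enumerate(cells):
        row = {"cell_id": i, "x_um": c.centroid_um[0], "y_um": c.centroid_um[1],
               "z_um": c.centroid_um[2]}
        row.update(c.intensities)
        rows.append(row)
    df = pd.DataFrame(rows, columns=None if rows else ["cell_id", "x_um", "y_um", "z_um"])
    df.to_csv(Path(path), index=False)
    return Path(path)


def read_cells(path: PathLike) -> list:
    from .masking import CellRecord

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such cell table: {path}")
    df = pd.read_csv(path)
    extra = [c for c in df.columns if c not in ("cell_id", "x_um", "y_um", "z_um")]
    return [
        CellRecord(
            centroid_um=(row["x_um"], row["y_um"], row["z_um"]),
            intensities={ch: row[ch] for ch in extra},
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# specs and ground truth


def write_ground_truth(truth: GroundTruth, path: PathLike) -> Path:
    """Sidecar JSON with centroids, levels, boundaries (no volumetric data)."""
    path = Path(path)
    path.write_text(json.dumps(truth.to_json_dict(), sort_keys=True) + "\n")
    return path


def write_spec(spec: SyntheticColonySpec, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    return path


def read_spec(path: PathLike) -> SyntheticColonySpec:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such spec file: {path}")
    with open(path) as fh:
        if path.suffix == ".json":
            data = json.load(fh)
        else:
            data = yaml.safe_load(fh)
    return SyntheticColonySpec.from_dict(data)
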