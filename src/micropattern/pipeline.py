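"""End-to-end orchestration: generate or ingest stacks, mask, profile,
gate, measure — from a single YAML config, with a manifest of outputs.

Every stage logs the parameters it actually used (after defaults) into
the manifest, and every output file is recorded with a SHA-256 checksum,
so a rerun with an identical config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as mio
from .coexpression import gate_from_reference, quadrant_percentages, voxel_pairs
from .errors import InputError, StageError
from .grids import DEFAULT_NUCLEAR_CHANNEL
from .masking import (classify_nuclei, detect_cell_centroids, estimate_background,
                      subtract_background, subtract_constant_background)
from .morphometrics import height_profile, internuclear_distances, nuclei_per_100um
from .radial import average_profiles, estimate_center, normalize_profile, radial_profile
from .synthetic import (ChannelTransition, MarkerDomainModel, NoiseModel, RidgeModel,
                        SyntheticColonySpec, generate_colony, generate_timecourse)

logger = logging.getLogger("micropattern")

_SEED_MOD = 2**31


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    ``mode`` is 'synthetic' (colonies generated from ``synthetic.spec``)
    or 'stacks' (pre-acquired stacks listed under ``stacks``).  A seed is
    mandatory in synthetic mode.
    """

    mode: str
    output_dir: str
    seed: Optional[int] = None
    synthetic: dict = field(default_factory=dict)
    stacks: list = field(default_factory=list)
    masking: dict = field(default_factory=dict)
    background: dict = field(default_factory=dict)
    profiling: dict = field(default_factory=dict)
    coexpression: Optional[dict] = None
    morphometrics: dict = field(default_factory=dict)
    plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("synthetic", "stacks"):
            raise InputError(f"mode must be 'synthetic' or 'stacks': {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise InputError("synthetic mode requires a seed")
        if self.mode == "stacks":
            if not self.stacks:
                raise InputError("stacks mode requires a non-empty 'stacks' list")
            mask_enabled = self.masking.get("enabled", True)
            for entry in self.stacks:
                stack = entry.get("stack")
                if stack is None or not Path(stack).exists():
                    raise InputError(f"stack path missing or nonexistent: {stack}")
                mask_path = entry.get("mask")
                if mask_path is None and not mask_enabled:
                    raise InputError(
                        f"stack {stack}: no mask supplied and masking is disabled — "
                        "enable masking or provide a mask"
                    )
                if mask_path is not None and not Path(mask_path).exists():
                    raise InputError(f"mask path nonexistent: {mask_path}")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "synthetic": self.synthetic,
            "stacks": self.stacks,
            "masking": self.masking,
            "background": self.background,
            "profiling": self.profiling,
            "coexpression": self.coexpression,
            "morphometrics": self.morphometrics,
            "plots": self.plots,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _chord_segments(center, radius, n_segments=10, span=0.5):
    """Parallel full-width chords at evenly spaced y offsets — the '10
    distinct positions across the entire width of the colony'."""
    cx, cy = center
    offsets = np.linspace(-span * radius, span * radius, n_segments)
    segs = []
    for dy in offsets:
        half = math.sqrt(max(radius**2 - dy**2, 0.0))
        segs.append(((cx - half, cy + dy), (cx + half, cy + dy)))
    return segs


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages in dependency order.

    Returns the manifest (also written to ``<output_dir>/manifest.json``).
    Stage failures raise :class:`StageError`; the manifest is still
    written, with partial outputs flagged.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": []}

    def record(stage, path, kind):
        manifest["outputs"].append({
            "stage": stage, "path": str(path.relative_to(outdir)),
            "kind": kind, "sha256": _sha256(path),
        })

    def finish(stage, params):
        manifest["stages"][stage] = {"status": "ok", "params": params}
        logger.info("stage %s ok (%s)", stage, params)

    def fail(stage, exc):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        raise StageError(stage, str(exc)) from exc

    colonies = []  # list of dicts: id, grid, mask, spec/truth
    nuclear_channel = DEFAULT_NUCLEAR_CHANNEL

    # -- acquire ---------------------------------------------------------
    stage = "acquire"
    try:
        if config.mode == "synthetic":
            spec_dict = config.synthetic.get("spec", {})
            n_colonies = int(config.synthetic.get("n_colonies", 1))
            base = SyntheticColonySpec.from_dict(spec_dict) if spec_dict else SyntheticColonySpec()
            nuclear_channel = base.nuclear_channel
            from dataclasses import replace as _replace
            for i in range(n_colonies):
                spec_i = _replace(base, seed=(int(config.seed) + i) % _SEED_MOD)
                grid, truth = generate_colony(spec_i, keep_clean=False)
                cid = f"colony_{i:03d}"
                paths = mio.write_stack(grid, outdir / "stacks", basename=cid)
                mio.write_ground_truth(truth, outdir / "stacks" / f"{cid}_truth.json")
                for p in paths:
                    record(stage, p, "stack")
                record(stage, outdir / "stacks" / f"{cid}_truth.json", "ground_truth")
                colonies.append({"id": cid, "grid": grid, "spec": spec_i, "truth": truth})
            params = {"n_colonies": n_colonies, "spec": base.to_dict(), "seed": config.seed}
        else:
            for i, entry in enumerate(config.stacks):
                grid = mio.read_stack(entry["stack"],
                                      voxel_spacing_um=entry.get("voxel_spacing_um"))
                cid = entry.get("id", f"colony_{i:03d}")
                col = {"id": cid, "grid": grid, "spec": None, "truth": None}
                if entry.get("mask"):
                    col["mask"] = mio.read_mask(entry["mask"],
                                                voxel_spacing_um=grid.voxel_spacing_um)
                colonies.append(col)
            nuclear_channel = config.masking.get("nuclear_channel", DEFAULT_NUCLEAR_CHANNEL)
            params = {"n_stacks": len(colonies)}
        finish(stage, params)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    # -- mask ------------------------------------------------------------
    stage = "mask"
    try:
        mp = config.masking
        sigma = float(mp.get("smooth_sigma_um", 2.0))
        softness = float(mp.get("softness", 0.1))
        ball = mp.get("ball_radius_um")
        for col in colonies:
            if "mask" not in col:
                col["mask"] = classify_nuclei(
                    col["grid"], nuclear_channel=nuclear_channel,
                    smooth_sigma_um=sigma, softness=softness,
                    ball_radius_um=ball,
                )
            p = mio.write_mask(col["mask"], outdir / "masks" / f"{col['id']}_mask.h5")
            record(stage, p, "mask")
        finish(stage, {"smooth_sigma_um": sigma, "softness": softness,
                       "ball_radius_um": ball})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- background ------------------------------------------------------
    stage = "background"
    try:
        bg_mode = config.background.get("mode", "constant")
        bg_params: dict = {"mode": bg_mode}
        if bg_mode == "constant":
            for col in colonies:
                levels = estimate_background(col["grid"], col["mask"])
                col["grid"] = subtract_constant_background(col["grid"], levels)
                col["background_levels"] = levels
            bg_params["estimator"] = "median outside mask"
        elif bg_mode == "rolling_ball":
            radius = float(config.background.get("ball_radius_um", 30.0))
            for col in colonies:
                col["grid"] = subtract_background(col["grid"], radius)
            bg_params["ball_radius_um"] = radius
        elif bg_mode != "none":
            raise InputError(f"unknown background mode {bg_mode!r}")
        finish(stage, bg_params)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- geometry + centroids -------------------------------------------
    stage = "centroids"
    try:
        min_sep = config.morphometrics.get("min_separation_um")
        if min_sep is None:
            if config.mode == "synthetic":
                min_sep = colonies[0]["spec"].spacing_um
            else:
                min_sep = 8.8
        for col in colonies:
            nominal = (col["spec"].radius_um if col.get("spec") is not None else None)
            col["geometry"] = estimate_center(col["mask"], nominal_radius_um=nominal)
            col["cells"] = detect_cell_centroids(
                col["mask"], col["grid"], nuclear_channel=nuclear_channel,
                min_separation_um=float(min_sep),
            )
            p = mio.write_cells(col["cells"], outdir / f"{col['id']}_cells.csv")
            record(stage, p, "cells")
        finish(stage, {"min_separation_um": float(min_sep)})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- radial profiles -------------------------------------------------
    stage = "profile"
    try:
        bin_width = float(config.profiling.get("bin_width_um", 10.0))
        norm = config.profiling.get("normalization", "raw")
        profiles = []
        for col in colonies:
            prof = radial_profile(col["grid"], col["mask"], col["geometry"],
                                  bin_width_um=bin_width, colony_id=col["id"])
            profiles.append(prof)
            p = mio.write_profile(prof, outdir / f"{col['id']}_profile.csv")
            record(stage, p, "profile")
        avg = average_profiles(profiles)
        if norm != "raw":
            avg = normalize_profile(avg, norm, hoechst_channel=nuclear_channel)
        p = mio.write_profile(avg, outdir / "average_profile.csv")
        record(stage, p, "profile")
        if config.plots:
            from .plotting import plot_radial_profile
            pp = plot_radial_profile(avg, outdir / "average_profile.png")
            record(stage, pp, "plot")
        manifest["average_profile"] = str(outdir / "average_profile.csv")
        finish(stage, {"bin_width_um": bin_width, "normalization": norm})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # -- coexpression ----------------------------------------------------
    stage = "coexpress"
    if config.coexpression is not None:
        try:
            cx = config.coexpression
            ch_a, ch_b = cx["channel_a"], cx["channel_b"]
            quantile = float(cx.get("quantile", 0.99))
            if config.mode == "synthetic":
                # 0 hr reference: same colonies, markers at their baseline level
                from dataclasses import replace as _replace
                base = colonies[0]["spec"]
                ref_models = [
                    _replace(m, level_inside=m.level_outside)
                    for m in base.marker_models
                ]
                ref_spec = _replace(base, marker_models=ref_models)
                ref_grid, _ = generate_colony(ref_spec, keep_clean=False)
                ref_mask = classify_nuclei(ref_grid, nuclear_channel=nuclear_channel)
                ref_desc = "synthetic 0 hr (markers at baseline)"
            else:
                ref_grid = mio.read_stack(cx["reference_stack"])
                ref_mask = (mio.read_mask(cx["reference_mask"],
                                          voxel_spacing_um=ref_grid.voxel_spacing_um)
                            if cx.get("reference_mask")
                            else classify_nuclei(ref_grid, nuclear_channel=nuclear_channel))
                ref_desc = str(cx.get("reference_stack"))
            thr_a = gate_from_reference(ref_grid, ref_mask, ch_a, quantile)
            thr_b = gate_from_reference(ref_grid, ref_mask, ch_b, quantile)
            results = []
            for col in colonies:
                pairs = voxel_pairs(col["grid"], col["mask"], ch_a, ch_b)
                gate = quadrant_percentages(pairs, thr_a, thr_b, reference=ref_desc)
                results.append({"colony_id": col["id"], **gate.to_dict()})
                if config.plots:
                    from .plotting import plot_density_scatter
                    pp = plot_density_scatter(pairs, outdir / f"{col['id']}_coexpr.png", gate)
                    record(stage, pp, "plot")
            path = outdir / "coexpression.json"
            path.write_text(json.dumps(results, indent=2, sort_keys=True) + "\n")
            record(stage, path, "gate")
            finish(stage, {"channel_a": ch_a, "channel_b": ch_b, "quantile": quantile,
                           "reference": ref_desc})
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            fail(stage, exc)

    # -- morphometrics ---------------------------------------------------
    stage = "morphometrics"
    try:
        mm = config.morphometrics
        hbin = float(mm.get("height_bin_width_um", 10.0))
        n_segments = int(mm.get("n_segments", 10))
        strip = float(mm.get("strip_width_um", 12.0))
        rows_h, rows_d, rows_n = [], [], []
        for col in colonies:
            hp = height_profile(col["mask"], col["geometry"], bin_width_um=hbin,
                                colony_id=col["id"])
            for c, h in zip(hp.bin_centers_um, hp.height_um):
                rows_h.append({"colony_id": col["id"], "bin_center_um": c, "height_um": h})
            segs = _chord_segments(col["geometry"].center_um,
                                   col["geometry"].radius_um, n_segments)
            dens = nuclei_per_100um(col["cells"], segs, strip_width_um=strip)
            rows_d.append({"colony_id": col["id"],
                           "nuclei_per_100um": dens.nuclei_per_100um,
                           "positions_sampled": dens.positions_sampled})
            if len(col["cells"]) >= 2:
                nnd = internuclear_distances(col["cells"])
                rows_n.append({"colony_id": col["id"],
                               "mean_nn_um": float(np.mean(nnd)),
                               "median_nn_um": float(np.median(nnd)),
                               "n_cells": len(col["cells"])})
        for name, rows in (("height.csv", rows_h), ("density.csv", rows_d),
                           ("nndist.csv", rows_n)):
            p = mio.write_table(rows, outdir / name)
            record(stage, p, "table")
        finish(stage, {"height_bin_width_um": hbin, "n_segments": n_segments,
                       "strip_width_um": strip})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> Path:
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# fixture presets


def _posterior_spec(diameter=1000.0, seed=0, **kw) -> SyntheticColonySpec:
    """72 hr '+BMP' posterior layout: central epiblast marker, mid
    streak annulus, outer extraembryonic-mesoderm ring."""
    r = diameter / 2
    return SyntheticColonySpec(
        diameter_um=diameter, seed=seed,
        marker_models=[
            MarkerDomainModel("sox2", "center_high", (0.5 * r,), 15.0),
            MarkerDomainModel("brachyury", "annulus", (0.5 * r, 0.8 * r), 15.0),
            MarkerDomainModel("cdx2", "edge_high", (0.8 * r,), 15.0),
        ], **kw,
    )


def _anterior_spec(diameter=1000.0, seed=0, **kw) -> SyntheticColonySpec:
    """72 hr '−BMP' anterior layout: definitive-endoderm markers
    coexpressed at the colony edge."""
    r = diameter / 2
    return SyntheticColonySpec(
        diameter_um=diameter, seed=seed,
        marker_models=[
            MarkerDomainModel("sox2", "center_high", (0.6 * r,), 15.0),
            MarkerDomainModel("sox17", "edge_high", (0.7 * r,), 15.0),
            MarkerDomainModel("foxa2", "edge_high", (0.7 * r,), 15.0),
        ], **kw,
    )


def make_fixtures(preset: str, outdir, seed: int = 0) -> list[Path]:
    """Write a battery of synthetic colonies + ground truth for a preset.

    Presets: 'diameter_series' (80/140/225/500/1000 μm), 'timecourse'
    (0/24/48/72 hr), 'plus_bmp', 'minus_bmp', 'volcano'.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name, grid, truth, spec=None):
        written.extend(mio.write_stack(grid, outdir, basename=name))
        written.append(mio.write_ground_truth(truth, outdir / f"{name}_truth.json"))
        if spec is not None:
            written.append(mio.write_spec(spec, outdir / f"{name}_spec.yaml"))

    if preset == "diameter_series":
        for d in (80.0, 140.0, 225.0, 500.0, 1000.0):
            # small colonies grow as taller aggregates: deepen the stack
            nz = 24 if d <= 140 else 16
            spec = _posterior_spec(diameter=d, seed=seed, n_z_layers=nz)
            grid, truth = generate_colony(spec, keep_clean=False)
            emit(f"diameter_{int(d):04d}um", grid, truth, spec)
    elif preset == "timecourse":
        spec0 = _posterior_spec(seed=seed)
        transitions = {
            "sox2": ChannelTransition([1.0, 0.5, 0.5, 0.5]),
            "brachyury": ChannelTransition([0.02, 1.0, 1.0, 1.0]),
            "cdx2": ChannelTransition([0.02, 0.1, 1.0, 1.0]),
        }
        series = generate_timecourse(spec0, transitions, [0.0, 24.0, 48.0, 72.0])
        for t, (grid, truth) in zip((0, 24, 48, 72), series):
            emit(f"timecourse_{t:02d}hr", grid, truth)
        written.append(mio.write_spec(spec0, outdir / "timecourse_spec.yaml"))
    elif preset == "plus_bmp":
        spec = _posterior_spec(seed=seed)
        grid, truth = generate_colony(spec, keep_clean=False)
        emit("plus_bmp_72hr", grid, truth, spec)
    elif preset == "minus_bmp":
        spec = _anterior_spec(seed=seed)
        grid, truth = generate_colony(spec, keep_clean=False)
        emit("minus_bmp_72hr", grid, truth, spec)
    elif preset == "volcano":
        spec = _posterior_spec(seed=seed, n_z_layers=28,
                               ridge=RidgeModel(350.0, 400.0, n_layers=3))
        grid, truth = generate_colony(spec, keep_clean=False)
        emit("volcano_72hr", grid, truth, spec)
    else:
        raise InputError(f"unknown preset {preset!r}")
    return written
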