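"""Dataset and result formats, configuration presets, run manifests.

Datasets live in a directory holding one multi-page TIFF per z-plane with
frames A and B interleaved, a YAML sidecar with per-pair metadata (dt,
z-index, timestamps, seed, ground-truth parameters) and, for periodic
flows, a phase-anchor CSV ``(timestamp_ms, phase_rad)``.  Vector fields are
written as tidy CSV and as gridded HDF5; similarity-map stacks as HDF5.

Analysis parameters ship as two named presets, ``tube`` and ``heart``,
carrying the published parameter sets for the bead-phantom and zebrafish-
heart experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .engine import PIVConfig, SimilarityMap, VectorField
from .scenes import FramePair, SceneConfig

__all__ = [
    "PRESETS",
    "load_preset",
    "load_run_config",
    "dump_run_config",
    "write_dataset",
    "read_dataset",
    "write_anchors_csv",
    "read_anchors_csv",
    "write_vector_fields_csv",
    "read_vector_fields_csv",
    "write_fields_h5",
    "write_map_stack_h5",
    "write_manifest",
]

#: Published parameter sets: bead phantom in a 50 um FEP tube and fRBCs in
#: the ~3 dpf zebrafish heart.
PRESETS: dict[str, dict] = {
    "tube": {
        "scene": {"tube_radius": 25.0, "flow_rate": 0.5,
                  "tracer_diameter": 1.04, "pixel_size": 0.3225,
                  "dt": 0.3, "sheet_fwhm": 2.0,
                  "image_shape": (176, 192), "seeding_density": 1.0},
        "piv": {"small_iw": (32, 12), "large_iw": (128, 16),
                "overlap_fraction": 0.5, "ratio_threshold": 1.10,
                "mask_halfwidth": 3, "dt": 0.3, "pixel_size": 0.3225,
                "binning": 1},
        "n_pairs_per_z": 250, "z_step_um": 2.0,
    },
    "heart": {
        "scene": {"tube_radius": 25.0, "tracer_diameter": 6.0,
                  "pixel_size": 0.3225, "dt": 1.5, "sheet_fwhm": 2.0,
                  "image_shape": (224, 96), "seeding_density": 0.5,
                  "v_max": 2.5},
        "piv": {"small_iw": (24, 24), "large_iw": (72, 48),
                "overlap_fraction": 0.5, "ratio_threshold": 1.07,
                "mask_halfwidth": 3, "dt": 1.5, "pixel_size": 0.3225,
                "binning": 2, "min_iw_intensity": 1e5},
        "n_pairs_per_z": 50, "z_step_um": 8.0, "n_bins": 30,
    },
}


def load_preset(name: str) -> dict:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return json.loads(json.dumps(PRESETS[name]))  # deep copy


def _tupled(d: dict, keys=("image_shape", "small_iw", "large_iw", "ref_iw")):
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def load_run_config(path: str | Path | None = None,
                    preset: str | None = None) -> dict:
    """Assemble a run configuration from a preset and/or a YAML file.

    File entries override preset entries section-by-section; the result
    round-trips losslessly through :func:`dump_run_config`.
    """
    cfg: dict = {"scene": {}, "piv": {}}
    if preset:
        cfg.update(load_preset(preset))
        cfg["preset"] = preset
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if isinstance(values, dict):
                cfg.setdefault(section, {}).update(values)
            else:
                cfg[section] = values
    _tupled(cfg.get("scene", {}))
    _tupled(cfg.get("piv", {}))
    return cfg


def dump_run_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(cfg), fh, sort_keys=True)


def scene_config_from(cfg: dict) -> SceneConfig:
    return SceneConfig(**_tupled(dict(cfg.get("scene", {}))))

def piv_config_from(cfg: dict) -> PIVConfig:
    return PIVConfig(**_tupled(dict(cfg.get("piv", {}))))


# ---------------------------------------------------------------------------
# datasets on disk
# ---------------------------------------------------------------------------

def write_dataset(path: str | Path, pairs: list[FramePair],
                  scene: SceneConfig | None = None,
                  truth_params: dict | None = None,
                  anchors: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """Write frame pairs as per-z interleaved TIFF stacks plus sidecar YAML."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_z: dict[int, list[FramePair]] = {}
    for p in pairs:
        by_z.setdefault(p.z_index, []).append(p)
    meta: dict = {"pairs": [], "files": {}}
    for z_idx, group in sorted(by_z.items()):
        fname = f"z{z_idx:03d}.tif"
        stack = np.stack([f for p in group for f in (p.frame_a, p.frame_b)])
        tifffile.imwrite(path / fname, stack.astype(np.float32),
                         photometric="minisblack")
        meta["files"][int(z_idx)] = fname
        for p in group:
            meta["pairs"].append({
                "pair_id": int(p.pair_id), "z_index": int(p.z_index),
                "z_um": float(p.z_um), "timestamp": float(p.timestamp),
                "dt": float(p.dt),
                "phase": None if p.phase is None else float(p.phase)})
    if scene is not None:
        meta["scene"] = _jsonable(dataclasses.asdict(scene))
    if truth_params is not None:
        meta["truth"] = _jsonable(truth_params)
    with open(path / "dataset.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    if anchors is not None:
        write_anchors_csv(path / "phase_anchors.csv", *anchors)


def read_dataset(path: str | Path) -> tuple[list[FramePair], dict]:
    """Read a dataset directory back into frame pairs and its metadata."""
    path = Path(path)
    sidecar = path / "dataset.yaml"
    if not sidecar.exists():
        raise FileNotFoundError(f"no dataset.yaml in {path}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    stacks = {int(z): tifffile.imread(path / fname)
              for z, fname in meta["files"].items()}
    cursor: dict[int, int] = {z: 0 for z in stacks}
    pairs = []
    for rec in meta["pairs"]:
        z = int(rec["z_index"])
        i = cursor[z]
        cursor[z] += 1
        pairs.append(FramePair(
            frame_a=np.asarray(stacks[z][2 * i], dtype=np.float64),
            frame_b=np.asarray(stacks[z][2 * i + 1], dtype=np.float64),
            dt=float(rec["dt"]), z_index=z, z_um=float(rec["z_um"]),
            timestamp=float(rec["timestamp"]),
            phase=rec.get("phase"), pair_id=int(rec["pair_id"])))
    return pairs, meta


def write_anchors_csv(path: str | Path, timestamps: np.ndarray,
                      phases: np.ndarray) -> None:
    pd.DataFrame({"timestamp_ms": timestamps,
                  "phase_rad": phases}).to_csv(path, index=False)


def read_anchors_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["timestamp_ms"].to_numpy(), df["phase_rad"].to_numpy()


# ---------------------------------------------------------------------------
# results on disk
# ---------------------------------------------------------------------------

def write_vector_fields_csv(path: str | Path,
                            fields: list[VectorField]) -> None:
    """Tidy CSV with one row per interrogation window per field."""
    pd.concat([f.to_dataframe() for f in fields],
              ignore_index=True).to_csv(path, index=False)


def read_vector_fields_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fields_h5(path: str | Path, fields: list[VectorField]) -> None:
    """Gridded arrays per (z, phase-bin) group."""
    with h5py.File(path, "w") as h5:
        for f in fields:
            bin_tag = "steady" if f.phase_bin is None else f"bin{f.phase_bin:03d}"
            g = h5.create_group(f"z{f.z_index:03d}/{bin_tag}")
            for name in ("grid_x", "grid_y", "u", "v", "u_px", "v_px",
                         "ratio"):
                g.create_dataset(name, data=getattr(f, name))
            g.create_dataset("valid", data=f.valid.astype(np.uint8))
            g.create_dataset("excluded", data=f.excluded.astype(np.uint8))
            g.attrs["z_um"] = f.z_um
            g.attrs["n_pairs"] = f.n_pairs


def write_map_stack_h5(path: str | Path,
                       stack: list[tuple[float, SimilarityMap]]) -> None:
    """Similarity-map stack over z (heatmap material for bias inspection)."""
    with h5py.File(path, "w") as h5:
        for i, (z_um, smap) in enumerate(stack):
            g = h5.create_group(f"plane{i:03d}")
            g.create_dataset("values", data=smap.values)
            g.attrs["z_um"] = z_um
            g.attrs["dx0"] = smap.displacement_origin[0]
            g.attrs["dy0"] = smap.displacement_origin[1]
            g.attrs["n_pairs"] = smap.n_contributing_pairs


def write_manifest(path: str | Path, cfg: dict, seed: int | None) -> dict:
    """Write a reproduction manifest (config hash, seed, versions)."""
    import scipy

    from . import __version__

    canonical = yaml.safe_dump(_jsonable(cfg), sort_keys=True)
    manifest = {
        "config": _jsonable(cfg),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "versions": {"spimpiv": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__},
    }
    with open(Path(path), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
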