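"""Readers and writers for the pipeline's standard formats.

NIfTI for volumes and maps (uncompressed ``.nii`` so reruns are
byte-identical — gzip embeds a timestamp), two-column CSV or JSON for the
AIF, ``.npy`` + JSON for trained SOMs, CSV for hit maps and per-fold
reports, JSON for manifests/summaries, PNG for fused RGB probability
slices.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DomainError
from .ksom import HitMap, SOMConfig, SOMGrid, SOMWeights, hex_distances
from .pk_models import AIFCurve, TimeGrid
from .pnms import ProbabilityVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_aif_csv",
    "load_aif_csv",
    "save_aif_json",
    "load_aif_json",
    "save_som",
    "load_som",
    "hitmap_to_csv",
    "load_hitmap_csv",
    "save_manifest",
    "save_rgb_probability_png",
]


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    """Write a 3-D map or 4-D study as NIfTI, preserving dtype.

    The time axis of a 4-D study is the fourth NIfTI dimension.
    """
    path = Path(path)
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_data_dtype(arr.dtype)
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file; returns ``(data, affine)`` in the stored dtype."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def save_aif_csv(path, aif: AIFCurve) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": aif.grid.timepoints, "value": aif.values}).to_csv(
        path, index=False
    )
    return path


def load_aif_csv(path, injection_index: int, retained_start: int = 20) -> AIFCurve:
    df = pd.read_csv(path)
    grid = TimeGrid.from_timepoints(
        df["time_s"].to_numpy(), injection_index, retained_start
    )
    return AIFCurve(values=df["value"].to_numpy(), grid=grid)


def save_aif_json(path, aif: AIFCurve) -> Path:
    """JSON AIF with the time-grid metadata embedded as a sidecar block."""
    path = Path(path)
    payload = {
        "grid": {
            "n_frames": aif.grid.n_frames,
            "dt": aif.grid.dt,
            "t0": aif.grid.t0,
            "injection_index": aif.grid.injection_index,
            "retained_start": aif.grid.retained_start,
        },
        "values": aif.values.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_aif_json(path) -> AIFCurve:
    payload = json.loads(Path(path).read_text())
    grid = TimeGrid(**payload["grid"])
    return AIFCurve(values=np.asarray(payload["values"], dtype=float), grid=grid)


def save_som(basepath, weights: SOMWeights) -> tuple[Path, Path]:
    """Persist a trained SOM as ``<base>_weights.npy`` + ``<base>_meta.json``
    (prototype matrix, config, lattice coordinates)."""
    base = Path(basepath)
    wpath = base.with_name(base.name + "_weights.npy")
    mpath = base.with_name(base.name + "_meta.json")
    np.save(wpath, weights.weights)
    meta = {
        "config": {
            "rows": weights.config.rows,
            "cols": weights.config.cols,
            "layout": weights.config.layout,
            "initial_radius": weights.config.initial_radius,
            "ordering_steps": weights.config.ordering_steps,
            "max_epochs": weights.config.max_epochs,
            "training_mode": weights.config.training_mode,
            "init": weights.config.init,
            "seed": weights.config.seed,
        },
        "positions": weights.grid.positions.tolist(),
    }
    mpath.write_text(json.dumps(meta, indent=1))
    return wpath, mpath


def load_som(basepath) -> SOMWeights:
    base = Path(basepath)
    w = np.load(base.with_name(base.name + "_weights.npy"))
    meta = json.loads(base.with_name(base.name + "_meta.json").read_text())
    config = SOMConfig(**meta["config"])
    return SOMWeights(weights=w, config=config, grid=hex_distances(config))


def hitmap_to_csv(path, hitmap: HitMap, config: SOMConfig) -> Path:
    """One row per neuron: lattice row/col, total hits, per-label hits."""
    if hitmap.total.shape[0] != config.n_neurons:
        raise DomainError("hit map size does not match SOM config")
    r, c = np.divmod(np.arange(config.n_neurons), config.cols)
    pd.DataFrame({
        "neuron_row": r,
        "neuron_col": c,
        "hits_total": hitmap.total,
        "hits_m1": hitmap.per_label[:, 0],
        "hits_m2": hitmap.per_label[:, 1],
        "hits_m3": hitmap.per_label[:, 2],
    }).to_csv(path, index=False)
    return Path(path)


def load_hitmap_csv(path) -> HitMap:
    df = pd.read_csv(path)
    per_label = df[["hits_m1", "hits_m2", "hits_m3"]].to_numpy(dtype=np.int64)
    return HitMap(total=df["hits_total"].to_numpy(dtype=np.int64),
                  per_label=per_label)


def save_manifest(path, payload: dict) -> Path:
    """Deterministic provenance manifest (sorted keys, no timestamps)."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
    return path


def save_rgb_probability_png(path, prob: ProbabilityVolume, z: int) -> Path:
    """Fused probability rendering of one slice: Model 3 -> red,
    Model 2 -> green, Model 1 -> blue."""
    nz = prob.p1.shape[2]
    if not 0 <= z < nz:
        raise DomainError(f"slice {z} outside [0, {nz})")
    rgb = np.stack(
        [prob.p3[:, :, z], prob.p2[:, :, z], prob.p1[:, :, z]], axis=-1
    )
    img = Image.fromarray((np.clip(rgb, 0, 1) * 255).astype(np.uint8), mode="RGB")
    img.save(Path(path))
    return Path(path)
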