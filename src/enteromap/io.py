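"""Persistence: TIFF stacks with calibration, CSV/JSON for patterns,
STMs, CIF maps and event tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .cif import CIFMap, ZScoreResult
from .imaging import ImageStack
from .motility import STM, ContractionEvent
from .points import PointPattern

__all__ = [
    "save_stack", "load_stack",
    "save_pattern", "load_pattern",
    "save_stm", "load_stm",
    "save_cifmap", "load_cifmap",
    "events_to_frame", "save_events",
    "save_zscore", "load_zscore",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(path, stack: ImageStack) -> None:
    """Write an ImageStack as multi-page TIFF plus a JSON sidecar.

    Pages are ordered channel-major, z within channel; the sidecar
    records channel names, shapes and calibration.
    """
    path = Path(path)
    pages = []
    names = []
    for name, vol in stack.channels.items():
        vol = np.asarray(vol, dtype=np.float32)
        pages.append(vol)
        names.append(name)
    data = np.concatenate(pages, axis=0)
    tifffile.imwrite(path, data, photometric="minisblack",
                     resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size))
    meta = {
        "channels": names,
        "nz": int(pages[0].shape[0]),
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "meta": _jsonable(stack.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def load_stack(path) -> ImageStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    nz = meta["nz"]
    channels = {name: data[i * nz:(i + 1) * nz]
                for i, name in enumerate(meta["channels"])}
    return ImageStack(channels=channels,
                      pixel_size=meta["pixel_size_um"],
                      z_step=meta["z_step_um"],
                      meta=meta.get("meta", {}))


def save_pattern(path, pattern: PointPattern) -> None:
    """Point pattern to CSV (one row per soma) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"x_um": pattern.points[:, 0],
                       "y_um": pattern.points[:, 1]})
    if pattern.depth is not None:
        df["depth_um"] = pattern.depth
    for name, lab in pattern.labels.items():
        df[f"label_{name}"] = np.asarray(lab, dtype=int)
    df.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({
        "window_um": list(pattern.window),
        "meta": _jsonable(pattern.meta),
    }, indent=2))


def load_pattern(path) -> PointPattern:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    labels = {c[len("label_"):]: df[c].values.astype(bool)
              for c in df.columns if c.startswith("label_")}
    return PointPattern(
        points=df[["x_um", "y_um"]].values,
        window=tuple(meta["window_um"]),
        labels=labels,
        depth=df["depth_um"].values if "depth_um" in df else None,
        meta=meta.get("meta", {}),
    )


def save_stm(path, stm: STM) -> None:
    path = Path(path)
    tifffile.imwrite(path, stm.diameter_um.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "frame_rate": stm.frame_rate,
        "bin_um": stm.bin_um,
        "condition": stm.condition,
        "valid": stm.valid.astype(int).tolist(),
        "meta": _jsonable(stm.meta),
    }, indent=2))


def load_stm(path) -> STM:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    return STM(tifffile.imread(path),
               frame_rate=meta["frame_rate"], bin_um=meta["bin_um"],
               condition=meta["condition"],
               valid=np.asarray(meta["valid"], dtype=bool),
               meta=meta.get("meta", {}))


def save_cifmap(path, cif: CIFMap) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.stack([
        cif.raw.astype(np.float32),
        cif.weights.astype(np.float32),
        cif.corrected.astype(np.float32),
        cif.smoothed.astype(np.float32),
    ]), photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "L": cif.L, "bin_size": cif.bin_size, "n_ref": cif.n_ref,
        "smooth_sd": cif.smooth_sd, "per_reference": cif.per_reference,
        "planes": ["raw", "weights", "corrected", "smoothed"],
        "meta": _jsonable(cif.meta),
    }, indent=2))


def load_cifmap(path) -> CIFMap:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    planes = tifffile.imread(path)
    return CIFMap(L=meta["L"], bin_size=meta["bin_size"],
                  raw=planes[0].astype(np.int64), weights=planes[1],
                  corrected=planes[2], smoothed=planes[3],
                  n_ref=meta["n_ref"], smooth_sd=meta["smooth_sd"],
                  per_reference=meta["per_reference"],
                  meta=meta.get("meta", {}))


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(dict(onset_s=e.onset_s, origin_um=e.origin_um,
                         direction=e.direction,
                         velocity_um_s=e.velocity_um_s,
                         amplitude_um=e.amplitude_um,
                         duration_s=e.duration_s))
    return pd.DataFrame(rows, columns=["onset_s", "origin_um", "direction",
                                       "velocity_um_s", "amplitude_um",
                                       "duration_s"])


def save_events(path, events) -> None:
    events_to_frame(events).to_csv(path, index=False)


def save_zscore(path, z: ZScoreResult) -> None:
    Path(path).write_text(json.dumps({
        "statistic": z.statistic, "null_mean": z.null_mean,
        "null_sd": z.null_sd, "z_data": z.z_data,
        "z_diff": z.z_diff, "null_band": list(z.null_band),
        "null_z": np.asarray(z.null_z).tolist(),
        "n_sim": z.n_sim, "d_min": z.d_min, "seed": z.seed,
    }, indent=2))


def load_zscore(path) -> ZScoreResult:
    d = json.loads(Path(path).read_text())
    return ZScoreResult(
        statistic=d["statistic"], null_mean=d["null_mean"],
        null_sd=d["null_sd"], z_data=d["z_data"],
        null_z=np.asarray(d["null_z"]), z_diff=d["z_diff"],
        null_band=tuple(d["null_band"]), n_sim=d["n_sim"],
        d_min=d["d_min"], seed=d["seed"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
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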