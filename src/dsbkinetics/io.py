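"""CSV/TIFF/JSON round-trips for traces, curves, images, and fit reports.

CSV schemas:
  FRAP record       : time_s, roi, reference, background
  normalized curve  : time_s, value
  intensity trace   : time_s, counts
  correlation curve : lag_s, g [, se]

Columns are validated by name; missing columns, non-numeric cells, and
non-monotone time/lag grids are rejected with the offending column named.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fcs import CorrelationCurve, IntensityTrace
from .frap import FrapRecord, NormalizedFrapCurve
from .imaging import ImageStack, RoiMasks

__all__ = [
    "write_frap_record",
    "read_frap_record",
    "write_curve",
    "read_curve",
    "write_trace",
    "read_trace",
    "write_correlation",
    "read_correlation",
    "write_stack",
    "read_stack",
    "write_masks",
    "read_masks",
    "write_json",
    "read_json",
]


class SchemaError(ValueError):
    """A tabular file does not match its declared schema."""


def _read_table(path, required: list[str], monotone: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(f"{path}: non-numeric cell in column {col!r} at row {row}")
        df[col] = vals.astype(float)
    if monotone is not None:
        if not np.all(np.diff(df[monotone].to_numpy()) > 0):
            raise SchemaError(f"{path}: column {monotone!r} must be strictly increasing")
    return df


def write_frap_record(path, record: FrapRecord) -> None:
    df = pd.DataFrame(
        {
            "time_s": record.time,
            "roi": record.roi_trace,
            "reference": record.reference_trace,
            "background": record.background_trace,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "bleach_index": int(record.bleach_index),
        "bleach_area_um2": None if record.bleach_area is None else float(record.bleach_area),
        "protocol_tag": record.protocol_tag,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_frap_record(path) -> FrapRecord:
    df = _read_table(path, ["time_s", "roi", "reference", "background"], monotone="time_s")
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"{path}: missing sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    return FrapRecord(
        time=df["time_s"].to_numpy(),
        roi_trace=df["roi"].to_numpy(),
        reference_trace=df["reference"].to_numpy(),
        background_trace=df["background"].to_numpy(),
        bleach_index=int(meta["bleach_index"]),
        bleach_area=meta.get("bleach_area_um2"),
        protocol_tag=meta.get("protocol_tag", "whole-nucleus-correction"),
    )


def write_curve(path, curve: NormalizedFrapCurve) -> None:
    pd.DataFrame({"time_s": curve.time_post_bleach, "value": curve.value}).to_csv(
        path, index=False
    )


def read_curve(path, bleach_area: float | None = None) -> NormalizedFrapCurve:
    df = _read_table(path, ["time_s", "value"], monotone="time_s")
    return NormalizedFrapCurve(
        time_post_bleach=df["time_s"].to_numpy(),
        value=df["value"].to_numpy(),
        bleach_area=bleach_area,
    )


def write_trace(path, trace: IntensityTrace) -> None:
    t = np.arange(trace.n_bins) * trace.sample_interval
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)


def read_trace(path) -> IntensityTrace:
    df = _read_table(path, ["time_s", "counts"], monotone="time_s")
    t = df["time_s"].to_numpy()
    dt = float(np.median(np.diff(t)))
    return IntensityTrace(sample_interval=dt, counts=df["counts"].to_numpy())


def write_correlation(path, curve: CorrelationCurve) -> None:
    data = {"lag_s": curve.lag, "g": curve.g}
    if curve.se is not None:
        data["se"] = curve.se
    pd.DataFrame(data).to_csv(path, index=False)


def read_correlation(path) -> CorrelationCurve:
    df = _read_table(path, ["lag_s", "g"], monotone="lag_s")
    se = df["se"].to_numpy() if "se" in df.columns else None
    return CorrelationCurve(lag=df["lag_s"].to_numpy(), g=df["g"].to_numpy(), se=se)


def write_stack(path_prefix, stack: ImageStack) -> dict:
    """Write one multi-page TIFF per channel plus a JSON config; returns the config."""
    prefix = Path(path_prefix)
    cfg = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "damage_frame": stack.damage_frame,
        "channel_map": {},
    }
    for role, arr in stack.channels.items():
        p = prefix.with_name(prefix.name + f"_{role}.tif")
        tifffile.imwrite(p, arr.astype(np.float32), photometric="minisblack")
        cfg["channel_map"][role] = p.name
    cfg_path = prefix.with_name(prefix.name + "_config.json")
    cfg_path.write_text(json.dumps(cfg, indent=1))
    return cfg


def read_stack(config_path) -> ImageStack:
    cfg_path = Path(config_path)
    cfg = json.loads(cfg_path.read_text())
    channels = {
        role: tifffile.imread(cfg_path.parent / fname).astype(float)
        for role, fname in cfg["channel_map"].items()
    }
    return ImageStack(
        channels=channels,
        pixel_size=float(cfg["pixel_size_um"]),
        frame_interval=float(cfg["frame_interval_s"]),
        damage_frame=int(cfg["damage_frame"]),
    )


def write_masks(path_prefix, masks: RoiMasks) -> None:
    prefix = Path(path_prefix)
    for name in ("damage", "nucleus", "background"):
        arr = getattr(masks, name).astype(np.uint8)
        tifffile.imwrite(prefix.with_name(prefix.name + f"_{name}.tif"), arr)


def read_masks(path_prefix) -> RoiMasks:
    prefix = Path(path_prefix)
    arrays = {
        name: tifffile.imread(prefix.with_name(prefix.name + f"_{name}.tif")).astype(bool)
        for name in ("damage", "nucleus", "background")
    }
    return RoiMasks(**arrays)


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
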