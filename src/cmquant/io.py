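"""Readers and writers for the package's on-disk formats.

All tabular formats are plain CSV (pandas); image stacks and single-channel
images are TIFF (tifffile, 16-bit grayscale). Columns:

- trace CSV: ``time_s,value``
- ROI CSV: ``roi_id,x,y,width,height`` (0-based pixels, half-open bounds)
- respirometry: ``time_s,o2_nmol_per_ml`` plus an events sidecar
  ``time_s,label``
- onset table: ``replicate,group,well,onset_day`` (empty onset_day = never)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .contractility import IntensityTrace
from .respirometry import RespTrace

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace_csv",
    "write_trace_csv",
    "read_roi_csv",
    "read_resp_csv",
    "write_resp_csv",
    "read_onset_csv",
    "write_onset_csv",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Multi-frame grayscale TIFF as a (frames, height, width) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel image stack")
    return arr


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_trace_csv(path: str | Path, well_id: str = "", roi_id: str = "") -> IntensityTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: trace CSV must have columns time_s,value")
    return IntensityTrace(
        times=df["time_s"].to_numpy(float),
        values=df["value"].to_numpy(float),
        well_id=well_id,
        roi_id=roi_id,
    )


def write_trace_csv(path: str | Path, trace: IntensityTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        path, index=False
    )


def read_roi_csv(path: str | Path) -> list[tuple[str, tuple[int, int, int, int]]]:
    """ROI definitions as ``[(roi_id, (x, y, width, height)), ...]``."""
    df = pd.read_csv(path)
    required = {"roi_id", "x", "y", "width", "height"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: ROI CSV must have columns {sorted(required)}")
    return [
        (str(row.roi_id), (int(row.x), int(row.y), int(row.width), int(row.height)))
        for row in df.itertuples()
    ]


def read_resp_csv(
    trace_path: str | Path, events_path: str | Path, cell_density: float = 1.0
) -> RespTrace:
    df = pd.read_csv(trace_path)
    if not {"time_s", "o2_nmol_per_ml"}.issubset(df.columns):
        raise ValueError(
            f"{trace_path}: respirometry CSV must have columns time_s,o2_nmol_per_ml"
        )
    ev = pd.read_csv(events_path)
    if not {"time_s", "label"}.issubset(ev.columns):
        raise ValueError(f"{events_path}: events CSV must have columns time_s,label")
    return RespTrace(
        times=df["time_s"].to_numpy(float),
        o2=df["o2_nmol_per_ml"].to_numpy(float),
        events=tuple((float(t), str(l)) for t, l in zip(ev["time_s"], ev["label"])),
        cell_density=cell_density,
    )


def write_resp_csv(
    trace_path: str | Path, events_path: str | Path, trace: RespTrace
) -> None:
    pd.DataFrame({"time_s": trace.times, "o2_nmol_per_ml": trace.o2}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(
        {"time_s": [t for t, _ in trace.events], "label": [l for _, l in trace.events]}
    ).to_csv(events_path, index=False)


def read_onset_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"replicate": str, "group": str, "well": str})
    required = {"replicate", "group", "well", "onset_day"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: onset CSV must have columns {sorted(required)}")
    df["onset_day"] = pd.array(
        [pd.NA if pd.isna(v) else int(v) for v in df["onset_day"]], dtype="Int64"
    )
    return df


def write_onset_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
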