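"""Reading and writing the pipeline's on-disk formats.

Micrographs travel as multi-page TIFF (one page per channel, float32) with a
JSON sidecar recording the channel roles, pixel size and metadata; ROI traces
travel as wide CSV (``time_s`` plus one column per ROI) with a JSON sidecar
for the stimulus time and group labels.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import Micrograph
from .kinetics import CalciumTrace

__all__ = [
    "write_micrograph",
    "read_micrograph",
    "write_traces",
    "read_traces",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_micrograph(micro: Micrograph, path: str | Path) -> Path:
    """Write a multichannel micrograph as multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    roles = list(micro.channels)
    stack = np.stack([np.asarray(micro.channels[r], dtype=np.float32) for r in roles])
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = {
        "channel_roles": roles,
        "pixel_size_um": micro.pixel_size_um,
        "metadata": _jsonable(micro.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_micrograph(
    path: str | Path, channel_roles: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
) -> Micrograph:
    """Read a multi-page TIFF micrograph; the sidecar supplies roles if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"micrograph not found: {path}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        channel_roles = channel_roles or side.get("channel_roles")
        pixel_size_um = pixel_size_um or side.get("pixel_size_um")
        meta = side.get("metadata", {})
    if channel_roles is None:
        channel_roles = ["nuclei"] + [f"marker_{i}" for i in range(1, len(stack))]
    if pixel_size_um is None:
        raise ValueError(f"pixel size for {path} not given and no sidecar found")
    if len(channel_roles) != len(stack):
        raise ValueError(
            f"{path}: {len(stack)} pages but {len(channel_roles)} channel roles"
        )
    channels = {r: np.asarray(stack[i], dtype=float) for i, r in enumerate(channel_roles)}
    return Micrograph(channels=channels, pixel_size_um=float(pixel_size_um), metadata=meta)


def write_traces(traces: Sequence[CalciumTrace], path: str | Path) -> Path:
    """Write ROI traces as wide CSV (time_s, roi_1...) plus JSON sidecar."""
    path = Path(path)
    if not traces:
        raise ValueError("no traces to write")
    t0 = traces[0].time_s
    for tr in traces:
        if tr.time_s.shape != t0.shape or not np.allclose(tr.time_s, t0):
            raise ValueError("all traces must share one time base for wide CSV")
    df = pd.DataFrame({"time_s": t0})
    for tr in traces:
        df[tr.roi_id] = tr.f
    df.to_csv(path, index=False, float_format="%.10g")
    side = {
        "stimulus_time_s": traces[0].stimulus_time_s,
        "roi_metadata": {tr.roi_id: _jsonable(tr.metadata) for tr in traces},
    }
    _sidecar(path).write_text(json.dumps(side, indent=2, sort_keys=True))
    return path


def read_traces(
    path: str | Path, stimulus_time_s: float | None = None
) -> list[CalciumTrace]:
    """Read a wide trace CSV back into per-ROI traces."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: wide trace CSV needs a 'time_s' column")
    side: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        side = json.loads(sc.read_text())
    stim = stimulus_time_s if stimulus_time_s is not None else side.get(
        "stimulus_time_s", 20.0
    )
    roi_meta = side.get("roi_metadata", {})
    t = df["time_s"].to_numpy(dtype=float)
    return [
        CalciumTrace(
            time_s=t,
            f=df[col].to_numpy(dtype=float),
            stimulus_time_s=float(stim),
            roi_id=col,
            metadata=dict(roi_meta.get(col, {})),
        )
        for col in df.columns
        if col != "time_s"
    ]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
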