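"""TIFF movie reading/writing and event-table output."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import DivisionEvent, FrameStack, InterphaseEvent

__all__ = ["read_movie", "write_movie", "write_label_masks",
           "events_to_frames", "write_event_tables"]


def read_movie(path, interval_min: float, bit_depth: int = 12) -> FrameStack:
    """Read a movie from a multi-page TIFF or a directory of frame TIFFs.

    Frames in a directory are ordered by sorted filename.  All frames must
    share one shape.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir()
                       if q.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF frames found in {p}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        arr = np.stack(frames)
    else:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("expected single-channel 2-D frames")
    return FrameStack(frames=arr, interval_min=interval_min, bit_depth=bit_depth)


def write_movie(stack: FrameStack, path) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.uint16))


def write_label_masks(masks: Sequence, path) -> None:
    """Write per-frame label rasters as one 16-bit multi-page TIFF."""
    arr = np.stack([m.labels for m in masks]).astype(np.uint16)
    tifffile.imwrite(path, arr)


def events_to_frames(divisions: Sequence[DivisionEvent],
                     interphases: Sequence[InterphaseEvent],
                     interval_min: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    div = pd.DataFrame(
        [{"trace_id": e.trace_id, "fmax": e.fmax, "fmin": e.fmin,
          "ipt_frame": e.ipt, "mat_frame": e.mat,
          "entry_time_min": e.ipt * interval_min,
          "mitotic_duration_min": e.mitotic_duration} for e in divisions],
        columns=["trace_id", "fmax", "fmin", "ipt_frame", "mat_frame",
                 "entry_time_min", "mitotic_duration_min"])
    inter = pd.DataFrame(
        [{"trace_id": e.trace_id, "start_frame": e.start, "end_frame": e.end,
          "start_time_min": e.start * interval_min,
          "interphase_duration_min": e.duration} for e in interphases],
        columns=["trace_id", "start_frame", "end_frame", "start_time_min",
                 "interphase_duration_min"])
    return div, inter


def write_event_tables(divisions, interphases, interval_min: float,
                       out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    div, inter = events_to_frames(divisions, interphases, interval_min)
    div.to_csv(out / "mitotic_events.csv", index=False)
    inter.to_csv(out / "interphase_events.csv", index=False)
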