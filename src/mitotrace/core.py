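"""Core data containers shared across the pipeline.

The central object is the :class:`Trace` — a single nucleus followed over
time.  When a division occurs, each daughter nucleus is tracked
independently, so one division produces two traces that share the full
pre-division history of the parent and differ only after anaphase.  The
only two per-frame features the time-series analysis consumes are the
nuclear area ``A`` (pixels) and the average intensity ``I`` (grey levels
over the nucleus mask); everything else is carried along for tracking and
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrameStack",
    "Trace",
    "DivisionEvent",
    "InterphaseEvent",
    "traces_to_frame",
    "traces_from_frame",
    "read_traces_csv",
    "write_traces_csv",
]


@dataclass
class FrameStack:
    """An ordered stack of single-channel grey-level frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.
    interval_min
        Acquisition interval in minutes per frame; must be positive.
    bit_depth
        Camera bit depth (values occupy ``[0, 2**bit_depth - 1]``).
    """

    frames: np.ndarray
    interval_min: float
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def subsample(self, every: int) -> "FrameStack":
        """Keep frames ``0, every, 2*every, ...`` and scale the interval."""
        if every < 1:
            raise ValueError("subsampling factor must be >= 1")
        return FrameStack(
            frames=self.frames[::every].copy(),
            interval_min=self.interval_min * every,
            bit_depth=self.bit_depth,
        )


@dataclass
class Trace:
    """One nucleus (and, past a division, one chosen daughter) over time.

    ``segments`` records the lineage composition of the trace as
    ``(segment_id, start_frame, end_frame)`` triples (end inclusive).  Two
    sibling daughter traces share every segment up to the division and
    differ in the last one; downstream event de-duplication keys on the
    segment that contains a detected event.
    """

    trace_id: str
    frames: np.ndarray
    area: np.ndarray
    intensity: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    parent_trace_id: str | None = None
    complete: bool = True
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    extras: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.area = np.asarray(self.area, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frames)
        if not (len(self.area) == len(self.intensity) == n):
            raise ValueError("frames, area and intensity must have equal length")
        if n and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def segment_at(self, frame: int) -> str:
        """Lineage segment id covering ``frame`` (falls back to trace id)."""
        for seg_id, start, end in self.segments:
            if start <= frame <= end:
                return seg_id
        return self.trace_id

    def subsample(self, every: int) -> "Trace":
        """Retain records at original frames ``0, every, 2*every, ...``.

        Frame indices are renumbered consecutively so that all TSA window
        parameters keep operating in (new) frame units; callers must scale
        the acquisition interval accordingly.
        """
        if every < 1:
            raise ValueError("subsampling factor must be >= 1")
        keep = np.where(self.frames % every == 0)[0]
        segs = [
            (sid, int(np.ceil(s / every)), e // every)
            for sid, s, e in self.segments
        ]
        return Trace(
            trace_id=self.trace_id,
            frames=self.frames[keep] // every,
            area=self.area[keep].copy(),
            intensity=self.intensity[keep].copy(),
            x=None if self.x is None else self.x[keep].copy(),
            y=None if self.y is None else self.y[keep].copy(),
            parent_trace_id=self.parent_trace_id,
            complete=self.complete,
            segments=[s for s in segs if s[1] <= s[2]],
            extras=None if self.extras is None else self.extras.iloc[keep].reset_index(drop=True),
        )


@dataclass(frozen=True)
class DivisionEvent:
    """One detected mitosis on a trace.

    ``mitotic_duration`` is ``(MAT - IPT) * interval_min`` minutes; the IPT
    is the last interphase frame and the MAT the first anaphase frame.
    """

    trace_id: str
    fmax: int
    fmin: int
    ipt: int
    mat: int
    mitotic_duration: float
    dedup_key: tuple = ()

    @property
    def duration_frames(self) -> int:
        return self.mat - self.ipt


@dataclass(frozen=True)
class InterphaseEvent:
    """Interphase between two successive divisions of the same trace."""

    trace_id: str
    start: int  # MAT of division k
    end: int    # IPT of division k + 1
    duration: float  # minutes
    dedup_key: tuple = ()


# ---------------------------------------------------------------------------
# Tabular round-trips (one row per trace per frame)

_TRACE_COLUMNS = ["trace_id", "frame", "area_px", "mean_intensity", "x", "y",
                  "segment_id", "parent_trace_id", "complete"]


def traces_to_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        n = len(tr)
        rows.append(pd.DataFrame({
            "trace_id": tr.trace_id,
            "frame": tr.frames,
            "area_px": tr.area,
            "mean_intensity": tr.intensity,
            "x": tr.x if tr.x is not None else np.full(n, np.nan),
            "y": tr.y if tr.y is not None else np.full(n, np.nan),
            # lineage segment per frame, so divisions shared by sibling
            # traces stay identifiable after a CSV round-trip
            "segment_id": [tr.segment_at(int(f)) for f in tr.frames],
            "parent_trace_id": tr.parent_trace_id or "",
            "complete": tr.complete,
        }))
    if not rows:
        return pd.DataFrame(columns=_TRACE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def _segments_from_column(frames: np.ndarray, seg_ids) -> list[tuple[str, int, int]]:
    segs: list[tuple[str, int, int]] = []
    for f, sid in zip(frames, seg_ids):
        if segs and segs[-1][0] == sid:
            segs[-1] = (sid, segs[-1][1], int(f))
        else:
            segs.append((str(sid), int(f), int(f)))
    return segs


def traces_from_frame(df: pd.DataFrame) -> list[Trace]:
    traces = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        parent = str(grp["parent_trace_id"].iloc[0]) if "parent_trace_id" in grp else ""
        frames = grp["frame"].to_numpy()
        segments = (_segments_from_column(frames, grp["segment_id"].astype(str))
                    if "segment_id" in grp else [])
        traces.append(Trace(
            trace_id=str(tid),
            frames=frames,
            area=grp["area_px"].to_numpy(),
            intensity=grp["mean_intensity"].to_numpy(),
            x=grp["x"].to_numpy() if "x" in grp else None,
            y=grp["y"].to_numpy() if "y" in grp else None,
            parent_trace_id=parent or None,
            complete=bool(grp["complete"].iloc[0]) if "complete" in grp else True,
            segments=segments,
        ))
    return traces


def write_traces_csv(traces: Sequence[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> list[Trace]:
    df = pd.read_csv(path)
    if "parent_trace_id" in df:
        df["parent_trace_id"] = df["parent_trace_id"].fillna("").astype(str)
    return traces_from_frame(df)
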