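"""Time-series analysis of nuclear area/intensity traces.

The detector works on only two per-frame features of a tracked nucleus:
area ``A`` (pixels) and average intensity ``I`` (grey levels).  Mitotic
entry condenses chromatin, so ``A`` falls sharply while ``I`` rises; the
area reaches its minimum at anaphase, after which the daughter nucleus
decondenses and ``A`` recovers.  The algorithm exploits exactly this
signature:

1. *Candidate divisions.*  Frames with ``A`` below an absolute threshold
   (default 230 px for HeLa nuclei imaged at 20x with 2x2 binning) mark
   potential mitoses.  The trace is scanned in consecutive
   ``min_window``-frame period windows (cells cannot divide more than once
   per window) and the area minimum of each window below the threshold
   becomes an ``Fmin``; the maximal ``A`` in the ``lookback`` frames before
   it becomes the paired ``Fmax``.
2. *IPT (interphase-prophase transition).*  If any frame between Fmax and
   Fmin shows a single-frame intensity rise ``dI`` above ``di_thresh``,
   the IPT is the such frame closest to Fmin.  Otherwise an area-based
   search looks for the first sustained, spike-free drop ``dA`` below
   ``da_entry_thresh``; candidates where Fmax and Fmin are adjacent frames
   are rejected as too short to be real divisions.
3. *MAT (metaphase-anaphase transition).*  The area minimum within
   ``mat_window`` frames after the IPT; a nucleus that never exits mitosis
   therefore saturates at exactly ``mat_window`` frames of measured
   mitotic duration.

Derivatives are forward differences, ``dX(t) = X(t+1) - X(t)``, so a
transition attaches to the last frame *before* the change: the IPT is the
last interphase frame.  This reproduces the behaviour of manual scoring
when early prophase falls between acquisitions and is the reason measured
mitotic duration grows slightly as the imaging interval grows.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np

from .core import DivisionEvent, InterphaseEvent, Trace

__all__ = [
    "TSAParams",
    "derivatives",
    "remove_error_traces",
    "find_candidate_divisions",
    "find_ipt",
    "find_mat",
    "call_events",
]


@dataclass(frozen=True)
class TSAParams:
    """Tunable thresholds of the transition detector.

    The numbered comments give the order in which the parameters appear in
    the program's input panel; all defaults are for HeLa H2B-GFP nuclei on
    a 12-bit intensity scale.
    """

    area_thresh: float = 230.0          # (1) A below this marks a potential division [px]
    min_window: int = 47                # (2) period window for locating each Fmin [frames]
    lookback: int = 50                  # (3) preceding frames searched for Fmax
    di_thresh: float = 30.0             # (4) dI above this triggers the intensity IPT branch
    da_entry_thresh: float = -50.0      # (5) dA below this marks prophase entry [px/frame]
    spike_guard_pct: float = 120.0      # (6) A(t) must be < this % of A(t-1) (segmentation-spike guard)
    short_mitosis_frames: int = 10      # (7) Fmin-Fmax cutoff choosing between (8) and (9)
    sustained_pct: float = 120.0        # (8) A(t) must exceed this % of every later A..Fmin (short mitoses)
    sustained_pct_long: float = 111.0   # (9) same, for long mitoses
    mat_window: int = 50                # (10) frames after IPT searched for the area minimum
    mat_prevframe_pct: float = 105.0    # (11) previous-frame tolerance for the anaphase-frame correction
    removal_da_thresh: float = 130.0    # single-frame area rise flagging an incorrect trace [px/frame]

    def __post_init__(self) -> None:
        if self.min_window < 1 or self.lookback < 1 or self.mat_window < 1:
            raise ValueError("window parameters must be at least 1 frame")
        if self.da_entry_thresh >= 0:
            raise ValueError("da_entry_thresh must be negative")
        for name in ("spike_guard_pct", "sustained_pct", "sustained_pct_long",
                     "mat_prevframe_pct"):
            if getattr(self, name) <= 100:
                raise ValueError(f"{name} must exceed 100 (percent)")

    def with_overrides(self, **kw) -> "TSAParams":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path) -> "TSAParams":
        """Read ``key = value`` lines; '#' starts a comment."""
        values: dict[str, float] = {}
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                values[key] = float(raw)
        ints = {"min_window", "lookback", "short_mitosis_frames", "mat_window"}
        return cls(**{k: int(v) if k in ints else v for k, v in values.items()})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def derivatives(values: np.ndarray) -> np.ndarray:
    """Forward first difference, defined for t in [0, len-2]."""
    values = np.asarray(values, dtype=float)
    return values[1:] - values[:-1]


# ---------------------------------------------------------------------------
# Trace quality control

def remove_error_traces(
    traces: Sequence[Trace], params: TSAParams = TSAParams()
) -> tuple[list[Trace], list[tuple[Trace, str]]]:
    """Drop traces showing a single-frame area increase above threshold.

    A nucleus has no biological way to gain area abruptly; a large positive
    ``dA`` betrays a segmentation error or two nuclei crossing, and such
    traces yield spurious transitions.  Returns ``(kept, removed)`` where
    each removed entry carries a reason string.
    """
    kept: list[Trace] = []
    removed: list[tuple[Trace, str]] = []
    for tr in traces:
        da = derivatives(tr.area)
        if da.size and float(da.max()) > params.removal_da_thresh:
            removed.append((tr, "area-spike"))
        else:
            kept.append(tr)
    return kept, removed


# ---------------------------------------------------------------------------
# Candidate divisions

def find_candidate_divisions(
    trace: Trace | np.ndarray, params: TSAParams = TSAParams()
) -> list[tuple[int, int]]:
    """Locate (Fmin, Fmax) pairs, each a potential division.

    Returns pairs in time order.  If no area value falls below
    ``area_thresh`` the whole trace is interphase and the list is empty.
    """
    area = trace.area if isinstance(trace, Trace) else np.asarray(trace, float)
    n = len(area)
    if n < 2 or float(area.min()) >= params.area_thresh:
        return []
    pairs: list[tuple[int, int]] = []
    for start in range(0, n, params.min_window):
        window = area[start:start + params.min_window]
        fmin = start + int(np.argmin(window))  # earliest index on ties
        if area[fmin] >= params.area_thresh:
            continue
        lo = max(0, fmin - params.lookback)
        if lo == fmin:
            continue  # Fmin at the first frame: no preceding frames
        fmax = lo + int(np.argmax(area[lo:fmin]))
        pairs.append((fmin, fmax))
    return pairs


# ---------------------------------------------------------------------------
# IPT

def find_ipt(
    trace: Trace,
    fmax: int,
    fmin: int,
    params: TSAParams = TSAParams(),
) -> int | None:
    """Interphase-prophase transition for one candidate, or ``None``.

    Intensity branch: the frame closest to Fmin (within the Fmax..Fmin
    window) whose ``dI`` exceeds ``di_thresh``.  Area branch (used when no
    such intensity rise exists): candidates with Fmin adjacent to Fmax are
    rejected outright; otherwise the first frame after Fmax with
    ``dA < da_entry_thresh`` that (i) is not preceded by a single-frame
    area spike and (ii) stays substantially above every subsequent area
    value through Fmin.  ``None`` rejects the candidate pair.
    """
    if not 0 <= fmax < fmin < len(trace):
        raise ValueError("need Fmax < Fmin within the trace")
    area, intens = trace.area, trace.intensity
    di = derivatives(intens)
    da = derivatives(area)

    # Intensity branch: dI(t) is the change from frame t to t+1, so frames
    # t in [fmax, fmin-1] cover every transition between Fmax and Fmin.
    # A spike on Fmax itself (the rise happens straight off the area
    # maximum) is clamped forward one frame so that Fmax < IPT holds.
    spike_frames = [
        t for t in range(fmax, fmin)
        if t < di.size and di[t] > params.di_thresh
    ]
    if spike_frames:
        return max(spike_frames[-1], fmax + 1)  # closest to Fmin

    # Area branch.
    if fmin == fmax + 1:
        return None  # sequential frames: too short to be a real division
    q = (params.sustained_pct if (fmin - fmax) <= params.short_mitosis_frames
         else params.sustained_pct_long) / 100.0
    guard = params.spike_guard_pct / 100.0
    for t in range(fmax + 1, fmin):
        if t >= da.size or da[t] >= params.da_entry_thresh:
            continue
        if not area[t] < guard * area[t - 1]:
            continue  # artifactual spike in A just before the drop
        if np.all(area[t] > q * area[t + 1:fmin + 1]):
            return t
    return None


# ---------------------------------------------------------------------------
# MAT

def find_mat(
    trace: Trace,
    ipt: int,
    params: TSAParams = TSAParams(),
) -> int | None:
    """Metaphase-anaphase transition: area minimum after the IPT.

    Searches ``(IPT, IPT + mat_window]`` clamped to the trace, which caps
    measured mitotic duration at ``mat_window`` frames for cells that
    arrest in mitosis.  When the located minimum is a strict local minimum
    whose previous frame lies within ``mat_prevframe_pct`` of it, the
    minimum sits on the *second* frame of anaphase (the daughters were not
    yet separable one frame earlier) and the MAT is moved one frame back.
    Returns ``None`` when the trace ends at the IPT.
    """
    n = len(trace)
    if not 0 <= ipt < n:
        raise ValueError("IPT outside trace")
    hi = min(ipt + params.mat_window, n - 1)
    if hi <= ipt:
        return None
    area = trace.area
    window = area[ipt + 1:hi + 1]
    mat = ipt + 1 + int(np.argmin(window))
    if mat == n - 1 and hi < ipt + params.mat_window:
        # the movie ended inside a truncated search window with the area
        # still at its running minimum: anaphase was never observed
        return None
    is_local_min = mat + 1 < n and area[mat + 1] > area[mat]
    if (
        is_local_min
        and mat - 1 > ipt
        and area[mat - 1] <= params.mat_prevframe_pct / 100.0 * area[mat]
    ):
        mat -= 1
    return mat


# ---------------------------------------------------------------------------
# Event assembly

def analyze_trace(
    trace: Trace, params: TSAParams = TSAParams()
) -> list[tuple[int, int, int, int]]:
    """Run the three detectors on one trace.

    Returns ``(fmax, fmin, ipt, mat)`` tuples, de-duplicated on IPT (two
    period windows straddling one narrow area dip can yield two candidate
    pairs for the same division).
    """
    out: list[tuple[int, int, int, int]] = []
    seen_ipt: set[int] = set()
    for fmin, fmax in find_candidate_divisions(trace, params):
        ipt = find_ipt(trace, fmax, fmin, params)
        if ipt is None or ipt in seen_ipt:
            continue
        mat = find_mat(trace, ipt, params)
        if mat is None:
            continue
        seen_ipt.add(ipt)
        out.append((fmax, fmin, ipt, mat))
    return out


def call_events(
    traces: Iterable[Trace],
    params: TSAParams = TSAParams(),
    interval_min: float = 12.0,
) -> tuple[list[DivisionEvent], list[InterphaseEvent]]:
    """Detect division and interphase events across a set of traces.

    Sibling daughter traces share the parent's history, so a division is
    detected once per daughter; events are de-duplicated by the lineage
    segment active at the IPT (which lies in the shared pre-division
    history) together with the IPT frame.  Interphase events (MAT of one
    division to IPT of the next) require at least two divisions in a trace.
    """
    divisions: list[DivisionEvent] = []
    interphases: list[InterphaseEvent] = []
    seen_div: set[tuple] = set()
    seen_inter: set[tuple] = set()
    for tr in traces:
        found = analyze_trace(tr, params)
        events: list[DivisionEvent] = []
        for fmax, fmin, ipt, mat in found:
            key = (tr.segment_at(ipt), ipt)
            ev = DivisionEvent(
                trace_id=tr.trace_id, fmax=fmax, fmin=fmin, ipt=ipt, mat=mat,
                mitotic_duration=(mat - ipt) * interval_min, dedup_key=key,
            )
            events.append(ev)
            if key not in seen_div:
                seen_div.add(key)
                divisions.append(ev)
        events.sort(key=lambda e: e.mat)
        for prev, nxt in zip(events, events[1:]):
            if nxt.ipt <= prev.mat:
                continue
            ikey = (prev.dedup_key, tr.segment_at(nxt.ipt), nxt.ipt)
            if ikey in seen_inter:
                continue
            seen_inter.add(ikey)
            interphases.append(InterphaseEvent(
                trace_id=tr.trace_id, start=prev.mat, end=nxt.ipt,
                duration=(nxt.ipt - prev.mat) * interval_min, dedup_key=ikey,
            ))
    return divisions, interphases
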