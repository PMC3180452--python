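"""Frame-to-frame nucleus linking and trace assembly.

Objects in consecutive frames are matched one-to-one by globally optimal
bipartite assignment over a composite cost (area change, grey-histogram
distance, displacement, speed change, direction change, shape
dissimilarity, Delaunay-neighborhood dissimilarity), restricted to
candidates within a configurable search radius (30 px by default — nuclei
do not move further between acquisitions).  A one-to-two link is recorded
as a division when one object at ``t`` explains two objects at ``t+1``
whose summed area approximates the parent's.

A trace follows one nucleus through the whole movie; at a division each
daughter continues as an independent trace that retains the parent's full
pre-division history.  Traces that do not span every frame (cells entering
or leaving the field, or dropped for border contact even once) are marked
incomplete and excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import Delaunay

from .core import FrameStack, Trace
from .features import extract_geometric_features, intensity_histograms
from .segmentation import SegmentationParams, segment_stack

__all__ = ["TrackingParams", "FrameObjects", "Assignment", "link_frames",
           "build_traces", "drop_incomplete_traces", "track_movie"]

_BIG = 1e6


@dataclass(frozen=True)
class TrackingParams:
    search_radius: float = 30.0      # px; candidates beyond this are impossible
    division_area_tol: float = 0.45  # daughters' summed area within this fraction of parent
    daughter_max_frac: float = 0.8   # each daughter must be below this fraction of parent area
    # equal weights on normalized cost components by default
    w_area: float = 1.0
    w_hist: float = 1.0
    w_disp: float = 1.0
    w_speed: float = 1.0
    w_direction: float = 1.0
    w_shape: float = 1.0
    w_delaunay: float = 1.0


@dataclass
class FrameObjects:
    """Feature table + grey histograms for the objects of one frame."""

    frame: int
    table: pd.DataFrame          # from extract_geometric_features
    histograms: dict[int, np.ndarray]

    @property
    def labels(self) -> list[int]:
        return self.table["label"].astype(int).tolist()

    def row(self, label: int) -> pd.Series:
        return self.table.loc[self.table["label"] == label].iloc[0]


@dataclass
class Assignment:
    matches: list[tuple[int, int]] = field(default_factory=list)       # (label_t, label_t1)
    divisions: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    unmatched_t: list[int] = field(default_factory=list)
    unmatched_t1: list[int] = field(default_factory=list)


def _neighbor_scale(table: pd.DataFrame) -> dict[int, float]:
    """Mean Delaunay-neighbor distance per object (local-density feature)."""
    pts = table[["x", "y"]].to_numpy()
    labels = table["label"].astype(int).to_numpy()
    if len(pts) < 4:
        return {int(l): 0.0 for l in labels}
    try:
        tri = Delaunay(pts)
    except Exception:
        return {int(l): 0.0 for l in labels}
    nbrs: dict[int, set[int]] = {i: set() for i in range(len(pts))}
    for simplex in tri.simplices:
        for i in simplex:
            nbrs[i].update(int(j) for j in simplex if j != i)
    return {
        int(labels[i]): float(np.mean(
            [np.linalg.norm(pts[i] - pts[j]) for j in js])) if js else 0.0
        for i, js in nbrs.items()
    }


def link_frames(objs_t: FrameObjects, objs_t1: FrameObjects,
                params: TrackingParams = TrackingParams(),
                prev_velocity: dict[int, np.ndarray] | None = None) -> Assignment:
    """One-to-one assignment of objects between consecutive frames.

    ``prev_velocity`` maps labels at ``t`` to their last displacement
    vector; speed and direction terms are zero-weighted when absent (a
    trace's first link).
    """
    la, lb = objs_t.labels, objs_t1.labels
    if not la or not lb:
        return Assignment(unmatched_t=la, unmatched_t1=lb)
    ta, tb = objs_t.table, objs_t1.table
    pa = ta[["x", "y"]].to_numpy()
    pb = tb[["x", "y"]].to_numpy()
    nbr_a = _neighbor_scale(ta)
    nbr_b = _neighbor_scale(tb)
    R = params.search_radius

    cost = np.full((len(la), len(lb)), _BIG)
    for i, a in enumerate(la):
        ra = ta.iloc[i]
        va = None if prev_velocity is None else prev_velocity.get(a)
        for j, b in enumerate(lb):
            disp = pb[j] - pa[i]
            d = float(np.linalg.norm(disp))
            if d > R:
                continue
            rb = tb.iloc[j]
            c = params.w_area * abs(ra["area"] - rb["area"]) / max(ra["area"], rb["area"])
            c += params.w_hist * 0.5 * float(np.abs(
                objs_t.histograms[a] - objs_t1.histograms[b]).sum())
            c += params.w_disp * d / R
            if va is not None and np.linalg.norm(va) > 0:
                c += params.w_speed * abs(d - float(np.linalg.norm(va))) / R
                if d > 0:
                    cosang = float(np.dot(disp, va) /
                                   (d * np.linalg.norm(va)))
                    c += params.w_direction * np.arccos(np.clip(cosang, -1, 1)) / np.pi
            c += params.w_shape * 0.5 * (abs(ra["eccentricity"] - rb["eccentricity"])
                                         + abs(ra["solidity"] - rb["solidity"]))
            c += params.w_delaunay * abs(nbr_a[a] - nbr_b[b]) / R
            cost[i, j] = c

    rows, cols = linear_sum_assignment(cost)
    matched_a, matched_b = set(), set()
    matches = []
    for i, j in zip(rows, cols):
        if cost[i, j] < _BIG / 2:
            matches.append((la[i], lb[j]))
            matched_a.add(la[i])
            matched_b.add(lb[j])
    out = Assignment(
        matches=matches,
        unmatched_t=[a for a in la if a not in matched_a],
        unmatched_t1=[b for b in lb if b not in matched_b],
    )
    _detect_divisions(out, objs_t, objs_t1, params)
    return out


def _detect_divisions(assign: Assignment, objs_t: FrameObjects,
                      objs_t1: FrameObjects, params: TrackingParams) -> None:
    """Promote matches to one-to-two links when areas say 'division'.

    A mitotic object at ``t`` that splits appears as one matched daughter
    plus one unmatched object nearby at ``t+1``; the link becomes a
    division when the two daughters' summed area is within
    ``division_area_tol`` of the parent's area.
    """
    if not assign.unmatched_t1:
        return
    match_of = dict(assign.matches)
    ta, tb = objs_t.table, objs_t1.table
    pos_b = {int(r["label"]): np.array([r["x"], r["y"]]) for _, r in tb.iterrows()}
    area_b = {int(r["label"]): float(r["area"]) for _, r in tb.iterrows()}
    used: set[int] = set()
    for _, ra in ta.iterrows():
        p = int(ra["label"])
        if p not in match_of:
            continue
        m = match_of[p]
        pp = np.array([ra["x"], ra["y"]])
        best = None
        parent_area = float(ra["area"])
        if area_b[m] > params.daughter_max_frac * parent_area:
            continue  # the matched partner is too big to be a daughter
        for d in assign.unmatched_t1:
            if d in used:
                continue
            if np.linalg.norm(pos_b[d] - pp) > params.search_radius:
                continue
            if area_b[d] > params.daughter_max_frac * parent_area:
                continue
            total = area_b[m] + area_b[d]
            err = abs(total - parent_area) / parent_area
            if err <= params.division_area_tol and (best is None or err < best[0]):
                best = (err, d)
        if best is not None:
            d = best[1]
            used.add(d)
            assign.matches.remove((p, m))
            assign.divisions.append((p, (m, d)))
            assign.unmatched_t1.remove(d)


# ---------------------------------------------------------------------------
# Trace assembly

@dataclass
class _Chain:
    chain_id: str
    parent: str | None
    start: int
    records: list[dict]
    children: tuple[str, str] | None = None
    end: int | None = None


def build_traces(frame_objects: list[FrameObjects],
                 assignments: list[Assignment],
                 n_frames: int | None = None) -> list[Trace]:
    """Chain per-frame assignments into traces.

    At a division both daughters open new chains carrying the parent
    chain id; a trace is the concatenation of a leaf chain with all its
    ancestors, so sibling traces share the pre-division history.  A trace
    is ``complete`` only if its lineage covers frame 0 through the final
    frame without interruption.
    """
    if n_frames is None:
        n_frames = len(frame_objects)
    chains: dict[str, _Chain] = {}
    active: dict[int, str] = {}  # label at current frame -> chain id
    counter = 0

    def _new_chain(parent: str | None, frame: int) -> _Chain:
        nonlocal counter
        ch = _Chain(chain_id=f"s{counter}", parent=parent, start=frame, records=[])
        counter += 1
        chains[ch.chain_id] = ch
        return ch

    def _record(ch: _Chain, fo: FrameObjects, label: int) -> None:
        r = fo.row(label)
        ch.records.append({
            "frame": fo.frame, "label": label, "x": float(r["x"]),
            "y": float(r["y"]), "area": float(r["area"]),
            "intensity": float(r["mean_intensity"]),
        })

    if frame_objects:
        for lab in frame_objects[0].labels:
            ch = _new_chain(None, frame_objects[0].frame)
            _record(ch, frame_objects[0], lab)
            active[lab] = ch.chain_id

    for fo_t, fo_t1, assign in zip(frame_objects, frame_objects[1:], assignments):
        nxt: dict[int, str] = {}
        for a, b in assign.matches:
            cid = active.get(a)
            if cid is None:
                continue
            _record(chains[cid], fo_t1, b)
            nxt[b] = cid
        for p, (d1, d2) in assign.divisions:
            cid = active.get(p)
            if cid is None:
                continue
            chains[cid].end = fo_t.frame
            kids = []
            for d in (d1, d2):
                ch = _new_chain(cid, fo_t1.frame)
                _record(ch, fo_t1, d)
                nxt[d] = ch.chain_id
                kids.append(ch.chain_id)
            chains[cid].children = (kids[0], kids[1])
        for a in assign.unmatched_t:
            cid = active.get(a)
            if cid is not None:
                chains[cid].end = fo_t.frame
        for b in assign.unmatched_t1:
            ch = _new_chain(None, fo_t1.frame)
            _record(ch, fo_t1, b)
            nxt[b] = ch.chain_id
        active = nxt

    last_frame = frame_objects[-1].frame if frame_objects else -1
    for cid in active.values():
        chains[cid].end = last_frame

    traces: list[Trace] = []
    leaf_ids = [cid for cid, ch in chains.items() if ch.children is None]
    for idx, leaf in enumerate(sorted(leaf_ids)):
        lineage: list[_Chain] = []
        cur: str | None = leaf
        while cur is not None:
            lineage.append(chains[cur])
            cur = chains[cur].parent
        lineage.reverse()
        recs = [r for ch in lineage for r in ch.records]
        if not recs:
            continue
        frames = np.array([r["frame"] for r in recs])
        complete = (frames[0] == 0 and frames[-1] == n_frames - 1
                    and len(frames) == n_frames)
        traces.append(Trace(
            trace_id=f"n{idx}",
            frames=frames,
            area=np.array([r["area"] for r in recs]),
            intensity=np.array([r["intensity"] for r in recs]),
            x=np.array([r["x"] for r in recs]),
            y=np.array([r["y"] for r in recs]),
            parent_trace_id=lineage[-1].parent,
            complete=bool(complete),
            segments=[(ch.chain_id, ch.records[0]["frame"],
                       ch.records[-1]["frame"]) for ch in lineage if ch.records],
        ))
    return traces


def drop_incomplete_traces(traces: list[Trace]) -> list[Trace]:
    """Keep only traces present and matched in every frame of the movie."""
    return [t for t in traces if t.complete]


# ---------------------------------------------------------------------------
# Movie-level convenience pipeline

def track_movie(stack: FrameStack,
                seg_params: SegmentationParams = SegmentationParams(),
                params: TrackingParams = TrackingParams()) -> list[Trace]:
    """Segment, extract features, link and assemble traces for a movie."""
    masks = segment_stack(stack.frames, seg_params, drop_border=True)
    frame_objs: list[FrameObjects] = []
    for f, mask in enumerate(masks):
        if mask.labels.max() == 0:
            frame_objs.append(FrameObjects(
                frame=f, table=pd.DataFrame(
                    columns=["label", "area", "mean_intensity", "x", "y",
                             "eccentricity", "solidity"]),
                histograms={}))
            continue
        tbl = extract_geometric_features(mask, stack.frames[f])
        hists = intensity_histograms(mask.labels, stack.frames[f],
                                     vmax=2 ** stack.bit_depth - 1)
        frame_objs.append(FrameObjects(frame=f, table=tbl, histograms=hists))

    assignments: list[Assignment] = []
    velocity: dict[int, np.ndarray] = {}
    for fo_t, fo_t1 in zip(frame_objs, frame_objs[1:]):
        assign = link_frames(fo_t, fo_t1, params, prev_velocity=velocity)
        assignments.append(assign)
        velocity = {}
        pos_t = {int(r["label"]): np.array([r["x"], r["y"]])
                 for _, r in fo_t.table.iterrows()}
        pos_t1 = {int(r["label"]): np.array([r["x"], r["y"]])
                  for _, r in fo_t1.table.iterrows()}
        for a, b in assign.matches:
            velocity[b] = pos_t1[b] - pos_t[a]
    return build_traces(frame_objs, assignments, n_frames=len(stack))
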