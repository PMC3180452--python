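"""Synthetic H2B-GFP trace and movie generator with known division timing.

The generator emulates the statistical structure the transition detector
assumes: an interphase nucleus holds a stable area (~400 px) and average
intensity; at mitotic entry chromatin condenses, so the area ramps down
linearly to the metaphase-plate area (~150 px) while the average intensity
steps up; at anaphase the nucleus splits into two daughters whose traces
start at the area minimum and decondense back to interphase values over
~48 minutes.  Optionally, a fraction of cells arrest in mitosis (area
keeps drifting down, never recovering) and a fraction of cell pairs are
forced to cross, producing the single-frame area spikes that the trace
removal step is designed to catch.

Every cell's true entry and anaphase frames are recorded in a
:class:`GroundTruthLog`, so the accuracy of each downstream stage can be
measured without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FrameStack, Trace

__all__ = ["SimConfig", "GroundTruthLog", "simulate_traces", "render_movie"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator (defaults emulate HeLa H2B-GFP
    imaged every 12 minutes at 20x with 2x2 binning, 12-bit camera)."""

    n_cells: int = 20
    n_frames: int = 241                   # 48 h at 12 min/frame
    interval_min: float = 12.0
    frame_shape: tuple[int, int] = (512, 672)
    interphase_area_mean: float = 400.0   # px
    interphase_area_sd: float = 40.0
    mitotic_area_min_mean: float = 150.0  # metaphase-plate area, px
    mitotic_area_min_sd: float = 15.0
    interphase_intensity_mean: float = 500.0  # grey levels (12-bit scale)
    interphase_intensity_sd: float = 50.0
    mitotic_intensity_gain: float = 200.0     # condensation intensity step
    interphase_duration_mean: float = 1224.0  # minutes (20.4 h)
    interphase_duration_sd: float = 180.0
    mitotic_duration_mean: float = 60.0       # minutes
    mitotic_duration_sd: float = 12.0
    motion_step_sd: float = 2.0           # px/frame random walk
    noise_sd: float = 5.0                 # grey levels; also applied to A in px
    arrest_fraction: float = 0.0          # cells entering mitosis and never exiting
    crossing_fraction: float = 0.0        # cell pairs forced to overlap once
    rng_seed: int = 0
    # Secondary shape parameters (minutes, so per-frame slopes stay
    # physiological at any imaging interval).
    condensed_hold_min: float = 12.0      # telophase: daughters stay condensed this long
    decondense_min: float = 60.0          # anaphase -> full interphase area, total
    daughter_area_frac: float = 0.6       # daughter area at anaphase / plate area
    arrest_decay: float = 0.002           # fractional area loss per frame during arrest

    def __post_init__(self) -> None:
        positive = [
            "interphase_area_mean", "mitotic_area_min_mean",
            "interphase_intensity_mean", "interphase_duration_mean",
            "mitotic_duration_mean", "interval_min",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("arrest_fraction", "crossing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        min_cycle = (self.mitotic_duration_mean + self.interphase_duration_mean) / self.interval_min
        if self.n_frames < min_cycle / 4:
            raise ValueError(
                "n_frames too short to contain one full cycle at the given durations"
            )


@dataclass
class GroundTruthLog:
    """True event timing for a simulated movie.

    ``divisions`` rows: (cell_id, entry_frame, anaphase_frame,
    daughter_a, daughter_b); arrested cells appear in ``arrests`` with
    their entry frame only.  ``parents`` maps daughter -> parent cell id;
    ``overlap_frames`` maps cell id -> frames at which the generator forced
    an overlap with another nucleus.
    """

    divisions: list[tuple[str, int, int, str, str]] = field(default_factory=list)
    arrests: list[tuple[str, int]] = field(default_factory=list)
    parents: dict[str, str] = field(default_factory=dict)
    overlap_frames: dict[str, list[int]] = field(default_factory=dict)

    def events_for_trace(self, trace: Trace, within_movie: bool = False
                         ) -> list[tuple[int, int]]:
        """(entry, anaphase) pairs of every division along a trace's lineage.

        With ``within_movie=True``, divisions whose anaphase falls past the
        trace's last frame (mitoses truncated by the end of the movie) are
        excluded.
        """
        segs = {sid for sid, _, _ in trace.segments}
        last = int(trace.frames[-1]) if len(trace) else -1
        return sorted(
            (entry, ana) for cid, entry, ana, _, _ in self.divisions
            if cid in segs and (not within_movie or ana <= last)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_id": cid, "event_idx": 0, "entry_frame": e, "anaphase_frame": a}
            for cid, e, a, _, _ in self.divisions
        ]
        rows += [
            {"cell_id": cid, "event_idx": 0, "entry_frame": e, "anaphase_frame": -1}
            for cid, e in self.arrests
        ]
        df = pd.DataFrame(rows, columns=["cell_id", "event_idx", "entry_frame",
                                         "anaphase_frame"])
        df["event_idx"] = df.groupby("cell_id").cumcount()
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Internal lineage node

@dataclass
class _Node:
    node_id: str
    parent_id: str | None
    start: int               # first frame the nucleus exists
    end: int                 # last frame (inclusive)
    area: np.ndarray         # noiseless per-frame values, frames start..end
    intensity: np.ndarray
    xy: np.ndarray           # (n, 2)
    children: tuple[str, str] | None = None
    entry: int | None = None      # mitotic entry of *this* node's division
    arrested: bool = False


def _frames(minutes: float, interval: float, lo: int = 1) -> int:
    return max(lo, int(round(minutes / interval)))


def simulate_traces(cfg: SimConfig) -> tuple[list[Trace], GroundTruthLog]:
    """Generate per-nucleus (A, I) traces plus the ground-truth event log.

    Every root cell is simulated through repeated interphase/mitosis
    cycles; at each anaphase two daughter nodes continue independently.
    Returned traces are root-to-leaf paths through the lineage (each trace
    follows exactly one daughter at every division), matching the trace
    semantics of the tracking stage.  The same config (including seed)
    always produces bit-identical output.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    T = cfg.n_frames
    log = GroundTruthLog()
    nodes: dict[str, _Node] = {}

    n_arrest = int(round(cfg.arrest_fraction * cfg.n_cells))
    arrest_flags = np.zeros(cfg.n_cells, dtype=bool)
    arrest_flags[:n_arrest] = True
    rng.shuffle(arrest_flags)

    margin = 2.5 * math.sqrt(cfg.interphase_area_mean / math.pi)
    h, w = cfg.frame_shape

    def _walk(n: int, start_xy: np.ndarray) -> np.ndarray:
        steps = rng.normal(0.0, cfg.motion_step_sd, size=(n, 2))
        xy = start_xy + np.cumsum(steps, axis=0)
        # reflect into the frame so nuclei stay renderable
        for k, bound in enumerate((w, h)):
            xy[:, k] = np.abs(xy[:, k])
            xy[:, k] = bound - np.abs(bound - xy[:, k])
        return xy

    def _interphase_len(first: bool) -> int:
        dur = rng.normal(cfg.interphase_duration_mean, cfg.interphase_duration_sd)
        n = _frames(max(dur, cfg.interval_min), cfg.interval_min)
        if first:
            # root cells start at a uniformly random point of their cycle
            n = int(rng.integers(1, max(2, n)))
        return n

    def _grow(node_id: str, parent_id: str | None, start: int, start_xy: np.ndarray,
              init_area: float | None, base_area: float, base_int: float,
              arrested: bool, first: bool, depth: int,
              sep_drift: np.ndarray | None = None) -> None:
        """Simulate one node from ``start`` until division or movie end."""
        plate = max(40.0, rng.normal(cfg.mitotic_area_min_mean, cfg.mitotic_area_min_sd))
        inter_n = _interphase_len(first)
        entry = start + inter_n                       # first condensed frame
        mito_n = _frames(rng.normal(cfg.mitotic_duration_mean,
                                    cfg.mitotic_duration_sd), cfg.interval_min, lo=2)
        anaphase = entry + mito_n                     # first frame of daughters

        end = min(T - 1, (T - 1) if arrested else anaphase - 1)
        if not arrested:
            end = min(T - 1, anaphase - 1)
        n = end - start + 1
        area = np.full(n, base_area)
        intens = np.full(n, base_int)
        # telophase of *this* node: daughters appear condensed at the
        # anaphase frame, stay near the minimum for ~condensed_hold_min,
        # then decondense linearly back to interphase area
        if init_area is not None:
            hold_n = _frames(cfg.condensed_hold_min, cfg.interval_min, lo=1)
            rec_n = _frames(cfg.decondense_min - cfg.condensed_hold_min,
                            cfg.interval_min, lo=2)
            j = np.arange(n, dtype=float)
            hold = init_area + j                      # slight creep upward
            top = init_area + hold_n
            ramp = top + (base_area - top) * (j - hold_n) / rec_n
            prof = np.where(j <= hold_n, hold, np.minimum(ramp, base_area))
            area[:] = prof
            idec = base_int + cfg.mitotic_intensity_gain * np.clip(
                1.0 - (j - hold_n) / rec_n, 0.0, 1.0)
            intens[:] = idec
        # condensation ramp into mitosis
        for j in range(n):
            f = start + j
            if f >= entry:
                k = f - entry + 1
                area[j] = base_area + (plate - base_area) * min(1.0, k / mito_n)
                intens[j] = base_int + cfg.mitotic_intensity_gain
        if arrested and end >= entry:
            # slow monotone drift downward once condensed, never recovering
            j0 = entry - start + mito_n - 1
            for j in range(n):
                if j > j0:
                    area[j] = area[j - 1] * (1.0 - cfg.arrest_decay)
        if cfg.noise_sd > 0 and not arrested:
            # measurement noise is drawn once per lineage node so sibling
            # traces agree on their shared history
            area = np.maximum(1.0, area + rng.normal(0, cfg.noise_sd, n))
            intens = np.maximum(1.0, intens + rng.normal(0, cfg.noise_sd, n))

        xy = _walk(n, start_xy)
        if sep_drift is not None:
            # anaphase B / daughter-cell respreading: the two daughters
            # move apart deterministically for a few frames after birth
            for j in range(min(4, n)):
                xy[j] += sep_drift * (6.0 * j)
            xy[min(4, n):] += sep_drift * 18.0
            xy[:, 0] = np.clip(xy[:, 0], 1.0, w - 2.0)
            xy[:, 1] = np.clip(xy[:, 1], 1.0, h - 2.0)
        nodes[node_id] = _Node(node_id, parent_id, start, end, area, intens, xy,
                               entry=entry if (entry <= T - 1) else None,
                               arrested=arrested)
        if parent_id is not None:
            log.parents[node_id] = parent_id

        if arrested:
            if entry <= T - 1:
                log.arrests.append((node_id, entry))
            return
        if anaphase > T - 1 or depth > 6:
            if entry <= T - 1 and depth <= 6:
                # mitotic entry visible but anaphase falls off the movie;
                # logged (no daughters) so evaluation can score partial events
                log.divisions.append((node_id, entry, anaphase, "", ""))
            return
        # division: two daughters starting at the anaphase frame
        d_ids = (f"{node_id}.0", f"{node_id}.1")
        log.divisions.append((node_id, entry, anaphase, *d_ids))
        nodes[node_id].children = d_ids
        init = cfg.daughter_area_frac * plate
        sep = rng.normal(0.0, 1.0, size=2)
        sep = 8.0 * sep / max(1e-6, np.linalg.norm(sep))
        for d_id, sgn in zip(d_ids, (+1.0, -1.0)):
            # daughters inherit the parent's H2B-GFP expression level (the
            # reporter is partitioned with the chromatin), with small jitter
            _grow(d_id, node_id, anaphase, xy[-1] + sgn * sep,
                  init_area=init,
                  base_area=max(100.0, rng.normal(cfg.interphase_area_mean,
                                                  cfg.interphase_area_sd)),
                  base_int=max(50.0, base_int + rng.normal(0.0, 5.0)),
                  arrested=False, first=False, depth=depth + 1,
                  sep_drift=sgn * sep / 8.0)

    for i in range(cfg.n_cells):
        xy0 = np.array([rng.uniform(margin, w - margin),
                        rng.uniform(margin, h - margin)])
        _grow(f"c{i}", None, 0, xy0,
              init_area=None,
              base_area=max(100.0, rng.normal(cfg.interphase_area_mean,
                                              cfg.interphase_area_sd)),
              base_int=max(50.0, rng.normal(cfg.interphase_intensity_mean,
                                            cfg.interphase_intensity_sd)),
              arrested=bool(arrest_flags[i]), first=True, depth=0)

    _force_crossings(cfg, rng, nodes, log)

    traces = _assemble_traces(cfg, rng, nodes, log)
    return traces, log


def _force_crossings(cfg: SimConfig, rng: np.random.Generator,
                     nodes: dict[str, _Node], log: GroundTruthLog) -> None:
    """Make selected root-cell pairs overlap for one frame.

    An overlap merges the two nuclei into a single segmented object, so
    both traces record the summed area and the intensity-weighted mean for
    that frame — the signature the trace-removal step must catch.
    """
    roots = [nid for nid, nd in nodes.items() if nd.parent_id is None]
    n_pairs = int(round(cfg.crossing_fraction * len(roots) / 2))
    if n_pairs == 0:
        return
    order = list(rng.permutation(len(roots)))
    for p in range(n_pairs):
        a = nodes[roots[order[2 * p]]]
        b = nodes[roots[order[2 * p + 1]]]
        hi = min(a.end, b.end)
        if hi < 2:
            continue
        f = int(rng.integers(1, hi))
        ia, ib = f - a.start, f - b.start
        merged_area = a.area[ia] + b.area[ib]
        merged_int = (a.area[ia] * a.intensity[ia] + b.area[ib] * b.intensity[ib]) / merged_area
        mid = (a.xy[ia] + b.xy[ib]) / 2.0
        for nd, idx in ((a, ia), (b, ib)):
            nd.area[idx] = merged_area
            nd.intensity[idx] = merged_int
            nd.xy[idx] = mid
            log.overlap_frames.setdefault(nd.node_id, []).append(f)


def _assemble_traces(cfg: SimConfig, rng: np.random.Generator,
                     nodes: dict[str, _Node], log: GroundTruthLog) -> list[Trace]:
    leaves = [nid for nid, nd in nodes.items() if nd.children is None]
    traces: list[Trace] = []
    for li, leaf in enumerate(sorted(leaves)):
        chain: list[_Node] = []
        nid: str | None = leaf
        while nid is not None:
            nd = nodes[nid]
            chain.append(nd)
            nid = nd.parent_id
        chain.reverse()
        area = np.concatenate([nd.area for nd in chain])
        intens = np.concatenate([nd.intensity for nd in chain])
        xy = np.concatenate([nd.xy for nd in chain])
        frames = np.arange(chain[0].start, chain[-1].end + 1)
        traces.append(Trace(
            trace_id=f"t{li}",
            frames=frames,
            area=area,
            intensity=intens,
            x=xy[:, 0], y=xy[:, 1],
            parent_trace_id=None,
            complete=(chain[0].start == 0 and chain[-1].end == cfg.n_frames - 1),
            segments=[(nd.node_id, nd.start, nd.end) for nd in chain],
        ))
    return traces


# ---------------------------------------------------------------------------
# Rendering

def render_movie(cfg: SimConfig, traces: list[Trace] | None = None,
                 log: GroundTruthLog | None = None, *,
                 nodes_df: pd.DataFrame | None = None) -> FrameStack:
    """Rasterize simulated nuclei into a 16-bit movie.

    Each nucleus is drawn as a filled ellipse of the trace's area, uniform
    at the trace's average intensity, over a dim noisy background.  At
    anaphase the two daughter blobs appear separated and drift apart as
    their random walks continue.
    """
    from skimage.draw import ellipse as draw_ellipse

    if traces is None or log is None:
        traces, log = simulate_traces(cfg)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    h, w = cfg.frame_shape
    maxval = 4095.0
    frames = np.zeros((cfg.n_frames, h, w), dtype=float)

    # collect one record per (segment, frame) so shared parent history is
    # drawn once even though sibling traces both carry it
    drawn: set[tuple[str, int]] = set()
    ecc = 1.2  # major/minor axis ratio
    for tr in traces:
        for i, f in enumerate(tr.frames):
            seg = tr.segment_at(int(f))
            key = (seg, int(f))
            if key in drawn:
                continue
            drawn.add(key)
            a_px = max(4.0, tr.area[i])
            r = math.sqrt(a_px / math.pi)
            r_major, r_minor = r * math.sqrt(ecc), r / math.sqrt(ecc)
            if 2 * r_major > min(h, w):
                raise ValueError("nucleus radius exceeds frame bounds")
            rr, cc = draw_ellipse(tr.y[i], tr.x[i], r_minor, r_major, shape=(h, w))
            frames[f, rr, cc] = np.maximum(frames[f, rr, cc],
                                           min(maxval, tr.intensity[i]))
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, frames.shape)
    frames = np.clip(frames, 0, maxval).astype(np.uint16)
    return FrameStack(frames=frames, interval_min=cfg.interval_min, bit_depth=12)
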