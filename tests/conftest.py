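import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.reference

from mitotrace.core import Trace
from mitotrace.simgen import SimConfig, simulate_traces
from mitotrace.tsa import TSAParams


@pytest.fixture(scope="session")
def params() -> TSAParams:
    return TSAParams()


@pytest.fixture(scope="session")
def hela_sim():
    """Default HeLa-like simulation at 12-min imaging, 100 lineages."""
    cfg = SimConfig(n_cells=100, n_frames=241, rng_seed=1)
    traces, log = simulate_traces(cfg)
    return cfg, traces, log


def make_trace(area, intensity=None, trace_id="t", frames=None) -> Trace:
    area = np.asarray(area, dtype=float)
    if intensity is None:
        intensity = np.full_like(area, 500.0)
    if frames is None:
        frames = np.arange(len(area))
    return Trace(trace_id=trace_id, frames=frames, area=area,
                 intensity=np.asarray(intensity, dtype=float))


@pytest.fixture(scope="session")
def arrested_trace() -> Trace:
    """Mitotic-arrest trace: 60 interphase frames at 400 px, a sharp
    condensation to 150 px with a +60 grey-level intensity step, then a
    slow monotone area drift downward for 250 frames with no recovery."""
    area = np.concatenate([
        np.full(60, 400.0),
        np.linspace(400.0, 150.0, 6)[1:],
        150.0 - 0.5 * np.arange(1, 251),
    ])
    intens = np.concatenate([np.full(60, 500.0), np.full(len(area) - 60, 560.0)])
    return make_trace(area, intens, trace_id="arrest")


def random_tsa_traces(n: int, seed: int, max_len: int = 60):
    """Short random traces mixing noise walks, division-like dips and
    arrest ramps — deliberately adversarial input for oracle comparison."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        L = int(rng.integers(2, max_len + 1))
        kind = rng.integers(0, 4)
        if kind == 0:      # noisy random walk around a random level
            area = np.abs(rng.normal(rng.uniform(100, 500), 80, L)) + 1
            intens = np.abs(rng.normal(500, 40, L)) + 1
        elif kind == 1:    # interphase plateau with a division-like dip
            area = rng.normal(rng.uniform(300, 450), 10, L)
            intens = rng.normal(500, 5, L)
            c = int(rng.integers(0, L))
            w = int(rng.integers(1, 8))
            lo = rng.uniform(60, 220)
            for j in range(max(0, c - w), min(L, c + w + 1)):
                area[j] = lo + abs(j - c) * rng.uniform(10, 60)
            if rng.random() < 0.5 and c >= 1:
                intens[c:] += rng.uniform(20, 80)
        elif kind == 2:    # monotone arrest ramp
            area = np.linspace(rng.uniform(300, 450), rng.uniform(30, 220), L)
            intens = rng.normal(520, 10, L)
        else:              # spiky trace (segmentation errors)
            area = rng.normal(300, 30, L)
            for _ in range(int(rng.integers(1, 4))):
                area[rng.integers(0, L)] += rng.uniform(100, 400)
            intens = rng.normal(500, rng.uniform(1, 25), L)
        area = np.maximum(area, 1.0)
        intens = np.maximum(intens, 1.0)
        out.append(make_trace(area, intens, trace_id=f"r{i}"))
    return out
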