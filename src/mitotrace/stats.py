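"""Summaries and comparisons of event-duration samples.

Condition-level outputs mirror what a screening experiment needs: per
condition the number of events N, median and mean duration, a cumulative
frequency curve, and pairwise Mann-Whitney-Wilcoxon comparisons against a
control at alpha = 0.05.  Durations are not normally distributed (mitotic
arrest produces a long right tail), hence the rank-based test.

``mww_test`` computes the exact null distribution of U by enumeration for
small samples (n_a + n_b <= 12, ties handled by midranks) and otherwise a
normal approximation with continuity and tie correction, two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["DurationSample", "ComparisonResult", "summarize",
           "cumulative_frequency", "mww_test", "report", "format_p"]

P_FLOOR = 2e-16  # smaller p values are reported as '<= 2e-16'
EXACT_MAX_N = 12


@dataclass(frozen=True)
class DurationSample:
    """Durations (minutes) of one experimental condition."""

    condition: str
    durations: tuple[float, ...]

    def __init__(self, condition: str, durations: Sequence[float]):
        durations = tuple(float(d) for d in durations)
        if any(d <= 0 for d in durations):
            raise ValueError("durations must be positive")
        object.__setattr__(self, "condition", condition)
        object.__setattr__(self, "durations", durations)

    @property
    def n(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class ComparisonResult:
    u: float
    p: float
    significant: bool
    alpha: float = 0.05
    exact: bool = False


def summarize(sample: DurationSample) -> tuple[float, float, int]:
    """(median, mean, N); errors on an empty sample."""
    if sample.n == 0:
        raise ValueError("empty sample")
    arr = np.asarray(sample.durations)
    return float(np.median(arr)), float(arr.mean()), sample.n


def cumulative_frequency(sample: DurationSample) -> pd.DataFrame:
    """Cumulative percent of events at or below each distinct duration."""
    if sample.n == 0:
        raise ValueError("empty sample")
    arr = np.sort(np.asarray(sample.durations))
    vals, counts = np.unique(arr, return_counts=True)
    pct = 100.0 * np.cumsum(counts) / sample.n
    return pd.DataFrame({"duration": vals, "cumulative_pct": pct})


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2)


def mww_test(sample_a: DurationSample | Sequence[float],
             sample_b: DurationSample | Sequence[float],
             alpha: float = 0.05) -> ComparisonResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test."""
    a = np.asarray(sample_a.durations if isinstance(sample_a, DurationSample)
                   else sample_a, float)
    b = np.asarray(sample_b.durations if isinstance(sample_b, DurationSample)
                   else sample_b, float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks on ties
    u = _u_statistic(ranks[:n_a], n_a)

    if n_a + n_b <= EXACT_MAX_N:
        p = _exact_p(ranks, n_a, n_b, u)
        exact = True
    else:
        p = _normal_p(ranks, n_a, n_b, u)
        exact = False
    p = min(1.0, p)
    return ComparisonResult(u=u, p=p, significant=p < alpha, alpha=alpha,
                            exact=exact)


def _exact_p(ranks: np.ndarray, n_a: int, n_b: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating every assignment of ranks to A."""
    n = n_a + n_b
    u_lo = min(u_obs, n_a * n_b - u_obs)
    u_hi = n_a * n_b - u_lo
    count = total = 0
    for idx in combinations(range(n), n_a):
        u = _u_statistic(ranks[list(idx)], n_a)
        total += 1
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            count += 1
    return count / total


def _normal_p(ranks: np.ndarray, n_a: int, n_b: int, u_obs: float) -> float:
    """Normal approximation with continuity and tie correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all observations identical
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return 2.0 * float(norm.sf(z))


def format_p(p: float) -> str:
    return "<=2e-16" if p < P_FLOOR else f"{p:.3g}"


def report(samples: Mapping[str, Sequence[float]], out_dir,
           control: str | None = None, alpha: float = 0.05,
           make_plot: bool = True) -> dict[str, pd.DataFrame]:
    """Write per-condition summaries, pairwise comparisons vs control,
    cumulative-frequency tables, and a cumulative-frequency plot.

    Returns the tables keyed by ``summary``/``comparisons``/``cumulative``.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not samples:
        raise ValueError("need at least one condition")
    dsamples = {name: DurationSample(name, durs) for name, durs in samples.items()}
    if control is None:
        control = next(iter(dsamples))

    rows = []
    for name, s in dsamples.items():
        med, mean, n = summarize(s)
        rows.append({"condition": name, "N": n, "median_min": med,
                     "mean_min": mean})
    summary = pd.DataFrame(rows)

    comps = []
    for name, s in dsamples.items():
        if name == control:
            continue
        res = mww_test(dsamples[control], s, alpha=alpha)
        comps.append({"condition": name, "control": control, "U": res.u,
                      "p": res.p, "p_label": format_p(res.p),
                      "significant": res.significant, "exact": res.exact})
    comparisons = pd.DataFrame(
        comps, columns=["condition", "control", "U", "p", "p_label",
                        "significant", "exact"])

    curves = []
    for name, s in dsamples.items():
        c = cumulative_frequency(s)
        c.insert(0, "condition", name)
        curves.append(c)
    cumulative = pd.concat(curves, ignore_index=True)

    summary.to_csv(out / "summary.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    cumulative.to_csv(out / "cumulative.csv", index=False)

    if make_plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, s in dsamples.items():
            c = cumulative_frequency(s)
            ax.step(c["duration"], c["cumulative_pct"], where="post",
                    label=f"{name} (N={s.n})")
        ax.set_xlabel("duration (min)")
        ax.set_ylabel("cumulative % of events")
        ax.set_ylim(0, 105)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "cumulative.png", dpi=120)
        plt.close(fig)

    return {"summary": summary, "comparisons": comparisons,
            "cumulative": cumulative}
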