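"""Independent brute-force reference implementations used as test oracles.

These re-derive the detector's published rules with literal frame-by-frame
loops and no shared code with the package, so agreement with the optimized
implementation is meaningful.  Likewise the exact rank-sum null
distribution is obtained by full enumeration.
"""

from itertools import combinations


def oracle_candidates(area, p):
    """Literal rule: period windows of p.min_window frames; the frame with
    the smallest area in each window is an Fmin if below p.area_thresh;
    its Fmax is the largest-area frame among the p.lookback preceding
    frames."""
    n = len(area)
    if n < 2:
        return []
    if min(area) >= p.area_thresh:
        return []
    pairs = []
    start = 0
    while start < n:
        stop = min(n, start + p.min_window)
        fmin = start
        for t in range(start, stop):
            if area[t] < area[fmin]:
                fmin = t
        if area[fmin] < p.area_thresh:
            lo = fmin - p.lookback
            if lo < 0:
                lo = 0
            if lo < fmin:
                fmax = lo
                for t in range(lo, fmin):
                    if area[t] > area[fmax]:
                        fmax = t
                pairs.append((fmin, fmax))
        start += p.min_window
    return pairs


def oracle_ipt(area, intens, fmax, fmin, p):
    spikes = []
    for t in range(fmax, fmin):
        if intens[t + 1] - intens[t] > p.di_thresh:
            spikes.append(t)
    if spikes:
        ipt = spikes[-1]
        if ipt < fmax + 1:
            ipt = fmax + 1
        return ipt
    if fmin == fmax + 1:
        return None
    if fmin - fmax <= p.short_mitosis_frames:
        q = p.sustained_pct / 100.0
    else:
        q = p.sustained_pct_long / 100.0
    for t in range(fmax + 1, fmin):
        if not area[t + 1] - area[t] < p.da_entry_thresh:
            continue
        if not area[t] < p.spike_guard_pct / 100.0 * area[t - 1]:
            continue
        sustained = True
        for s in range(t + 1, fmin + 1):
            if not area[t] > q * area[s]:
                sustained = False
                break
        if sustained:
            return t
    return None


def oracle_mat(area, ipt, p):
    n = len(area)
    hi = ipt + p.mat_window
    if hi > n - 1:
        hi = n - 1
    if hi <= ipt:
        return None
    mat = ipt + 1
    for t in range(ipt + 1, hi + 1):
        if area[t] < area[mat]:
            mat = t
    if mat == n - 1 and hi < ipt + p.mat_window:
        return None  # trace ended before a minimum was confirmed
    strict_local_min = mat + 1 < n and area[mat + 1] > area[mat]
    if (strict_local_min and mat - 1 > ipt
            and area[mat - 1] <= p.mat_prevframe_pct / 100.0 * area[mat]):
        mat -= 1
    return mat


def oracle_analyze(area, intens, p):
    """Full per-trace detection with the same de-duplication contract."""
    out = []
    seen = set()
    for fmin, fmax in oracle_candidates(area, p):
        ipt = oracle_ipt(area, intens, fmax, fmin, p)
        if ipt is None or ipt in seen:
            continue
        mat = oracle_mat(area, ipt, p)
        if mat is None:
            continue
        seen.add(ipt)
        out.append((fmax, fmin, ipt, mat))
    return out


def oracle_mww_exact_p(a, b):
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    pooled = list(a) + list(b)
    n_a = len(a)
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    def ustat(idx):
        return sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2.0
    u_obs = ustat(range(n_a))
    u_lo = min(u_obs, n_a * (n - n_a) - u_obs)
    u_hi = n_a * (n - n_a) - u_lo
    cnt = tot = 0
    for idx in combinations(range(n), n_a):
        u = ustat(idx)
        tot += 1
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            cnt += 1
    return cnt / tot
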