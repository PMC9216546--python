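"""Compiled Doob-Gillespie core.

The kernel works on a compact encoding of the rate laws (see
``rates.KIND_CODES``) so a single compiled function serves every built-in
system.  Propensities are updated incrementally: after a reaction fires only
the channels that depend on a changed species are re-evaluated, and the
running total is refreshed from scratch every 2**16 events to keep
floating-point drift out of the waiting-time clock.

Randomness comes from numba's internal Mersenne-Twister seeded per call, so
trajectories are bit-reproducible for a given (state, seed) pair.
"""

import numpy as np
from numba import njit

__all__ = ["sample_core", "trajectory_core", "build_dependency_table"]


@njit(cache=True, inline="always")
def _ipow(v, m):
    # v**m for integer m >= 1 without libm pow
    out = v
    for _ in range(int(m) - 1):
        out *= v
    return out


@njit(cache=True, inline="always")
def _powf(v, n):
    if v == 0.0:
        return 0.0
    if n == np.floor(n) and 1.0 <= n <= 32.0:
        return _ipow(v, n)
    return v**n


@njit(cache=True, inline="always")
def _prop_one(kind, sA, sB, p0, p1, p2, p3, x):
    if kind == 0:
        return p0
    if kind == 1:
        return p0 * x[sA]
    if kind == 5:
        return p0 * x[sA] * (x[sA] - 1.0)
    # Hill family: p0=lam, p1=n, p2=K**n (n>0) or K**|n| (n<0), p3=offset coef
    v = x[sA]
    if p1 > 0.0:
        vn = _powf(v, p1)
        h = p0 * vn / (p2 + vn)
    elif p1 < 0.0:
        vn = _powf(v, -p1)
        h = p0 * p2 / (p2 + vn)
    else:
        h = 0.5 * p0
    if kind == 2:
        return h
    if kind == 3:
        return h + p3 * x[sB]
    return h + p3  # kind 4


@njit(cache=True)
def _all_props(kind, sA, sB, pp, x, props):
    tot = 0.0
    for r in range(kind.shape[0]):
        props[r] = _prop_one(kind[r], sA[r], sB[r], pp[r, 0], pp[r, 1], pp[r, 2], pp[r, 3], x)
        tot += props[r]
    return tot


@njit(cache=True)
def sample_core(x0, kind, sA, sB, pp, stoich, dep, ndep, burn_in, interval, n_samples, seed):
    """Run SSA and record the full state every ``interval`` after ``burn_in``.

    Returns (snapshots[n_samples, n_species], n_events, absorbed_flag).
    If an absorbing state is hit, remaining snapshots repeat that state and
    the flag is set.
    """
    np.random.seed(seed)
    nr = kind.shape[0]
    ns = x0.shape[0]
    x = x0.astype(np.float64)
    out = np.zeros((n_samples, ns), dtype=np.int64)
    props = np.zeros(nr)
    tot = _all_props(kind, sA, sB, pp, x, props)
    t = 0.0
    next_t = burn_in
    k = 0
    n_events = 0
    absorbed = False
    while k < n_samples:
        if tot <= 1e-300:
            absorbed = True
            while k < n_samples:
                for s in range(ns):
                    out[k, s] = int(x[s])
                k += 1
            break
        dt = -np.log(np.random.random()) / tot
        t_new = t + dt
        while k < n_samples and next_t <= t_new:
            for s in range(ns):
                out[k, s] = int(x[s])
            k += 1
            next_t += interval
        t = t_new
        u = np.random.random() * tot
        acc = 0.0
        rr = nr - 1
        for r in range(nr):
            acc += props[r]
            if u <= acc:
                rr = r
                break
        for s in range(ns):
            x[s] += stoich[rr, s]
        n_events += 1
        if n_events % 65536 == 0:
            tot = _all_props(kind, sA, sB, pp, x, props)
        else:
            for s in range(ns):
                if stoich[rr, s] != 0:
                    for q in range(ndep[s]):
                        r2 = dep[s, q]
                        tot -= props[r2]
                        props[r2] = _prop_one(
                            kind[r2], sA[r2], sB[r2], pp[r2, 0], pp[r2, 1], pp[r2, 2], pp[r2, 3], x
                        )
                        tot += props[r2]
    return out, n_events, absorbed


@njit(cache=True)
def trajectory_core(x0, kind, sA, sB, pp, stoich, t_end, max_events, seed):
    """Full event record up to ``t_end`` (or ``max_events``).

    Returns (times, states, n_recorded, absorbed).  ``times[0] = 0`` holds the
    initial state; entry i is the state right after the i-th event.
    """
    np.random.seed(seed)
    nr = kind.shape[0]
    ns = x0.shape[0]
    x = x0.astype(np.float64)
    times = np.zeros(max_events + 1)
    states = np.zeros((max_events + 1, ns), dtype=np.int64)
    for s in range(ns):
        states[0, s] = int(x[s])
    props = np.zeros(nr)
    t = 0.0
    k = 0
    absorbed = False
    while k < max_events:
        tot = _all_props(kind, sA, sB, pp, x, props)
        if tot <= 1e-300:
            absorbed = True
            break
        dt = -np.log(np.random.random()) / tot
        if t + dt > t_end:
            break
        t += dt
        u = np.random.random() * tot
        acc = 0.0
        rr = nr - 1
        for r in range(nr):
            acc += props[r]
            if u <= acc:
                rr = r
                break
        for s in range(ns):
            x[s] += stoich[rr, s]
        k += 1
        times[k] = t
        for s in range(ns):
            states[k, s] = int(x[s])
    return times[: k + 1], states[: k + 1], k, absorbed


def build_dependency_table(kind, sA, sB, n_species):
    """dep[s] lists reaction indices whose propensity reads species s."""
    deps = [[] for _ in range(n_species)]
    for r in range(len(kind)):
        used = set()
        if sA[r] >= 0:
            used.add(int(sA[r]))
        if int(kind[r]) == 3 and sB[r] >= 0:
            used.add(int(sB[r]))
        for s in used:
            deps[s].append(r)
    mx = max((len(d) for d in deps), default=1) or 1
    dep = np.zeros((n_species, mx), dtype=np.int64)
    ndep = np.zeros(n_species, dtype=np.int64)
    for s, lst in enumerate(deps):
        ndep[s] = len(lst)
        for q, r in enumerate(lst):
            dep[s, q] = r
    return dep, ndep


def encode_for_kernel(rows):
    """Split the (nr, 7) encoding rows into kernel arrays, pre-powering K."""
    rows = np.asarray(rows, dtype=np.float64)
    kind = rows[:, 0].astype(np.int64)
    sA = rows[:, 1].astype(np.int64)
    sB = rows[:, 2].astype(np.int64)
    pp = rows[:, 3:7].copy()
    for r in range(len(kind)):
        if kind[r] in (2, 3, 4):
            lam, n, K = rows[r, 3], rows[r, 4], rows[r, 5]
            pp[r, 2] = K ** abs(n) if n != 0 else 1.0
    return kind, sA, sB, pp
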