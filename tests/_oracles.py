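"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal double loops over the definitions, kept
deliberately separate from the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def brute_detect(x: np.ndarray, M: int, h: float) -> list[int]:
    """Scan every index against the local-maximum event definition."""
    x = np.asarray(x, dtype=float)
    out = []
    for t in range(M, x.size - M):
        is_event = all(
            x[t] > x[t + m] for m in range(-M + 1, M) if m != 0
        )
        is_event = is_event and x[t] > x[t - M] + h and x[t] > x[t + M] + h
        if is_event:
            out.append(t)
    return out


def brute_tau(t1: np.ndarray, t2: np.ndarray) -> float:
    """Min over all interior event pairs of half the smallest neighbour gap."""
    best = np.inf
    for r in range(1, len(t1) - 1):
        for s in range(1, len(t2) - 1):
            tau_rs = 0.5 * min(
                t1[r + 1] - t1[r],
                t1[r] - t1[r - 1],
                t2[s + 1] - t2[s],
                t2[s] - t2[s - 1],
            )
            best = min(best, tau_rs)
    return float(best)


def brute_pair_counts(t1: np.ndarray, t2: np.ndarray, tau: float) -> tuple[float, float]:
    """(e_ab, e_ba): double loop over the coincidence matrix definition."""
    e_ab = 0.0
    e_ba = 0.0
    for a in t1:
        for b in t2:
            d = a - b
            if d == 0:
                e_ab += 0.5
                e_ba += 0.5
            elif 0 < d <= tau:
                e_ab += 1.0
            elif 0 < -d <= tau:
                e_ba += 1.0
    return e_ab, e_ba


def brute_cumulative(t1: np.ndarray, t2: np.ndarray, tau: float, n: int) -> tuple[float, float]:
    """(Q(n), q(n)) with each pair gated by the step function on its own side."""
    e_ab_n = 0.0
    e_ba_n = 0.0
    for a in t1:
        for b in t2:
            d = a - b
            w_ab = 0.5 if d == 0 else (1.0 if 0 < d <= tau else 0.0)
            w_ba = 0.5 if d == 0 else (1.0 if 0 < -d <= tau else 0.0)
            if n - a > 0:  # step function on the a-side event
                e_ab_n += w_ab
            if n - b > 0:  # step function on the b-side event
                e_ba_n += w_ba
    return e_ba_n + e_ab_n, e_ba_n - e_ab_n


def brute_rate(
    t1: np.ndarray, t2: np.ndarray, tau: float, window: int, n: int
) -> tuple[float, float]:
    """(dQ(n), dq(n)) recomputed from the truncated double loops."""
    Q_hi, q_hi = brute_cumulative(t1, t2, tau, n)
    Q_lo, q_lo = brute_cumulative(t1, t2, tau, n - window)
    d1 = sum(1 for a in t1 if n - window <= a < n)
    d2 = sum(1 for b in t2 if n - window <= b < n)
    if d1 * d2 == 0:
        return 0.0, 0.0
    return (Q_hi - Q_lo) / (d1 * d2), (q_hi - q_lo) / (d1 * d2)


def straight_line_indices(A: np.ndarray) -> tuple[float, float, float]:
    """(H_in, H_se, H_sb_norm) recomputed in one flat pass over the definitions."""
    A = np.asarray(A, dtype=float)
    N = A.shape[0]
    vals, vecs = np.linalg.eig(A)
    order = sorted(range(len(vals)), key=lambda k: (-abs(vals[k]), np.angle(vals[k])))
    vals = vals[order]
    vecs = vecs[:, order]
    moduli = np.abs(vals)
    H_in = moduli[0] ** 2 / N**2
    H_se = 0.0
    for i in range(1, N):
        comp = np.abs(vecs[:, i] / np.linalg.norm(vecs[:, i]))
        avg, sd = comp.mean(), comp.std()
        sizes = []
        for lo, hi in ((-np.inf, avg + sd), (avg + sd, avg + 2 * sd), (avg + 2 * sd, np.inf)):
            m = int(((comp > lo) & (comp <= hi)).sum())
            if m:
                sizes.append(m)
        M_i = len(sizes)
        p_i = sum(abs(m - N / M_i) for m in sizes) / N
        H_se += moduli[i] ** 2 * M_i * (1 - p_i) / N**2
    total = H_in + H_se
    hsb = (H_in - H_se) / total if total > 0 else 0.0
    return float(H_in), float(H_se), float(hsb)


def random_train(
    rng: np.random.Generator,
    n_events: int,
    length: int,
    min_spacing: int = 10,
) -> np.ndarray:
    """Random strictly increasing event times respecting a minimum spacing."""
    times: list[int] = []
    guard = 0
    while len(times) < n_events and guard < 100 * n_events:
        t = int(rng.integers(min_spacing, length - min_spacing))
        if all(abs(t - u) >= min_spacing for u in times):
            times.append(t)
        guard += 1
    return np.sort(np.asarray(times, dtype=np.int64))
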