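"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

import numpy as np


def window_union_oracle(times, threshold: float, n_spikes: int) -> np.ndarray:
    """Burst detection by exhaustive window enumeration + time-interval union.

    Every window of ``n_spikes`` consecutive spikes is tested against the
    span criterion; the closed time intervals of qualifying windows are then
    merged wherever they overlap or touch.  O(n * N) and deliberately naive.
    """
    t = list(times)
    merged: list[list[float]] = []
    for i in range(len(t) - n_spikes + 1):
        s, e = t[i], t[i + n_spikes - 1]
        if e - s <= threshold:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
    return np.array(merged, dtype=float).reshape(-1, 2)


def episode_closure_oracle(intervals, gap_threshold: float) -> list[list[int]]:
    """Episode grouping as the transitive closure of the pairwise gap relation.

    ``intervals`` is a time-ordered list of (start, end).  Two bursts are
    related when the quiet time between them is at most ``gap_threshold``;
    groups are the connected components (union-find over all pairs).
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(0.0, intervals[j][0] - intervals[i][1])
            if gap <= gap_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def exhaustive_permutation_p(test, control) -> float:
    """Exact two-sided permutation p over every label assignment."""
    from itertools import combinations

    x = list(test)
    y = list(control)
    pool = x + y
    nx = len(x)
    obs = abs(np.mean(x) - np.mean(y))
    hits = 0
    total = 0
    idx = range(len(pool))
    for comb in combinations(idx, nx):
        sel = set(comb)
        a = [pool[i] for i in idx if i in sel]
        b = [pool[i] for i in idx if i not in sel]
        if abs(np.mean(a) - np.mean(b)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total
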