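"""Independent pure-Python reference implementations used as test oracles.

Everything here is written with explicit loops and the standard library
(plus float arithmetic identical in order to the package's numpy
expressions), deliberately avoiding the package's own code paths.
"""

from __future__ import annotations

import math
from itertools import combinations


def ref_embed(values, E):
    """Delay vectors <y(t), y(t-1), ..., y(t-(E-1))> with their anchor index."""
    n = len(values)
    out = []
    for t in range(E - 1, n):
        out.append((t, tuple(values[t - k] for k in range(E))))
    return out


def ref_distance(u, v):
    s = 0.0
    for a, b in zip(u, v):
        s += (a - b) * (a - b)
    return math.sqrt(s)


def ref_weights(distances):
    if distances[0] == 0.0:
        w = [1.0 if d == 0.0 else 0.0 for d in distances]
        total = sum(w)
        return [x / total for x in w]
    u = [math.exp(-d / distances[0]) for d in distances]
    total = sum(u)
    return [x / total for x in u]


def ref_neighbors(library, query, k, exclude_anchor=None):
    """k nearest (anchor, distance) pairs; ties broken by smaller anchor."""
    cands = []
    for anchor, vec in library:
        if exclude_anchor is not None and anchor == exclude_anchor:
            continue
        cands.append((ref_distance(query, vec), anchor, vec))
    cands.sort(key=lambda c: (c[0], c[1]))
    if len(cands) < k:
        raise ValueError("not enough neighbors")
    return [(a, d) for d, a, _ in cands[:k]]


def ref_simplex_forecast(target, library, E, exclude_self):
    """One-step simplex forecasts of `target` from `library` (lists of floats).

    Returns a list of (anchor, observed_next, predicted_next).  When
    exclude_self is set, anchors are matched positionally (target and
    library are then the same series).
    """
    lib = [
        (t, vec)
        for t, vec in ref_embed(library, E)
        if t < len(library) - 1
    ]
    out = []
    for t, vec in ref_embed(target, E):
        if t >= len(target) - 1:
            continue
        nn = ref_neighbors(lib, vec, E + 1, exclude_anchor=t if exclude_self else None)
        w = ref_weights([d for _, d in nn])
        pred = sum(wi * library[a + 1] for wi, (a, _) in zip(w, nn))
        out.append((t, target[t + 1], pred))
    return out


def ref_cross_map_forecast(target_x, target_y, library_x, library_y, E, exclude_self):
    """Contemporaneous cross-map forecasts of target_y from library pairs."""
    lib = list(ref_embed(library_x, E))
    out = []
    for t, vec in ref_embed(target_x, E):
        nn = ref_neighbors(lib, vec, E + 1, exclude_anchor=t if exclude_self else None)
        w = ref_weights([d for _, d in nn])
        pred = sum(wi * library_y[a] for wi, (a, _) in zip(w, nn))
        out.append((t, target_y[t], pred))
    return out


def ref_loo_best_E(values, E_max):
    """(best_E, best_r): exhaustive leave-one-out simplex skill search."""
    best = None
    for E in range(1, E_max + 1):
        rows = ref_simplex_forecast(values, values, E, exclude_self=True)
        obs = [o for _, o, _ in rows]
        pred = [p for _, _, p in rows]
        r = ref_pearson(obs, pred)
        if r is not None and (best is None or r > best[1]):
            best = (E, r)
    return best


def ref_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x))
    sy = math.sqrt(sum((v - my) ** 2 for v in y))
    if sx == 0.0 or sy == 0.0:
        return None
    return sum((a - mx) * (b - my) for a, b in zip(x, y)) / (sx * sy)


def ref_exact_permutation_p(across, within):
    """Exact one-sided p by complete enumeration of group assignments."""
    pooled = list(across) + list(within)
    n, n_a = len(pooled), len(across)
    d_obs = sum(across) / n_a - sum(within) / (n - n_a)
    hits = 0
    total = 0
    for combo in combinations(range(n), n_a):
        group_a = [pooled[i] for i in combo]
        group_w = [pooled[i] for i in range(n) if i not in set(combo)]
        d = sum(group_a) / n_a - sum(group_w) / (n - n_a)
        total += 1
        if d >= d_obs - 1e-12:
            hits += 1
    return hits / total


def ref_fold_scan(drift, c_lo=0.5, c_hi=4.0, c_step=1e-4, x_hi=12.0, x_step=1e-3):
    """Fold locations by dense sign-change scan of the skeleton drift.

    `drift(x, c)` is the deterministic right-hand side.  Returns the (lo, hi)
    harvest rates where the count of positive equilibria changes.
    """
    import numpy as np

    xs = np.arange(x_step, x_hi, x_step)
    transitions = []
    prev = None
    c = c_lo
    while c <= c_hi + 1e-12:
        f = drift(xs, c)
        count = int(((f[:-1] > 0) & (f[1:] <= 0)).sum() + ((f[:-1] <= 0) & (f[1:] > 0)).sum())
        if prev is not None and count != prev:
            transitions.append(c)
        prev = count
        c += c_step
    return transitions
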