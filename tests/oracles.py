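"""Independent reference implementations used to check the package.

These deliberately use the most literal, brute-force formulation of each
quantity (exact rational arithmetic where feasible) and share no code with
the implementations they audit.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def brute_force_betweenness(nodes, edges) -> dict:
    """Betweenness by exhaustive enumeration of all shortest paths.

    For every unordered pair (s, t) all shortest s-t paths are enumerated by
    depth-first search over the BFS predecessor structure; each interior
    vertex of a path receives Fraction(1, n_paths) credit. Exact arithmetic.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS distances from s
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    path.append(w)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    bc = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        share = Fraction(1, len(paths))
        for p in paths:
            for v in p[1:-1]:
                bc[v] += share
    return bc


def exact_hypergeom_tail(n_bg: int, n_term: int, n_query: int, count: int) -> Fraction:
    """P[X >= count] for X ~ Hypergeom(n_bg, n_term, n_query), exact."""
    total = comb(n_bg, n_query)
    acc = Fraction(0)
    for k in range(count, min(n_term, n_query) + 1):
        if n_query - k > n_bg - n_term:
            continue
        acc += Fraction(comb(n_term, k) * comb(n_bg - n_term, n_query - k), total)
    return acc


def brute_force_bh(p) -> np.ndarray:
    """BH adjusted p by the definition: min over j >= rank of (m/j) p_(j), cap 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        adj[idx] = min(1.0, min(m * p[order[j]] / (j + 1) for j in range(pos, m)))
    return adj


def pooled_t(x1, x0) -> tuple[float, float]:
    """Classical pooled two-sample t: (t, df)."""
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    n1, n0 = x1.size, x0.size
    df = n1 + n0 - 2
    sp2 = (np.sum((x1 - x1.mean()) ** 2) + np.sum((x0 - x0.mean()) ** 2)) / df
    t = (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    return float(t), float(df)


def residual_partial_corr(x, y, z) -> float:
    """Partial correlation as the correlation of OLS residuals on {1, z}."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    design = np.column_stack([np.ones_like(z), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spreadsheet_km(time, event):
    """Step-by-step product-limit table: rows (t, n, d, S, greenwood V)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    s = 1.0
    acc = 0.0
    for t in sorted(set(time[event == 1])):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s = s * (n - d) / n
        if n > d:
            acc += d / (n * (n - d))
            v = s * s * acc
        else:
            v = 0.0
        rows.append((t, n, d, s, v))
    return rows


def exhaustive_best_subset(nodes, edges, seed, penalty=2.0):
    """The cohesiveness-maximising subset containing ``seed`` (tiny graphs)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def f(members):
        members = set(members)
        w_in = sum(1 for e in edge_set if e <= members)
        w_bound = sum(1 for e in edge_set if len(e & members) == 1)
        denom = w_in + w_bound + penalty * len(members)
        return w_in / denom if denom else 0.0

    others = [v for v in nodes if v != seed]
    best, best_f = {seed}, f({seed})
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            members = {seed, *combo}
            val = f(members)
            if val > best_f:
                best, best_f = members, val
    return best, best_f
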