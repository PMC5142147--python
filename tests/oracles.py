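"""Independent brute-force oracles used only by the test-suite."""

import numpy as np
from scipy.optimize import linprog


def single_linkage_groups(values: np.ndarray, threshold: float) -> np.ndarray:
    """Connected components of the 'distance <= threshold' graph on 1-D
    points, via union-find over all pairs; labels 1..k ascending by value."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i in range(n):
        for j in range(i + 1, n):
            if abs(v[i] - v[j]) <= threshold:
                union(i, j)
    roots = np.array([find(i) for i in range(n)])
    # order components by their minimum value
    comp_min = {}
    for i, r in enumerate(roots):
        comp_min[r] = min(comp_min.get(r, np.inf), v[i])
    order = {r: rank + 1 for rank, r in enumerate(sorted(comp_min, key=comp_min.get))}
    return np.array([order[r] for r in roots], dtype=float)


def dip_lp(x: np.ndarray) -> float:
    """Dip from the definition: minimise sup|F_n - G| over unimodal G by
    linear programming, enumerating the modal point (a jump at the mode
    is allowed).  Exponential in nothing, but O(n) LPs — small n only."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    best = np.inf
    for k in range(1, n + 1):
        # variables: t, g_1..g_n (g_k = G(mode^-)), g_{n+1} = G(mode)
        nv = n + 2
        jr = n + 1
        c = np.zeros(nv)
        c[0] = 1.0
        A, b = [], []

        def add(row, rhs):
            A.append(row)
            b.append(rhs)

        for i in range(1, n + 1):
            targets = (((i - 1) / n, i), (i / n, jr if i == k else i)) if i == k else (
                ((i - 1) / n, i), (i / n, i))
            for fv, vi in targets:
                row = np.zeros(nv); row[vi] = 1.0; row[0] = -1.0
                add(row, fv)
                row = np.zeros(nv); row[vi] = -1.0; row[0] = -1.0
                add(row, -fv)

        def left_vec(i):
            v = np.zeros(nv); v[i] = 1.0; return v

        def right_vec(i):
            v = np.zeros(nv); v[jr if i == k else i] = 1.0; return v

        seq = [left_vec(i) for i in range(1, k + 1)] + [right_vec(k)] + [
            right_vec(i) for i in range(k + 1, n + 1)]
        for a1, a2 in zip(seq[:-1], seq[1:]):
            add(a1 - a2, 0.0)  # nondecreasing

        left_slopes = [
            (left_vec(i + 1) - left_vec(i)) / (x[i] - x[i - 1])
            for i in range(1, k) if x[i] != x[i - 1]
        ]
        for s1, s2 in zip(left_slopes[:-1], left_slopes[1:]):
            add(s1 - s2, 0.0)  # convex: slopes nondecreasing
        right_slopes = [
            (left_vec(i + 1) - right_vec(i)) / (x[i] - x[i - 1])
            for i in range(k, n) if x[i] != x[i - 1]
        ]
        for s1, s2 in zip(right_slopes[:-1], right_slopes[1:]):
            add(s2 - s1, 0.0)  # concave: slopes nonincreasing

        bounds = [(0, None)] + [(0, 1)] * (n + 1)
        res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                      method="highs")
        assert res.success, res.message
        best = min(best, res.fun)
    return float(best)


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the probability that a positive outranks a negative, by
    explicit enumeration of all (positive, negative) pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for c in neg:
            total += 1.0 if a > c else (0.5 if a == c else 0.0)
    return total / (len(pos) * len(neg))
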