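"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive (loops, enumeration, closed forms) and
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import lognorm


def brute_pairwise(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.hypot(
                coords[i][0] - coords[j][0], coords[i][1] - coords[j][1]
            )
    return out


def brute_directional_nn(ids, coords, bearing_deg):
    """(source_id, neighbor_id, distance) triples by exhaustive scan.

    'Further along the bearing' is the strict lexicographic order on
    (along-bearing coordinate, perpendicular coordinate, identifier).
    """
    rad = math.radians(bearing_deg)
    ux, uy = math.sin(rad), math.cos(rad)
    px, py = math.cos(rad), -math.sin(rad)
    keys = {
        i: (coords[k][0] * ux + coords[k][1] * uy,
            coords[k][0] * px + coords[k][1] * py,
            i)
        for k, i in enumerate(ids)
    }
    pos = {i: coords[k] for k, i in enumerate(ids)}
    out = []
    for i in ids:
        best = None
        for j in ids:
            if j == i or keys[j] <= keys[i]:
                continue
            d = math.hypot(pos[j][0] - pos[i][0], pos[j][1] - pos[i][1])
            if best is None or (d, j) < best:
                best = (d, j)
        if best is not None:
            out.append((i, best[1], best[0]))
    return out


def brute_chain_components(ids, coords, edge_threshold) -> dict:
    """Transitive closure of the <=-threshold adjacency; ``edge_threshold``
    is a float or a function (i_index, j_index) -> threshold."""
    n = len(ids)
    thr = edge_threshold if callable(edge_threshold) else (lambda a, b: edge_threshold)
    adj = [[False] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a != b:
                d = math.hypot(
                    coords[a][0] - coords[b][0], coords[a][1] - coords[b][1]
                )
                adj[a][b] = d <= thr(a, b)
    comp = list(range(n))
    changed = True
    while changed:  # naive closure: propagate smallest component index
        changed = False
        for a in range(n):
            for b in range(n):
                if adj[a][b] and comp[a] != comp[b]:
                    lo = min(comp[a], comp[b])
                    comp[a] = comp[b] = lo
                    changed = True
    groups: dict[int, set] = {}
    for k, c in enumerate(comp):
        groups.setdefault(c, set()).add(ids[k])
    return {frozenset(v) for v in groups.values()}


def partition_to_sets(assignment: dict) -> set:
    groups: dict[str, set] = {}
    for ind, comp in assignment.items():
        groups.setdefault(comp, set()).add(ind)
    return {frozenset(v) for v in groups.values()}


def brute_adjusted_rand(labels_a, labels_b) -> float:
    """Adjusted Rand from explicit pair counting over all item pairs."""
    n = len(labels_a)
    a = b = ab = 0  # same-in-a, same-in-b, same-in-both
    for i, j in combinations(range(n), 2):
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        a += sa
        b += sb
        ab += sa and sb
    total = n * (n - 1) // 2
    expected = a * b / total if total else 0.0
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return (ab - expected) / (max_index - expected)


def lognormal_mixture_antimode(
    params, weights, lo=1e-3, hi=1e4, m=200_001
) -> float:
    """Deepest interior valley of a lognormal mixture pdf by dense scan.

    ``params`` is a list of (mu, sigma) of the underlying normals.
    """
    d = np.geomspace(lo, hi, m)
    f = sum(
        w * lognorm.pdf(d, s, scale=np.exp(mu))
        for w, (mu, s) in zip(weights, params)
    )
    interior = np.flatnonzero((f[1:-1] < f[:-2]) & (f[1:-1] <= f[2:])) + 1
    assert interior.size, "mixture has no interior valley"
    return float(d[interior[np.argmin(f[interior])]])


def lognormal_mixture_antimodes(params, weights, lo=1e-3, hi=1e4, m=200_001):
    """All interior valleys of a lognormal mixture pdf, ascending."""
    d = np.geomspace(lo, hi, m)
    f = sum(
        w * lognorm.pdf(d, s, scale=np.exp(mu))
        for w, (mu, s) in zip(weights, params)
    )
    interior = np.flatnonzero((f[1:-1] < f[:-2]) & (f[1:-1] <= f[2:])) + 1
    return [float(d[i]) for i in interior]
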