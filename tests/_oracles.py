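"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (exhaustive scans, plain recursion)
and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def brute_components(nodes: list, edges: set[tuple]) -> list[set]:
    """Connected components by repeated BFS over an explicit edge set."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            n = frontier.pop()
            for m in adj[n]:
                if m not in comp:
                    comp.add(m)
                    frontier.append(m)
        seen |= comp
        comps.append(comp)
    return comps


def brute_chromatic(nodes: list, edges: set[tuple]) -> int:
    """Minimal k admitting a proper coloring, by plain backtracking.

    Nodes are taken in their given order; every color 0..k-1 is tried for
    each node with only the adjacency check as pruning.
    """
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def colorable(k: int) -> bool:
        colors: dict = {}

        def rec(i: int) -> bool:
            if i == len(nodes):
                return True
            n = nodes[i]
            for c in range(k):
                if all(colors.get(m) != c for m in adj[n]):
                    colors[n] = c
                    if rec(i + 1):
                        return True
                    del colors[n]
            return False

        return rec(0)

    k = 1
    while not colorable(k):
        k += 1
    return k


def brute_min_boundary_distance(img_pixels: np.ndarray, label_u: int, label_v: int,
                                pixel_size: float) -> float:
    """Minimum distance (µm) over all boundary-pixel pairs of two labels."""

    def boundary(label: int) -> np.ndarray:
        mask = img_pixels == label
        coords = []
        rows, cols = mask.shape
        for r, c in zip(*np.nonzero(mask)):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                    coords.append((r, c))
                    break
        return np.array(coords, dtype=float)

    bu, bv = boundary(label_u), boundary(label_v)
    d2 = ((bu[:, None, :] - bv[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min())) * pixel_size


def rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman r as Pearson correlation of mid-ranks, ranks by exhaustive count."""

    def midranks(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, val in enumerate(v):
            less = np.sum(v < val)
            equal = np.sum(v == val)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def random_graph(n: int, p: float, rng: np.random.Generator) -> tuple[list, set]:
    """Erdős–Rényi style node/edge sets over integer nodes."""
    nodes = list(range(n))
    edges = {(u, v) for u in nodes for v in nodes if u < v and rng.random() < p}
    return nodes, edges
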