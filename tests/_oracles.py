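"""Independent brute-force oracles used by the test suite.

Everything here is deliberately built on third-party graph/image routines
(networkx, scipy.ndimage) rather than on the package's own propagation
code, so that agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import ndimage

OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, v):
    return all(0 <= c < s for c, s in zip(v, shape))


def fuzzy_graph(mu: np.ndarray, spacing) -> nx.Graph:
    """26-adjacency graph over the support with link-length edge weights."""
    sp = np.asarray(spacing, dtype=float)
    g = nx.Graph()
    for p in map(tuple, np.argwhere(mu > 0)):
        g.add_node(p)
        for off in OFFSETS:
            q = tuple(np.add(p, off))
            if _inside(mu.shape, q) and mu[q] > 0:
                w = 0.5 * (mu[p] + mu[q]) * float(np.linalg.norm(np.asarray(off) * sp))
                if not g.has_edge(p, q) or g.edges[p, q]["weight"] > w:
                    g.add_edge(p, q, weight=w)
    return g


def fdt_oracle(mu: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive Dijkstra distance-to-background for every support voxel."""
    sp = np.asarray(spacing, dtype=float)
    g = fuzzy_graph(mu, spacing)
    g.add_node("bg")
    for p in map(tuple, np.argwhere(mu > 0)):
        best = np.inf
        for off in OFFSETS:
            q = tuple(np.add(p, off))
            if not _inside(mu.shape, q) or mu[q] == 0:
                step = float(np.linalg.norm(np.asarray(off) * sp))
                best = min(best, 0.5 * mu[p] * step)
        if np.isfinite(best):
            g.add_edge("bg", p, weight=best)
    dist = nx.single_source_dijkstra_path_length(g, "bg")
    out = np.zeros(mu.shape)
    for p in map(tuple, np.argwhere(mu > 0)):
        out[p] = dist.get(p, np.inf)
    return out


def fuzzy_distance_oracle(mu: np.ndarray, spacing, p, q) -> float:
    g = fuzzy_graph(mu, spacing)
    try:
        return float(nx.dijkstra_path_length(g, tuple(p), tuple(q)))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return float("inf")


def node_weight_cost_oracle(weight: np.ndarray, region: np.ndarray, src, dst) -> float:
    """Minimal sum of node weights over paths (each voxel counted once)."""
    g = nx.DiGraph()
    for p in map(tuple, np.argwhere(region)):
        for off in OFFSETS:
            q = tuple(np.add(p, off))
            if _inside(region.shape, q) and region[q]:
                g.add_edge(p, q, weight=float(weight[q]))
    src, dst = tuple(src), tuple(dst)
    if src == dst:
        return float(weight[src])
    return float(weight[src]) + float(nx.dijkstra_path_length(g, src, dst))


def geodesic_length_oracle(region: np.ndarray, spacing, src, dst) -> float:
    """Shortest physical path length between two voxels inside a mask."""
    sp = np.asarray(spacing, dtype=float)
    g = nx.Graph()
    for p in map(tuple, np.argwhere(region)):
        g.add_node(p)
        for off in OFFSETS:
            q = tuple(np.add(p, off))
            if _inside(region.shape, q) and region[q]:
                g.add_edge(p, q, weight=float(np.linalg.norm(np.asarray(off) * sp)))
    return float(nx.dijkstra_path_length(g, tuple(src), tuple(dst)))


def erosion_disconnection_oracle(mask: np.ndarray, seed_a, seed_b):
    """Split a fused binary object into two labels.

    Erode at increasing Euclidean radii until the two seeds fall into
    different components, label the eroded remnants by their seed, then
    back-propagate the labels by simultaneous geodesic dilation inside the
    object (26-connected, one shell per round; voxels reached by both in
    the same round go to label 1).  Returns an int array with 1 where
    seed_a's object lies and 2 for seed_b's.
    """
    seed_a, seed_b = tuple(seed_a), tuple(seed_b)
    structure = np.ones((3, 3, 3), dtype=bool)
    edt = ndimage.distance_transform_edt(mask)
    radius = 0.0
    eroded = mask
    while True:
        lab, _ = ndimage.label(eroded, structure=structure)
        if lab[seed_a] == 0 or lab[seed_b] == 0 or lab[seed_a] != lab[seed_b]:
            break
        radius += 1.0
        nxt = edt >= radius
        if not nxt.any():
            break
        eroded = nxt
    lab, _ = ndimage.label(eroded, structure=structure)
    a = lab == lab[seed_a] if lab[seed_a] else np.zeros_like(mask)
    b = lab == lab[seed_b] if lab[seed_b] else np.zeros_like(mask)
    a = a & mask
    b = b & mask & ~a
    a = a.copy()
    b = b.copy()
    a[seed_a] = True
    b[seed_b] = True
    while True:
        grow_a = ndimage.binary_dilation(a, structure=structure) & mask & ~a & ~b
        grow_b = ndimage.binary_dilation(b, structure=structure) & mask & ~a & ~b
        if not grow_a.any() and not grow_b.any():
            break
        both = grow_a & grow_b
        a |= grow_a  # simultaneous round; contested shell voxels go to a
        b |= grow_b & ~both & ~a
    out = np.zeros(mask.shape, dtype=np.int8)
    out[a] = 1
    out[b] = 2
    return out


def fused_balls_instance(rng: np.random.Generator, shape=(26, 26, 26)):
    """A random pair of fused balls with interior seed voxels (unit spacing)."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    while True:
        r1 = int(rng.integers(5, 8))
        r2 = int(rng.integers(5, 8))
        c1 = np.array([shape[0] // 2, shape[1] // 2, r1 + 2]) + rng.integers(-1, 2, 3)
        gap = int(rng.integers(-2, 2))  # centre distance r1 + r2 + gap
        c2 = c1 + np.array([0, 0, r1 + r2 + gap])
        c2 += rng.integers(-2, 3, 3) * np.array([1, 1, 0])
        if c2[2] + r2 + 2 >= shape[2]:
            continue
        b1 = (zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2 <= r1**2
        b2 = (zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2 <= r2**2
        mask = b1 | b2
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        if n != 1:
            continue  # not fused; try again
        return mask, tuple(int(c) for c in c1), tuple(int(c) for c in c2)
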