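"""Fuzzy objects, membership ramps, fuzzy distance transforms and geodesic paths.

A fuzzy object is a membership map mu : Z^3 -> [0, 1]; its *support* is the
set of voxels with nonzero membership and everything else (including the
outside of the acquired field of view) is background.  All geometry is
carried out on the 26-adjacency graph of the voxel grid with physically
scaled links: a link between adjacent voxels p, q has length

    0.5 * (mu(p) + mu(q)) * ||p - q||,

where ``||.||`` is the Euclidean step in micrometres under the (possibly
anisotropic) voxel spacing.  The fuzzy distance between two voxels is the
minimum total link length over all 26-connected paths, and the fuzzy
distance transform (FDT) of an object is, per voxel, the fuzzy distance to
the background: a depth map measuring the local half-width of the
structure.  The FDT of a dendrite+spine object is what both the multi-scale
opening segmentation and all width/length morphometry are built on.

Memberships for the two-object (spine vs. dendrite) model are intensity
ramps between a spine-representative intensity ``i_spine`` and a
dendrite-representative intensity ``i_dendrite``: below the band a voxel is
purely spine-like, above it purely dendrite-like, and inside the shared
band the two complementary ramps encode partial belonging.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import NoPathError, ValidationError

Voxel = tuple[int, int, int]

#: All 26 neighbour offsets in lexicographic order.
OFFSETS: np.ndarray = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)

#: One offset per unordered neighbour pair (the lexicographically negative half).
HALF_OFFSETS: np.ndarray = OFFSETS[:13]

_OFFSET_TUPLES: list[Voxel] = [tuple(int(c) for c in o) for o in OFFSETS]


def _as_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValidationError(f"spacing must be 3 positive components, got {spacing!r}")
    return sp  # type: ignore[return-value]


def _shift_slices(shape: Sequence[int], offset: Sequence[int]):
    """Slices (a, b) such that voxels a and a+offset are paired: b = a + offset."""
    a, b = [], []
    for dim, o in zip(shape, offset):
        o = int(o)
        a.append(slice(max(0, -o), dim - max(0, o)))
        b.append(slice(max(0, o), dim - max(0, -o)))
    return tuple(a), tuple(b)


@dataclass(frozen=True)
class FuzzyObject:
    """A fuzzy subset of the voxel grid with physical voxel spacing (um)."""

    membership: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        mem = np.asarray(self.membership, dtype=np.float64)
        if mem.ndim != 3:
            raise ValidationError("membership must be a 3-D array")
        if mem.size and (mem.min() < 0.0 or mem.max() > 1.0):
            raise ValidationError("membership values must lie in [0, 1]")
        object.__setattr__(self, "membership", mem)
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))

    @property
    def support(self) -> np.ndarray:
        """Boolean mask of voxels with nonzero membership."""
        return self.membership > 0.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.membership.shape


@dataclass(frozen=True)
class FDTMap:
    """Per-voxel fuzzy distance from the background, in micrometres."""

    omega: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=np.float64))
        object.__setattr__(self, "spacing", _as_spacing(self.spacing))


@dataclass(frozen=True)
class VoxelPath:
    """An ordered 26-connected voxel sequence with cached lengths.

    ``length_um`` is the geometric (unit-membership) length of the chain;
    ``cost`` optionally carries the node-weight sum used to select the path.
    """

    voxels: tuple[Voxel, ...]
    length_um: float
    cost: float = float("nan")

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class IntensityBands:
    """Pure/shared intensity bands of the two-object model.

    ``i_min <= i_spine < i_dendrite <= i_max``; intensities below ``i_spine``
    are purely spine-like, at or above ``i_dendrite`` purely dendrite-like,
    and the interval between them is the shared band where the two ramp
    memberships are complementary.
    """

    i_min: float
    i_spine: float
    i_dendrite: float
    i_max: float

    def __post_init__(self):
        if not (self.i_min <= self.i_spine < self.i_dendrite <= self.i_max):
            raise ValidationError(
                "bands must satisfy i_min <= i_spine < i_dendrite <= i_max, got "
                f"({self.i_min}, {self.i_spine}, {self.i_dendrite}, {self.i_max})"
            )

    @classmethod
    def auto(cls, intensities: np.ndarray) -> "IntensityBands":
        """Two-threshold Otsu on the foreground intensity histogram."""
        from skimage.filters import threshold_multiotsu

        vals = np.asarray(intensities, dtype=np.float64).ravel()
        if vals.size == 0:
            raise ValidationError("cannot derive intensity bands from an empty sample")
        lo, hi = float(vals.min()), float(vals.max())
        n_distinct = np.unique(vals).size
        if n_distinct == 1:
            # single-level foreground: everything is pure dendrite
            return cls(lo - 1.0, lo - 0.5, lo, hi)
        if n_distinct == 2:
            # two crisp levels: split the gap into pure/shared/pure thirds
            return cls(lo, lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0, hi)
        t1, t2 = threshold_multiotsu(vals, classes=3)
        return cls(lo, float(t1), float(t2), hi)

    def pure_spine(self, intensity: np.ndarray) -> np.ndarray:
        return np.asarray(intensity) < self.i_spine

    def pure_dendrite(self, intensity: np.ndarray) -> np.ndarray:
        return np.asarray(intensity) >= self.i_dendrite


def membership_dendrite(intensity, bands: IntensityBands):
    """Dendrite membership ramp: 0 below the band, linear inside, 1 above."""
    i = np.asarray(intensity, dtype=np.float64)
    ramp = (i - bands.i_spine) / (bands.i_dendrite - bands.i_spine)
    out = np.clip(ramp, 0.0, 1.0)
    return float(out) if np.isscalar(intensity) else out


def membership_spine(intensity, bands: IntensityBands):
    """Spine membership: 0 below ``i_min``, 1 in the pure spine band, ramp down
    across the shared band, 0 at or above ``i_dendrite``."""
    i = np.asarray(intensity, dtype=np.float64)
    ramp = (bands.i_dendrite - i) / (bands.i_dendrite - bands.i_spine)
    out = np.where(i < bands.i_min, 0.0, np.clip(ramp, 0.0, 1.0))
    return float(out) if np.isscalar(intensity) else out


def fuzzy_union(a: FuzzyObject, b: FuzzyObject) -> FuzzyObject:
    """Voxelwise maximum of the two memberships."""
    if a.shape != b.shape or a.spacing != b.spacing:
        raise ValidationError("fuzzy_union requires identical shapes and spacings")
    return FuzzyObject(np.maximum(a.membership, b.membership), a.spacing)


def link_length(p: Voxel, q: Voxel, obj: FuzzyObject) -> float:
    """Length of the link p--q: 0.5 * (mu(p) + mu(q)) * physical step."""
    d = np.subtract(p, q)
    if np.all(d == 0) or np.abs(d).max() > 1:
        raise ValidationError(f"voxels {p} and {q} are not 26-adjacent")
    step = float(np.linalg.norm(d * np.asarray(obj.spacing)))
    return 0.5 * (float(obj.membership[p]) + float(obj.membership[q])) * step


def path_length(voxels: Sequence[Voxel], spacing, membership: np.ndarray | None = None) -> float:
    """Sum of link lengths along a voxel chain (unit membership if omitted)."""
    sp = np.asarray(_as_spacing(spacing))
    total = 0.0
    for a, b in zip(voxels[:-1], voxels[1:]):
        d = np.subtract(a, b)
        if np.abs(d).max() > 1 or np.all(d == 0):
            raise ValidationError("path voxels must be consecutive 26-neighbours")
        step = float(np.linalg.norm(d * sp))
        mu = 1.0 if membership is None else 0.5 * (float(membership[tuple(a)]) + float(membership[tuple(b)]))
        total += mu * step
    return total


def build_link_graph(
    mask: np.ndarray,
    spacing,
    membership: np.ndarray | None = None,
) -> tuple[csr_matrix, np.ndarray]:
    """Sparse 26-adjacency graph over ``mask`` with link-length edge weights.

    Returns the symmetric CSR matrix and an index volume mapping each masked
    voxel to its node id (-1 outside).  With ``membership=None`` the links are
    purely geometric (unit membership).
    """
    sp = np.asarray(_as_spacing(spacing))
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    node_id = np.full(mask.shape, -1, dtype=np.int64)
    node_id[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    for off in HALF_OFFSETS:
        a_sl, b_sl = _shift_slices(mask.shape, off)
        both = mask[a_sl] & mask[b_sl]
        if not both.any():
            continue
        ai = node_id[a_sl][both]
        bi = node_id[b_sl][both]
        step = float(np.linalg.norm(off * sp))
        if membership is None:
            w = np.full(ai.size, step)
        else:
            w = 0.5 * (membership[a_sl][both] + membership[b_sl][both]) * step
        rows.append(ai)
        cols.append(bi)
        vals.append(w)
    if rows:
        r = np.concatenate(rows + cols)
        c = np.concatenate(cols + rows)
        v = np.concatenate(vals + vals)
    else:
        r = c = np.empty(0, dtype=np.int64)
        v = np.empty(0)
    return coo_matrix((v, (r, c)), shape=(n, n)).tocsr(), node_id


def fuzzy_distance(p: Voxel, q: Voxel, obj: FuzzyObject) -> float:
    """Minimum path length between two support voxels (inf if disconnected)."""
    mask = obj.support
    p, q = tuple(map(int, p)), tuple(map(int, q))
    if not (mask[p] and mask[q]):
        raise ValidationError("fuzzy_distance endpoints must lie in the support")
    if p == q:
        return 0.0
    graph, node_id = build_link_graph(mask, obj.spacing, obj.membership)
    dist = _csgraph_dijkstra(graph, directed=False, indices=int(node_id[p]))
    return float(dist[node_id[q]])


def fuzzy_distance_transform(obj: FuzzyObject) -> FDTMap:
    """FDT: per support voxel, the shortest fuzzy path length to the background.

    The background is every voxel with zero membership plus everything
    outside the volume.  The terminal half-link into a background neighbour
    contributes 0.5 * mu(p) * step, so an isolated unit-membership voxel at
    unit spacing has depth 0.5.
    """
    mask = obj.support
    omega = np.zeros(obj.shape, dtype=np.float64)
    if not mask.any():
        warnings.warn("fuzzy_distance_transform: empty support", stacklevel=2)
        return FDTMap(omega, obj.spacing)
    # Pad with one background layer so the field-of-view boundary is background.
    pmask = np.pad(mask, 1)
    pmem = np.pad(obj.membership, 1)
    sp = np.asarray(obj.spacing)
    n = int(pmask.sum())
    graph, node_id = build_link_graph(pmask, obj.spacing, pmem)
    # Seed distances: best half-link from each boundary support voxel into
    # an adjacent background voxel.
    init = np.full(n, np.inf)
    for off in OFFSETS:
        a_sl, b_sl = _shift_slices(pmask.shape, off)
        edge = pmask[a_sl] & ~pmask[b_sl]
        if not edge.any():
            continue
        ai = node_id[a_sl][edge]
        step = float(np.linalg.norm(off * sp))
        cand = 0.5 * pmem[a_sl][edge] * step
        np.minimum.at(init, ai, cand)
    boundary = np.flatnonzero(np.isfinite(init))
    # Virtual background node connected to every boundary support voxel.
    aug = coo_matrix(
        (
            np.concatenate([graph.tocoo().data, init[boundary], init[boundary]]),
            (
                np.concatenate([graph.tocoo().row, np.full(boundary.size, n), boundary]),
                np.concatenate([graph.tocoo().col, boundary, np.full(boundary.size, n)]),
            ),
        ),
        shape=(n + 1, n + 1),
    ).tocsr()
    dist = _csgraph_dijkstra(aug, directed=False, indices=n)
    padded = np.zeros(pmask.shape)
    padded[pmask] = dist[:n]
    omega[:] = padded[1:-1, 1:-1, 1:-1]
    return FDTMap(omega, obj.spacing)


def geodesic_distance(
    mask: np.ndarray,
    spacing,
    sources: np.ndarray,
    membership: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-source shortest fuzzy path distance from ``sources`` within ``mask``.

    Returns a float array (inf where unreachable, including outside ``mask``).
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.full(mask.shape, np.inf)
    src = np.asarray(sources, dtype=bool) & mask
    if not src.any():
        return out
    graph, node_id = build_link_graph(mask, spacing, membership)
    idx = node_id[src]
    dist = _csgraph_dijkstra(graph, directed=False, indices=idx, min_only=True)
    out[mask] = dist
    return out


def _lex_path_dijkstra(keys, src: Voxel, dst: Voxel, region: np.ndarray):
    """Dijkstra over 26-paths with lexicographic cost tuples.

    ``keys(u, v)`` returns the additive cost increment(s) of stepping to
    voxel ``v`` (from ``u``; ``u`` is None for the start voxel) as a tuple.
    Full labels are (costs..., n_voxels, path) compared lexicographically,
    so ties on every cost component fall back to fewer voxels and then to
    the lexicographically smallest voxel sequence — a deterministic rule.
    """
    region = np.asarray(region, dtype=bool)
    src = tuple(map(int, src))
    dst = tuple(map(int, dst))
    if not (region[src] and region[dst]):
        raise ValidationError("path endpoints must lie inside the region")
    shape = region.shape
    zero = keys(None, src)

    start = zero + (1, (src,))
    best: dict[Voxel, tuple] = {src: start}
    heap = [start]
    ncost = len(zero)
    while heap:
        entry = heapq.heappop(heap)
        path = entry[-1]
        v = path[-1]
        if best.get(v) != entry:
            continue
        if v == dst:
            return entry
        vz, vy, vx = v
        for dz, dy, dx in _OFFSET_TUPLES:
            u = (vz + dz, vy + dy, vx + dx)
            if not (0 <= u[0] < shape[0] and 0 <= u[1] < shape[1] and 0 <= u[2] < shape[2]):
                continue
            if not region[u]:
                continue
            inc = keys(v, u)
            cand = tuple(entry[i] + inc[i] for i in range(ncost)) + (entry[ncost] + 1, path + (u,))
            old = best.get(u)
            if old is None or cand < old:
                best[u] = cand
                heapq.heappush(heap, cand)
    raise NoPathError(f"no path from {src} to {dst} inside the region")


def min_weight_path(
    weight: np.ndarray,
    src: Voxel,
    dst: Voxel,
    region: np.ndarray,
    spacing=None,
) -> VoxelPath:
    """Path inside ``region`` minimising the sum of node weights.

    Every visited voxel's weight is counted once, endpoints included.  Ties
    are broken first by fewer voxels, then by lexicographic comparison of the
    voxel sequences, which makes the result deterministic.  ``spacing`` (if
    given) is used to cache the geometric length of the winning path.
    """
    w = np.asarray(weight, dtype=np.float64)

    def keys(u, v):
        return (float(w[v]),)

    entry = _lex_path_dijkstra(keys, src, dst, region)
    cost, _, path = entry
    length = path_length(path, spacing) if spacing is not None else float("nan")
    return VoxelPath(path, length, cost)


def geodesic_center_path(
    weight: np.ndarray,
    src: Voxel,
    dst: Voxel,
    region: np.ndarray,
    spacing,
) -> VoxelPath:
    """Shortest geometric path; among shortest paths, maximal node-weight sum.

    A geodesic joining the two landmarks whose depth-sum tie-break selects a
    single deterministic central route.  The 26-adjacency metric leaves many
    staircase paths exactly tied in length; preferring the deepest of them
    keeps the route on the axis of tubular structures instead of letting it
    crawl along the surface, so depths sampled along the path reflect the
    local half-width.
    """
    w = np.asarray(weight, dtype=np.float64)
    sp = np.asarray(_as_spacing(spacing))
    steps = {o: float(np.linalg.norm(np.asarray(o) * sp)) for o in _OFFSET_TUPLES}

    def keys(u, v):
        if u is None:
            return (0.0, -float(w[v]))
        o = (v[0] - u[0], v[1] - u[1], v[2] - u[2])
        return (steps[o], -float(w[v]))

    entry = _lex_path_dijkstra(keys, src, dst, region)
    length, neg_cost, _, path = entry
    return VoxelPath(path, length, -neg_cost)


def bottleneck_depth(omega: np.ndarray, mask: np.ndarray, p: Voxel, q: Voxel) -> float:
    """Max-min depth over 26-paths from p to q inside ``mask``.

    The returned value is the depth of the deepest corridor connecting the two
    voxels: the largest t such that p and q are 26-connected through voxels
    with omega >= t.  Used to detect the constriction between two candidate
    spine heads.
    """
    from scipy import ndimage

    mask = np.asarray(mask, dtype=bool)
    p, q = tuple(map(int, p)), tuple(map(int, q))
    if not (mask[p] and mask[q]):
        raise ValidationError("bottleneck endpoints must lie inside the mask")
    lo = 0.0
    hi = float(min(omega[p], omega[q]))
    structure = np.ones((3, 3, 3), dtype=bool)
    levels = np.unique(omega[mask])
    levels = levels[(levels <= hi)][::-1]
    for t in levels:
        sub = mask & (omega >= t)
        lab, _ = ndimage.label(sub, structure=structure)
        if lab[p] and lab[p] == lab[q]:
            return float(t)
    return lo
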