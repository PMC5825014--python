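"""Per-spine landmarks, central paths and morphometric features.

For each segmented spine region R the depth map Omega is recomputed with R
in isolation (the dendrite and everything else treated as background), so
that depth measures the spine itself rather than the parent dendrite.  The
landmarks are:

* base B — dendrite voxels 26-adjacent to R (the attachment ring);
* central base point CBP — the centroid of B, snapped to the nearest base
  or region voxel for path computations (the unsnapped point is reported);
* locally deepest points HP — voxels whose depth is maximal within their
  (2l+1)^3 neighbourhood intersected with R (l=2 suppresses noisy maxima);
* head centre CH — the deepest of HP (ties: centroid, snapped to the
  nearest tied voxel);
* tip T — the region voxel geodesically farthest from CBP.

The base-to-head path BH and head-to-tip path HT are geodesics (shortest
paths) whose depth-sum tie-break keeps them on the axis of the structure,
realising central routes through the neck; a variant that minimises the
depth sum outright is available.  Features:

* neck length     NL  = length(BH) - Omega(CH), clamped at 0;
* min neck width  MNW = 2 * min Omega over the region voxels of BH;
* avg head width  AHW = 2 * mean Omega over HP;
* spine length    L   = length(BH) + length(HT);
* volume          |R| * voxel volume.

Widths are reported as diameters (2x the depth, which is a radius); path
lengths are geometric (unit membership) since Omega already encodes the
fuzziness of the original image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import UndefinedLandmarkError, ValidationError
from .fuzzy import (
    FuzzyObject,
    VoxelPath,
    build_link_graph,
    fuzzy_distance_transform,
    geodesic_center_path,
    min_weight_path,
)

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: tolerance (um) for treating two depth/distance values as tied
TIE_TOL = 1e-9


def _depth_quantum(spacing) -> float:
    """Resolution of binary-grid depth values (um).

    Depths are only defined to about half a voxel step; thin structures are
    resolved along the finest-sampled axes, so the quantum scales with the
    smallest spacing component rather than with the full (possibly very
    anisotropic) voxel diagonal.
    """
    return 0.5 * float(np.sqrt(3.0)) * float(min(spacing))


@dataclass
class SpineRegion:
    """One connected spine region with its landmarks, paths and features.

    Only ``spine_id``, ``mask`` and ``spacing`` are required; everything else
    is filled in by :func:`analyze_spine`.  Real-valued landmark coordinates
    (``cbp``, ``ch``, ``tip``) are voxel-index triples; the ``*_voxel``
    variants are the snapped integer voxels used for path computations.
    """

    spine_id: int
    mask: np.ndarray
    spacing: tuple[float, float, float]
    omega: Optional[np.ndarray] = None
    base: Optional[np.ndarray] = None      # (n, 3) int voxels in the dendrite
    detached: bool = False
    branched: bool = False
    cbp: Optional[tuple] = None
    cbp_voxel: Optional[tuple] = None
    hp: Optional[np.ndarray] = None        # (m, 3) locally deepest voxels
    ch: Optional[tuple] = None
    ch_voxel: Optional[tuple] = None
    tip: Optional[tuple] = None
    tip_voxel: Optional[tuple] = None
    bh: Optional[VoxelPath] = None
    ht: Optional[VoxelPath] = None
    features: dict = field(default_factory=dict)
    spine_class: Optional[str] = None
    decision_trace: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def omega_at(self, voxel) -> float:
        return float(self.omega[tuple(map(int, voxel))])

    def feature_row(self) -> dict:
        f = self.features
        flags = []
        if self.detached:
            flags.append("detached")
        if self.branched:
            flags.append("branched")
        def pt(p):
            return (None, None, None) if p is None else tuple(float(c) for c in p)
        cbp, ch, tip = pt(self.cbp), pt(self.ch), pt(self.tip)
        return {
            "spine_id": self.spine_id,
            "n_voxels": self.n_voxels,
            "volume_um3": f.get("volume_um3"),
            "neck_length_um": f.get("neck_length_um"),
            "min_neck_width_um": f.get("min_neck_width_um"),
            "avg_head_width_um": f.get("avg_head_width_um"),
            "spine_length_um": f.get("spine_length_um"),
            "class": self.spine_class,
            "flags": "|".join(flags),
            "cbp_z": cbp[0], "cbp_y": cbp[1], "cbp_x": cbp[2],
            "ch_z": ch[0], "ch_y": ch[1], "ch_x": ch[2],
            "tip_z": tip[0], "tip_y": tip[1], "tip_x": tip[2],
        }


def region_fdt(region: SpineRegion) -> np.ndarray:
    """Depth map of the region alone (binary membership, rest background)."""
    obj = FuzzyObject(region.mask.astype(np.float64), region.spacing)
    region.omega = fuzzy_distance_transform(obj).omega
    return region.omega


def spine_base(region: SpineRegion, dendrite_mask: np.ndarray) -> np.ndarray:
    """Dendrite voxels 26-adjacent to the region; flags detached spines."""
    halo = ndimage.binary_dilation(region.mask, structure=_STRUCT26) & ~region.mask
    base_mask = halo & dendrite_mask
    coords = np.argwhere(base_mask)
    region.base = coords
    region.detached = coords.shape[0] == 0
    if region.detached:
        logger.info("spine %d is detached from the dendrite", region.spine_id)
    return coords


def _snap(point, candidates: np.ndarray, spacing) -> tuple:
    """Nearest candidate voxel to a real-valued point (physical distance;
    ties resolved lexicographically)."""
    sp = np.asarray(spacing)
    d2 = np.sum(((candidates - np.asarray(point)) * sp) ** 2, axis=1)
    tied = np.flatnonzero(d2 <= d2.min() + TIE_TOL**2)
    order = np.lexsort((candidates[tied, 2], candidates[tied, 1], candidates[tied, 0]))
    return tuple(int(c) for c in candidates[tied[order[0]]])


def central_base_point(region: SpineRegion) -> tuple:
    """Centroid of the base, snapped to the nearest base-or-region voxel."""
    if region.base is None or region.base.shape[0] == 0:
        raise UndefinedLandmarkError(f"spine {region.spine_id}: empty base (detached spine)")
    centroid = region.base.mean(axis=0)
    candidates = np.concatenate([region.base, np.argwhere(region.mask)], axis=0)
    region.cbp = tuple(float(c) for c in centroid)
    region.cbp_voxel = _snap(centroid, candidates, region.spacing)
    return region.cbp


def locally_deepest_points(region: SpineRegion, l: int = 2) -> np.ndarray:
    """Voxels of maximal depth within their (2l+1)^3 neighbourhood in R."""
    if region.omega is None:
        region_fdt(region)
    size = 2 * int(l) + 1
    masked = np.where(region.mask, region.omega, -np.inf)
    local_max = ndimage.maximum_filter(masked, size=size, mode="constant", cval=-np.inf)
    hp_mask = region.mask & (masked >= local_max - TIE_TOL)
    region.hp = np.argwhere(hp_mask)
    return region.hp


def center_of_head(region: SpineRegion) -> tuple:
    """Deepest of the locally deepest points; tie centroid snapped to a tied voxel.

    Depths on a binary grid are only defined to roughly half a voxel, so
    candidates within half a voxel diagonal of the maximum are treated as tied:
    on a depth plateau (a uniform filament, or the core of a head) the head
    centre is then the centroid of the plateau rather than whichever voxel
    won the quantisation lottery.
    """
    if region.hp is None or region.hp.shape[0] == 0:
        raise UndefinedLandmarkError(f"spine {region.spine_id}: no locally deepest points")
    depths = region.omega[tuple(region.hp.T)]
    tol = _depth_quantum(region.spacing)
    tied = region.hp[depths >= depths.max() - tol]
    centroid = tied.mean(axis=0)
    region.ch = tuple(float(c) for c in centroid)
    region.ch_voxel = _snap(centroid, tied, region.spacing)
    return region.ch


def _geodesic_from(region_mask: np.ndarray, spacing, source) -> np.ndarray:
    out = np.full(region_mask.shape, np.inf)
    graph, node_id = build_link_graph(region_mask, spacing)
    dist = _csgraph_dijkstra(graph, directed=False, indices=int(node_id[tuple(source)]))
    out[region_mask] = dist
    return out


def spine_tip(region: SpineRegion) -> tuple:
    """Region voxel geodesically farthest from the central base point."""
    if region.cbp_voxel is None:
        raise UndefinedLandmarkError(f"spine {region.spine_id}: central base point undefined")
    arena = region.mask.copy()
    arena[region.cbp_voxel] = True  # CBP may sit on the dendrite side
    dist = _geodesic_from(arena, region.spacing, region.cbp_voxel)
    dist = np.where(region.mask, dist, -np.inf)
    finite = np.isfinite(dist) & region.mask
    if not finite.any():
        raise UndefinedLandmarkError(f"spine {region.spine_id}: region unreachable from base")
    dmax = dist[finite].max()
    tied = np.argwhere(region.mask & (dist >= dmax - TIE_TOL))
    centroid = tied.mean(axis=0)
    region.tip = tuple(float(c) for c in centroid)
    region.tip_voxel = _snap(centroid, tied, region.spacing)
    return region.tip


def central_paths(region: SpineRegion, mode: str = "geodesic") -> tuple[VoxelPath, VoxelPath]:
    """Central paths base->head (BH) and head->tip (HT).

    Paths are confined to the region plus its base voxels; base voxels carry
    zero depth (they are background for the region's depth map).  The
    default ``mode="geodesic"`` takes the shortest path with the depth sum
    as tie-break, so the neck length read off BH is a true geodesic
    distance; ``mode="min_depth_sum"`` minimises the depth sum outright,
    which tends to detour along shallow surface voxels and is kept only as
    an opt-in variant.
    """
    for name in ("cbp_voxel", "ch_voxel", "tip_voxel"):
        if getattr(region, name) is None:
            raise UndefinedLandmarkError(f"spine {region.spine_id}: {name} undefined")
    arena = region.mask.copy()
    if region.base is not None and region.base.shape[0]:
        arena[tuple(region.base.T)] = True
    if mode == "geodesic":
        finder = geodesic_center_path
    elif mode == "min_depth_sum":
        finder = min_weight_path
    else:
        raise ValidationError(f"unknown central-path mode {mode!r}")
    region.bh = finder(region.omega, region.cbp_voxel, region.ch_voxel, arena, region.spacing)
    region.ht = finder(region.omega, region.ch_voxel, region.tip_voxel, arena, region.spacing)
    return region.bh, region.ht


def spine_features(region: SpineRegion) -> dict:
    """Compute the feature record; neck features are missing for detached spines."""
    voxel_volume = float(np.prod(region.spacing))
    feats: dict = {
        "volume_um3": region.n_voxels * voxel_volume,
        "n_voxels": region.n_voxels,
    }
    if region.hp is not None and region.hp.shape[0]:
        feats["avg_head_width_um"] = 2.0 * float(region.omega[tuple(region.hp.T)].mean())
    if region.ch_voxel is not None:
        feats["head_depth_um"] = region.omega_at(region.ch_voxel)
    if region.detached or region.bh is None or region.ht is None:
        feats["neck_length_um"] = None
        feats["min_neck_width_um"] = None
        feats["spine_length_um"] = None
        region.features.update(feats)
        return region.features
    bh_len = region.bh.length_um
    ht_len = region.ht.length_um
    head_depth = region.omega_at(region.ch_voxel)
    raw_nl = bh_len - head_depth
    if raw_nl < 0:
        logger.debug("spine %d: head-at-base geometry, raw neck length %.4f clamped to 0",
                     region.spine_id, raw_nl)
    feats["neck_length_um"] = max(0.0, raw_nl)
    feats["neck_length_raw_um"] = raw_nl
    in_region = [v for v in region.bh.voxels if region.mask[v]]
    feats["min_neck_width_um"] = 2.0 * min(region.omega_at(v) for v in in_region) if in_region else None
    feats["spine_length_um"] = bh_len + ht_len
    feats["bh_length_um"] = bh_len
    feats["ht_length_um"] = ht_len
    region.features.update(feats)
    return region.features


def analyze_spine(region: SpineRegion, dendrite_mask: np.ndarray, l: int = 2) -> SpineRegion:
    """Full morphometry for one region: depth map, landmarks, paths, features."""
    region_fdt(region)
    spine_base(region, dendrite_mask)
    locally_deepest_points(region, l=l)
    center_of_head(region)
    if not region.detached:
        central_base_point(region)
        spine_tip(region)
        central_paths(region)
    spine_features(region)
    return region
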