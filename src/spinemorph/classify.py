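"""Rule-based spine shape classification.

Each spine is assigned to one of four categories by a fixed rule cascade:

1. **Stubby** — the neck length is (effectively) zero.  On a discrete grid
   a hemispherical protrusion sitting directly on the dendrite yields a
   small positive or negative raw neck length, so "zero" is read as
   ``NL <= tau_stubby`` (default 0.15 um, about two lateral pixels).
2. **Filopodia** — the deep portion of the spine is spread along its whole
   length: the spread statistic (fraction of the central path running at
   head-like depth) is at least ``tau_spread``.
3. **Mushroom** — short base-to-head distance relative to the total
   length: BH / L <= tau_ratio.
4. **Spine-head protrusion** — everything else (long neck, distal head).

"Thin" is deliberately not a class (it is an intermediate form), and
branched spines — two depth-significant head clusters reached from the
base by paths that diverge — bypass the cascade and are only flagged.

Depth values on a binary grid are quantised to roughly half a voxel, so
every statistic that compares depths treats differences below half a voxel
diagonal as ties; without this, a uniform filament whose centreline depth
hops between quantisation levels would read as a head plus neck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .fuzzy import geodesic_center_path
from .morphometry import SpineRegion, TIE_TOL, _depth_quantum

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

STUBBY = "Stubby"
FILOPODIA = "Filopodia"
MUSHROOM = "Mushroom"
SPINE_HEAD_PROTRUSION = "SpineHeadProtrusion"
CLASS_LABELS = (STUBBY, FILOPODIA, MUSHROOM, SPINE_HEAD_PROTRUSION)


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the rule cascade (all dimensionless unless noted)."""

    tau_stubby_um: float = 0.15    # neck length below which a spine is stubby
    tau_spread: float = 0.5        # deepest-point spread for filopodia
    tau_ratio: float = 0.65        # BH/L at or below which a spine is mushroom
    head_frac: float = 0.6         # depth fraction defining "head-like" deep points
    merge_radius_um: float = 0.35  # peak separation merging nearby head clusters
    valley_frac: float = 0.5       # depth valley ratio splitting branched heads
    smooth_window: int = 5         # path voxels averaged when profiling depth


@dataclass(frozen=True)
class SpineClass:
    """Label plus the decision trace (rule fired and statistic values)."""

    label: str | None
    trace: dict


def _significant_hp(region: SpineRegion, head_frac: float) -> np.ndarray:
    depths = region.omega[tuple(region.hp.T)]
    quantum = _depth_quantum(region.spacing)
    thr = min(head_frac * depths.max(), depths.max() - quantum)
    keep = depths >= thr - TIE_TOL
    return region.hp[keep]


def _path_depth_profile(region: SpineRegion, window: int):
    """Central-path voxels, their arc lengths, and a smoothed depth profile.

    The raw per-voxel depths carry +/- half-a-voxel quantisation, so a short
    moving average along the path is taken before thresholding.
    """
    path = list(region.bh.voxels) + list(region.ht.voxels[1:])
    sp = np.asarray(region.spacing)
    pathv = np.asarray(path, dtype=float)
    if len(path) == 1:
        return path, np.zeros(1), np.array([region.omega_at(path[0])])
    steps = np.linalg.norm(np.diff(pathv, axis=0) * sp, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    depth = np.array([region.omega_at(v) for v in path])
    w = max(1, min(int(window), len(path)))
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(depth, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")[: len(path)]
    return path, arc, smooth


def deepest_point_spread(region: SpineRegion, params: ClassifyParams = ClassifyParams()) -> float:
    """Fraction of the central path running at head-like depth.

    The depth profile along the base->head->tip path is smoothed and
    thresholded at ``head_frac`` of its maximum; the spread is the summed
    arc length of the supra-threshold stretches divided by the spine
    length.  A uniform filament is deep along its whole course (spread near
    1) while a bulbous head concentrates the deep stretch around the head
    (spread well below 1/2), which is what separates filopodia from
    mushroom and spine-head protrusions.
    """
    if region.bh is None or region.ht is None:
        raise ValidationError("deepest_point_spread requires the central paths")
    length = region.features.get("spine_length_um") or 0.0
    if length <= 0:
        return 0.0
    path, arc, smooth = _path_depth_profile(region, params.smooth_window)
    if len(path) == 1:
        return 0.0
    # Depth is quantised to about half a voxel; a stretch less than half a
    # voxel diagonal shallower than the maximum is indistinguishable from
    # it, so the threshold never rises above max - quantum.
    quantum = _depth_quantum(region.spacing)
    thr = min(params.head_frac * smooth.max(), smooth.max() - quantum)
    deep = smooth >= thr - TIE_TOL
    seg = np.diff(arc)
    covered = float(np.sum(seg * (deep[:-1] & deep[1:])))
    return covered / length


def flag_branched(region: SpineRegion, params: ClassifyParams = ClassifyParams()) -> bool:
    """True when two depth-significant head clusters are joined to the base
    by paths that diverge.

    Significant deepest points are clustered by 26-connectivity and clusters
    whose peaks lie within ``merge_radius_um`` of each other (peak-to-peak
    physical distance) are merged, so the depth plateau of a filament reads
    as a single head.  The spine is branched when two merged clusters remain
    whose connecting corridor is markedly shallower than either peak (the
    deepest corridor depth is at most ``valley_frac`` of the shallower peak
    — two heads joined through a constriction) and whose minimal
    base-to-peak paths, after removing the shared prefix, are voxel-disjoint
    and both nonempty.
    """
    if region.hp is None or region.omega is None:
        raise ValidationError("flag_branched requires the depth map and deepest points")
    if region.detached or region.cbp_voxel is None:
        region.branched = False
        return False
    hp = _significant_hp(region, params.head_frac)
    hp_mask = np.zeros(region.mask.shape, dtype=bool)
    hp_mask[tuple(hp.T)] = True
    lab, ncl = ndimage.label(hp_mask, structure=_STRUCT26)
    if ncl < 2:
        region.branched = False
        return False
    # peak voxel of each cluster (deepest, ties lexicographic)
    peaks = []
    for c in range(1, ncl + 1):
        voxels = np.argwhere(lab == c)
        depths = region.omega[tuple(voxels.T)]
        tied = voxels[depths >= depths.max() - TIE_TOL]
        order = np.lexsort((tied[:, 2], tied[:, 1], tied[:, 0]))
        peaks.append(tuple(int(v) for v in tied[order[0]]))
    # merge clusters whose peaks are close (single head sampled twice)
    sp = np.asarray(region.spacing)
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            if np.linalg.norm((np.asarray(peaks[i]) - peaks[j]) * sp) <= params.merge_radius_um:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    if len(groups) < 2:
        region.branched = False
        return False
    # deepest representative per merged group
    reps = []
    for members in groups.values():
        members.sort(key=lambda v: (-region.omega_at(v), v))
        reps.append(members[0])
    reps.sort()
    arena = region.mask.copy()
    if region.base is not None and region.base.shape[0]:
        arena[tuple(region.base.T)] = True
    from .fuzzy import bottleneck_depth

    paths = [geodesic_center_path(region.omega, region.cbp_voxel, r, arena, region.spacing).voxels
             for r in reps]
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            shallow_peak = min(region.omega_at(reps[i]), region.omega_at(reps[j]))
            valley = bottleneck_depth(region.omega, region.mask, reps[i], reps[j])
            quantum = _depth_quantum(region.spacing)
            if valley > params.valley_frac * shallow_peak or shallow_peak - valley <= quantum:
                continue  # the two maxima share one deep body (or the dip is below quantisation)
            a, b = paths[i], paths[j]
            k = 0
            while k < min(len(a), len(b)) and a[k] == b[k]:
                k += 1
            ra, rb = a[k:], b[k:]
            if ra and rb and not (set(ra) & set(rb)):
                region.branched = True
                return True
    region.branched = False
    return False


def classify_spine(
    region: SpineRegion,
    params: ClassifyParams = ClassifyParams(),
) -> SpineClass:
    """Apply the rule cascade; detached/branched spines bypass it."""
    trace: dict = {
        "tau_stubby_um": params.tau_stubby_um,
        "tau_spread": params.tau_spread,
        "tau_ratio": params.tau_ratio,
        "head_frac": params.head_frac,
    }
    if region.detached:
        trace["rule"] = "detached"
        region.spine_class = None
        region.decision_trace = trace
        return SpineClass(None, trace)
    if region.branched:
        trace["rule"] = "branched"
        region.spine_class = None
        region.decision_trace = trace
        return SpineClass(None, trace)
    feats = region.features
    nl = feats.get("neck_length_um")
    length = feats.get("spine_length_um")
    bh_len = feats.get("bh_length_um")
    if nl is None or length is None or bh_len is None:
        trace["rule"] = "unclassified:missing-features"
        region.spine_class = None
        region.decision_trace = trace
        return SpineClass(None, trace)
    trace["neck_length_um"] = nl
    if nl <= params.tau_stubby_um:
        trace["rule"] = "stubby:zero-neck"
        label = STUBBY
    else:
        spread = deepest_point_spread(region, params)
        trace["spread"] = spread
        if spread >= params.tau_spread:
            trace["rule"] = "filopodia:spread"
            label = FILOPODIA
        else:
            ratio = bh_len / length if length > 0 else 0.0
            trace["bh_over_l"] = ratio
            if ratio <= params.tau_ratio:
                trace["rule"] = "mushroom:short-base-to-head"
                label = MUSHROOM
            else:
                trace["rule"] = "spine-head-protrusion:default"
                label = SPINE_HEAD_PROTRUSION
    region.spine_class = label
    region.decision_trace = trace
    return SpineClass(label, trace)
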