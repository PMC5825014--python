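"""Two-step segmentation: foreground extraction and multi-scale opening (MSO).

Step 1 thresholds the denoised stack and keeps sufficiently large
26-connected components; the result is a fuzzy object whose membership is
the fuzzy union of the spine and dendrite intensity ramps.

Step 2 separates the two mutually fused objects.  Conceptually the fused
assembly is eroded at progressively finer scales until the objects
disconnect, and each object then reclaims territory by geodesic dilation
from its seeds.  Concretely, two depth maps are computed first: the FDT of
the combined object with the rival seeds and all separators pushed into the
background (``omega_spine0`` / ``omega_dendrite0``).  The scale parameter s
then sweeps from the global maximum depth down to zero in one-voxel
decrements; at each scale an object claims the still-unclaimed voxels of
depth >= s that are 26-reachable from its already-claimed set through
voxels of depth >= s (never through rival territory and never through
separators).  Where both objects can reach a voxel at the same scale, the
voxel goes to the object whose previously claimed region is geodesically
closer; exact ties go to the dendrite, which favours the large structure at
ambiguous junctions.  Voxels never reached (isolated by separators,
including the separators themselves) fall back to the dendrite so that the
foreground is always fully partitioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import EmptyForegroundError, ValidationError
from .fuzzy import (
    FuzzyObject,
    IntensityBands,
    build_link_graph,
    fuzzy_distance_transform,
    membership_dendrite,
    membership_spine,
)
from .image_io import IntensityVolume, SeedSet

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_DENDRITE = 1
FIRST_SPINE_LABEL = 2

#: provenance codes
PROV_BACKGROUND = 0
PROV_SEED = 1
PROV_GROWN = 2
PROV_FALLBACK = 3

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Label volume (0 background, 1 dendrite, 2+i spine region i), the number
    of spine regions K, and a per-voxel provenance map recording whether a
    voxel was seeded, claimed by scale growth, or assigned by fallback."""

    labels: np.ndarray
    k: int
    provenance: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def dendrite_mask(self) -> np.ndarray:
        return self.labels == LABEL_DENDRITE

    @property
    def spine_mask(self) -> np.ndarray:
        return self.labels >= FIRST_SPINE_LABEL

    def spine_masks(self):
        for lbl in range(FIRST_SPINE_LABEL, FIRST_SPINE_LABEL + self.k):
            yield lbl, self.labels == lbl


def threshold_foreground(
    vol: IntensityVolume,
    theta: float | None = None,
    min_voxels: int = 27,
    bands: IntensityBands | None = None,
) -> tuple[FuzzyObject, IntensityBands]:
    """Step-1 foreground extraction.

    ``theta=None`` picks the lower of the two three-class Otsu thresholds of
    the full volume — with a dark background, a dim spine band and a bright
    dendrite band the intensity histogram is trimodal, and the lower
    threshold is the background/foreground split (a plain two-class Otsu
    would land between the spine and dendrite bands and truncate the
    spines).  Components with fewer than ``min_voxels`` voxels are
    discarded.  ``bands=None`` derives the spine/dendrite intensity bands by
    two-threshold Otsu on the retained foreground intensities.  Returns the
    combined fuzzy object (fuzzy union of the two ramp memberships on the
    support) together with the bands.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if theta is None:
        from skimage.filters import threshold_multiotsu, threshold_otsu

        if np.unique(data).size < 2:
            raise EmptyForegroundError("volume is constant; cannot threshold")
        if np.unique(data).size < 3:
            theta = float(threshold_otsu(data))
        else:
            theta = float(threshold_multiotsu(data, classes=3)[0])
    support = data >= theta
    if not support.any():
        raise EmptyForegroundError(f"no voxels at or above theta={theta}")
    lab, ncomp = ndimage.label(support, structure=_STRUCT26)
    if min_voxels > 1 and ncomp:
        counts = np.bincount(lab.ravel())
        keep = np.flatnonzero(counts >= min_voxels)
        keep = keep[keep > 0]
        support = np.isin(lab, keep)
        if not support.any():
            raise EmptyForegroundError(
                f"all foreground components smaller than min_voxels={min_voxels}"
            )
    if bands is None:
        bands = IntensityBands.auto(data[support])
    mu = np.maximum(membership_spine(data, bands), membership_dendrite(data, bands))
    mu = np.where(support, np.maximum(mu, 1e-12), 0.0)  # support must stay nonzero
    return FuzzyObject(mu, vol.spacing), bands


def _reachable(
    eligible: np.ndarray, claimed: np.ndarray
) -> np.ndarray:
    """Unclaimed eligible voxels 26-connected to the claimed set through
    eligible-or-claimed voxels."""
    m = eligible | claimed
    lab, _ = ndimage.label(m, structure=_STRUCT26)
    ids = np.unique(lab[claimed])
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(eligible)
    return eligible & np.isin(lab, ids)


def _distance_from_claimed(
    region: np.ndarray, sources: np.ndarray, spacing, membership: np.ndarray
) -> np.ndarray:
    """Fuzzy geodesic distance from ``sources`` within ``region | sources``."""
    arena = region | sources
    out = np.full(region.shape, np.inf)
    if not sources.any():
        return out
    graph, node_id = build_link_graph(arena, spacing, membership)
    dist = _csgraph_dijkstra(graph, directed=False, indices=node_id[sources], min_only=True)
    out[arena] = dist
    return out


def multi_scale_opening(
    obj: FuzzyObject,
    seeds: SeedSet,
    scale_step: float | None = None,
) -> SegmentationResult:
    """Separate the fused spine/dendrite object into two labelled classes.

    Requires at least one seed of each class inside the support.  Returns a
    SegmentationResult whose spine voxels are provisionally labelled by
    connected component (see :func:`extract_spine_components` for the final
    seed-checked decomposition).
    """
    support = obj.support
    seeds.check_bounds(obj.shape)
    if not seeds.spine or not seeds.dendrite:
        raise ValidationError("multi_scale_opening needs >= 1 spine seed and >= 1 dendrite seed")
    spine_seed = seeds.mask(obj.shape, "spine")
    dend_seed = seeds.mask(obj.shape, "dendrite")
    sep = seeds.mask(obj.shape, "separators")
    for name, m in (("spine", spine_seed), ("dendrite", dend_seed)):
        if (m & ~support).any():
            raise ValidationError(f"{name} seeds must lie inside the foreground support")

    mu = obj.membership
    # Rival-suppressed depth maps: rival seeds and separators -> background.
    mu_spine0 = np.where(dend_seed | sep, 0.0, mu)
    mu_dend0 = np.where(spine_seed | sep, 0.0, mu)
    omega_spine0 = fuzzy_distance_transform(FuzzyObject(mu_spine0, obj.spacing)).omega
    omega_dend0 = fuzzy_distance_transform(FuzzyObject(mu_dend0, obj.spacing)).omega

    claimed = np.zeros(obj.shape, dtype=np.int8)  # 0 unclaimed, 1 dendrite, 2 spine
    claimed[dend_seed] = 1
    claimed[spine_seed] = 2
    provenance = np.zeros(obj.shape, dtype=np.uint8)
    provenance[dend_seed | spine_seed] = PROV_SEED

    step = float(scale_step) if scale_step else float(min(obj.spacing))
    s_max = float(max(omega_spine0.max(), omega_dend0.max()))
    scales = list(np.arange(s_max, 0.0, -step)) + [0.0]

    claimable = support & ~sep
    for s in scales:
        unclaimed = claimable & (claimed == 0)
        if not unclaimed.any():
            break
        new_d = _reachable(unclaimed & (omega_dend0 >= s), claimed == 1)
        new_s = _reachable(unclaimed & (omega_spine0 >= s), claimed == 2)
        contested = new_d & new_s
        claimed[new_d & ~contested] = 1
        claimed[new_s & ~contested] = 2
        provenance[(new_d | new_s) & ~contested] = PROV_GROWN
        if contested.any():
            dist_d = _distance_from_claimed(contested, claimed == 1, obj.spacing, mu)
            dist_s = _distance_from_claimed(contested, claimed == 2, obj.spacing, mu)
            take_spine = contested & (dist_s < dist_d)  # ties -> dendrite
            claimed[contested & ~take_spine] = 1
            claimed[take_spine] = 2
            provenance[contested] = PROV_GROWN

    leftover = support & (claimed == 0)
    if leftover.any():
        logger.info("MSO: %d voxels unreachable from seeds assigned to dendrite", int(leftover.sum()))
        claimed[leftover] = 1
        provenance[leftover] = PROV_FALLBACK

    labels = np.zeros(obj.shape, dtype=np.int32)
    labels[claimed == 1] = LABEL_DENDRITE
    spine_lab, k = ndimage.label(claimed == 2, structure=_STRUCT26)
    labels[claimed == 2] = spine_lab[claimed == 2] + (FIRST_SPINE_LABEL - 1)
    return SegmentationResult(labels=labels, k=int(k), provenance=provenance, spacing=obj.spacing)


def extract_spine_components(seg: SegmentationResult, seeds: SeedSet):
    """Final connected-component decomposition of the spine class.

    Components that contain no spine seed are merged into the dendrite (the
    merge is logged), so that every returned region holds at least one seed
    and the foreground partition is preserved.  ``seg`` is relabelled in
    place with compact spine labels 2..K+1 ordered by first voxel; returns
    the list of SpineRegion shells ready for morphometry.
    """
    from .morphometry import SpineRegion

    spine_seed = seeds.mask(seg.labels.shape, "spine")
    lab, ncomp = ndimage.label(seg.spine_mask, structure=_STRUCT26)
    regions = []
    labels = seg.labels
    next_label = FIRST_SPINE_LABEL
    relabelled = np.where(seg.spine_mask, LABEL_DENDRITE, labels)
    for comp in range(1, ncomp + 1):
        mask = lab == comp
        if not (mask & spine_seed).any():
            logger.info(
                "extract_spine_components: merging unseeded spine component of %d voxels into dendrite",
                int(mask.sum()),
            )
            continue
        relabelled[mask] = next_label
        regions.append(SpineRegion(spine_id=next_label, mask=mask, spacing=seg.spacing))
        next_label += 1
    seg.labels = relabelled
    seg.k = len(regions)
    return regions
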