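# Methods

This note documents the models and numerical choices behind `spinemorph`:
what each stage computes, which parameters matter and why their defaults
are what they are, what the synthetic phantoms do and do not emulate, and
the known limitations.

## Fuzzy geometry

All geometry lives on the 26-adjacency graph of the voxel grid. Physical
voxel spacing (µm per axis, order `(z, y, x)`) scales every step: confocal
stacks are strongly anisotropic (typically 0.07 µm laterally, 0.2 µm
between planes), and ignoring this would distort axial lengths threefold.

A *fuzzy object* is a membership map μ ∈ [0, 1]; a link between adjacent
voxels p, q has length ½(μ(p)+μ(q))·‖p−q‖ and the fuzzy distance is the
minimal total link length over connected paths. The *fuzzy distance
transform* (FDT) Ω(p) is the fuzzy distance from p to the background
(zero-membership voxels and everything outside the field of view); the
terminal half-link into the background contributes ½μ(p)·‖step‖, so an
isolated unit-membership voxel at unit spacing has Ω = 0.5. Ω is a depth
map: inside a tube of radius r it plateaus near r, which is what both the
segmentation scales and all width features are built on.

Implementation: support graphs are assembled sparsely and distances are
computed by Dijkstra's algorithm (`scipy.sparse.csgraph`) with a virtual
background node for the FDT. The test suite checks exact agreement
(to 1e-6 µm) with an exhaustive shortest-path oracle on random fuzzy fields,
the Lipschitz property |Ω(p)−Ω(q)| ≤ link length, homogeneity under
membership scaling, and reduction to the Euclidean distance transform
(within one voxel diagonal) on binary balls.

**Depth quantisation.** On a binary support, Ω values are only defined to
about half a voxel step; structures are resolved along the finest-sampled
axes, so the package treats depth differences below
`0.5·√3·min(spacing)` (≈ 0.06 µm at 0.07 µm sampling) as ties. Every
statistic that compares depths (head-centre selection, the spread
statistic, branch detection) uses this quantum; without it, a uniform
filament whose centreline depth hops between quantisation levels reads as
a head plus neck.

## Intensity model and foreground extraction

Spines are dimmer than the dendrite shaft, and the two intensity
distributions overlap. Two representative intensities, `i_spine` and
`i_dendrite`, bound a *shared band*: below `i_spine` a voxel is purely
spine-like, at or above `i_dendrite` purely dendrite-like, and in between
two complementary linear ramps encode partial belonging. By default both
values come from two-threshold Otsu on the foreground histogram; both are
configurable. The combined object's membership is the fuzzy union
(voxelwise maximum) of the two ramps.

Preprocessing is a separable Gaussian (reflect padding, default σ = 0.5
voxels per axis). A full voxel of smoothing — with 0.2 µm z-steps, 0.2 µm
of axial blur — erases sub-resolution spine necks from the foreground, so
the default is deliberately light; σ is exposed in the config.

The foreground threshold θ defaults to the *lower* of the two three-class
Otsu thresholds of the volume: with a dark background, a dim spine band
and a bright shaft, the histogram is trimodal and a plain two-class Otsu
lands between the spine and dendrite bands, truncating every spine.
Components smaller than `min_voxels` (default 27 ≈ a 3³ neighbourhood) are
discarded as noise.

## Multi-scale opening

Seeded separation of the fused spine/dendrite object. Inputs: at least one
seed voxel per class and optional separator voxels that act as hard
barriers. Two depth maps are computed first, each with the rival seeds and
all separators pushed into the background (`Ω_spine,0`, `Ω_dendrite,0`).
The scale s then sweeps from the global maximum depth to zero in
decrements of one fine voxel step (configurable). At each scale an object
claims the unclaimed voxels of depth ≥ s that are 26-reachable from its
already-claimed set through voxels of depth ≥ s — never through rival
territory or separators. Where both objects reach a voxel at the same
scale, the voxel goes to whichever object's previously claimed region is
geodesically closer (competitive geodesic dilation); exact ties go to the
dendrite, favouring the large structure at ambiguous junctions. Voxels
never reached (isolated by separators, including the separators
themselves) fall back to the dendrite so the foreground is always fully
partitioned. Spine components that end up without a seed are merged back
into the dendrite (logged), so every reported region contains a seed.

Two design choices deserve emphasis because plausible alternatives fail:

* *Growth starts from seeds only; pure-band voxels are not pre-assigned to
  their intensity class.* The blurred partial-volume shell of the dendrite
  lies in the spine intensity band; pre-assigning it by intensity would
  fuse that shell with every seeded spine into one component.
* *Conflicts are resolved against the previously claimed regions, not
  against the seed sets.* The dendrite is typically marked with a single
  distant seed; by raw seed distance every spine would annex the patch of
  dendrite surface around its own base.

The construction is validated against an independent oracle that erodes a
fused binary object at increasing Euclidean radii until the seeds
disconnect and back-propagates labels by simultaneous geodesic dilation;
on random fused two-ball objects the two agree on ≥ 95 % of voxels.

**Structural ambiguity at the junction.** Opening-style separation places
the spine/dendrite boundary within about one opening-scale of the
geometric attachment, so a ring of neck-base voxels — up to roughly half
of a 0.1 µm neck — is intrinsically ambiguous and is assigned to the
dendrite by the tie rule. Even on a crisp noiseless phantom, small spines
therefore recover their ground-truth label with Dice ≈ 0.92–0.97 rather
than 1.0; this also biases the measured neck length slightly short of the
full anatomical neck.

## Per-spine morphometry

Each region R is re-measured in isolation: its depth map Ω is recomputed
with everything outside R (including the dendrite) as background, so depth
reflects the spine itself. Landmarks:

* **base** — dendrite voxels 26-adjacent to R; empty for spines whose neck
  fell below the foreground threshold, which are flagged `detached` and
  report no neck features;
* **central base point (CBP)** — centroid of the base, snapped to the
  nearest base-or-region voxel for path computations (the unsnapped point
  is reported);
* **locally deepest points (HP)** — voxels of maximal depth within their
  (2l+1)³ neighbourhood in R, l = 2 by default to suppress noisy maxima;
* **head centre (CH)** — deepest HP; candidates within one depth quantum
  of the maximum are tied and their centroid (snapped to a tied voxel) is
  used, so on a depth plateau the head centre is the plateau's centroid;
* **tip (T)** — region voxel geodesically farthest from the CBP
  (fuzzy-geodesic, consistent with the rest of the distance machinery).

The central paths base→head (BH) and head→tip (HT) are geodesics (shortest
26-paths by physical length) with the maximal depth-sum as tie-break.
The grid metric leaves many staircase paths exactly tied; preferring the
deepest keeps the route on the axis of tubular parts, so depths sampled
along the path estimate local half-widths. A variant that minimises the
depth sum outright (`central_paths(..., mode="min_depth_sum")`) is kept
for comparison but is not the default: an unconstrained depth-sum
minimiser trades directness for shallow detours along the surface, which
on phantoms inflates neck length by ~0.4 µm and collapses the minimum neck
width to the half-voxel floor.

Features (all in physical units):

| feature | definition | note |
|---|---|---|
| neck length NL | length(BH) − Ω(CH), clamped at 0 | negative raw values (head sitting on the base) are logged and read as 0 |
| min neck width MNW | 2·min Ω over the region voxels of BH | base voxels carry Ω = 0 and are excluded from the minimum |
| avg head width AHW | 2·mean Ω over HP | for long thin necks the centreline plateau joins HP and pulls AHW down — inherent to the definition |
| spine length L | length(BH) + length(HT) | |
| volume | voxel count × voxel volume | |

Widths are reported as diameters (2×Ω, which is a radius); this doubles
the raw depth values and is chosen to match the biological convention for
"head width".

## Shape classification

A fixed rule cascade with a recorded decision trace:

1. **Stubby** if NL ≤ `tau_stubby` (0.15 µm): on a discrete grid a
   hemisphere sitting on the shaft yields a small positive or negative raw
   neck length, so "zero neck" is read with a two-lateral-pixel tolerance.
2. **Filopodia** if the *spread* ≥ `tau_spread` (0.5). The spread is the
   arc-length fraction of the BH∪HT path whose smoothed depth profile
   (moving average over `smooth_window` = 5 path voxels) is head-like,
   i.e. ≥ `head_frac` (0.6) of the profile maximum, capped at one depth
   quantum below the maximum. A uniform filament is deep along its whole
   course (spread ≈ 0.8–1); a bulbous head concentrates the deep stretch
   (spread ≈ 0.15–0.45).
3. **Mushroom** if BH/L ≤ `tau_ratio` (0.65). For a head of radius r on a
   neck of length n, BH/L ≈ (n+r)/(n+2r): mushroom-like geometry (n ≲ r)
   gives ≤ ~0.6 while a long-necked spine (n ≳ 2r) gives ≥ ~0.75, so 0.65
   sits in the gap.
4. **Spine-head protrusion** otherwise.

"Thin" is deliberately not a class — it is an intermediate form without a
crisp geometric definition. Branched spines bypass the cascade: a spine is
flagged branched when two depth-significant HP clusters (peaks within
`merge_radius` = 0.35 µm are merged as one head) are separated by a
corridor whose bottleneck depth is at most `valley_frac` (0.5) of the
shallower peak by more than one quantum, and their minimal base-to-peak
paths diverge into voxel-disjoint branches. Detached spines are likewise
reported with a flag only.

All thresholds live in the pipeline config and are echoed in each spine's
decision trace. They were calibrated once against the analytic geometry of
the phantom categories below, not fitted to data.

## Synthetic phantoms

The generator rasterises a dendritic cylinder (default radius 0.45 µm)
along x with attached spines: spheres on cylindrical necks, hemispheres
directly on the shaft (stubby), and uniform tubes (filopodia). Intensities
follow the observed band structure — background 10, spine band 120,
dendrite band 220 on an 8-bit scale — with a linear transition ramp
(0.15 µm) at the attachment reproducing the overlapping spine/dendrite
histogram of real stacks. The volume is convolved with a Gaussian PSF
(σ = 0.07 µm) and corrupted with additive Gaussian noise (σ = 4 grey
levels), then quantised to 8 bits. Every phantom carries exact truth: the
label volume, per-spine geometry, and one auto-placed seed per structure
(its deepest interior voxel).

Category geometry ranges (µm): stubby, hemisphere radius 0.25–0.40;
filopodia, tube radius 0.10–0.14, length 1.2–1.8; mushroom, head radius
0.30–0.45, neck radius 0.09–0.13 (capped at head/2.5), neck length
0.30–0.50; spine-head protrusion, head radius 0.26–0.34, neck radius
0.10–0.13, neck length 0.90–1.30. Neck radii below ~0.1 µm are not used:
they are sub-voxel laterally and blur below any threshold, which no
segmentation method at this sampling could recover.

Two standard scenes:

* the **five-spine recovery phantom** — one tube carrying five
  sphere-on-neck spines at the acquisition anisotropy (0.2/0.07/0.07 µm),
  used for segmentation and feature-recovery scoring;
* the **classification suite** — single-spine phantoms, ten per category,
  rendered at isotropic 0.07 µm sampling. At 0.2 µm z-steps the depth of
  0.1 µm necks sits below the half-voxel quantisation floor of the
  distance transform, so an anisotropic suite would measure the sampling,
  not the shape rules; the isotropic suite corresponds to a z-oversampled
  acquisition.

What the phantoms do *not* emulate: realistic (Gibson–Lanni) PSFs,
photon-counting noise, curved or tapering dendrites, touching spines from
neighbouring dendrites, and uneven staining. Passing the phantom tests
shows the geometry pipeline is correct under the stated imaging model; it
does not certify performance on real tissue, where seed placement and
threshold choice remain the user's responsibility.

## Validation statistics

`agreement_stats` returns the Pearson correlation of two paired series
plus a Bland–Altman summary: mean difference μ, SD of differences σ
(ddof = 1), and the fraction of points within μ ± 1.5σ. A zero-variance
series makes r undefined; it is returned as NaN with a flag and a warning.
`reproducibility_stats` summarises a raters × spines matrix as the per-spine
percent SD across raters (100·SD/mean, ddof = 1), averaged over spines;
zero-mean spines are excluded with a warning. Both are verified against
direct textbook formulas to 1e-12.

## Determinism

Every stage is deterministic: the scale sweep, claim order and conflict
rule in the opening are pure array operations; path searches break ties by
(cost, fewer voxels, lexicographic voxel order); landmark snapping breaks
ties lexicographically; phantom generation is driven by a single seeded
generator. Two runs on identical inputs produce bit-identical label
volumes and feature tables. The one caveat: lexicographic tie-breaking is
not rotation-equivariant, so a 90° rotated volume can snap the tip to a
different equally-far voxel; features are rotation-invariant to 1e-6
except the head-to-tip leg, which is pinned down to one voxel step.

## Known limitations

* Neck widths bottom out at one voxel (0.14 µm laterally): sub-resolution
  necks report the quantisation floor, not their true width.
* At 0.2 µm z-steps, heads smaller than ~0.3 µm radius span barely one
  z-slice; their depth contrast vanishes and the filopodia/mushroom
  distinction becomes unreliable (visible in the README example). Shape
  classification should be trusted only for structures resolved by ≥ 2–3
  voxels per axis.
* The junction ambiguity described above biases neck length slightly short
  and leaves a ring of neck-base voxels with the dendrite.
* Branched spines are flagged but not decomposed into their branches.
* Spine density, longitudinal tracking across time points, and vendor
  microscope formats are out of scope.
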