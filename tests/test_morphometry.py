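"""Landmarks, central paths and per-spine features on constructed regions."""

import numpy as np
import pytest
from scipy import ndimage

from spinemorph import UndefinedLandmarkError, analyze_spine
from spinemorph.morphometry import (
    SpineRegion,
    central_base_point,
    central_paths,
    center_of_head,
    locally_deepest_points,
    region_fdt,
    spine_base,
    spine_features,
    spine_tip,
)

from _oracles import geodesic_length_oracle

ISO = (0.07, 0.07, 0.07)


def _region(mask, spacing=(1.0, 1.0, 1.0), spine_id=2):
    return SpineRegion(spine_id=spine_id, mask=np.asarray(mask, dtype=bool), spacing=spacing)


def _ball(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*[np.arange(s) * d for s, d in zip(shape, spacing)], indexing="ij")
    c = np.asarray(center, dtype=float) * np.asarray(spacing)
    return sum((g - ci) ** 2 for g, ci in zip(grids, c)) <= radius**2


class TestSpineBase:
    def test_single_voxel_on_slab_has_nine_base_voxels(self):
        dendrite = np.zeros((4, 5, 5), dtype=bool)
        dendrite[0] = True
        mask = np.zeros_like(dendrite)
        mask[1, 2, 2] = True
        region = _region(mask)
        base = spine_base(region, dendrite)
        assert base.shape[0] == 9
        assert set(map(tuple, base)) == {(0, y, x) for y in (1, 2, 3) for x in (1, 2, 3)}

    def test_detached_spine_flagged(self):
        dendrite = np.zeros((4, 4, 4), dtype=bool)
        dendrite[0] = True
        mask = np.zeros_like(dendrite)
        mask[3, 2, 2] = True
        region = _region(mask)
        assert spine_base(region, dendrite).shape[0] == 0
        assert region.detached
        with pytest.raises(UndefinedLandmarkError):
            central_base_point(region)


class TestCentralBasePoint:
    def test_mean_of_two_voxels(self):
        region = _region(np.ones((3, 3, 3), dtype=bool))
        region.base = np.array([[0, 0, 0], [2, 0, 0]])
        assert central_base_point(region) == (1.0, 0.0, 0.0)

    def test_singleton(self):
        region = _region(np.ones((2, 2, 2), dtype=bool))
        region.base = np.array([[1, 1, 0]])
        assert central_base_point(region) == (1.0, 1.0, 0.0)
        assert region.cbp_voxel == (1, 1, 0)

    def test_symmetric_ring_centroid(self):
        region = _region(np.ones((3, 5, 5), dtype=bool))
        ring = [(0, 1, 2), (0, 2, 1), (0, 2, 3), (0, 3, 2)]
        region.base = np.array(ring)
        assert central_base_point(region) == (0.0, 2.0, 2.0)


class TestLocallyDeepestPoints:
    def test_ball_has_central_maximum(self):
        mask = _ball((11, 11, 11), (5, 5, 5), 4.2)
        region = _region(mask)
        hp = locally_deepest_points(region, l=2)
        assert (5, 5, 5) in set(map(tuple, hp))
        assert all(np.linalg.norm(np.asarray(p) - 5) <= 1.8 for p in map(tuple, hp))

    def test_thin_filament_is_one_big_plateau(self):
        mask = np.zeros((3, 3, 15), dtype=bool)
        mask[1, 1, :] = True
        region = _region(mask)
        hp = locally_deepest_points(region, l=2)
        assert hp.shape[0] == 15  # constant depth: every voxel qualifies

    def test_dumbbell_has_exactly_two_centres(self):
        # two directly fused balls; the waist is shallower than either centre
        mask = _ball((9, 9, 15), (4, 4, 4), 3.4) | _ball((9, 9, 15), (4, 4, 10), 3.4)
        region = _region(mask)
        hp = set(map(tuple, locally_deepest_points(region, l=2)))
        assert (4, 4, 4) in hp and (4, 4, 10) in hp
        assert all(min(abs(p[2] - 4), abs(p[2] - 10)) <= 1 for p in hp)


class TestCenterOfHeadAndTip:
    def test_ball_center_and_depth(self):
        r_um = 0.35
        mask = _ball((11, 11, 11), (5, 5, 5), r_um, ISO)
        region = _region(mask, ISO)
        locally_deepest_points(region)
        center_of_head(region)
        assert region.ch_voxel == (5, 5, 5)
        # depth at the centre of a rasterised ball is the radius up to a voxel
        assert region.omega_at(region.ch_voxel) == pytest.approx(r_um, abs=1.5 * 0.07)

    def test_filament_tip_is_far_end(self):
        mask = np.zeros((3, 3, 12), dtype=bool)
        mask[1, 1, :] = True
        region = _region(mask)
        region_fdt(region)
        region.base = np.array([[1, 1, 0]])
        region.cbp_voxel = (1, 1, 0)
        region.cbp = (1.0, 1.0, 0.0)
        spine_tip(region)
        assert region.tip_voxel == (1, 1, 11)

    def test_tip_matches_exhaustive_argmax(self, rng):
        mask = rng.uniform(0, 1, (5, 5, 5)) < 0.8
        mask[2, 2, 2] = True
        lab, _ = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        mask = lab == lab[2, 2, 2]
        region = _region(mask, ISO)
        region_fdt(region)
        region.cbp_voxel = (2, 2, 2)
        region.base = np.empty((0, 3), dtype=int)
        spine_tip(region)
        best = max(
            (geodesic_length_oracle(mask, ISO, (2, 2, 2), p), p)
            for p in map(tuple, np.argwhere(mask))
        )
        assert region.omega is not None
        got = geodesic_length_oracle(mask, ISO, (2, 2, 2), region.tip_voxel)
        assert got == pytest.approx(best[0], abs=1e-9)


class TestCentralPathsAndFeatures:
    def _hemisphere_on_slab(self, r_vox=5):
        shape = (14, 17, 17)
        dendrite = np.zeros(shape, dtype=bool)
        dendrite[:4] = True
        ball = _ball(shape, (3, 8, 8), r_vox + 0.2)
        mask = ball & ~dendrite
        return _region(mask), dendrite

    def test_adjacent_landmarks_give_two_voxel_path(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        region = _region(mask)
        region_fdt(region)
        region.base = np.empty((0, 3), dtype=int)
        region.cbp_voxel = (1, 1, 1)
        region.ch_voxel = (1, 1, 2)
        region.tip_voxel = (1, 1, 2)
        bh, ht = central_paths(region)
        assert len(bh) == 2 and len(ht) == 1

    def test_straight_filament_path_is_the_filament(self):
        mask = np.zeros((3, 3, 10), dtype=bool)
        mask[1, 1, :] = True
        region = _region(mask)
        region_fdt(region)
        region.base = np.empty((0, 3), dtype=int)
        region.cbp_voxel = (1, 1, 0)
        region.ch_voxel = (1, 1, 5)
        region.tip_voxel = (1, 1, 9)
        bh, ht = central_paths(region)
        assert [v[2] for v in bh.voxels] == list(range(6))
        assert bh.length_um + ht.length_um == pytest.approx(9.0)

    def test_hemisphere_neck_length_is_below_stubby_threshold(self):
        # hemisphere directly on the shaft: base-to-head distance barely
        # exceeds the head depth, so the neck reads as (effectively) zero
        region, dendrite = self._hemisphere_on_slab()
        region = SpineRegion(spine_id=region.spine_id, mask=region.mask, spacing=ISO)
        dendrite = dendrite
        analyze_spine(region, dendrite)
        assert region.features["neck_length_um"] <= 0.15  # default stubby threshold

    def test_neck_length_clamped_at_zero_for_head_at_base(self):
        from spinemorph.fuzzy import VoxelPath

        mask = np.zeros((3, 3, 5), dtype=bool)
        mask[1, 1, :] = True
        region = _region(mask)
        region.omega = np.zeros(mask.shape)
        region.omega[1, 1, 1] = 5.0  # head depth far exceeds the path length
        region.ch_voxel = (1, 1, 1)
        region.tip_voxel = (1, 1, 4)
        region.hp = np.array([[1, 1, 1]])
        region.bh = VoxelPath(((1, 1, 0), (1, 1, 1)), 1.0)
        region.ht = VoxelPath(((1, 1, 1), (1, 1, 4)), 3.0)
        spine_features(region)
        assert region.features["neck_length_um"] == 0.0
        assert region.features["neck_length_raw_um"] == pytest.approx(-4.0)

    def test_sphere_on_neck_feature_recovery(self):
        # head radius 0.4 um, neck radius 0.1 um, neck length 0.6 um at 0.07 iso
        shape = (30, 17, 17)
        sp = ISO
        dendrite = np.zeros(shape, dtype=bool)
        dendrite[:4] = True
        surface_z = 3.5 * 0.07
        neck = np.zeros(shape, dtype=bool)
        zz, yy, xx = np.meshgrid(*[np.arange(s) * 0.07 for s in shape], indexing="ij")
        axis_y, axis_x = 8 * 0.07, 8 * 0.07
        in_z = (zz > surface_z - 0.05) & (zz <= surface_z + 0.6)
        neck = in_z & ((yy - axis_y) ** 2 + (xx - axis_x) ** 2 <= 0.1**2)
        head = (zz - (surface_z + 1.0)) ** 2 + (yy - axis_y) ** 2 + (xx - axis_x) ** 2 <= 0.4**2
        region = _region((neck | head) & ~dendrite, sp)
        analyze_spine(region, dendrite)
        f = region.features
        tol = 1.5 * np.linalg.norm(sp)  # 1.5 voxel diagonals
        assert f["head_depth_um"] == pytest.approx(0.4, abs=tol)
        assert f["min_neck_width_um"] == pytest.approx(0.2, abs=tol)
        assert f["neck_length_um"] == pytest.approx(0.6, abs=tol)
        assert f["spine_length_um"] == pytest.approx(1.4, abs=2 * tol)
        assert f["avg_head_width_um"] <= 2 * f["head_depth_um"] + 1e-9

    def test_volume_is_voxel_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.flat[:100] = True
        region = _region(mask, (0.2, 0.07, 0.07))
        region_fdt(region)
        region.detached = True
        spine_features(region)
        assert region.features["volume_um3"] == pytest.approx(100 * 0.2 * 0.07 * 0.07)

    def test_feature_invariants_on_phantom(self, five_spine_result):
        _, _, result = five_spine_result
        for r in result.regions:
            f = r.features
            assert f["volume_um3"] > 0
            if r.detached:
                assert f["neck_length_um"] is None
                continue
            assert f["neck_length_um"] >= 0
            assert f["min_neck_width_um"] <= 2 * f["head_depth_um"] + 1e-9
            assert f["spine_length_um"] >= f["ht_length_um"] - 1e-9
            assert f["avg_head_width_um"] > 0


class TestRotationInvariance:
    def test_90_degree_rotation_preserves_features(self):
        from spinemorph import PhantomSpec, SpineSpec, make_phantom, run

        spec = PhantomSpec(
            shape=(40, 48, 48),
            spacing=(0.07, 0.07, 0.07),
            dendrite_center_um=(1.4, 1.0),
            spines=(
                SpineSpec("mushroom", attach_x_um=1.6, direction=(0.1, 1.0, 0.15),
                          head_radius_um=0.35, neck_radius_um=0.12, neck_length_um=0.45),
            ),
            seed=5,
        )
        vol, truth = make_phantom(spec)
        res = run(vol, truth.seeds)

        k = 1  # rotate 90 degrees in the (y, x) plane
        rot_data = np.rot90(vol.data, k=k, axes=(1, 2)).copy()
        n_y = vol.shape[1]

        def rot_voxel(v):
            z, y, x = v
            return (z, vol.shape[2] - 1 - x, y)

        from spinemorph import IntensityVolume, SeedSet

        rot_vol = IntensityVolume(rot_data, vol.spacing)
        rot_seeds = SeedSet(
            spine={rot_voxel(v) for v in truth.seeds.spine},
            dendrite={rot_voxel(v) for v in truth.seeds.dendrite},
        )
        rot_res = run(rot_vol, rot_seeds)
        assert rot_res.segmentation.k == res.segmentation.k == 1
        a, b = res.regions[0].features, rot_res.regions[0].features
        for key in ("volume_um3", "neck_length_um", "min_neck_width_um",
                    "avg_head_width_um", "head_depth_um"):
            assert a[key] == pytest.approx(b[key], abs=1e-6), key
        # tip tie-breaking is lexicographic, so the head-to-tip leg is only
        # pinned down to a voxel step under rotation
        assert a["spine_length_um"] == pytest.approx(b["spine_length_um"], abs=0.07)
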