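import numpy as np
import pytest
from scipy import ndimage as ndi

from bctseg import generate_phantom, dsc
from bctseg._flood import watershed
from bctseg.core_io import Volume
from bctseg.detection import detect_all
from bctseg.watershed_seg import (
    locate_nipple,
    segment_hard,
    segment_muscle,
    segment_skin,
    segment_skinfold,
    upper_distance_marker,
    _nipple_sphere,
)

from _reference import reference_watershed
from conftest import small_spec


def _two_spheres_with_neck(shape=(40, 24, 24), r=7, neck=1):
    g = np.zeros(shape, bool)
    x, y, z = np.indices(shape)
    c1, c2 = 10, 29
    g |= (x - c1) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= r * r
    g |= (x - c2) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= r * r
    g |= (np.abs(y - 12) <= neck) & (np.abs(z - 12) <= neck) & (x >= c1) & (x <= c2)
    return g, c1, c2


def test_watershed_oracle_equivalence_on_neck_toy():
    g, c1, c2 = _two_spheres_with_neck((20, 20, 20), r=5, neck=1)
    d = ndi.distance_transform_edt(g)
    markers = np.zeros(g.shape, np.int32)
    markers[5, 10, 10] = 1
    markers[14, 10, 10] = 2
    ours = watershed(-d, markers, g)
    ref = reference_watershed(-d, markers, g)
    assert np.array_equal(ours, ref)


def test_watershed_cut_at_minimal_neck():
    g, c1, c2 = _two_spheres_with_neck()
    d = ndi.distance_transform_edt(g)
    markers = np.zeros(g.shape, np.int32)
    markers[10, 12, 12] = 1
    markers[29, 12, 12] = 2
    out = watershed(-d, markers, g)
    assert set(np.unique(out[g])) == {1, 2}
    # the boundary between catchments lies within 1 voxel of the neck's
    # minimal cross-section (everything between the sphere surfaces)
    boundary_x = np.where((out == 1).any(axis=(1, 2)))[0].max()
    assert 10 + 7 - 1 <= boundary_x <= 29 - 7 + 1


def test_watershed_partitions_marked_components():
    rng = np.random.default_rng(0)
    g = rng.random((15, 15, 15)) < 0.6
    d = ndi.distance_transform_edt(g)
    markers = np.zeros(g.shape, np.int32)
    lab, n = ndi.label(g, ndi.generate_binary_structure(3, 1))
    for comp in range(1, n + 1):
        idx = np.argwhere(lab == comp)[0]
        markers[tuple(idx)] = comp
    out = watershed(-d, markers, g)
    assert (out[g] > 0).all()
    assert not out[~g].any()


class TestSegmentHard:
    def test_erosion_dilation_reconstruction_identity_on_sphere(self):
        x, y, z = np.indices((30, 30, 30))
        sphere = (x - 15) ** 2 + (y - 15) ** 2 + (z - 15) ** 2 <= 81
        seed = ndi.binary_erosion(sphere, np.ones((5, 5, 5), bool))
        recovered = segment_hard(seed, sphere)
        assert np.array_equal(recovered, sphere)

    def test_seed_equal_to_object_is_idempotent(self):
        x, y, z = np.indices((20, 20, 20))
        sphere = (x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 36
        assert np.array_equal(segment_hard(sphere, sphere), sphere)

    def test_reconstruction_confined_to_seeded_object(self):
        # two bright cubes touching only at a corner (diagonal adjacency):
        # 6-connected propagation stays within the seeded one
        binary = np.zeros((24, 24, 24), bool)
        binary[4:10, 4:10, 4:10] = True
        binary[10:16, 10:16, 10:16] = True
        seed = np.zeros_like(binary)
        seed[6:8, 6:8, 6:8] = True
        out = segment_hard(seed, binary)
        assert out[4:10, 4:10, 4:10].all()
        assert not out[10:16, 10:16, 10:16].any()

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            segment_hard(np.zeros((8, 8, 8), bool), np.ones((8, 8, 8), bool))


def test_upper_distance_marker_concentric_ball():
    x, y, z = np.indices((31, 31, 31))
    ball = (x - 15) ** 2 + (y - 15) ** 2 + (z - 15) ** 2 <= 13**2
    d = ndi.distance_transform_edt(ball)
    marker = upper_distance_marker(d, ball)
    # marker is the analytic concentric ball at the 60th-percentile radius
    cutoff = np.percentile(d[ball], 60.0)
    expected = ball & (d >= cutoff)
    assert np.array_equal(marker, expected)
    assert marker.sum() > 0
    # concentric: marker centroid equals ball centroid
    assert np.allclose(ndi.center_of_mass(marker), (15, 15, 15), atol=0.1)


class TestNipple:
    def test_phantom_tip_within_3_voxels(self, cal, small_phantom):
        v, truth = small_phantom
        tip = locate_nipple(v, cal)
        assert np.linalg.norm(np.subtract(tip, truth.nipple_tip)) <= 3.0

    def test_all_air_raises(self, cal):
        v = Volume(np.full((16, 16, 16), -1000.0, dtype=np.float32), 1.0)
        with pytest.raises(ValueError):
            locate_nipple(v, cal)

    def test_duct_sphere_geometry(self):
        sphere = _nipple_sphere((40, 40, 40), (20, 20, 10), radius_vox=9.0)
        x, y, z = np.nonzero(sphere)
        dist = np.sqrt((x - 20.0) ** 2 + (y - 20.0) ** 2 + (z - 10.0) ** 2)
        assert dist.max() <= 9.0


class TestSoftTissueStages:
    def test_skinfold_separation_on_phantom(self, cal):
        v, truth = generate_phantom(
            small_spec(glandular_fraction=0.2, include_skinfold=True, rng_seed=31)
        )
        seeds = detect_all(v, cal)
        assert seeds.flags.skinfold
        fold = segment_skinfold(v, seeds, cal)
        assert dsc(fold, truth.labels.mask("skinfold")) >= 0.95

    def test_skinfold_requires_flag(self, cal, small_phantom):
        v, _ = small_phantom
        seeds = detect_all(v, cal)
        seeds.flags.skinfold = False
        with pytest.raises(ValueError):
            segment_skinfold(v, seeds, cal)

    def test_muscle_on_phantom(self, cal):
        v, truth = generate_phantom(
            small_spec(glandular_fraction=0.3, include_muscle=True, rng_seed=32)
        )
        seeds = detect_all(v, cal)
        assert seeds.flags.muscle
        muscle = segment_muscle(v, seeds, cal)
        assert dsc(muscle, truth.labels.mask("muscle")) >= 0.90

    def test_skin_shell_thickness_recovered(self, cal):
        """Uniform 2-mm shell: DSC and recovered thickness at the surface."""
        v, truth = generate_phantom(
            small_spec(glandular_fraction=0.2, skin_thickness_mm=(2.0, 2.0), rng_seed=33)
        )
        tip = locate_nipple(v, cal)
        skin = segment_skin(v, cal, tip)
        assert dsc(skin, truth.labels.mask("skin")) >= 0.89
        # thickness: depth of skin voxels below the outer surface stays
        # within one voxel of the generated 2 mm
        air = ~(truth.labels.labels > 0)
        depth = ndi.distance_transform_edt(~air) * v.spacing_mm
        p90 = np.percentile(depth[skin], 90)
        assert 2.0 - v.spacing_mm <= p90 <= 2.0 + 1.5 * v.spacing_mm

    def test_skin_does_not_leak_down_gland_branches(self, cal):
        """Where gland meets the shell away from the nipple the skin result
        must not extend deeper than the true shell plus one voxel."""
        v, truth = generate_phantom(small_spec(glandular_fraction=0.5, rng_seed=34))
        tip = locate_nipple(v, cal)
        skin = segment_skin(v, cal, tip)
        air = ~(truth.labels.labels > 0)
        depth = ndi.distance_transform_edt(~air) * v.spacing_mm
        tmax = max(small_spec().skin_thickness_mm)
        sphere = _nipple_sphere(v.shape, tip, 9.0 / v.spacing_mm)
        deep_leak = skin & ~sphere & (depth > tmax + v.spacing_mm)
        assert deep_leak.sum() / skin.sum() < 0.02

    def test_skin_nipple_tip_outside_volume_rejected(self, cal, small_phantom):
        v, _ = small_phantom
        with pytest.raises(ValueError):
            segment_skin(v, cal, (-1, 0, 0))
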