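"""Capsule muscle model: seeding, contact growth, volumes, orientation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from myogape import (AttachmentPatch, EyeballSphere, MuscleFiber, MuscleGroup,
                     TriangleMesh, fiber_orientation, fit_eyeball, grow_radii,
                     muscle_volume, relative_volumes, seed_fibers,
                     segment_distance)
from myogape.geometry_core import SymmetryPlane
from myogape.muscle_model import MuscleError, capsule_volume_closed_form

BONE_PLANE = TriangleMesh([[-20, -20, 0], [40, -20, 0], [40, 40, 0],
                           [-20, 40, 0]], [[0, 1, 2], [0, 2, 3]], "plane")


def _line_patch(muscle, role, start, step, n=10):
    pts = np.asarray(start, float) + np.arange(n)[:, None] * np.asarray(step, float)
    return AttachmentPatch(muscle, role, pts)


def _group(points_pairs, muscle="m. temp pro", radius=0.0):
    fibers = [MuscleFiber(o, i, radius, muscle, k)
              for k, (o, i) in enumerate(points_pairs)]
    return MuscleGroup(muscle, fibers)


class TestSeedFibers:
    def test_single_fiber_joins_centroid_points(self):
        o = _line_patch("m. mass sup", "origin", [0, 0, 10], [1, 0, 0])
        i = _line_patch("m. mass sup", "insertion", [0, 0, 0], [1, 0, 0])
        (f,) = seed_fibers(o, i, 1)
        # the patch point nearest each centroid is the middle of the line
        assert abs(f.origin[0] - 4.5) <= 0.5
        assert abs(f.insertion[0] - 4.5) <= 0.5

    def test_parallel_line_patches_give_non_crossing_fibers(self):
        """Rank pairing on two parallel 10-point lines must reproduce the
        minimal-crossing pairing found by brute force (identity pairing)."""
        o = _line_patch("m. mass sup", "origin", [0, 0, 10], [1, 0, 0])
        i = _line_patch("m. mass sup", "insertion", [0, 0, 0], [1, 0, 0])
        fibers = seed_fibers(o, i, 10)
        assert len(fibers) == 10
        # brute-force oracle: pairing by sorted x minimises total crossing;
        # check every returned fiber is vertical (same x at both ends)
        for f in fibers:
            assert abs(f.origin[0] - f.insertion[0]) < 1e-9
        # and no two fibers cross (as segments in the xz-plane)
        for a in fibers:
            for b in fibers:
                if a.id != b.id:
                    assert segment_distance(a.origin, a.insertion,
                                            b.origin, b.insertion) > 0.5

    def test_determinism(self):
        o = _line_patch("m. temp pro", "origin", [0, 0, 10], [1, 0.2, 0])
        i = _line_patch("m. temp pro", "insertion", [0, 1, 0], [1, -0.1, 0])
        a = seed_fibers(o, i, 7, seed=3)
        b = seed_fibers(o, i, 7, seed=3)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.origin, fb.origin)
            assert np.array_equal(fa.insertion, fb.insertion)

    def test_oversized_request_warns_and_uses_all_points(self):
        o = _line_patch("m. temp pro", "origin", [0, 0, 10], [1, 0, 0], n=4)
        i = _line_patch("m. temp pro", "insertion", [0, 0, 0], [1, 0, 0], n=4)
        with pytest.warns(UserWarning):
            fibers = seed_fibers(o, i, 8)
        assert len(fibers) == 4


class TestSegmentDistance:
    def test_identical_and_skew_segments(self):
        assert segment_distance([0, 0, 0], [1, 1, 1], [0, 0, 0], [1, 1, 1]) == 0
        assert np.isclose(
            segment_distance([0, 0, 0], [1, 0, 0], [0, 0, 2], [0, 1, 2]), 2.0)

    def test_random_pairs_match_refined_grid_oracle(self, rng):
        """1000 random segment pairs vs an independent parameter-grid oracle
        with local refinement, agreement to 1e-6 mm."""
        for _ in range(1000):
            p1, q1, p2, q2 = rng.uniform(-5, 5, size=(4, 3))
            got = segment_distance(p1, q1, p2, q2)

            def dist2(x):
                s, t = x
                diff = (p1 + s * (q1 - p1)) - (p2 + t * (q2 - p2))
                return float(diff @ diff)

            ss, tt = np.meshgrid(np.linspace(0, 1, 41), np.linspace(0, 1, 41))
            a = p1 + ss[..., None] * (q1 - p1)
            b = p2 + tt[..., None] * (q2 - p2)
            dd = np.linalg.norm(a - b, axis=-1)
            k = np.unravel_index(np.argmin(dd), dd.shape)
            ref = minimize(dist2, [ss[k], tt[k]], method="L-BFGS-B",
                           bounds=[(0, 1), (0, 1)],
                           options={"ftol": 1e-16, "gtol": 1e-12})
            assert abs(got - np.sqrt(ref.fun)) < 1e-6


class TestGrowRadii:
    def test_parallel_fibers_merge_at_half_separation(self):
        g = _group([([0, 0, 0], [10, 0, 0]), ([0, 4, 0], [10, 4, 0])])
        grow_radii([g], [], [], 0.1)
        assert np.isclose(g.radius, 2.0, atol=1e-9)

    def test_bone_plane_stops_growth_at_clearance(self):
        g = _group([([0, 0, 3], [10, 0, 3])])
        grow_radii([g], [BONE_PLANE], [], 0.1)
        assert abs(g.radius - 3.0) <= 0.1 + 1e-9

    def test_eyeball_obstacle_stops_growth(self):
        g = _group([([0, 0, 0], [10, 0, 0])])
        eye = EyeballSphere([5, 4, 0], 1.0)
        grow_radii([g], [], [eye], 0.1)
        assert abs(g.radius - 3.0) <= 0.1 + 1e-9  # 4 mm gap - 1 mm eye radius

    def test_lone_fiber_caps_at_rest_length(self):
        g = _group([([0, 0, 0], [10, 0, 0])])
        grow_radii([g], [], [], 0.5)
        assert g.radius == 10.0

    def test_other_muscle_contact_stops_both_groups(self):
        a = _group([([0, 0, 0], [10, 0, 0])], muscle="m. temp pro")
        b = _group([([0, 6, 0], [10, 6, 0])], muscle="m. mass sup")
        grow_radii([a, b], [], [], 0.5)
        # groups grow synchronously; they meet when r_a + r_b = 6
        assert a.radius + b.radius <= 6.0 + 0.5
        assert a.radius + b.radius >= 6.0 - 1e-9

    def test_growth_monotone_under_step_halving(self):
        def run(dr):
            g = _group([([0, 0, 3], [10, 0, 3])])
            grow_radii([g], [BONE_PLANE], [], dr)
            return g.radius

        r_coarse, r_fine = run(0.4), run(0.2)
        assert r_fine <= r_coarse + 0.4 + 1e-9

    def test_invalid_step_rejected(self):
        g = _group([([0, 0, 0], [10, 0, 0])])
        with pytest.raises(MuscleError):
            grow_radii([g], [], [], 0.0)


class TestMuscleVolume:
    def test_single_capsule_matches_closed_form(self):
        g = _group([([0, 0, 0], [10, 0, 0])], radius=1.0)
        v = muscle_volume(g, 0.2)
        exact = capsule_volume_closed_form(10, 1.0)
        assert abs(v - exact) / exact < 0.02

    def test_disjoint_capsules_are_additive(self):
        g = _group([([0, 0, 0], [10, 0, 0]), ([0, 10, 0], [10, 10, 0])],
                   radius=1.0)
        v = muscle_volume(g, 0.2)
        exact = 2 * capsule_volume_closed_form(10, 1.0)
        assert abs(v - exact) / exact < 0.02

    def test_overlapping_union_matches_monte_carlo(self, rng):
        segs = [([0, 0, 0], [10, 0, 0]), ([0, 1, 0], [10, 1, 1])]
        g = _group(segs, radius=1.0)
        v = muscle_volume(g, 0.2)
        lo, hi = np.array([-1.2, -1.2, -1.2]), np.array([11.2, 2.2, 2.2])
        pts = rng.uniform(lo, hi, size=(10 ** 6, 3))
        from myogape.muscle_model import point_segment_distance

        inside = np.zeros(len(pts), dtype=bool)
        for p, q in segs:
            inside |= point_segment_distance(pts, np.array(p, float),
                                             np.array(q, float)) <= 1.0
        mc = inside.mean() * np.prod(hi - lo)
        assert abs(v - mc) / mc < 0.02

    def test_pitch_convergence(self):
        g = _group([([0, 0, 0], [10, 0, 0])], radius=1.0)
        assert abs(muscle_volume(g, 0.2) - muscle_volume(g, 0.1)) \
            / muscle_volume(g, 0.1) < 0.01

    def test_coarse_pitch_rejected(self):
        g = _group([([0, 0, 0], [10, 0, 0])], radius=1.0)
        with pytest.raises(MuscleError, match="too coarse"):
            muscle_volume(g, 0.75)


class TestRelativeVolumes:
    def test_ratios_and_sum(self):
        # closed-form 2:1:1 by doubling the cylinder length contribution is
        # messy; use two identical + verify symmetry, then a known ratio
        g1 = _group([([0, 0, 0], [10, 0, 0])], muscle="m. temp pro", radius=1.0)
        g2 = _group([([0, 20, 0], [10, 20, 0])], muscle="m. mass sup", radius=1.0)
        rep = relative_volumes([g1, g2], 0.2)
        assert np.allclose(rep.fractions_pct, [50, 50], atol=0.5)
        assert abs(rep.fractions_pct.sum() - 100.0) < 1e-6

    def test_single_group_is_hundred_percent(self):
        g = _group([([0, 0, 0], [10, 0, 0])], radius=1.0)
        rep = relative_volumes([g], 0.2)
        assert np.isclose(rep.fractions_pct[0], 100.0)

    def test_zero_radius_rejected(self):
        g = _group([([0, 0, 0], [10, 0, 0])], radius=0.0)
        with pytest.raises(MuscleError):
            relative_volumes([g], 0.2)


class TestFiberOrientation:
    PLANE = SymmetryPlane([1, 0, 0], [0, 0, 0])
    HORIZ = np.array([0.0, 1.0, 0.0])

    @pytest.mark.parametrize("insertion,expected", [
        ((0, 1, 0), 0.0), ((0, 0, 1), 90.0), ((0, 1, 1), 45.0)])
    def test_reference_angles(self, insertion, expected):
        f = MuscleFiber([0, 0, 0], insertion, 0, "m. mass sup", 0)
        assert np.isclose(fiber_orientation(f, self.PLANE, self.HORIZ),
                          expected, atol=1e-9)

    def test_fiber_along_plane_normal_rejected(self):
        f = MuscleFiber([0, 0, 0], [1, 0, 0], 0, "m. mass sup", 0)
        with pytest.raises(MuscleError, match="undefined"):
            fiber_orientation(f, self.PLANE, self.HORIZ)


class TestFitEyeball:
    def test_ring_orbit_gives_inscribed_sphere(self):
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        ring = np.column_stack([5 * np.cos(t), 5 * np.sin(t), np.zeros_like(t)])
        eye = fit_eyeball(ring, [])
        assert np.allclose(eye.center, 0, atol=1e-6)
        assert np.isclose(eye.radius, 5.0, atol=1e-6)

    def test_rim_in_box_bounds_radius(self):
        import trimesh

        box = trimesh.creation.box(extents=[8, 8, 8])
        bone = TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces), "box")
        t = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        rim = np.column_stack([2 * np.cos(t), 2 * np.sin(t), np.zeros_like(t)])
        eye = fit_eyeball(rim, [bone])
        assert eye.radius <= 4.0 + 1e-6

    def test_sphere_does_not_penetrate_bone(self, rng):
        from myogape.geometry_core import point_mesh_distance

        t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        rim = np.column_stack([3 * np.cos(t), 3 * np.sin(t), np.zeros_like(t)])
        eye = fit_eyeball(rim, [BONE_PLANE])
        # sample the sphere surface; signed check reduces to distance >= 0
        dirs = rng.normal(size=(2000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        surf = eye.center + eye.radius * dirs
        d = point_mesh_distance(surf, BONE_PLANE)
        assert d.min() >= -1e-6


class TestPatchValidation:
    def test_unknown_muscle_rejected(self):
        with pytest.raises(MuscleError, match="unknown muscle"):
            AttachmentPatch("m. bogus", "origin", [[0, 0, 0]])

    def test_off_bone_patch_rejected(self):
        patch = AttachmentPatch("m. temp pro", "origin", [[0, 0, 5]])
        with pytest.raises(MuscleError, match="off bone"):
            patch.validate_on_bone(BONE_PLANE)

    def test_generated_patches_lie_on_their_bones(self, scene):
        for p in scene.patches[:6]:
            p.validate_on_bone(getattr(scene, p.bone))
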