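"""Scene sampling, rendering, noise and labelling."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

import stereomantis as sm
from stereomantis import Eye, HeadPose, RetinalGrid, Scene, Sphere


class TestRetinalGrid:
    def test_default_matches_reference_configuration(self):
        grid = RetinalGrid()
        assert (grid.n_azimuth, grid.n_elevation) == (51, 51)
        assert grid.azimuths[0] == -70 and grid.azimuths[-1] == 70
        assert grid.spacing == (pytest.approx(2.8), pytest.approx(2.8))
        assert grid.n_units == 2601

    def test_linear_index_round_trip(self):
        grid = RetinalGrid(25, 25, 70.0)
        az, el = grid.direction_of(grid.linear_index(3, 17))
        assert az == pytest.approx(grid.azimuths[17])
        assert el == pytest.approx(grid.elevations[3])


class TestSubtense:
    def test_printed_example_diameter(self):
        assert sm.sphere_diameter_for_subtense(8, 15) == pytest.approx(2.1, abs=0.05)

    def test_zero_subtense_limit(self):
        assert sm.sphere_diameter_for_subtense(5, 0) == 0

    @pytest.mark.parametrize("distance,subtense", [(4, 10), (2, 30), (10, 5)])
    def test_matches_brute_force_root_of_subtense_function(self, distance, subtense):
        d = sm.sphere_diameter_for_subtense(distance, subtense)
        oracle = brentq(
            lambda diam: sm.angular_subtense(diam, distance) - subtense,
            1e-9, 2 * distance - 1e-9, xtol=1e-12,
        )
        assert d == pytest.approx(oracle, abs=1e-9)

    def test_round_trips_with_subtense(self):
        d = sm.sphere_diameter_for_subtense(4, 10)
        assert sm.angular_subtense(d, 4) == pytest.approx(10, abs=1e-9)


class TestSampling:
    def test_sampled_spheres_subtend_the_requested_angle(self, rng):
        scene = sm.sample_training_scene(rng)
        assert len(scene) == 4
        for s in scene.spheres:
            assert sm.angular_subtense(s.diameter, s.distance) == pytest.approx(
                10.0, abs=1e-6
            )

    def test_distribution_parameters(self, rng):
        spheres = [
            s
            for _ in range(25000)
            for s in sm.sample_training_scene(rng).spheres
        ]
        az = np.array([s.azimuth for s in spheres])
        dist = np.array([s.distance for s in spheres])
        assert dist.min() >= 1.0 and dist.max() <= 11.0
        assert abs(az.mean()) < 1.0
        assert az.std() == pytest.approx(45.0, rel=0.02)

    def test_empty_scene(self, rng):
        assert len(sm.sample_training_scene(rng, n_objects=0)) == 0

    def test_invalid_ranges_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.sample_training_scene(rng, distance_range=(5, 2))
        with pytest.raises(ValueError):
            sm.sample_training_scene(rng, subtense=0)


class TestRendering:
    grid = RetinalGrid()
    pose = HeadPose(interocular=1.0)

    def test_empty_scene_renders_black(self):
        img = sm.render_scene(Scene(), self.pose, Eye.LEFT, self.grid)
        assert not img.values.any()

    def test_active_set_matches_per_unit_angular_oracle(self):
        sphere = Sphere(0, 0, 5, sm.sphere_diameter_for_subtense(5, 10))
        img = sm.render_scene(Scene((sphere,)), self.pose, Eye.LEFT, self.grid)
        # oracle: brute-force angular test per unit at the eye's nodal point
        nodal = sm.eye_nodal_point(self.pose, Eye.LEFT)
        rel = sphere.centre() - nodal
        ang_radius = np.degrees(np.arcsin(sphere.diameter / 2 / np.linalg.norm(rel)))
        expected = np.zeros_like(img.values)
        for i, el in enumerate(self.grid.elevations):
            for j, az in enumerate(self.grid.azimuths):
                u = sm.fick_rotation(az, el) @ [0, 0, 1]
                sep = np.degrees(
                    np.arccos(np.clip(u @ rel / np.linalg.norm(rel), -1, 1))
                )
                expected[i, j] = 1.0 * (sep <= ang_radius)
        np.testing.assert_array_equal(img.values, expected)

    def test_midline_sphere_images_mirror_in_azimuth(self):
        sphere = Sphere(0, 7, 4, sm.sphere_diameter_for_subtense(4, 12))
        left = sm.render_scene(Scene((sphere,)), self.pose, Eye.LEFT, self.grid)
        right = sm.render_scene(Scene((sphere,)), self.pose, Eye.RIGHT, self.grid)
        np.testing.assert_array_equal(left.values, right.values[:, ::-1])

    def test_high_elevation_sphere_spans_more_azimuth_columns(self):
        # lat-long flattening elongates off-equator spheres
        lo = Sphere(0, 0, 6, sm.sphere_diameter_for_subtense(6, 10))
        hi = Sphere(0, 53, 6, sm.sphere_diameter_for_subtense(6, 10))
        cols = {}
        for name, sph in [("lo", lo), ("hi", hi)]:
            img = sm.render_scene(Scene((sph,)), self.pose, Eye.LEFT, self.grid)
            cols[name] = np.count_nonzero(img.values.any(axis=0))
        assert cols["hi"] > cols["lo"]

    def test_rendering_is_monotone_in_scene_content(self, rng):
        spheres = tuple(sm.sample_training_scene(rng).spheres)
        partial = sm.render_scene(Scene(spheres[:2]), self.pose, Eye.LEFT, self.grid)
        full = sm.render_scene(Scene(spheres), self.pose, Eye.LEFT, self.grid)
        assert np.all(full.values >= partial.values)

    def test_monocular_image_centroids_separate_by_the_disparity(self):
        # on a refined grid the left/right azimuth centroids of one sphere
        # differ by approximately the geometric disparity of its centre
        fine = RetinalGrid(281, 281, 35.0)  # 0.25 deg spacing
        sphere = Sphere(-5, 0, 3, sm.sphere_diameter_for_subtense(3, 8))
        point = sphere.centre()
        delta = sm.disparity(
            sm.project_to_retina(self.pose, Eye.LEFT, point),
            sm.project_to_retina(self.pose, Eye.RIGHT, point),
        )
        cents = {}
        for eye in (Eye.LEFT, Eye.RIGHT):
            img = sm.render_scene(Scene((sphere,)), self.pose, eye, fine)
            w = img.values.sum(axis=0)
            cents[eye] = np.sum(fine.azimuths * w) / w.sum()
        assert cents[Eye.RIGHT] - cents[Eye.LEFT] == pytest.approx(delta, abs=0.3)


class TestNoise:
    def test_zero_sigma_is_identity(self, rng):
        img = sm.RetinalImage(Eye.LEFT, np.zeros((51, 51)), RetinalGrid())
        out = sm.add_noise(img, 0.0, rng)
        np.testing.assert_array_equal(out.values, img.values)

    def test_negative_sigma_rejected(self, rng):
        img = sm.RetinalImage(Eye.LEFT, np.zeros((51, 51)), RetinalGrid())
        with pytest.raises(ValueError):
            sm.add_noise(img, -0.1, rng)

    def test_same_seed_gives_identical_noise(self):
        img = sm.RetinalImage(Eye.LEFT, np.zeros((51, 51)), RetinalGrid())
        a = sm.add_noise(img, 0.1, np.random.default_rng(3)).values
        b = sm.add_noise(img, 0.1, np.random.default_rng(3)).values
        np.testing.assert_array_equal(a, b)

    def test_background_mean_matches_clipped_gaussian(self, rng):
        sigma = 0.1
        grid = RetinalGrid(101, 101, 70.0)
        img = sm.RetinalImage(Eye.LEFT, np.zeros((101, 101)), grid)
        vals = sm.add_noise(img, sigma, rng).values.ravel()
        # E[max(X,0)] for X ~ N(0, sigma^2) = sigma/sqrt(2 pi)
        expected = sigma * norm.pdf(0)
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 3 * se


class TestLabelling:
    grid = RetinalGrid()

    def test_empty_scene_is_no_action(self):
        lab = sm.label_scene(Scene(), self.grid)
        assert lab.is_no_action and (lab.azimuth, lab.elevation) == (0, 0)

    def test_reference_four_sphere_scene(self):
        # nearest sphere at (-40, 52, 3.7 cm) -> grid point (-39.2, 53.2)
        spheres = tuple(
            Sphere(a, e, d, sm.sphere_diameter_for_subtense(d, 10))
            for a, e, d in [(-40, 52, 3.7), (31, 4, 6.0), (-17, 0, 7.8), (29, -54, 9.0)]
        )
        lab = sm.label_scene(Scene(spheres), self.grid)
        assert lab.azimuth == pytest.approx(-39.2)
        assert lab.elevation == pytest.approx(53.2)
        assert not lab.is_no_action

    def test_invisible_near_sphere_defers_to_farther_visible_one(self):
        near_hidden = Sphere(100, 0, 2, sm.sphere_diameter_for_subtense(2, 10))
        far_seen = Sphere(10, 0, 9, sm.sphere_diameter_for_subtense(9, 10))
        # oracle: brute-force check that the near sphere is outside both eyes
        pose = HeadPose(interocular=1.0)
        for eye in (Eye.LEFT, Eye.RIGHT):
            proj = sm.project_to_retina(pose, eye, near_hidden.centre())
            assert abs(proj.azimuth) > self.grid.extent
        lab = sm.label_scene(Scene((near_hidden, far_seen)), self.grid)
        assert lab.azimuth == pytest.approx(11.2)  # nearest grid point to 10
        assert not lab.is_no_action

    def test_label_invariant_to_sphere_order(self, rng):
        for _ in range(10):
            scene = sm.sample_training_scene(rng)
            perm = Scene(tuple(reversed(scene.spheres)))
            assert sm.label_scene(scene, self.grid) == sm.label_scene(perm, self.grid)


def test_scene_csv_round_trip(tmp_path, rng):
    scenes = [sm.sample_training_scene(rng) for _ in range(5)]
    path = tmp_path / "scenes.csv"
    sm.scenes.write_scenes_csv(scenes, path)
    back = sm.scenes.read_scenes_csv(path)
    assert len(back) == len(scenes)
    for a, b in zip(scenes, back):
        for sa, sb in zip(a.spheres, b.spheres):
            assert sa.azimuth == pytest.approx(sb.azimuth)
            assert sa.diameter == pytest.approx(sb.diameter)
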