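"""Generator contracts: latent sampling, template geometry, allometric
measurements, rendering and dataset writing."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from morphopose.core import KEYPOINT_NAMES, MEASUREMENT_FIELDS, NAMED_PAIRS
from morphopose.synthetic import (
    ConfigurationError,
    FramingError,
    IndividualLatent,
    PopulationConfig,
    SceneSpec,
    ellipse_perimeter,
    generate_dataset,
    keypoints_from_latent,
    measurements_from_latent,
    render_scene,
    sample_individual,
)


class TestSampleIndividual:
    def test_same_seed_gives_identical_latents(self):
        assert sample_individual(0) == sample_individual(0)

    def test_positive_support_and_open_intervals(self):
        for seed in range(300):
            lat = sample_individual(seed)
            assert lat.size_scale > 0
            for f in ("chest_depth_frac", "cannon_width_frac", "girth_eccentricity"):
                assert 0 < getattr(lat, f) < 1

    def test_size_scale_mean_matches_configuration(self):
        cfg = PopulationConfig()
        vals = np.array([sample_individual(s).size_scale for s in range(1000)])
        se = cfg.size_scale_sd / np.sqrt(len(vals))
        assert abs(vals.mean() - cfg.size_scale_mean) < 3 * se

    def test_invalid_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_individual(0, PopulationConfig(size_scale_sd=-1.0))


class TestKeypointGeometry:
    def test_zero_jitter_height_point_above_ground_contact(self):
        kps = keypoints_from_latent(sample_individual(3), pose_jitter=0.0)
        assert kps.xy("body_height_top")[0] == pytest.approx(kps.xy("body_height_ground")[0])
        assert kps.xy("body_height_ground")[1] == 0.0

    def test_animal_faces_left(self):
        kps = keypoints_from_latent(sample_individual(3), pose_jitter=0.0)
        assert kps.xy("body_length_anterior")[0] < kps.xy("body_length_posterior")[0]

    def test_doubling_size_scale_doubles_every_pairwise_distance(self):
        lat = sample_individual(5)
        big = IndividualLatent(**{**vars(lat), "size_scale": 2 * lat.size_scale})
        k1 = keypoints_from_latent(lat, 0.0).as_array(with_visibility=False)
        k2 = keypoints_from_latent(big, 0.0).as_array(with_visibility=False)
        d1 = np.linalg.norm(k1[:, None] - k1[None], axis=-1)
        d2 = np.linalg.norm(k2[:, None] - k2[None], axis=-1)
        assert np.allclose(d2, 2 * d1)

    def test_body_length_equals_trunk_length_from_latent(self):
        lat = sample_individual(8)
        kps = keypoints_from_latent(lat, 0.0)
        assert kps.distance(*NAMED_PAIRS["body_length"]) == pytest.approx(
            lat.size_scale * lat.trunk_aspect
        )

    def test_jitter_is_deterministic_under_pose_seed(self):
        lat = sample_individual(9)
        a = keypoints_from_latent(lat, 0.02).as_array()
        b = keypoints_from_latent(lat, 0.02).as_array()
        assert np.array_equal(a, b)


class TestMeasurements:
    def test_height_is_definitional(self):
        lat = sample_individual(1)
        kps = keypoints_from_latent(lat, 0.0)
        rec = measurements_from_latent(lat, kps)
        assert rec.body_height == pytest.approx(100 * kps.distance(*NAMED_PAIRS["body_height"]))

    def test_circular_limit_of_chest_girth(self):
        lat = sample_individual(2)
        lat.girth_eccentricity = 1.0 - 1e-12
        kps = keypoints_from_latent(lat, 0.0)
        rec = measurements_from_latent(lat, kps)
        depth = kps.distance(*NAMED_PAIRS["chest_girth"])
        assert rec.chest_girth == pytest.approx(np.pi * depth * 100, rel=1e-6)

    def test_girth_matches_quadrature_perimeter(self):
        lat = sample_individual(4)
        kps = keypoints_from_latent(lat, 0.0)
        rec = measurements_from_latent(lat, kps)
        a = kps.distance(*NAMED_PAIRS["chest_girth"]) / 2
        b = lat.girth_eccentricity * a

        integrand = lambda t: np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
        perimeter, _ = quad(integrand, 0, 2 * np.pi)
        assert rec.chest_girth == pytest.approx(100 * perimeter, rel=1e-3)

    def test_record_invariants_hold_across_population(self):
        for seed in range(50):
            lat = sample_individual(seed)
            rec = measurements_from_latent(lat, keypoints_from_latent(lat, 0.0))
            assert rec.chest_girth > rec.cannon_circumference
            assert rec.oblique_body_length >= 0.8 * rec.body_length
            assert np.all(rec.as_array() > 0)

    def test_noise_resampling_cannot_go_negative(self, rng):
        lat = sample_individual(6)
        kps = keypoints_from_latent(lat, 0.0)
        rec = measurements_from_latent(lat, kps, noise_sd=1.0, rng=rng)
        assert np.all(rec.as_array() > 0)


class TestRenderScene:
    def scene(self, mirror=False):
        return SceneSpec(image_size=(320, 320), pixels_per_meter=100.0, origin_px=(60.0, 300.0), mirror=mirror)

    def test_pixel_metric_round_trip(self):
        sc = self.scene()
        pts = np.array([[0.3, 0.8], [1.1, 0.0], [0.0, 1.2]])
        assert np.allclose(sc.to_meters(sc.to_pixels(pts)), pts, atol=1e-9)

    def test_ruler_pixel_length_matches_scale(self):
        sc = self.scene()
        ends = sc.ruler_endpoints
        assert np.linalg.norm(ends[1] - ends[0]) == pytest.approx(110.0, abs=0.5)

    def test_same_seed_renders_identical_images(self):
        lat = sample_individual(11)
        kps = keypoints_from_latent(lat, 0.0)
        img1, _ = render_scene(lat, kps, self.scene(), rng_seed=5)
        img2, _ = render_scene(lat, kps, self.scene(), rng_seed=5)
        assert np.array_equal(img1, img2)

    def test_annotation_pixels_are_mapped_keypoints(self):
        lat = sample_individual(11)
        kps = keypoints_from_latent(lat, 0.0)
        sc = self.scene()
        _, ann = render_scene(lat, kps, sc, rng_seed=5)
        expected = sc.to_pixels(kps.as_array(with_visibility=False))
        assert np.allclose(ann.keypoints.as_array(with_visibility=False), expected)

    def test_out_of_frame_keypoint_raises_naming_it(self):
        lat = sample_individual(11)
        kps = keypoints_from_latent(lat, 0.0)
        bad = SceneSpec(image_size=(80, 80), pixels_per_meter=100.0, origin_px=(0.0, 79.0))
        with pytest.raises(FramingError, match="keypoint '\\w+' maps outside"):
            render_scene(lat, kps, bad)

    def test_keypoints_lie_on_or_near_silhouette(self):
        lat = sample_individual(13)
        kps = keypoints_from_latent(lat, 0.0)
        img, ann = render_scene(lat, kps, self.scene(), rng_seed=1)
        grey = img.mean(axis=-1)
        body = grey < 110  # coat is dark on a light background
        from scipy.ndimage import binary_dilation

        fat = binary_dilation(body, iterations=3)
        for name in KEYPOINT_NAMES:
            x, y, _ = ann.keypoints[name]
            assert fat[int(round(y)), int(round(x))], f"{name} not within 3 px of the silhouette"


class TestGenerateDataset:
    def test_image_count_is_individuals_times_views(self, small_dataset):
        root, manifest = small_dataset["root"], small_dataset["manifest"]
        assert len(manifest) == 6 * 2
        assert len(list((root / "images").glob("*.png"))) == 12

    def test_single_individual_manifest_matches_csv(self, tmp_path):
        manifest = generate_dataset(1, 1, tmp_path, seed=3)
        meas = pd.read_csv(tmp_path / "measurements.csv")
        assert len(manifest) == 1 and len(meas) == 1
        assert manifest.iloc[0]["individual_id"] == meas.iloc[0]["individual_id"]

    def test_regeneration_is_deterministic(self, tmp_path):
        m1 = generate_dataset(3, 2, tmp_path / "a", seed=9)
        m2 = generate_dataset(3, 2, tmp_path / "b", seed=9)
        c1 = pd.read_csv(tmp_path / "a" / "measurements.csv")
        c2 = pd.read_csv(tmp_path / "b" / "measurements.csv")
        pd.testing.assert_frame_equal(c1, c2)
        assert [p.split("/")[-1] for p in m1["image"]] == [p.split("/")[-1] for p in m2["image"]]

    def test_zero_noise_annotations_reproduce_measurements(self, clean_dataset):
        from morphopose.annotations import read_labelme
        from morphopose.morphometry import features_from_annotation

        meas = clean_dataset["measurements"]
        for _, row in clean_dataset["manifest"].iterrows():
            ann = read_labelme(row["annotation"])
            feats = features_from_annotation(ann, mode="named5")
            truth = meas.loc[row["individual_id"], list(MEASUREMENT_FIELDS)].to_numpy(dtype=float)
            # the three linear measures are direct keypoint distances
            assert np.all(np.abs(feats[:3] - truth[:3]) < 0.5)
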