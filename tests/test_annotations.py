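"""Annotation round trips, pose-label dialect, augmentation geometry,
ID-based splitting and training-set expansion."""

import json

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest

from morphopose.annotations import (
    AugmentPolicy,
    Letterbox,
    SplitError,
    augment,
    expand_training_set,
    parse_pose_label,
    read_labelme,
    split_by_individual,
    to_pose_label,
    write_labelme,
)
from morphopose.core import KEYPOINT_NAMES, AnnotatedImage, KeypointSet, SchemaError


class TestLabelmeIO:
    def test_generator_files_round_trip(self, small_dataset):
        row = small_dataset["manifest"].iloc[0]
        ann = read_labelme(row["annotation"])
        out = small_dataset["root"] / "rt.json"
        write_labelme(ann, out)
        ann2 = read_labelme(out)
        assert np.allclose(ann.keypoints.as_array(), ann2.keypoints.as_array())
        assert np.allclose(ann.ruler_endpoints, ann2.ruler_endpoints)
        assert ann.individual_id == ann2.individual_id

    def test_missing_keypoint_label_names_the_absent_one(self, small_dataset, tmp_path):
        row = small_dataset["manifest"].iloc[0]
        data = json.loads(open(row["annotation"]).read())
        data["shapes"] = [s for s in data["shapes"] if s["label"] != "chest_girth_lower"]
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(data))
        with pytest.raises(SchemaError, match="chest_girth_lower"):
            read_labelme(bad)

    def test_shuffled_shape_order_yields_canonical_ordering(self, small_dataset, tmp_path):
        row = small_dataset["manifest"].iloc[0]
        data = json.loads(open(row["annotation"]).read())
        rng = np.random.default_rng(1)
        data["shapes"] = [data["shapes"][i] for i in rng.permutation(len(data["shapes"]))]
        shuffled = tmp_path / "shuffled.json"
        shuffled.write_text(json.dumps(data))
        a, b = read_labelme(row["annotation"]), read_labelme(shuffled)
        assert list(a.keypoints.points) == list(KEYPOINT_NAMES)
        assert np.allclose(a.keypoints.as_array(), b.keypoints.as_array())


class TestPoseLabel:
    def test_center_keypoint_normalises_to_half(self):
        arr = np.full((10, 3), 2.0)
        arr[:, 0], arr[:, 1] = 320.0, 320.0
        ann = AnnotatedImage(
            image_path="x", image_size=(640, 640), keypoints=KeypointSet.from_array(arr),
            box=(160.0, 160.0, 480.0, 480.0), ruler_endpoints=[[0, 0], [110, 0]],
        )
        parts = to_pose_label(ann).split()
        assert float(parts[5]) == pytest.approx(0.5) and float(parts[6]) == pytest.approx(0.5)
        assert float(parts[3]) == pytest.approx(320 / 640) and float(parts[4]) == pytest.approx(320 / 640)

    def test_parse_inverts_format(self, small_dataset):
        ann = read_labelme(small_dataset["manifest"].iloc[1]["annotation"])
        box, kps = parse_pose_label(to_pose_label(ann), ann.image_size)
        assert np.allclose(box, ann.box, atol=1e-3)
        assert np.allclose(kps[:, :2], ann.keypoints.as_array()[:, :2], atol=1e-3)


class TestAugment:
    def _load(self, ds, i=0):
        row = ds["manifest"].iloc[i]
        return read_labelme(row["annotation"]), iio.imread(row["image"])

    def test_identity_policy_is_identity(self, small_dataset):
        ann, img = self._load(small_dataset)
        out_img, out_ann = augment(ann, img, AugmentPolicy.identity(), rng_seed=0)
        assert np.array_equal(out_img, img)
        assert np.allclose(out_ann.keypoints.as_array(), ann.keypoints.as_array())
        assert np.allclose(out_ann.ruler_endpoints, ann.ruler_endpoints)

    def test_flip_twice_restores_coordinates(self, small_dataset):
        ann, img = self._load(small_dataset)
        policy = AugmentPolicy(hflip_prob=1.0, scale_range=(1.0, 1.0), rotate_deg=0.0,
                               translate_frac=0.0, gauss_noise_sd=0.0)
        _, once = augment(ann, img, policy, rng_seed=0)
        _, twice = augment(once, img, policy, rng_seed=1)
        assert np.allclose(twice.keypoints.as_array()[:, :2], ann.keypoints.as_array()[:, :2], atol=1e-9)

    def test_single_affine_map_applies_to_all_geometry(self, small_dataset):
        """Recover the sampled affine from three keypoints and verify every
        other keypoint plus the ruler follows the same map exactly."""
        ann, img = self._load(small_dataset)
        policy = AugmentPolicy(hflip_prob=0.0, gauss_noise_sd=0.0)
        _, out = augment(ann, img, policy, rng_seed=3)
        src = ann.keypoints.as_array()[:, :2]
        dst = out.keypoints.as_array()[:, :2]
        A = np.column_stack([src[:3], np.ones(3)])
        coeff = np.linalg.solve(A, dst[:3])  # 3x2 affine coefficients
        mapped = np.column_stack([src, np.ones(len(src))]) @ coeff
        assert np.allclose(mapped, dst, atol=1e-6)
        ruler_mapped = np.column_stack([ann.ruler_endpoints, np.ones(2)]) @ coeff
        assert np.allclose(ruler_mapped, out.ruler_endpoints, atol=1e-6)

    def test_similarity_scales_distances_uniformly(self, small_dataset):
        ann, img = self._load(small_dataset)
        policy = AugmentPolicy(hflip_prob=0.0, gauss_noise_sd=0.0)
        _, out = augment(ann, img, policy, rng_seed=11)
        src = ann.keypoints.as_array()[:, :2]
        dst = out.keypoints.as_array()[:, :2]
        d_src = np.linalg.norm(src[0] - src[1:], axis=1)
        d_dst = np.linalg.norm(dst[0] - dst[1:], axis=1)
        ratios = d_dst / d_src
        assert ratios.std() < 1e-6  # one global scale factor
        ruler_ratio = np.linalg.norm(out.ruler_endpoints[1] - out.ruler_endpoints[0]) / np.linalg.norm(
            ann.ruler_endpoints[1] - ann.ruler_endpoints[0]
        )
        assert ruler_ratio == pytest.approx(ratios.mean(), abs=1e-6)

    def test_pixels_move_with_the_declared_map(self, small_dataset):
        """A bright blob painted at a keypoint lands at the transformed
        keypoint after augmentation (pixels and points share one map)."""
        ann, img = self._load(small_dataset)
        img = np.zeros_like(img)
        x, y, _ = ann.keypoints["chest_girth_upper"]
        img[int(y) - 2 : int(y) + 3, int(x) - 2 : int(x) + 3] = 255
        policy = AugmentPolicy(hflip_prob=0.0, gauss_noise_sd=0.0, rotate_deg=10.0)
        out_img, out_ann = augment(ann, img, policy, rng_seed=4)
        ys, xs = np.nonzero(out_img[..., 0] > 100)
        cx, cy = xs.mean(), ys.mean()
        tx, ty, _ = out_ann.keypoints["chest_girth_upper"]
        assert np.hypot(cx - tx, cy - ty) < 1.5


class TestSplit:
    def test_study_scale_split_sizes(self):
        ids = [f"anm{i}" for i in range(111)]
        split = split_by_individual(ids, ratios=(7, 2, 1), seed=0)
        assert (len(split["train"]), len(split["val"]), len(split["test"])) == (78, 22, 11)

    def test_split_is_a_partition(self):
        ids = [f"a{i}" for i in range(37)] * 3  # repeated image-level ids
        split = split_by_individual(ids, seed=5)
        all_ids = split["train"] + split["val"] + split["test"]
        assert sorted(all_ids) == sorted(set(ids))

    def test_same_seed_identical_different_seeds_differ(self):
        ids = [f"a{i}" for i in range(40)]
        first = split_by_individual(ids, seed=1)
        assert first == split_by_individual(ids, seed=1)
        assert any(split_by_individual(ids, seed=s) != first for s in range(2, 7))

    def test_too_few_individuals_rejected(self):
        with pytest.raises(SplitError):
            split_by_individual(["a", "b"])


class TestExpand:
    def test_multiplicity_zero_is_identity(self, small_dataset, tmp_path):
        man = small_dataset["manifest"].iloc[:2]
        out = expand_training_set(man, AugmentPolicy(multiplicity=0), tmp_path, seed=0)
        assert len(out) == 2 and (out["augmented"] == 0).all()

    def test_output_count_and_revalidation(self, small_dataset, tmp_path):
        man = small_dataset["manifest"].iloc[:3]
        out = expand_training_set(man, AugmentPolicy(multiplicity=3), tmp_path, seed=0)
        assert len(out) == 3 * (1 + 3)
        for _, row in out[out["augmented"] == 1].iterrows():
            ann = read_labelme(row["annotation"])  # must re-validate
            assert "_aug" in row["image"]
            assert ann.ruler_length_m == pytest.approx(1.1)


class TestLetterbox:
    def test_round_trip_within_half_pixel(self):
        lb = Letterbox((320, 448), 160)
        pts = np.array([[10.0, 20.0], [440.0, 300.0], [224.0, 160.0]])
        assert np.allclose(lb.to_original(lb.to_input(pts)), pts, atol=0.5)

    def test_resize_preserves_aspect_with_padding(self):
        lb = Letterbox((240, 320), 160)
        img = np.full((240, 320, 3), 200, dtype=np.uint8)
        out = lb.apply(img)
        assert out.shape[:2] == (160, 160)
        assert (out[0] == 114).all() and (out[-1] == 114).all()  # grey pad rows
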