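"""Augmentation geometry, corpus bookkeeping, split stratification/leakage,
synthetic-generator determinism and manifest round-trips."""

import numpy as np
import pytest
from PIL import Image

from julite.datapipe import (CLASSES, AugmentConfig, FolderDataset, ImageRecord,
                             SyntheticConfig, apply_params, augment_corpus,
                             eval_transform, generate_dataset,
                             generate_synthetic_image, identity_params,
                             load_manifest, random_occlusion, split_dataset,
                             train_transform)


def _img(size=96, seed=0):
    return generate_synthetic_image("normal", seed,
                                    SyntheticConfig(image_size=size, n_per_class=1))


class TestTrainTransform:
    def test_output_is_standard_shape_and_finite(self, rng):
        out = train_transform(_img(), rng)
        assert out.shape == (3, 224, 224)
        assert np.isfinite(out).all()

    def test_identity_draws_reduce_to_plain_resize(self):
        img = _img()
        cfg = AugmentConfig()
        out = apply_params(img, identity_params(), cfg)
        ref = np.asarray(img.resize((224, 224), Image.BICUBIC), dtype=np.float64) / 255.0
        ref = ((ref - 0.5) / 0.25).transpose(2, 0, 1)
        assert np.allclose(out, ref)

    def test_fixed_seed_is_reproducible(self):
        img = _img()
        a = train_transform(img, np.random.default_rng(99))
        b = train_transform(img, np.random.default_rng(99))
        assert np.array_equal(a, b)

    def test_rejects_non_rgb_and_tiny_inputs(self, rng):
        with pytest.raises(ValueError):
            train_transform(Image.new("L", (128, 128)), rng)
        with pytest.raises(ValueError):
            train_transform(Image.new("RGB", (32, 32)), rng)


class TestEvalTransform:
    def test_center_crop_geometry(self):
        arr = np.zeros((256, 256, 3), np.uint8)
        arr[16:240, 16:240] = 255
        out = eval_transform(Image.fromarray(arr))
        # central 224x224 of a 256x256 input is retained unchanged
        ref = (arr[16:240, 16:240] / 255.0 - 0.5) / 0.25
        assert np.allclose(out, ref.transpose(2, 0, 1))

    def test_deterministic(self):
        img = _img(300)
        assert np.array_equal(eval_transform(img), eval_transform(img))

    def test_large_input_equals_composed_resize(self):
        img = _img(448)
        direct = eval_transform(img)
        composed = eval_transform(img.resize((256, 256), Image.BICUBIC))
        assert np.allclose(direct, composed, atol=1e-12)


class TestOcclusion:
    def test_minimum_area_pixel_count(self):
        class MinRng:
            def uniform(self, a, b=None):
                return a
            def integers(self, a, b):
                return a

        out = random_occlusion(np.zeros((100, 100, 3), np.uint8), MinRng(),
                               area_range=(0.02, 0.20))
        n_occ = int((out == 128).all(axis=2).sum())
        assert abs(n_occ - 200) <= 30  # rectangle quantization

    def test_fill_value_and_outside_unchanged(self, rng):
        base = np.full((60, 80, 3), 7, np.uint8)
        out = random_occlusion(base, rng)
        occluded = (out == 128).all(axis=2)
        assert occluded.any()
        assert (out[~occluded] == 7).all()
        assert (base == 7).all()  # input untouched

    def test_rejects_degenerate_images(self, rng):
        with pytest.raises(ValueError):
            random_occlusion(np.zeros((5, 5, 3), np.uint8), rng)


class TestCorpusBookkeeping:
    def _records(self, n_per_class):
        return [ImageRecord(f"{c}/{c}_{i}.png", c, base_id=f"{c}/{c}_{i}.png")
                for c in CLASSES for i in range(n_per_class)]

    def test_expansion_to_printed_total(self):
        out = augment_corpus(self._records(2000), 4)
        assert len(out) == 48000
        per_class = {c: sum(r.label == c for r in out) for c in CLASSES}
        assert all(v == 8000 for v in per_class.values())

    def test_multiplicity_one_is_identity_count(self):
        recs = self._records(3)
        assert len(augment_corpus(recs, 1)) == len(recs)

    def test_split_reproduces_printed_counts(self):
        out = augment_corpus(self._records(2000), 4)
        tr, te, va = split_dataset(out, (0.7, 0.2, 0.1), seed=0)
        assert (len(tr), len(te), len(va)) == (33600, 9600, 4800)

    def test_split_small_per_class_rounding(self):
        tr, te, va = split_dataset(self._records(10), (0.7, 0.2, 0.1), seed=1)
        for c in CLASSES:
            assert sum(r.label == c for r in tr) == 7
            assert sum(r.label == c for r in te) == 2
            assert sum(r.label == c for r in va) == 1

    def test_split_is_partition_with_no_leakage(self):
        out = augment_corpus(self._records(30), 4)
        tr, te, va = split_dataset(out, (0.7, 0.2, 0.1), seed=3)
        assert len(tr) + len(te) + len(va) == len(out)
        ids = lambda xs: {(r.base_id, r.seed) for r in xs}
        assert not ids(tr) & ids(te) and not ids(tr) & ids(va) and not ids(te) & ids(va)
        bases = lambda xs: {r.base_id for r in xs}
        assert not bases(tr) & bases(te) and not bases(tr) & bases(va)

    def test_split_deterministic_in_seed(self):
        recs = self._records(20)
        a = split_dataset(recs, seed=5)
        b = split_dataset(recs, seed=5)
        assert [r.path for r in a[0]] == [r.path for r in b[0]]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._records(4), (0.5, 0.2, 0.1))


class TestSyntheticGenerator:
    def test_pure_function_of_inputs(self):
        cfg = SyntheticConfig(image_size=64, n_per_class=1)
        a = generate_synthetic_image("cracked", 7, cfg)
        b = generate_synthetic_image("cracked", 7, cfg)
        assert a.tobytes() == b.tobytes()

    def test_label_only_changes_defect_region(self):
        cfg = SyntheticConfig(image_size=96, n_per_class=1)
        normal = np.asarray(generate_synthetic_image("normal", 5, cfg))
        cracked = np.asarray(generate_synthetic_image("cracked", 5, cfg))
        assert (normal != cracked).any()
        # background corners (outside the fruit) are byte-identical
        for sl in (np.s_[:10, :10], np.s_[:10, -10:], np.s_[-10:, :10], np.s_[-10:, -10:]):
            assert np.array_equal(normal[sl], cracked[sl])

    def test_all_classes_render_distinctly(self):
        cfg = SyntheticConfig(image_size=64, n_per_class=1)
        imgs = {c: np.asarray(generate_synthetic_image(c, 3, cfg)) for c in CLASSES}
        keys = list(CLASSES)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                assert (imgs[a] != imgs[b]).any()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_image("bruised", 0, SyntheticConfig(image_size=64,
                                                                   n_per_class=1))


class TestDatasetFolder:
    def test_counts_and_manifest_round_trip(self, tiny_dataset):
        root, manifest, cfg = tiny_dataset
        records, mean, std = load_manifest(manifest)
        assert len(records) == 6 * cfg.n_per_class
        assert len(list(root.rglob("*.png"))) == 6 * cfg.n_per_class
        assert len(mean) == 3 and len(std) == 3
        assert all(0 < m < 1 for m in mean) and all(s > 0 for s in std)
        labels = {r.label for r in records}
        assert labels == set(CLASSES)

    def test_regeneration_is_identical(self, tiny_dataset, tmp_path):
        root, manifest, cfg = tiny_dataset
        manifest2 = generate_dataset(cfg, tmp_path)
        assert manifest.read_text() == manifest2.read_text()

    def test_folder_dataset_static_expansion_and_determinism(self, tiny_dataset, aug64):
        root, _, _ = tiny_dataset
        ds = FolderDataset(root, "train", augment=aug64, train=True)
        base = FolderDataset(root, "train", augment=aug64)
        assert len(ds) == aug64.multiplicity * len(base)
        x1, y1 = ds.get(0)
        x2, y2 = ds.get(0)
        assert np.array_equal(x1, x2) and y1 == y2
        assert x1.shape == (3, 64, 64)
        # original and its augmented variants share the label, differ in pixels
        xa, ya = ds.get(1)
        assert ya == y1 and not np.array_equal(x1, xa)
        # a fresh dataset object reproduces the same variant arrays
        ds2 = FolderDataset(root, "train", augment=aug64, train=True)
        xb, _ = ds2.get(1)
        assert np.array_equal(xa, xb)
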