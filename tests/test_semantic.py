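import numpy as np
import pytest

from nucseg.semantic import (
    CLASS_NAMES,
    ClassifierConfig,
    PatchClassifier,
    augment,
    class_to_semantic,
    extract_patches,
    mask_adaptive,
    mask_from_semantic,
    mask_otsu,
    predict_semantic_map,
    semantic_to_class,
    train_classifier,
)

# ---------------------------------------------------------------- fixtures


def _separable_patches(rng, n_per_class, size=17):
    """4 classes with disjoint mean intensities — trivially separable."""
    xs, ys = [], []
    for cls, mu in enumerate((0.0, 3.0, 6.0, 9.0)):
        xs.append(rng.normal(mu, 0.5, size=(n_per_class, size, size)))
        ys.append(np.full(n_per_class, cls))
    x = np.concatenate(xs).astype(np.float32)
    x = (x - 4.5) / 3.4  # patches reach the classifier standardized
    y = np.concatenate(ys)
    order = rng.permutation(len(y))
    return x[order], y[order]


TINY_CFG = ClassifierConfig(
    patch_size=17, conv_channels=(4, 4, 8, 8), dense_units=32,
    learning_rate=0.05, momentum=0.9, batch_size=64, epochs=8,
    dropout=0.1, seed=0,
)


@pytest.fixture(scope="module")
def trained_tiny():
    rng = np.random.default_rng(0)
    tx, ty = _separable_patches(rng, 120)
    vx, vy = _separable_patches(rng, 40)
    model, history = train_classifier(tx, ty, vx, vy, TINY_CFG)
    return model, history


# ------------------------------------------------------------ extraction


class TestExtractPatches:
    def test_count_forced(self):
        stain = np.zeros((20, 20), dtype=np.float32)
        ref = np.full((20, 20), 3, dtype=np.uint8)  # all nucleus
        patches, labels, _ = extract_patches(stain, ref, size=5)
        assert len(patches) == 400
        assert (labels == 0).all()  # class index for nucleus

    def test_indeterminate_excluded(self):
        stain = np.zeros((10, 10), dtype=np.float32)
        ref = np.full((10, 10), 1, dtype=np.uint8)
        ref[4, 4] = 0  # indeterminate
        patches, labels, pos = extract_patches(stain, ref, size=5)
        assert len(patches) == 99
        assert not ((pos[:, 0] == 4) & (pos[:, 1] == 4)).any()

    def test_corner_patch_shape_via_reflection(self):
        stain = np.arange(100, dtype=np.float32).reshape(10, 10)
        ref = np.full((10, 10), 2, dtype=np.uint8)
        patches, _, pos = extract_patches(stain, ref, size=7)
        assert patches.shape == (100, 7, 7)
        corner = patches[0]  # pixel (0, 0)
        assert corner[3, 3] == stain[0, 0]  # center = source pixel
        assert corner[2, 3] == stain[1, 0]  # reflected row

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_patches(np.zeros((5, 5)), size=4)

    def test_misaligned_reference(self):
        with pytest.raises(ValueError, match="align"):
            extract_patches(np.zeros((5, 5)), np.zeros((6, 6), dtype=np.uint8))


class TestPaletteMapping:
    def test_roundtrip(self):
        classes = np.array([[0, 1], [2, 3]])
        assert np.array_equal(semantic_to_class(class_to_semantic(classes)),
                              classes)

    def test_indeterminate_maps_to_minus_one(self):
        assert semantic_to_class(np.array([[0]]))[0, 0] == -1


# ------------------------------------------------------------ augmentation


class TestAugment:
    def test_border_class_multiplied(self, rng):
        patches = rng.normal(size=(40, 9, 9)).astype(np.float32)
        labels = np.array([1] * 10 + [0] * 10 + [2] * 10 + [3] * 10)
        out_p, out_l = augment(patches, labels, factor=4, rng_seed=0)
        assert (out_l == 1).sum() == 40
        for cls in (0, 2, 3):
            assert (out_l == cls).sum() == 10
        assert out_p.shape[1:] == (9, 9)

    def test_factor_one_identity(self, rng):
        patches = rng.normal(size=(8, 9, 9)).astype(np.float32)
        labels = np.array([1, 0, 2, 3, 1, 0, 2, 3])
        out_p, out_l = augment(patches, labels, factor=1, rng_seed=0)
        assert np.array_equal(out_p, patches)
        assert np.array_equal(out_l, labels)

    def test_deterministic(self, rng):
        patches = rng.normal(size=(12, 9, 9)).astype(np.float32)
        labels = np.array([1, 1, 0, 0, 2, 2, 3, 3, 1, 0, 2, 3])
        a = augment(patches, labels, factor=3, rng_seed=42)
        b = augment(patches, labels, factor=3, rng_seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_labels_never_change(self, rng):
        patches = rng.normal(size=(20, 9, 9)).astype(np.float32)
        labels = rng.integers(0, 4, 20)
        _, out_l = augment(patches, labels, factor=2, rng_seed=1)
        assert np.array_equal(out_l[:20], labels)
        assert (out_l[20:] == 1).all()

    def test_empty_border_class_warns_noop(self, rng):
        patches = rng.normal(size=(6, 9, 9)).astype(np.float32)
        labels = np.array([0, 0, 2, 2, 3, 3])
        with pytest.warns(UserWarning, match="border"):
            out_p, out_l = augment(patches, labels, factor=4, rng_seed=0)
        assert np.array_equal(out_p, patches)

    def test_bad_factor(self, rng):
        with pytest.raises(ValueError, match="factor"):
            augment(np.zeros((2, 9, 9)), np.array([1, 1]), factor=0)


# -------------------------------------------------------------- training


class TestTraining:
    def test_separable_data_high_accuracy(self, trained_tiny):
        _, history = trained_tiny
        assert history.val_accuracy[-1] >= 0.95

    def test_beats_chance_by_3x(self, trained_tiny):
        _, history = trained_tiny
        assert history.val_accuracy[-1] >= 0.75

    def test_missing_class_error(self, rng):
        tx, ty = _separable_patches(rng, 20)
        keep = ty != 2
        with pytest.raises(ValueError, match="cytoplasm"):
            train_classifier(tx[keep], ty[keep], tx, ty, TINY_CFG)

    def test_determinism_same_seed(self, rng):
        tx, ty = _separable_patches(rng, 30)
        cfg = ClassifierConfig(patch_size=17, conv_channels=(2, 2, 4, 4),
                               dense_units=16, epochs=1, batch_size=32,
                               learning_rate=0.01, seed=7)
        m1, h1 = train_classifier(tx, ty, tx, ty, cfg)
        m2, h2 = train_classifier(tx, ty, tx, ty, cfg)
        assert h1.train_loss[0] == h2.train_loss[0]  # bitwise-identical
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_zero_epochs_chance_level(self, rng):
        tx, ty = _separable_patches(rng, 50)
        cfg = ClassifierConfig(patch_size=17, conv_channels=(2, 2, 4, 4),
                               dense_units=16, epochs=0, seed=0)
        with pytest.warns(UserWarning, match="untrained"):
            model, history = train_classifier(tx, ty, tx, ty, cfg)
        probs = model.predict_proba(tx)
        acc = (probs.argmax(axis=1) == ty).mean()
        assert 0.05 < acc < 0.55  # near chance on a balanced set

    def test_empty_sets_rejected(self, rng):
        tx, ty = _separable_patches(rng, 5)
        with pytest.raises(ValueError, match="non-empty"):
            train_classifier(tx[:0], ty[:0], tx, ty, TINY_CFG)


class TestModelSerialization:
    def test_save_load_roundtrip(self, trained_tiny, tmp_path):
        model, _ = trained_tiny
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = PatchClassifier.load(path)
        assert loaded.config == model.config
        x = np.random.default_rng(0).normal(size=(10, 17, 17)).astype(np.float32)
        assert np.array_equal(model.predict_proba(x), loaded.predict_proba(x))

    def test_stats_preserved(self, tmp_path, rng):
        from nucseg.stains import fit_position_stats

        cfg = ClassifierConfig(patch_size=9, conv_channels=(2, 2),
                               pool_after=(0,), dense_units=8, epochs=0, seed=0)
        model = PatchClassifier(cfg)
        stats = fit_position_stats(rng.normal(2, 3, size=(30, 9, 9)))
        model.set_stats(stats.mean, stats.std)
        path = tmp_path / "m.npz"
        model.save(path)
        loaded = PatchClassifier.load(path)
        assert np.allclose(loaded.stats_mean, stats.mean)


# ------------------------------------------------------------- prediction


class TestPrediction:
    def test_probability_rows_sum_to_one(self, trained_tiny, rng):
        model, _ = trained_tiny
        stain = rng.normal(3, 3, size=(20, 20)).astype(np.float32)
        smap, probs = predict_semantic_map(model, stain)
        assert probs.shape == (20, 20, 4)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert smap.shape == (20, 20)
        assert set(np.unique(smap)) <= {1, 2, 3, 4}  # never indeterminate

    def test_argmax_and_tie_break(self):
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        assert CLASS_NAMES[probs.argmax()] == "nucleus"
        tie = np.array([0.25, 0.25, 0.25, 0.25])
        assert CLASS_NAMES[tie.argmax()] == "nucleus"  # first in fixed order

    def test_patch_size_mismatch(self, trained_tiny):
        model, _ = trained_tiny
        with pytest.raises(ValueError, match="patch size"):
            model.predict_proba(np.zeros((3, 9, 9), dtype=np.float32))


# ------------------------------------------------------------ mask backends


class TestMasks:
    def test_mask_from_semantic_all_background(self):
        smap = np.full((10, 10), 1, dtype=np.uint8)
        assert not mask_from_semantic(smap).any()

    def test_border_excluded(self):
        smap = np.full((9, 9), 1, dtype=np.uint8)
        smap[2:7, 2:7] = 4  # border ring
        smap[3:6, 3:6] = 3  # interior
        mask = mask_from_semantic(smap)
        assert mask.sum() == 9
        assert mask_from_semantic(smap, include_border=True).sum() == 25

    def test_border_line_splits_components(self):
        from nucseg.morphometrics import label_components

        smap = np.full((9, 17), 1, dtype=np.uint8)
        smap[2:7, 2:15] = 3
        smap[:, 8] = 4  # 1-px border line
        assert label_components(mask_from_semantic(smap)).max() == 2

    def test_otsu_bimodal(self, rng):
        img = np.concatenate([np.full(500, 0.1), np.full(500, 0.9)])
        img = img.reshape(20, 50) + rng.normal(0, 0.01, (20, 50))
        mask = mask_otsu(img)
        assert mask.sum() == pytest.approx(500, abs=5)

    def test_otsu_constant_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = mask_otsu(np.full((10, 10), 0.5))
        assert not mask.any()

    def test_otsu_merges_what_border_separates(self, small_scene,
                                               small_scene_hematoxylin):
        from nucseg.morphometrics import label_components

        n_interior = label_components(small_scene.interior_mask).max()
        n_otsu = label_components(mask_otsu(small_scene_hematoxylin)).max()
        assert n_otsu <= n_interior

    def test_adaptive_detects_local_objects(self, rng):
        # threshold = local mean - offset, so a negative offset raises it
        # above the background noise floor
        img = rng.normal(0, 0.01, (60, 60))
        img[20:30, 20:30] += 1.0
        mask = mask_adaptive(img, window=21, offset=-0.1)
        assert mask[22:28, 22:28].all()
        assert mask.mean() < 0.2

    def test_adaptive_window_validation(self):
        with pytest.raises(ValueError, match="window"):
            mask_adaptive(np.zeros((5, 5)), window=4)

    def test_nonfinite_rejected(self):
        bad = np.full((5, 5), np.nan)
        with pytest.raises(ValueError, match="finite"):
            mask_otsu(bad)
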