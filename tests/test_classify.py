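"""Pixel-classifier contracts: separability, determinism, normalization,
split-oracle agreement, serialization."""

import numpy as np
import pytest

import debriscope as dsc
from debriscope.classify import Scribbles, TrainingError, train_classifier
from debriscope.features import FeatureStack


def _two_class_image(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full((40, 40), 0.2)
    img[:, 20:] = 0.8
    img = img + noise * rng.normal(size=img.shape)
    scr = Scribbles(
        regions={
            "particle": [(np.repeat(np.arange(5, 15), 5), np.tile(np.arange(25, 30), 10))],
            "membrane": [(np.repeat(np.arange(5, 15), 5), np.tile(np.arange(5, 10), 10))],
        },
        image_shape=img.shape,
    )
    return img, scr


def test_linearly_separable_two_class_is_perfect():
    img, scr = _two_class_image()
    feats = dsc.compute_features(img, scales=(1,))
    clf = train_classifier(feats, scr, n_trees=25, seed=0, classes=("particle", "membrane"))
    pred = dsc.classify(img, clf, features=feats).argmax_names()
    # held out: every off-scribble pixel away from the boundary
    assert (pred[:, :18] == "membrane").all()
    assert (pred[:, 22:] == "particle").all()


def test_missing_class_raises_naming_it():
    img, scr = _two_class_image()
    feats = dsc.compute_features(img, scales=(1,))
    with pytest.raises(TrainingError, match="residue"):
        train_classifier(feats, scr, classes=("particle", "membrane", "residue"))


def test_probabilities_normalized_and_deterministic(default_scene, trained_classifier):
    clf, feats, _ = trained_classifier
    prob = dsc.classify(default_scene.dic_image, clf, features=feats)
    sums = prob.maps.sum(axis=0)
    assert prob.maps.min() >= 0
    assert np.allclose(sums, 1.0, atol=1e-6)
    prob2 = dsc.classify(default_scene.dic_image, clf, features=feats)
    assert np.array_equal(prob.maps, prob2.maps)


def test_training_image_scribbles_reproduced(default_scene, trained_classifier):
    clf, feats, scribbles = trained_classifier
    pred = dsc.classify(default_scene.dic_image, clf, features=feats).argmax_names()
    rows, cols, labels = scribbles.flatten()
    agreement = (pred[rows, cols] == labels.astype(str)).mean()
    assert agreement >= 0.99


def test_same_seed_identical_ensembles(default_scene):
    feats = dsc.compute_features(default_scene.dic_image.data, scales=(1, 2))
    scr = dsc.sample_scribbles(default_scene.class_map, seed=3)
    a = train_classifier(feats, scr, n_trees=20, seed=9)
    b = train_classifier(feats, scr, n_trees=20, seed=9)
    pa = dsc.classify(default_scene.dic_image, a, features=feats).maps
    pb = dsc.classify(default_scene.dic_image, b, features=feats).maps
    assert np.array_equal(pa, pb)


def test_feature_mismatch_rejected(default_scene, trained_classifier):
    clf, _, _ = trained_classifier
    wrong = dsc.compute_features(default_scene.dic_image.data, scales=(1,))
    with pytest.raises(ValueError, match="feature configuration"):
        dsc.classify(default_scene.dic_image, clf, features=wrong)


def test_modality_mismatch_rejected(default_scene, trained_classifier):
    clf, _, _ = trained_classifier
    with pytest.raises(ValueError, match="trained on"):
        dsc.classify(default_scene.fluo_image, clf)


def test_single_tree_matches_exhaustive_best_split_oracle():
    """A depth-1 tree's decision regions equal the brute-force Gini-optimal
    axis-aligned split on a 2-feature, 2-class problem."""
    rng = np.random.default_rng(42)
    n = 150
    X = rng.uniform(0, 1, size=(n, 2))
    y = np.where(X[:, 0] + 0.3 * rng.normal(size=n) > 0.5, "particle", "membrane")
    feats = FeatureStack(X.T.reshape(2, 1, n), ("f0", "f1"), (1.0,))
    regions = {
        "particle": [(np.zeros((y == "particle").sum(), int), np.nonzero(y == "particle")[0])],
        "membrane": [(np.zeros((y == "membrane").sum(), int), np.nonzero(y == "membrane")[0])],
    }
    scr = Scribbles(regions, (1, n))
    clf = train_classifier(
        feats, scr, n_trees=1, seed=0, classes=("particle", "membrane"),
        max_depth=1, max_features=None, bootstrap=False,
    )

    # exhaustive oracle: best Gini split over all midpoints of both features
    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.mean(labels == "particle")
        return 1 - p * p - (1 - p) ** 2

    best = (np.inf, None, None)
    for j in range(2):
        vs = np.sort(np.unique(X[:, j]))
        for t in (vs[1:] + vs[:-1]) / 2:
            left, right = y[X[:, j] <= t], y[X[:, j] > t]
            imp = len(left) / n * gini(left) + len(right) / n * gini(right)
            if imp < best[0] - 1e-12:
                best = (imp, j, t)
    _, j, t = best

    def oracle_predict(pts):
        left_major = "particle" if np.mean(y[X[:, j] <= t] == "particle") > 0.5 else "membrane"
        right_major = "particle" if np.mean(y[X[:, j] > t] == "particle") > 0.5 else "membrane"
        return np.where(pts[:, j] <= t, left_major, right_major)

    grid = rng.uniform(0, 1, size=(500, 2))
    pred = clf.estimator.predict(grid)
    assert (pred == oracle_predict(grid)).all()


def test_debris_free_scene_has_low_particle_fraction(trained_classifier):
    clf, _, _ = trained_classifier
    bg = dsc.generate_scene(dsc.SceneSpec(n_particles=0, n_fibers=0, seed=11))
    pred = dsc.classify(bg.dic_image, clf).argmax_map()
    assert (pred == dsc.CLASS_NAMES.index("particle")).mean() <= 0.01


def test_save_load_roundtrip(tmp_path, default_scene, trained_classifier):
    clf, feats, _ = trained_classifier
    path = tmp_path / "clf.joblib"
    dsc.save_classifier(clf, path)
    clf2 = dsc.load_classifier(path)
    assert clf2.classes == clf.classes
    assert clf2.feature_names == clf.feature_names
    p1 = dsc.classify(default_scene.dic_image, clf, features=feats).maps
    p2 = dsc.classify(default_scene.dic_image, clf2, features=feats).maps
    assert np.array_equal(p1, p2)
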