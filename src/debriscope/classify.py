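"""Trainable per-pixel classification of membrane micrographs.

A random forest is trained from a handful of scribbled example regions of
five classes — particle (debris), slot, residue, membrane, edge — and then
applied to every image of a sample, emitting one probability map per class.
The forest defaults to 200 trees; tree hyperparameters follow common
random-forest practice (unlimited depth, √n_features per split, bootstrap)
and are recorded in the classifier metadata so results are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import scipy.ndimage as ndi
from sklearn.ensemble import RandomForestClassifier

from .features import DEFAULT_SCALES, FeatureStack, compute_features
from .specs import CLASS_NAMES, Micrograph

__all__ = [
    "Scribbles",
    "TrainedClassifier",
    "ProbabilityStack",
    "sample_scribbles",
    "train_classifier",
    "classify",
    "save_classifier",
    "load_classifier",
    "TrainingError",
]


class TrainingError(ValueError):
    """Raised when the scribble set cannot train the requested classes."""


@dataclass
class Scribbles:
    """Labeled example regions: ``regions`` maps class name -> list of
    ``(rows, cols)`` coordinate arrays inside the source image."""

    regions: Dict[str, List[Tuple[np.ndarray, np.ndarray]]]
    image_shape: Tuple[int, int]
    source: str = ""

    def counts(self) -> Dict[str, int]:
        return {c: int(sum(r.size for r, _ in regs)) for c, regs in self.regions.items()}

    def flatten(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All scribbled pixels as (rows, cols, labels)."""
        rows, cols, labels = [], [], []
        for cls, regs in self.regions.items():
            for r, c in regs:
                rows.append(np.asarray(r))
                cols.append(np.asarray(c))
                labels.append(np.full(len(r), cls, dtype=object))
        if not rows:
            return np.empty(0, int), np.empty(0, int), np.empty(0, object)
        return np.concatenate(rows), np.concatenate(cols), np.concatenate(labels)

    def validate(self, classes: Sequence[str] = CLASS_NAMES) -> None:
        h, w = self.image_shape
        for cls in classes:
            regs = self.regions.get(cls, [])
            if not regs:
                raise TrainingError(f"class {cls!r} has no scribbled region")
            for r, c in regs:
                r, c = np.asarray(r), np.asarray(c)
                if r.size == 0:
                    raise TrainingError(f"class {cls!r} has an empty region")
                if (r < 0).any() or (r >= h).any() or (c < 0).any() or (c >= w).any():
                    raise TrainingError(f"class {cls!r} has coordinates outside the image")


def sample_scribbles(
    class_map: np.ndarray,
    classes: Sequence[str] = CLASS_NAMES,
    n_regions: int = 8,
    stroke_length: int = 60,
    seed: int = 0,
) -> Scribbles:
    """Draw stroke-like example regions from a ground-truth class map.

    Emulates the few manually scribbled training examples per class: for
    each class, ``n_regions`` strokes start at a random in-class pixel,
    walk in a random direction until they leave the class (or reach
    ``stroke_length``), and are thickened by one pixel within the class.
    Because strokes are clipped at the class boundary rather than kept in
    eroded interiors, they sample near-boundary context the way a human
    scribble does.
    """
    rng = np.random.default_rng(seed)
    regions: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    h, w = class_map.shape
    for code, cls in enumerate(CLASS_NAMES):
        if cls not in classes:
            continue
        mask = class_map == code
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise TrainingError(f"class {cls!r} absent from class map")
        regs = []
        for _ in range(n_regions):
            idx = int(rng.integers(0, rows.size))
            r, c = float(rows[idx]), float(cols[idx])
            ang = rng.uniform(0.0, 2 * np.pi)
            dr, dc = np.sin(ang), np.cos(ang)
            pts = set()
            for _step in range(stroke_length):
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < h and 0 <= ci < w) or not mask[ri, ci]:
                    break
                pts.add((ri, ci))
                r += dr
                c += dc
            if not pts:
                pts = {(int(rows[idx]), int(cols[idx]))}
            # thicken by one pixel, staying in class
            thick = set(pts)
            for ri, ci in pts:
                for ar in (ri - 1, ri, ri + 1):
                    for ac in (ci - 1, ci, ci + 1):
                        if 0 <= ar < h and 0 <= ac < w and mask[ar, ac]:
                            thick.add((ar, ac))
            arr = np.array(sorted(thick))
            regs.append((arr[:, 0], arr[:, 1]))
        regions[cls] = regs
    return Scribbles(regions=regions, image_shape=class_map.shape, source="class_map")


@dataclass
class TrainedClassifier:
    """Fitted forest plus the metadata needed to reapply it faithfully."""

    estimator: RandomForestClassifier
    classes: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    scales: Tuple[float, ...]
    n_trees: int
    seed: int
    modality: str = "brightfield_dic"

    def metadata(self) -> dict:
        return {
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "scales": list(self.scales),
            "n_trees": self.n_trees,
            "seed": self.seed,
            "modality": self.modality,
            "max_depth": self.estimator.max_depth,
            "max_features": self.estimator.max_features,
            "bootstrap": self.estimator.bootstrap,
        }


@dataclass
class ProbabilityStack:
    """One probability map per class; per pixel the maps sum to 1."""

    maps: np.ndarray  # (n_classes, H, W)
    classes: Tuple[str, ...]

    def __getitem__(self, cls: str) -> np.ndarray:
        return self.maps[self.classes.index(cls)]

    def argmax_map(self) -> np.ndarray:
        """Per-pixel index into ``classes`` of the most probable class."""
        return np.argmax(self.maps, axis=0)

    def argmax_names(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.argmax_map()]


def train_classifier(
    features: FeatureStack,
    scribbles: Scribbles,
    n_trees: int = 200,
    seed: int = 0,
    classes: Sequence[str] = CLASS_NAMES,
    max_depth: Optional[int] = None,
    max_features="sqrt",
    bootstrap: bool = True,
    modality: str = "brightfield_dic",
) -> TrainedClassifier:
    """Train a random forest on the scribbled pixels of one image.

    Deterministic given ``seed``; raises :class:`TrainingError` when a class
    has no labeled pixels.
    """
    scribbles.validate(classes)
    if features.data.shape[1:] != tuple(scribbles.image_shape):
        raise TrainingError(
            f"scribbles were drawn on an image of shape {scribbles.image_shape}, "
            f"features have shape {features.data.shape[1:]}"
        )
    rows, cols, labels = scribbles.flatten()
    keep = np.isin(labels.astype(str), list(classes))
    X = features.at(rows[keep], cols[keep])
    y = labels[keep].astype(str)
    est = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        n_jobs=1,
        max_depth=max_depth,
        max_features=max_features,
        bootstrap=bootstrap,
    )
    est.fit(X, y)
    return TrainedClassifier(
        estimator=est,
        classes=tuple(classes),
        feature_names=features.names,
        scales=features.scales,
        n_trees=n_trees,
        seed=seed,
        modality=modality,
    )


def classify(
    img, clf: TrainedClassifier, features: Optional[FeatureStack] = None
) -> ProbabilityStack:
    """Apply a trained classifier to an image, producing probability maps.

    Features are recomputed with the classifier's recorded scales unless a
    precomputed stack is passed, in which case its recipe must match the
    classifier's metadata.
    """
    if isinstance(img, Micrograph) and img.modality != clf.modality:
        raise ValueError(
            f"classifier was trained on {clf.modality!r} images, got {img.modality!r}"
        )
    if features is None:
        features = compute_features(img, clf.scales)
    if features.names != clf.feature_names:
        raise ValueError("feature configuration does not match classifier metadata")
    h, w = features.data.shape[1:]
    proba = clf.estimator.predict_proba(features.matrix())
    order = [list(clf.estimator.classes_).index(c) for c in clf.classes]
    maps = proba[:, order].T.reshape(len(clf.classes), h, w)
    return ProbabilityStack(maps=maps, classes=clf.classes)


def save_classifier(clf: TrainedClassifier, path) -> None:
    """Serialize estimator + JSON metadata block into a single archive."""
    joblib.dump({"metadata_json": json.dumps(clf.metadata()), "estimator": clf.estimator}, path)


def load_classifier(path) -> TrainedClassifier:
    blob = joblib.load(path)
    meta = json.loads(blob["metadata_json"])
    return TrainedClassifier(
        estimator=blob["estimator"],
        classes=tuple(meta["classes"]),
        feature_names=tuple(meta["feature_names"]),
        scales=tuple(meta["scales"]),
        n_trees=meta["n_trees"],
        seed=meta["seed"],
        modality=meta.get("modality", "brightfield_dic"),
    )
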