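"""Affected-pixel classification: CIE-Lab clustering to build a training
set, then an RGB-input neural network applied to the whole raster.

The workflow mirrors the cluster-assisted supervised labelling used for
leaf-area and pest mapping from very-high-resolution RGB orthoimages:

1. a small training patch of the orthoimage is converted from sRGB to
   CIE 1976 L*a*b* (D65) and k-means is run on the chromatic (a*, b*)
   components only — lightness is excluded so shadows do not dominate;
2. each cluster is related to a semantic class ({affected, other}),
   either explicitly or by nearest mean RGB to a declared reference
   color (the config-driven surrogate of the original interactive
   step);
3. the labelled patch pixels train a small multilayer perceptron whose
   inputs are the RGB values and whose sigmoid output is 1 for affected
   vegetation, 0 for everything else;
4. the trained network classifies every valid pixel of the raster,
   thresholding the score at ``threshold``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans
from sklearn.neural_network import MLPClassifier

from .grids import GeoRaster
from .geomatic_io import MASK_NODATA

__all__ = [
    "LabImage",
    "ClusterModel",
    "AnnConfig",
    "PixelClassifier",
    "rgb_to_lab",
    "cluster_ab",
    "label_clusters_by_reference",
    "make_training_set",
    "train_ann",
    "classify_raster",
    "save_classifier",
    "load_classifier",
]

log = logging.getLogger(__name__)

AFFECTED = "affected"
OTHER = "other"


@dataclass
class LabImage:
    """Per-pixel CIE L*a*b* values (D65) with a validity mask."""

    lab: np.ndarray  # (..., 3) float; L in [0, 100]
    valid: np.ndarray | None = None

    @property
    def L(self) -> np.ndarray:
        return self.lab[..., 0]

    @property
    def a(self) -> np.ndarray:
        return self.lab[..., 1]

    @property
    def b(self) -> np.ndarray:
        return self.lab[..., 2]


@dataclass
class ClusterModel:
    """k-means model in (a*, b*) chroma space."""

    k: int
    centroids: np.ndarray  # (k, 2) in (a, b)
    seed: int
    inertia: float

    def assign(self, ab: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for (n, 2) chroma samples."""
        d2 = ((ab[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass(frozen=True)
class AnnConfig:
    """Small-MLP configuration: RGB in, sigmoid 'affected' score out."""

    hidden_layers: tuple[int, ...] = (10,)
    activation: str = "logistic"
    max_epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    threshold: float = 0.5
    max_train_samples: int = 20000

    def __post_init__(self) -> None:
        if not self.hidden_layers or min(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden unit")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class PixelClassifier:
    """Trained per-pixel classifier: RGB triple → affected score in [0, 1]."""

    mlp: MLPClassifier
    config: AnnConfig
    input_scale: float = 255.0

    def score(self, rgb: np.ndarray) -> np.ndarray:
        """Affected-class probability for (n, 3) RGB samples."""
        x = np.asarray(rgb, dtype=np.float64).reshape(-1, 3) / self.input_scale
        return self.mlp.predict_proba(x)[:, 1]

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        return (self.score(rgb) >= self.config.threshold).astype(np.uint8)


def rgb_to_lab(image: GeoRaster | np.ndarray) -> LabImage:
    """sRGB (8-bit, D65) → CIE 1976 L*a*b*; nodata propagates into the
    validity mask."""
    if isinstance(image, GeoRaster):
        if not image.is_rgb:
            raise ValueError("rgb_to_lab needs a 3-band RGB raster")
        data, valid = image.data, image.valid_mask()
    else:
        data = np.asarray(image)
        if data.ndim < 2 or data.shape[-1] != 3:
            raise ValueError("rgb_to_lab needs (..., 3) RGB data")
        valid = None
    lab = rgb2lab(data.astype(np.float64) / 255.0)
    return LabImage(lab, valid=valid)


def cluster_ab(patch: LabImage, k: int, seed: int = 0) -> tuple[ClusterModel, np.ndarray]:
    """k-means on the (a*, b*) chroma plane of a training patch.

    Returns the model and the per-pixel cluster assignment (−1 on
    invalid pixels).  Lightness is deliberately excluded.
    """
    if not 2 <= k <= 10:
        raise ValueError("k must be between 2 and 10")
    ab = np.stack([patch.a, patch.b], axis=-1)
    valid = (
        patch.valid
        if patch.valid is not None
        else np.ones(ab.shape[:-1], dtype=bool)
    )
    samples = ab[valid].reshape(-1, 2)
    if len(samples) < k:
        raise ValueError(f"patch has {len(samples)} valid pixels; need >= k={k}")
    if len(np.unique(samples, axis=0)) < k:
        raise ValueError(f"patch has fewer than k={k} distinct (a, b) values")
    km = KMeans(n_clusters=k, n_init=10, tol=1e-6, random_state=seed)
    labels = km.fit_predict(samples)
    assignment = np.full(valid.shape, -1, dtype=np.int32)
    assignment[valid] = labels
    model = ClusterModel(
        k=k, centroids=km.cluster_centers_.copy(), seed=seed,
        inertia=float(km.inertia_),
    )
    return model, assignment


def cluster_mean_rgb(assignment: np.ndarray, patch_rgb: np.ndarray, k: int) -> np.ndarray:
    """Mean RGB of each cluster — the information the operator uses to
    relate clusters to scene features."""
    rgb = np.asarray(patch_rgb, dtype=np.float64).reshape(-1, 3)
    labels = assignment.reshape(-1)
    means = np.full((k, 3), np.nan)
    for c in range(k):
        sel = labels == c
        if np.any(sel):
            means[c] = rgb[sel].mean(axis=0)
    return means


def label_clusters_by_reference(
    assignment: np.ndarray,
    patch_rgb: np.ndarray,
    k: int,
    affected_rgb: tuple[float, float, float],
    max_rgb_distance: float = 25.0,
) -> dict[int, str]:
    """Automatic cluster→class mapping: a cluster is 'affected' when its
    mean RGB lies within ``max_rgb_distance`` (Euclidean) of the declared
    affected reference color; the nearest cluster is always affected.

    Stands in for the interactive visual labelling step.
    """
    means = cluster_mean_rgb(assignment, patch_rgb, k)
    dist = np.linalg.norm(means - np.asarray(affected_rgb, dtype=float), axis=1)
    labeling = {c: OTHER for c in range(k)}
    near = np.flatnonzero(dist <= max_rgb_distance)
    if near.size == 0:
        near = [int(np.nanargmin(dist))]
    for c in near:
        labeling[int(c)] = AFFECTED
    return labeling


def make_training_set(
    assignment: np.ndarray,
    labeling: dict[int, str],
    patch_rgb: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled (RGB, 0/1) pixels from a cluster assignment and a
    cluster→class mapping."""
    labels = assignment.reshape(-1)
    rgb = np.asarray(patch_rgb).reshape(-1, 3)
    present = sorted(int(c) for c in np.unique(labels) if c >= 0)
    missing = [c for c in present if c not in labeling]
    if missing:
        raise ValueError(f"labeling does not cover clusters {missing}")
    bad = [c for c, v in labeling.items() if v not in (AFFECTED, OTHER)]
    if bad:
        raise ValueError(f"labeling values must be '{AFFECTED}' or '{OTHER}'")
    if not any(labeling.get(c) == AFFECTED for c in present):
        raise ValueError("no cluster is labelled affected: nothing to learn")
    keep = labels >= 0
    y = np.array(
        [1 if labeling[int(c)] == AFFECTED else 0 for c in present], dtype=np.uint8
    )
    lut = np.zeros(max(present) + 1, dtype=np.uint8)
    lut[present] = y
    return rgb[keep], lut[labels[keep]]


def train_ann(
    x_rgb: np.ndarray, y: np.ndarray, config: AnnConfig | None = None
) -> PixelClassifier:
    """Train the affected/other MLP on labelled RGB pixels.

    The training set is subsampled (stratified, seeded) to
    ``max_train_samples`` — color distributions are low-dimensional and
    saturate long before that.
    """
    config = config or AnnConfig()
    x = np.asarray(x_rgb, dtype=np.float64).reshape(-1, 3)
    y = np.asarray(y).reshape(-1).astype(np.uint8)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y disagree in length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    if len(y) > config.max_train_samples:
        rng = np.random.default_rng(config.seed)
        idx = []
        for c in classes:
            members = np.flatnonzero(y == c)
            quota = max(1, int(round(config.max_train_samples * len(members) / len(y))))
            idx.append(rng.choice(members, size=min(quota, len(members)), replace=False))
        idx = np.sort(np.concatenate(idx))
        x, y = x[idx], y[idx]
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        solver="lbfgs",  # full-batch: fast and deterministic on small color sets
        max_iter=config.max_epochs,
        random_state=config.seed,
        tol=1e-6,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        mlp.fit(x / 255.0, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        log.warning(
            "ANN did not fully converge in %d epochs (loss %.4g)",
            config.max_epochs,
            mlp.loss_,
        )
    clf = PixelClassifier(mlp, config)
    acc = float((clf.predict(x) == y).mean())
    log.info("ANN trained on %d pixels; training accuracy %.3f", len(y), acc)
    return clf


def classify_raster(ortho: GeoRaster, clf: PixelClassifier,
                    chunk: int = 2_000_000) -> GeoRaster:
    """Apply the classifier to every valid pixel: 1 = affected,
    0 = other, nodata propagated."""
    if not ortho.is_rgb:
        raise ValueError("classify_raster needs an RGB raster")
    valid = ortho.valid_mask()
    out = np.full(ortho.grid.shape, MASK_NODATA, dtype=np.uint8)
    flat_rgb = ortho.data.reshape(-1, 3)
    flat_valid = valid.reshape(-1)
    idx = np.flatnonzero(flat_valid)
    flat_out = out.reshape(-1)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        flat_out[sel] = clf.predict(flat_rgb[sel])
    return GeoRaster(ortho.grid, out, nodata=MASK_NODATA)


# --------------------------------------------------------------------------
# model persistence: JSON with config + weights (versioned)
# --------------------------------------------------------------------------

_MODEL_FORMAT = "vinepest-ann/1"


def save_classifier(clf: PixelClassifier, path: str | Path) -> None:
    doc = {
        "format": _MODEL_FORMAT,
        "config": {
            "hidden_layers": list(clf.config.hidden_layers),
            "activation": clf.config.activation,
            "max_epochs": clf.config.max_epochs,
            "learning_rate": clf.config.learning_rate,
            "seed": clf.config.seed,
            "threshold": clf.config.threshold,
            "max_train_samples": clf.config.max_train_samples,
        },
        "input_scale": clf.input_scale,
        "coefs": [w.tolist() for w in clf.mlp.coefs_],
        "intercepts": [b.tolist() for b in clf.mlp.intercepts_],
    }
    Path(path).write_text(json.dumps(doc))


def load_classifier(path: str | Path) -> PixelClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} model file")
    cfg = doc["config"]
    config = AnnConfig(
        hidden_layers=tuple(cfg["hidden_layers"]),
        activation=cfg["activation"],
        max_epochs=cfg["max_epochs"],
        learning_rate=cfg["learning_rate"],
        seed=cfg["seed"],
        threshold=cfg["threshold"],
        max_train_samples=cfg["max_train_samples"],
    )
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        random_state=config.seed,
    )
    coefs = [np.asarray(w, dtype=np.float64) for w in doc["coefs"]]
    intercepts = [np.asarray(b, dtype=np.float64) for b in doc["intercepts"]]
    # rebuild the fitted state without retraining
    mlp.coefs_ = coefs
    mlp.intercepts_ = intercepts
    mlp.n_layers_ = len(coefs) + 1
    mlp.n_outputs_ = 1
    mlp.n_features_in_ = 3
    mlp.out_activation_ = "logistic"
    mlp.classes_ = np.array([0, 1])
    return PixelClassifier(mlp, config, input_scale=float(doc["input_scale"]))
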