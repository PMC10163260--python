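"""Visual-integrity detection (VID).

Each cell receives a weight ``W_v = W_1 * W_2`` multiplied into its class
probabilities:

* ``W_1 = 1 - P_bad`` from a gradient-boosted tree classifier over the
  eight geometric features, trained with five-fold cross-validation on
  good/bad cell examples;
* ``W_2`` from a four-class image classifier that predicts the fraction of
  the cell body captured, binned as ``[0, 0.3) -> 1``, ``[0.3, 0.5) -> 2``,
  ``[0.5, 0.8) -> 3``, ``[0.8, 1] -> 4`` and mapped to weights
  ``0.1, 0.5, 1, 1``.

Down-weighting never increases a probability, so applying VID is a
contraction on the prediction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from xgboost import XGBClassifier

from .data import CellInstance

CAPTURE_WEIGHTS = {1: 0.1, 2: 0.5, 3: 1.0, 4: 1.0}


@dataclass
class VIDWeights:
    w_1: float
    w_2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_1 <= 1.0:
            raise ValueError("W_1 outside [0, 1]")
        if self.w_2 not in CAPTURE_WEIGHTS.values():
            raise ValueError("W_2 must be one of 0.1, 0.5, 1.0")

    @property
    def w_v(self) -> float:
        return self.w_1 * self.w_2


def capture_class(capture_ratio: float) -> int:
    """Bin the captured fraction of the cell body into classes 1-4."""
    if not 0.0 <= capture_ratio <= 1.0:
        raise ValueError("capture_ratio must lie in [0, 1]")
    if capture_ratio < 0.3:
        return 1
    if capture_ratio < 0.5:
        return 2
    if capture_ratio < 0.8:
        return 3
    return 4


def capture_weight(cls: int) -> float:
    """``W_2`` for a capture class."""
    if cls not in CAPTURE_WEIGHTS:
        raise ValueError("capture class must be 1, 2, 3 or 4")
    return CAPTURE_WEIGHTS[cls]


# ---------------------------------------------------------------------------
# structural integrity (module 1)

def train_structural_classifier(features: np.ndarray, is_bad: np.ndarray,
                                seed: int = 0, n_folds: int = 5):
    """Fit the gradient-boosted structural classifier with k-fold validation.

    ``is_bad`` is 1 for structurally compromised cells. Returns the final
    model (fit on all data) and the mean held-out fold accuracy.
    """
    features = np.asarray(features, dtype=float)
    is_bad = np.asarray(is_bad, dtype=int)
    n = len(features)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    accs = []
    for k in range(n_folds):
        test_idx = folds[k]
        train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        clf = _new_xgb(seed)
        clf.fit(features[train_idx], is_bad[train_idx])
        accs.append(float((clf.predict(features[test_idx]) == is_bad[test_idx]).mean()))
    final = _new_xgb(seed)
    final.fit(features, is_bad)
    return final, float(np.mean(accs))


def _new_xgb(seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=60, max_depth=3, learning_rate=0.3,
        random_state=seed, n_jobs=1, verbosity=0,
        eval_metric="logloss",
    )


def structural_weight(features, classifier) -> float:
    """``W_1 = 1 - P_bad`` for one cell's geometric features."""
    vec = features.as_vector() if hasattr(features, "as_vector") else np.asarray(features, float)
    try:
        p_bad = float(classifier.predict_proba(vec[None])[0, 1])
    except Exception as exc:  # noqa: BLE001 - surface untrained models clearly
        raise ValueError(f"structural classifier is not usable: {exc}") from exc
    return 1.0 - p_bad


# ---------------------------------------------------------------------------
# capture-ratio model (module 2) and the combined weight

def train_capture_model(cells: list[CellInstance], input_size: int,
                        spec=None, seed: int = 0, cfg=None):
    """Train the four-class capture-ratio classifier on simulated defects.

    Each training cell is corrupted towards a total captured fraction drawn
    uniformly from each capture bin in turn (compounding any truncation the
    cell already carries), giving an approximately balanced four-class set;
    the network is trained with cross-entropy.
    """
    from .cellex import resize_crop
    from .nets import BackboneSpec, SoftmaxClassifier, TrainConfig, train_softmax_classifier
    from .synth import corrupt_cell

    rng = np.random.default_rng(seed)
    bins = [(0.05, 0.3), (0.3, 0.5), (0.5, 0.8), (0.8, 1.0)]
    crops, labels = [], []
    for i, cell in enumerate(cells):
        for cls, (lo, hi) in enumerate(bins, start=1):
            if cell.capture_ratio <= lo:
                continue  # bin unreachable by further cropping
            target = float(rng.uniform(lo, min(hi, cell.capture_ratio)))
            keep = min(target / cell.capture_ratio, 1.0)
            corrupted, _ = corrupt_cell(cell, keep, rng_seed=int(rng.integers(2 ** 31)))
            crops.append(resize_crop(corrupted.crop, input_size))
            labels.append(capture_class(corrupted.capture_ratio) - 1)
    crops = np.stack(crops)
    labels = np.asarray(labels)
    spec = spec or BackboneSpec(input_size=input_size, feature_dim=32,
                                n_blocks=3, base_channels=8)
    model = SoftmaxClassifier(spec, n_classes=4, seed=seed)
    cfg = cfg or TrainConfig(epochs=4, batch_size=64, lr0=2e-3, seed=seed)
    history = train_softmax_classifier(model, crops, labels, cfg)
    return model, history


def predict_capture_class(model, crop: np.ndarray, input_size: int) -> int:
    from .cellex import resize_crop
    resized = resize_crop(crop, input_size)
    probs = model.predict_probs(resized[None])[0]
    return int(probs.argmax()) + 1


def visual_integrity(cell: CellInstance, structural_classifier, capture_model,
                     input_size: int = 32) -> VIDWeights:
    """End-to-end visual-integrity weight for one cell."""
    from .cellex import geometric_features
    w1 = structural_weight(geometric_features(cell), structural_classifier)
    cls = predict_capture_class(capture_model, cell.crop, input_size)
    return VIDWeights(w_1=w1, w_2=capture_weight(cls))


def apply_vid(probs: np.ndarray, w_v: np.ndarray) -> np.ndarray:
    """Scale each cell's probability vector by its visual-integrity weight."""
    probs = np.asarray(probs, dtype=float)
    w_v = np.asarray(w_v, dtype=float)
    if (w_v < 0).any() or (w_v > 1).any():
        raise ValueError("W_v outside [0, 1]")
    return probs * w_v[:, None]
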