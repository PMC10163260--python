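"""Cells re-labelling algorithm (CRA).

Weak cell labels (image-level unions naively copied to every cell) carry
many false positives. CRA trains an ensemble of cell-level models on the
current labels, averages their per-cell confidences, power-normalises the
result (``c -> c^beta``, ``beta < 1`` inflating mid-range confidences), and
replaces each *positive* weak label with the transformed confidence.
Negatives are never touched: a class absent from the image label cannot be
re-introduced. The process is iterated (two rounds by default), handing the
continuous labels of round ``r`` to the training of round ``r + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CRAConfig:
    beta_cra: float = 0.5
    n_rounds: int = 2
    source_seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        if self.beta_cra <= 0:
            raise ValueError("beta_cra must be positive")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be at least 1")
        if len(self.source_seeds) < 1:
            raise ValueError("at least one source model is required")


def combine_confidences(per_model_probs: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-model probability matrices."""
    if not per_model_probs:
        raise ValueError("no probability matrices supplied")
    shapes = {np.asarray(m).shape for m in per_model_probs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across models: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=float) for m in per_model_probs])
    if (stack < 0).any() or (stack > 1).any():
        raise ValueError("confidences outside [0, 1]")
    return stack.mean(axis=0)


def relabel(confidences: np.ndarray, weak_labels: np.ndarray,
            config: CRAConfig) -> np.ndarray:
    """Replace positive weak labels by power-normalised confidences.

    Entries with ``weak_label == 0`` stay exactly 0; positive entries become
    ``c ** beta`` and are continuous in ``[0, 1]``.
    """
    confidences = np.asarray(confidences, dtype=float)
    weak = np.asarray(weak_labels, dtype=float)
    if confidences.shape != weak.shape:
        raise ValueError("confidence and label shapes differ")
    if config.beta_cra <= 0:
        raise ValueError("beta_cra must be positive")
    transformed = np.clip(confidences, 0.0, 1.0) ** config.beta_cra
    return np.where(weak > 0, transformed, 0.0)


def run_rounds(crops: np.ndarray, weak_labels: np.ndarray,
               config: CRAConfig, model_builder, train_fn,
               predict_fn=None) -> tuple[np.ndarray, list, dict]:
    """Iterate train -> predict -> relabel for ``config.n_rounds`` rounds.

    ``model_builder(seed)`` returns a fresh source model;
    ``train_fn(model, crops, labels, seed)`` trains it in place;
    ``predict_fn(model, crops)`` (default: ``model.predict_probs``) yields
    a cells x C probability matrix. Returns the refined label matrix, the
    models of the final round, and a provenance record.
    """
    predict_fn = predict_fn or (lambda m, x: m.predict_probs(x))
    labels = np.asarray(weak_labels, dtype=float)
    provenance: dict = {"beta": config.beta_cra, "rounds": []}
    models: list = []
    for rnd in range(1, config.n_rounds + 1):
        models = []
        probs = []
        for seed in config.source_seeds:
            model = model_builder(seed)
            train_fn(model, crops, labels, seed)
            probs.append(predict_fn(model, crops))
            models.append(model)
        combined = combine_confidences(probs)
        labels = relabel(combined, weak_labels, config)
        provenance["rounds"].append({
            "round": rnd,
            "seeds": list(config.source_seeds),
            "mean_positive_label": float(labels[np.asarray(weak_labels) > 0].mean())
            if (np.asarray(weak_labels) > 0).any() else 0.0,
        })
    return labels, models, provenance
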