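"""Stream fusion, diversity-based model selection and ensemble aggregation.

Per class, the image-stream and cell-stream probabilities are either
multiplied (when their Pearson correlation over cells carrying the class
exceeds ``rho_th = 0.32``) or the cell-stream value is kept alone (low
correlation flags classes the image stream over-labels). Ensembles are
formed by picking the best-scoring member of each architecture family, and
member outputs are hierarchically aggregated: mean within a family, then
mean across families, then stream fusion, then multiplication by each
cell's visual-integrity weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_RHO_TH = 0.32


@dataclass
class FusionPolicy:
    """Per-class correlations and the product/cell-only decision."""

    r: np.ndarray
    rho_th: float = DEFAULT_RHO_TH

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    @property
    def mode(self) -> np.ndarray:
        """'product' where r > rho_th, else 'cell_only'."""
        return np.where(self.r > self.rho_th, "product", "cell_only")

    def to_json(self) -> str:
        return json.dumps({
            "rho_th": self.rho_th,
            "r": self.r.tolist(),
            "mode": self.mode.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "FusionPolicy":
        obj = json.loads(text)
        return cls(r=np.asarray(obj["r"]), rho_th=float(obj["rho_th"]))


@dataclass
class EnsembleSpec:
    """Selected members (one per family) and the diversity diagnostic."""

    members: list[tuple[str, str]]            # (model_id, family)
    correlation_matrix: np.ndarray | None = None
    aggregation: str = "hierarchical"

    def to_json(self) -> str:
        return json.dumps({
            "members": self.members,
            "aggregation": self.aggregation,
            "correlation_matrix": None if self.correlation_matrix is None
            else np.asarray(self.correlation_matrix).tolist(),
        })


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def classwise_correlation(image_probs: np.ndarray, cell_probs: np.ndarray,
                          labels: np.ndarray) -> np.ndarray:
    """Per-class Pearson correlation between the two streams.

    For class ``c`` the correlation is computed over the cells whose parent
    image is labelled with ``c`` (``labels`` is the image label mapped to
    cells). Degenerate cases (fewer than two eligible cells, or a constant
    stream) yield ``r = 0``.
    """
    image_probs = np.asarray(image_probs, dtype=float)
    cell_probs = np.asarray(cell_probs, dtype=float)
    labels = np.asarray(labels)
    if image_probs.shape != cell_probs.shape or image_probs.shape != labels.shape:
        raise ValueError("prediction matrices and labels must be aligned")
    n_classes = image_probs.shape[1]
    r = np.zeros(n_classes)
    for c in range(n_classes):
        sel = labels[:, c] > 0
        if sel.sum() < 2:
            warnings.warn(f"class {c}: fewer than 2 labelled cells; r set to 0")
            continue
        r[c] = _pearson(image_probs[sel, c], cell_probs[sel, c])
    return r


def fuse_streams(image_prob: np.ndarray, cell_prob: np.ndarray,
                 policy: FusionPolicy) -> np.ndarray:
    """Per-class product where correlated, cell-stream value otherwise."""
    image_prob = np.asarray(image_prob, dtype=float)
    cell_prob = np.asarray(cell_prob, dtype=float)
    product = policy.r > policy.rho_th
    return np.where(product, image_prob * cell_prob, cell_prob)


def select_diverse(candidates: list[tuple[str, str, float]],
                   prob_matrices: dict[str, np.ndarray] | None = None) -> EnsembleSpec:
    """Pick the best-scoring member of each architecture family.

    ``candidates`` holds ``(model_id, family, validation_score)`` triples;
    ties are broken by lexicographic model id. When flattened probability
    matrices are supplied, the inter-model correlation matrix over all
    candidates is attached as the diversity diagnostic.
    """
    best: dict[str, tuple[str, float]] = {}
    for model_id, family, score in candidates:
        if family not in best:
            best[family] = (model_id, score)
        else:
            cur_id, cur_score = best[family]
            if score > cur_score or (score == cur_score and model_id < cur_id):
                best[family] = (model_id, score)
    members = sorted((mid, fam) for fam, (mid, _) in best.items())
    corr = None
    if prob_matrices:
        ids = [mid for mid, _, _ in candidates]
        flat = [np.asarray(prob_matrices[m]).ravel() for m in ids]
        k = len(flat)
        corr = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                corr[i, j] = corr[j, i] = _pearson(flat[i], flat[j])
    return EnsembleSpec(members=members, correlation_matrix=corr)


def aggregate_apply(member_cell_probs: list[np.ndarray],
                    member_image_probs: list[np.ndarray],
                    policy: FusionPolicy, w_v: np.ndarray,
                    families: list[str] | None = None,
                    aggregation: str = "hierarchical") -> np.ndarray:
    """Ensemble aggregation, stream fusion and visual-integrity weighting.

    Member outputs are cells x C matrices aligned row-wise. Hierarchical
    aggregation averages within each family first, then across families;
    ``aggregation='flat'`` averages all members uniformly. The fused matrix
    is finally scaled per cell by ``w_v``.
    """
    if len(member_cell_probs) != len(member_image_probs):
        raise ValueError("cell and image member lists differ in length")
    shapes = {np.asarray(m).shape for m in member_cell_probs + member_image_probs}
    if len(shapes) != 1:
        raise ValueError(f"member shape mismatch: {sorted(shapes)}")
    cell_stack = np.stack([np.asarray(m, float) for m in member_cell_probs])
    image_stack = np.stack([np.asarray(m, float) for m in member_image_probs])
    if aggregation == "hierarchical" and families is not None:
        fams = sorted(set(families))
        fam_cell = [cell_stack[[i for i, f in enumerate(families) if f == fam]].mean(axis=0)
                    for fam in fams]
        fam_image = [image_stack[[i for i, f in enumerate(families) if f == fam]].mean(axis=0)
                     for fam in fams]
        cell_mean = np.mean(fam_cell, axis=0)
        image_mean = np.mean(fam_image, axis=0)
    else:
        cell_mean = cell_stack.mean(axis=0)
        image_mean = image_stack.mean(axis=0)
    fused = np.empty_like(cell_mean)
    for i in range(len(fused)):
        fused[i] = fuse_streams(image_mean[i], cell_mean[i], policy)
    from .vid import apply_vid
    return apply_vid(fused, w_v)
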