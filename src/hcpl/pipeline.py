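"""End-to-end orchestration at desk scale.

Glue between the synthetic datasets and the model/refinement/ensembling
modules: build per-cell crop tables from a manifest, hold out validation
images, train the three model families, run label refinement, fit the
visual-integrity models, and score predictions. The CLI, the test suite
and the reproduction script all drive the pipeline through this module so
the study conditions are defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cellex, cra, ensemble, evaluation, vid
from .data import CellInstance, DatasetManifest
from .nets import (BackboneSpec, CLAModel, DSAModel, LossWeights, TrainConfig,
                   class_weights_from_frequencies, train_cell_model, train_dsa)

#: Model input side used throughout the desk-scale benchmarks.
DESK_INPUT = 32


def desk_spec(input_size: int = DESK_INPUT) -> BackboneSpec:
    """The small trunk used by the benchmarks: three stride-2 blocks, 32-d."""
    return BackboneSpec(input_size=input_size, feature_dim=32,
                        n_blocks=3, base_channels=8)


def desk_train_config(seed: int, epochs: int = 5) -> TrainConfig:
    """Desk-scale training schedule for the small trunk."""
    return TrainConfig(epochs=epochs, batch_size=64, lr0=2e-3, seed=seed,
                       max_shift=2, p_cutout=0.2)


@dataclass
class CellTable:
    """Flat per-cell view of a manifest, ready for model input."""

    crops: np.ndarray                 # (n, 4, s, s), intensities scaled to [0, 1]
    cells: list[CellInstance]
    cell_labels: np.ndarray           # ground truth (withheld from training)
    weak_labels: np.ndarray           # image unions mapped to cells
    image_ids: np.ndarray             # parent image id per cell
    capture_ratios: np.ndarray
    n_classes: int
    image_size: int = 128

    def rows_of_images(self, ids) -> np.ndarray:
        wanted = set(ids)
        return np.flatnonzero(np.isin(self.image_ids, list(wanted)))


def build_cell_table(manifest: DatasetManifest, input_size: int = DESK_INPUT,
                     pad: int = 2) -> CellTable:
    """Extract, mask, resize and normalise every cell of a manifest."""
    crops, cells, ids = [], [], []
    for image, raster in zip(manifest.images, manifest.instance_masks):
        for cell in cellex.extract_cells(image, raster, pad=pad):
            crops.append(cellex.resize_crop(cell.crop, input_size) / 255.0)
            cells.append(cell)
            ids.append(image.image_id)
    return CellTable(
        crops=np.stack(crops),
        cells=cells,
        cell_labels=manifest.cell_labels.astype(float),
        weak_labels=manifest.weak_labels.astype(float),
        image_ids=np.asarray(ids),
        capture_ratios=manifest.capture_ratios,
        n_classes=manifest.n_classes,
        image_size=manifest.images[0].shape[0] if manifest.images else 128,
    )


def split_images(manifest: DatasetManifest, val_fraction: float,
                 seed: int) -> tuple[list[str], list[str]]:
    """Hold out whole images (never cells) for validation."""
    rng = np.random.default_rng(seed)
    ids = [img.image_id for img in manifest.images]
    order = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    val = sorted(ids[i] for i in order[:n_val])
    train = sorted(ids[i] for i in order[n_val:])
    return train, val


# ---------------------------------------------------------------------------
# model training on a table

def train_cla(table: CellTable, labels: np.ndarray, rows: np.ndarray,
              seed: int, epochs: int = 5,
              spec: BackboneSpec | None = None) -> CLAModel:
    spec = spec or desk_spec(table.crops.shape[-1])
    model = CLAModel(spec, table.n_classes, seed=seed)
    weights = class_weights_from_frequencies(
        np.maximum(labels[rows].mean(axis=0), 1e-6))
    train_cell_model(model, table.crops[rows], labels[rows],
                     desk_train_config(seed, epochs), class_weights=weights)
    return model


def train_dsa_model(table: CellTable, cell_labels: np.ndarray,
                    train_ids: list[str], seed: int, epochs: int = 5,
                    round: int = 1,
                    spec: BackboneSpec | None = None) -> DSAModel:
    """Train the dual-stream model on per-image bags of the training split."""
    spec = spec or desk_spec(table.crops.shape[-1])
    model = DSAModel(spec, table.n_classes, seed=seed)
    bags, image_targets, bag_targets = [], [], []
    for iid in train_ids:
        rows = table.rows_of_images([iid])
        bags.append(table.crops[rows])
        image_targets.append(table.weak_labels[rows[0]])  # union label
        bag_targets.append(cell_labels[rows])
    weights = class_weights_from_frequencies(
        np.maximum(np.stack(image_targets).mean(axis=0), 1e-6))
    train_dsa(model, bags, np.stack(image_targets), bag_targets,
              desk_train_config(seed, epochs), LossWeights.for_round(round),
              class_weights=weights)
    return model


def dsa_predict_table(model: DSAModel, table: CellTable,
                      rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Both streams for every cell in ``rows``, bagged per parent image.

    Returns ``(image_probs, cell_probs)`` aligned with ``rows``; each cell
    inherits its image's image-stream vector.
    """
    image_probs = np.zeros((len(rows), table.n_classes))
    cell_probs = np.zeros((len(rows), table.n_classes))
    pos_of = {r: i for i, r in enumerate(rows)}
    for iid in np.unique(table.image_ids[rows]):
        img_rows = [r for r in rows if table.image_ids[r] == iid]
        img_p, cell_p = model.predict(table.crops[img_rows])
        for j, r in enumerate(img_rows):
            image_probs[pos_of[r]] = img_p
            cell_probs[pos_of[r]] = cell_p[j]
    return image_probs, cell_probs


# ---------------------------------------------------------------------------
# label refinement

def run_cra_on_table(table: CellTable, rows: np.ndarray,
                     config: cra.CRAConfig, epochs: int = 5,
                     spec: BackboneSpec | None = None) -> np.ndarray:
    """CRA over the table's weak labels using small cell-level source models.

    Returns the refined label matrix for ``rows`` (aligned with them).
    """
    spec = spec or desk_spec(table.crops.shape[-1])
    weights = class_weights_from_frequencies(
        np.maximum(table.weak_labels[rows].mean(axis=0), 1e-6))

    def builder(seed):
        return CLAModel(spec, table.n_classes, seed=seed)

    def train_fn(model, crops, labels, seed):
        train_cell_model(model, crops, labels, desk_train_config(seed, epochs),
                         class_weights=weights)

    refined, _models, _prov = cra.run_rounds(
        table.crops[rows], table.weak_labels[rows], config, builder, train_fn)
    return refined


# ---------------------------------------------------------------------------
# visual integrity

def _is_border_cell(cell: CellInstance, image_size: int) -> bool:
    r0, r1, c0, c1 = cell.bbox
    return r0 == 0 or c0 == 0 or r1 >= image_size or c1 >= image_size


def structural_training_set(table: CellTable, rng: np.random.Generator,
                            bad_fraction: float = 0.5,
                            n_cells: int | None = None):
    """Good/bad cells for the structural classifier.

    Labels follow the half-captured convention: 'good' cells retain most of
    their body (keep fraction above 0.55, including fully intact cells),
    'bad' cells are severely occluded (keep fraction 0.1-0.45). The gap
    around one half keeps the two populations separable.
    """
    from .synth import corrupt_cell

    whole = [i for i, c in enumerate(table.cells)
             if table.capture_ratios[i] == 1.0
             and not _is_border_cell(c, table.image_size)]
    n = n_cells or len(table.cells)
    feats, labels = [], []
    for _ in range(n):
        i = int(whole[rng.integers(len(whole))])
        cell = table.cells[i]
        if rng.uniform() < bad_fraction:
            keep = float(rng.uniform(0.1, 0.45))
            labels.append(1)
        else:
            keep = float(rng.uniform(0.55, 1.0))
            labels.append(0)
        if keep < 1.0:
            cell, _ = corrupt_cell(cell, keep, rng_seed=int(rng.integers(2 ** 31)))
        feats.append(cellex.geometric_features(cell).as_vector())
    return np.stack(feats), np.asarray(labels)


def vid_weights_for_table(table: CellTable, structural_clf, capture_model,
                          rows: np.ndarray) -> np.ndarray:
    """``W_v`` for each cell in ``rows``."""
    out = np.empty(len(rows))
    for i, r in enumerate(rows):
        out[i] = vid.visual_integrity(table.cells[r], structural_clf,
                                      capture_model,
                                      input_size=table.crops.shape[-1]).w_v
    return out


# ---------------------------------------------------------------------------
# scoring shortcuts

def score_rows(probs: np.ndarray, table: CellTable, rows: np.ndarray,
               min_capture: float | None = None) -> evaluation.APResult:
    """mAP of per-cell probabilities against ground-truth labels.

    Predicted cells coincide with ground-truth cells here (segmentation is
    taken from the manifest), so mask matching is exact. With
    ``min_capture`` set, cells whose captured fraction falls below it are
    removed from the ground truth — the convention that a cell under half
    captured is not a scorable target — while their predictions remain in
    the ranking as unmatchable detections.
    """
    gt = table.cell_labels[rows]
    if min_capture is not None:
        gt = gt.copy()
        gt[table.capture_ratios[rows] < min_capture] = 0.0
    return evaluation.score_matched(probs, gt)


def fusion_policy_from_split(model: DSAModel, table: CellTable,
                             val_rows: np.ndarray,
                             rho_th: float = ensemble.DEFAULT_RHO_TH) -> ensemble.FusionPolicy:
    """Estimate per-class stream correlations on held-out cells."""
    image_probs, cell_probs = dsa_predict_table(model, table, val_rows)
    r = ensemble.classwise_correlation(image_probs, cell_probs,
                                       table.weak_labels[val_rows])
    return ensemble.FusionPolicy(r=r, rho_th=rho_th)
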