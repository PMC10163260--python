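"""File formats: channel rasters, label masks, RLE strings, manifests, predictions.

On-disk dataset layout
----------------------
Each image ``<id>`` is stored as four single-channel PNGs
(``<id>_nucleus.png``, ``<id>_protein.png``, ``<id>_microtubules.png``,
``<id>_er.png``), one 16-bit instance-label PNG ``<id>_mask.png``, and one
shared CSV manifest with columns ``image_id, cell_id, labels`` where
``labels`` holds pipe-separated class indices (empty for no label).

RLE dialect
-----------
1-based, column-major, space-separated ``start length`` pairs — the classic
segmentation-competition convention. Internal coordinates stay 0-based;
the dialect applies at the serialisation boundary only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .data import CHANNEL_NAMES, ChannelImage


class ChannelReadError(ValueError):
    """A channel file is missing or inconsistent with its siblings."""


def read_channel_image(paths: dict[str, str] | list[str], image_id: str = "") -> ChannelImage:
    """Read four single-channel rasters into one :class:`ChannelImage`.

    ``paths`` is either a list in the fixed channel order or a mapping from
    channel name to path. Intensities are preserved losslessly (cast to
    float32).
    """
    if not isinstance(paths, dict):
        if len(paths) != len(CHANNEL_NAMES):
            missing = CHANNEL_NAMES[len(paths):]
            raise ChannelReadError(f"missing channel file(s): {', '.join(missing)}")
        paths = dict(zip(CHANNEL_NAMES, paths))
    for name in CHANNEL_NAMES:
        if name not in paths:
            raise ChannelReadError(f"missing channel file(s): {name}")
        if not os.path.exists(paths[name]):
            raise ChannelReadError(f"channel '{name}' file not found: {paths[name]}")
    planes = []
    shape = None
    for name in CHANNEL_NAMES:
        arr = np.asarray(iio.imread(paths[name]))
        if arr.ndim != 2:
            raise ChannelReadError(f"channel '{name}' is not single-channel: shape {arr.shape}")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ChannelReadError(
                f"channel '{name}' has shape {arr.shape}, expected {shape}"
            )
        planes.append(arr.astype(np.float32))
    return ChannelImage(np.stack(planes), image_id=image_id)


def write_channel_image(image: ChannelImage, directory: str, image_id: str | None = None) -> dict[str, str]:
    """Write one PNG per channel; returns the channel->path mapping."""
    image_id = image_id or image.image_id or "image"
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for k, name in enumerate(CHANNEL_NAMES):
        plane = image.pixels[k]
        if plane.max() > 255:
            out = np.clip(plane, 0, 65535).astype(np.uint16)
        else:
            out = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
        path = os.path.join(directory, f"{image_id}_{name}.png")
        iio.imwrite(path, out)
        paths[name] = path
    return paths


def write_instance_mask(labels: np.ndarray, path: str) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 instances in one image")
    iio.imwrite(path, labels.astype(np.uint16))


def read_instance_mask(path: str) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# Run-length encoding

def rle_encode(mask: np.ndarray) -> str:
    """Encode a binary mask as 1-based column-major ``start length`` pairs."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    flat = mask.astype(np.uint8).flatten(order="F")
    # run boundaries via the discrete difference of a 0-padded sequence
    padded = np.concatenate([[0], flat, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    pairs = np.empty(2 * len(starts), dtype=np.int64)
    pairs[0::2] = starts + 1
    pairs[1::2] = ends - starts
    return " ".join(map(str, pairs))


def rle_decode(rle: str, height: int, width: int) -> np.ndarray:
    """Decode the dialect of :func:`rle_encode` to a ``bool`` raster."""
    out = np.zeros(height * width, dtype=bool)
    tokens = rle.split()
    if len(tokens) % 2:
        raise ValueError("RLE string has an odd number of tokens")
    for run_idx in range(len(tokens) // 2):
        start = int(tokens[2 * run_idx]) - 1
        length = int(tokens[2 * run_idx + 1])
        if start < 0 or length <= 0 or start + length > out.size:
            raise ValueError(f"run {run_idx} out of bounds: start={start + 1} length={length}")
        if out[start:start + length].any():
            raise ValueError(f"run {run_idx} overlaps a previous run")
        out[start:start + length] = True
    return out.reshape((height, width), order="F")


# ---------------------------------------------------------------------------
# Prediction records

@dataclass
class PredictionRecord:
    """One cell's output row: probabilities plus its visual-integrity weight."""

    image_id: str
    cell_id: int
    rle_mask: str
    class_probs: np.ndarray
    w_v: float = 1.0

    def validate(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if p.ndim != 1:
            raise ValueError("class_probs must be a vector")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("class probabilities outside [0, 1]")
        if not 0.0 <= self.w_v <= 1.0:
            raise ValueError("W_v outside [0, 1]")


def write_predictions(records: list[PredictionRecord], path: str) -> None:
    """Write prediction records as CSV with a stable column order.

    Probabilities are serialised with 9 significant digits so a read-back
    reproduces them well within 1e-6.
    """
    bad = []
    for i, rec in enumerate(records):
        try:
            rec.validate()
        except ValueError as exc:
            bad.append(f"row {i} (image {rec.image_id}, cell {rec.cell_id}): {exc}")
    if bad:
        raise ValueError("invalid prediction record(s):\n" + "\n".join(bad))
    n_classes = len(records[0].class_probs) if records else 0
    columns = ["image_id", "cell_id", "rle_mask", "w_v"] + [f"prob_{c}" for c in range(n_classes)]
    rows = []
    for rec in records:
        row = {
            "image_id": rec.image_id,
            "cell_id": rec.cell_id,
            "rle_mask": rec.rle_mask,
            "w_v": f"{rec.w_v:.9g}",
        }
        for c, p in enumerate(np.asarray(rec.class_probs, dtype=float)):
            row[f"prob_{c}"] = f"{p:.9g}"
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_predictions(path: str) -> list[PredictionRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    prob_cols = sorted(
        (c for c in frame.columns if c.startswith("prob_")),
        key=lambda c: int(c.split("_")[1]),
    )
    records = []
    for _, row in frame.iterrows():
        records.append(
            PredictionRecord(
                image_id=str(row["image_id"]),
                cell_id=int(row["cell_id"]),
                rle_mask=str(row["rle_mask"]),
                class_probs=np.array([float(row[c]) for c in prob_cols]),
                w_v=float(row["w_v"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Label manifests

def labels_to_field(indices: np.ndarray | list[int]) -> str:
    return "|".join(str(int(i)) for i in indices)


def field_to_labels(field: str, n_classes: int) -> np.ndarray:
    vec = np.zeros(n_classes, dtype=np.float32)
    if field:
        for tok in str(field).split("|"):
            vec[int(tok)] = 1.0
    return vec


def write_label_manifest(path: str, rows: list[tuple[str, int, np.ndarray]],
                         float_labels: bool = False) -> None:
    """Write (image_id, cell_id, labels) rows.

    Binary labels are stored as pipe-separated class indices; continuous
    labels (post-refinement) as pipe-separated ``index:value`` pairs.
    """
    out = []
    for image_id, cell_id, vec in rows:
        vec = np.asarray(vec)
        if float_labels:
            field = "|".join(
                f"{c}:{vec[c]:.9g}" for c in np.flatnonzero(vec > 0)
            )
        else:
            field = labels_to_field(np.flatnonzero(vec > 0))
        out.append({"image_id": image_id, "cell_id": cell_id, "labels": field})
    pd.DataFrame(out, columns=["image_id", "cell_id", "labels"]).to_csv(path, index=False)


def save_dataset(manifest, directory: str) -> None:
    """Write a generated dataset in the on-disk layout the pipeline consumes.

    Channel PNGs and 16-bit instance-label PNGs per image, ``cells.csv``
    (ground-truth cell labels), ``images.csv`` (union labels) and
    ``meta.json`` (provenance).
    """
    import json

    img_dir = os.path.join(directory, "images")
    mask_dir = os.path.join(directory, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    for image, labels in zip(manifest.images, manifest.instance_masks):
        write_channel_image(image, img_dir)
        write_instance_mask(labels, os.path.join(mask_dir, f"{image.image_id}_mask.png"))
    cell_rows = [(iid, cid, vec) for (iid, cid), vec
                 in zip(manifest.cell_index, manifest.cell_labels)]
    write_label_manifest(os.path.join(directory, "cells.csv"), cell_rows)
    image_rows = [(img.image_id, 0, vec) for img, vec
                  in zip(manifest.images, manifest.image_labels)]
    write_label_manifest(os.path.join(directory, "images.csv"), image_rows)
    meta = {
        "n_classes": int(manifest.n_classes),
        "image_ids": [img.image_id for img in manifest.images],
        "capture_ratios": [float(r) for r in manifest.capture_ratios],
        "provenance": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in manifest.provenance.get("config", {}).items()},
        "seed": manifest.provenance.get("seed"),
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_dataset(directory: str):
    """Read a dataset written by :func:`save_dataset`."""
    import json

    from .data import DatasetManifest

    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    n_classes = meta["n_classes"]
    images, instance_masks = [], []
    for image_id in meta["image_ids"]:
        paths = {name: os.path.join(directory, "images", f"{image_id}_{name}.png")
                 for name in CHANNEL_NAMES}
        images.append(read_channel_image(paths, image_id=image_id))
        instance_masks.append(
            read_instance_mask(os.path.join(directory, "masks", f"{image_id}_mask.png")))
    cells = read_label_manifest(os.path.join(directory, "cells.csv"), n_classes)
    image_frame = read_label_manifest(os.path.join(directory, "images.csv"), n_classes)
    by_id = {str(r["image_id"]): r["label_vector"] for _, r in image_frame.iterrows()}
    image_labels = np.stack([by_id[iid] for iid in meta["image_ids"]])
    cell_index = [(str(r["image_id"]), int(r["cell_id"])) for _, r in cells.iterrows()]
    return DatasetManifest(
        images=images,
        instance_masks=instance_masks,
        cell_labels=np.stack(list(cells["label_vector"])),
        image_labels=image_labels,
        cell_index=cell_index,
        capture_ratios=np.asarray(meta.get("capture_ratios",
                                           [1.0] * len(cell_index)), dtype=np.float32),
        provenance={"config": meta.get("provenance", {}), "seed": meta.get("seed")},
    )


def read_label_manifest(path: str, n_classes: int) -> pd.DataFrame:
    """Read a manifest; returns a frame with an expanded float label matrix."""
    frame = pd.read_csv(path, keep_default_na=False)
    mats = []
    for field in frame["labels"]:
        vec = np.zeros(n_classes, dtype=np.float32)
        if field:
            for tok in str(field).split("|"):
                if ":" in tok:
                    idx, val = tok.split(":")
                    vec[int(idx)] = float(val)
                else:
                    vec[int(tok)] = 1.0
        mats.append(vec)
    frame["label_vector"] = mats
    return frame
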