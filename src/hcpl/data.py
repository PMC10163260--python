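"""Core in-memory containers shared across the pipeline.

Images are four-channel fluorescence rasters with a fixed channel order:
nucleus, protein of interest, microtubules, endoplasmic reticulum.
Arrays are ``float32`` in ``[0, 255]`` (8-bit intensity scale) unless noted.
Coordinates are 0-based; bounding boxes are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order of every multi-channel image in the pipeline.
CHANNEL_NAMES: tuple[str, ...] = ("nucleus", "protein", "microtubules", "er")


@dataclass
class ChannelImage:
    """A four-channel raster of shape ``(4, H, W)``."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError(
                f"expected ({len(CHANNEL_NAMES)}, H, W) pixel array, got {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[CHANNEL_NAMES.index(name)]


@dataclass
class CellInstance:
    """One segmented cell: masked crop plus bookkeeping.

    ``crop`` has shape ``(4, h, w)`` with pixels outside ``mask`` zeroed,
    so neighbouring cells cannot leak into cell-level models. ``bbox`` is
    the half-open box of the crop within the parent image.
    """

    image_id: str
    cell_id: int
    crop: np.ndarray
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    capture_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.crop.shape[1:] != self.mask.shape:
            raise ValueError("crop and mask spatial shapes differ")

    @property
    def mask_area(self) -> int:
        return int(self.mask.sum())


@dataclass
class DatasetManifest:
    """A generated or loaded dataset with per-cell ground truth.

    ``cell_labels`` is the cells x C ground-truth matrix (withheld from
    training); ``weak_labels`` maps each image's union label onto every one
    of its cells, which is the supervision the pipeline actually trains on.
    ``cell_index`` aligns rows of the label matrices with (image, cell) ids.
    """

    images: list[ChannelImage]
    instance_masks: list[np.ndarray]
    cell_labels: np.ndarray
    image_labels: np.ndarray
    cell_index: list[tuple[str, int]]
    capture_ratios: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.cell_labels.shape[1]

    @property
    def n_cells(self) -> int:
        return self.cell_labels.shape[0]

    def image_label_of(self, image_id: str) -> np.ndarray:
        for img, lab in zip(self.images, self.image_labels):
            if img.image_id == image_id:
                return lab
        raise KeyError(image_id)

    @property
    def weak_labels(self) -> np.ndarray:
        """Image-level labels naively mapped to every cell of the image."""
        rows = np.empty_like(self.cell_labels)
        by_id = {img.image_id: lab for img, lab in zip(self.images, self.image_labels)}
        for i, (image_id, _) in enumerate(self.cell_index):
            rows[i] = by_id[image_id]
        return rows

    def cells_of(self, image_id: str) -> list[int]:
        return [i for i, (iid, _) in enumerate(self.cell_index) if iid == image_id]
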