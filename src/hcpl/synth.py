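"""Synthetic multi-cell fluorescence images with known per-cell ground truth.

The generator emulates the statistical structure of weakly labelled
subcellular-localisation data: several cells per image, per-cell multi-labels
over ``C`` classes drawn from an imbalanced frequency vector, image-level
labels formed as the union of the cell labels, and optional capture defects
(a contiguous angular sector of the cell body removed) for training the
visual-integrity models. It makes no attempt at photorealism — each class is
rendered as a distinct spatial pattern of the protein channel relative to the
nucleus so that classes are learnable by a small model.

Pattern vocabulary (class index -> pattern, cycling if ``C`` exceeds it):

====  =======================  ==========================================
idx   name                     protein-channel rendering
====  =======================  ==========================================
0     nuclear fill             uniform signal over the nucleus
1     nuclear rim              thin ring at the nucleus boundary
2     cytoplasmic fill         cell body minus the nucleus
3     punctate spots           small random puncta in the cytoplasm
4     perinuclear blob         single compact blob hugging the nucleus
5     cell rim                 thin ring at the cell boundary
6     radial filaments         spokes from the cell centre
7     nucleolar dots           two or three puncta inside the nucleus
====  =======================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import CellInstance, ChannelImage, DatasetManifest
from .vid import capture_class


class PlacementError(RuntimeError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset generator.

    Labels are hierarchical, mirroring how weak labelling arises in
    practice: each image (one stained protein) carries a small label set
    drawn from the imbalanced ``class_frequencies``, and every cell in the
    image expresses a nonempty subset of that set (``p_cell_keep`` per
    class, clipped to the ``labels_per_cell`` range). The image-level label
    is then the union of the cell labels by construction, and propagating
    it to every cell yields the characteristic false-positive weak labels.

    Defaults are the desk-scale study conditions used throughout the test
    suite: six imbalanced classes, one to three classes per image, eight to
    twelve cells in a 128 px image.
    """

    n_images: int = 20
    cells_per_image: tuple[int, int] = (8, 12)
    n_classes: int = 6
    class_frequencies: tuple[float, ...] | None = None
    labels_per_image: tuple[int, int] = (1, 3)
    labels_per_cell: tuple[int, int] = (1, 2)
    p_cell_keep: float = 0.6
    pattern_indices: tuple[int, ...] | None = None
    image_size: int = 128
    cell_radius: tuple[float, float] = (10.0, 15.0)
    intensity_noise_sd: float = 8.0
    defect_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.class_frequencies is None:
            # imbalanced geometric-style profile; the 0.75 ratio keeps the
            # largest frequency below 1/3 so that image label sets of up to
            # three classes have unclipped inclusion probabilities and cell
            # label marginals stay exactly proportional to the profile
            raw = np.array([0.75 ** k for k in range(self.n_classes)])
            self.class_frequencies = tuple(raw / raw.sum())
        freqs = np.asarray(self.class_frequencies, dtype=float)
        if len(freqs) != self.n_classes:
            raise ValueError("class_frequencies length must equal n_classes")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("class_frequencies must sum to 1")
        if (freqs < 0).any():
            raise ValueError("class_frequencies must be nonnegative")
        if not (1 <= self.labels_per_cell[0] <= self.labels_per_cell[1] <= self.n_classes):
            raise ValueError("labels_per_cell range must lie in [1, n_classes]")
        if not (1 <= self.labels_per_image[0] <= self.labels_per_image[1] <= self.n_classes):
            raise ValueError("labels_per_image range must lie in [1, n_classes]")
        if not 0.0 < self.p_cell_keep <= 1.0:
            raise ValueError("p_cell_keep must lie in (0, 1]")
        if self.pattern_indices is not None and len(self.pattern_indices) != self.n_classes:
            raise ValueError("pattern_indices length must equal n_classes")
        for name in ("n_images", "n_classes", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cells_per_image[0] < 1 or self.cells_per_image[0] > self.cells_per_image[1]:
            raise ValueError("invalid cells_per_image range")
        if self.cell_radius[0] <= 0 or self.cell_radius[0] > self.cell_radius[1]:
            raise ValueError("invalid cell_radius range")


# ---------------------------------------------------------------------------
# pattern registry

def _ring(mask: np.ndarray, width: int) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, iterations=width)


def _puncta(region: np.ndarray, rng: np.random.Generator, n: int, radius: int) -> np.ndarray:
    out = np.zeros_like(region)
    coords = np.argwhere(region)
    if len(coords) == 0:
        return out
    picks = coords[rng.integers(0, len(coords), size=n)]
    h, w = region.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for r, c in picks:
        out |= (yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2
    return out & region


def _pattern_nuclear_fill(cell, nucleus, rng, geom):
    return nucleus.astype(float)


def _pattern_nuclear_rim(cell, nucleus, rng, geom):
    return _ring(nucleus, 2).astype(float)


def _pattern_cytoplasm(cell, nucleus, rng, geom):
    return (cell & ~nucleus).astype(float)


def _pattern_puncta(cell, nucleus, rng, geom):
    return _puncta(cell & ~nucleus, rng, n=10, radius=2).astype(float)


def _pattern_perinuclear(cell, nucleus, rng, geom):
    cy, cx, rad = geom
    h, w = cell.shape
    ang = rng.uniform(0, 2 * np.pi)
    br = 0.55 * rad
    by, bx = cy + 0.55 * rad * np.sin(ang), cx + 0.55 * rad * np.cos(ang)
    yy, xx = np.mgrid[0:h, 0:w]
    blob = (yy - by) ** 2 + (xx - bx) ** 2 <= (0.4 * br) ** 2
    return (blob & cell & ~nucleus).astype(float)


def _pattern_cell_rim(cell, nucleus, rng, geom):
    return _ring(cell, 2).astype(float)


def _pattern_filaments(cell, nucleus, rng, geom):
    cy, cx, _ = geom
    h, w = cell.shape
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    phase = rng.uniform(0, 2 * np.pi)
    spokes = np.cos(6 * (theta + phase)) > 0.82
    return (spokes & cell & ~nucleus).astype(float)


def _pattern_nucleolar(cell, nucleus, rng, geom):
    inner = ndimage.binary_erosion(nucleus, iterations=2)
    return _puncta(inner, rng, n=3, radius=2).astype(float)


PATTERN_REGISTRY = (
    _pattern_nuclear_fill,
    _pattern_nuclear_rim,
    _pattern_cytoplasm,
    _pattern_puncta,
    _pattern_perinuclear,
    _pattern_cell_rim,
    _pattern_filaments,
    _pattern_nucleolar,
)


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _full_ellipse_area(cy: float, cx: float, a: float, b: float,
                       theta: float) -> int:
    """Pixel count of the unclipped ellipse (same rasterisation rule)."""
    r = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    dy = yy - (cy - np.floor(cy))
    dx = xx - (cx - np.floor(cx))
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return int(((u / a) ** 2 + (v / b) ** 2 <= 1.0).sum())


def remove_sector(mask: np.ndarray, keep_fraction: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Remove a contiguous angular sector so that ``keep_fraction`` remains.

    The sector is taken about the mask centroid starting at a random angle;
    the number of removed pixels is chosen by exact count, so the retained
    area matches ``keep_fraction`` up to integer rounding.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return mask.copy()
    coords = np.argwhere(mask)
    cy, cx = coords.mean(axis=0)
    angles = np.arctan2(coords[:, 0] - cy, coords[:, 1] - cx)
    start = rng.uniform(-np.pi, np.pi)
    rel = np.mod(angles - start, 2 * np.pi)
    n_remove = int(round((1.0 - keep_fraction) * len(coords)))
    order = np.argsort(rel)
    removed = coords[order[:n_remove]]
    out = mask.copy()
    out[removed[:, 0], removed[:, 1]] = False
    return out


def corrupt_cell(cell: CellInstance, keep_fraction: float,
                 rng_seed: int) -> tuple[CellInstance, int]:
    """Simulate a capture defect on one cell.

    Removes a boundary-adjacent angular sector of the cell body so that
    approximately ``keep_fraction`` of the mask area remains, zeroing the
    corresponding crop pixels. Returns the corrupted cell and its capture
    class (the bin of the retained fraction).
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    new_mask = remove_sector(cell.mask, keep_fraction, rng)
    crop = cell.crop.copy()
    crop[:, ~new_mask] = 0.0
    retained = (1.0 if keep_fraction == 1.0
                else new_mask.sum() / max(cell.mask.sum(), 1))
    out = CellInstance(
        image_id=cell.image_id,
        cell_id=cell.cell_id,
        crop=crop,
        mask=new_mask,
        bbox=cell.bbox,
        # total captured fraction compounds any pre-existing truncation
        capture_ratio=float(cell.capture_ratio * retained),
    )
    return out, capture_class(float(retained))


# ---------------------------------------------------------------------------
# dataset generation

def _pps_without_replacement(rng: np.random.Generator, freqs: np.ndarray,
                             k: int) -> list[int]:
    """Draw ``k`` distinct classes with inclusion probability ~ ``k * freqs``.

    Systematic probability-proportional-to-size sampling on a randomly
    permuted class order; inclusion probabilities are exact, so the class
    marginal of image label sets is proportional to ``freqs``.
    """
    pi = k * freqs.astype(float)
    # clip at 1 and push the excess onto the unclipped classes
    for _ in range(len(freqs)):
        over = pi > 1.0
        if not over.any():
            break
        excess = (pi[over] - 1.0).sum()
        pi[over] = 1.0
        free = ~over
        if pi[free].sum() > 0:
            pi[free] += excess * pi[free] / pi[free].sum()
    perm = rng.permutation(len(freqs))
    cum = np.concatenate([[0.0], np.cumsum(pi[perm])])
    u = rng.uniform()
    picks = set()
    for m in range(k):
        j = int(np.searchsorted(cum, u + m, side="left")) - 1
        picks.add(int(perm[min(j, len(freqs) - 1)]))
    return sorted(picks)


def sample_image_label_set(rng: np.random.Generator, config: SynthConfig) -> list[int]:
    """The label set of one image (one stained protein)."""
    freqs = np.asarray(config.class_frequencies, dtype=float)
    k = int(rng.integers(config.labels_per_image[0],
                         min(config.labels_per_image[1], config.n_classes) + 1))
    return _pps_without_replacement(rng, freqs, k)


def sample_cell_label_rows(rng: np.random.Generator, config: SynthConfig,
                           image_classes: list[int], n_cells: int) -> np.ndarray:
    """Per-cell subsets of an image's label set.

    Each cell keeps each image class with probability ``p_cell_keep``;
    cell label counts are clipped to the ``labels_per_cell`` range by
    symmetric (uniform) additions or removals, and every image class is
    guaranteed to appear in at least one cell so the union property holds
    by construction.
    """
    lo = min(config.labels_per_cell[0], len(image_classes))
    hi = min(config.labels_per_cell[1], len(image_classes))
    rows = np.zeros((n_cells, config.n_classes), dtype=np.float32)
    chosen: list[set[int]] = []
    for i in range(n_cells):
        keep = {c for c in image_classes if rng.uniform() < config.p_cell_keep}
        pool = [c for c in image_classes if c not in keep]
        while len(keep) < lo and pool:
            keep.add(pool.pop(int(rng.integers(len(pool)))))
        while len(keep) > hi:
            keep.discard(list(keep)[int(rng.integers(len(keep)))])
        chosen.append(keep)
    covered = set().union(*chosen) if chosen else set()
    for c in image_classes:
        if c not in covered:
            chosen[int(rng.integers(n_cells))].add(c)
    for i, keep in enumerate(chosen):
        rows[i, sorted(keep)] = 1.0
    return rows


def _place_cells(rng: np.random.Generator, config: SynthConfig,
                 n_cells: int) -> list[tuple[np.ndarray, tuple[float, float, float]]]:
    size = config.image_size
    occupied = np.zeros((size, size), dtype=bool)
    cells = []
    for _ in range(n_cells):
        placed = False
        for _attempt in range(300):
            a = rng.uniform(*config.cell_radius)
            b = rng.uniform(*config.cell_radius)
            theta = rng.uniform(0, np.pi)
            margin = 2.0  # centres stay on-canvas; masks may clip at borders
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            mask = _ellipse_mask(size, cy, cx, a, b, theta)
            if mask.sum() < 20:
                continue
            if not (mask & occupied).any():
                occupied |= mask
                visible = mask.sum() / max(_full_ellipse_area(cy, cx, a, b, theta), 1)
                cells.append((mask, (cy, cx, max(a, b)), min(float(visible), 1.0)))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {n_cells} non-overlapping cells of radius "
                f"{config.cell_radius} in a {size}x{size} image"
            )
    return cells


def _render_cell(channels: np.ndarray, mask: np.ndarray, geom, labels: np.ndarray,
                 rng: np.random.Generator,
                 pattern_indices: tuple[int, ...] | None = None) -> None:
    cy, cx, rad = geom
    nucleus = _ellipse_mask(channels.shape[1], cy, cx, 0.45 * rad, 0.45 * rad, 0.0) & mask
    if not nucleus.any():  # degenerate sliver: fall back to eroded body
        nucleus = ndimage.binary_erosion(mask, iterations=2)
    channels[0][nucleus] += 200.0
    channels[2][mask] += 60.0 * _pattern_filaments(mask, np.zeros_like(mask), rng, geom)[mask]
    channels[2][mask] += 25.0
    channels[3][mask & ~nucleus] += 45.0
    protein = np.zeros(mask.shape, dtype=float)
    for c in np.flatnonzero(labels):
        idx = pattern_indices[c] if pattern_indices is not None else c
        f = PATTERN_REGISTRY[idx % len(PATTERN_REGISTRY)]
        protein = np.maximum(protein, f(mask, nucleus, rng, geom))
    channels[1] += 190.0 * protein


def generate_dataset(config: SynthConfig) -> DatasetManifest:
    """Generate a full synthetic dataset with ground truth and weak labels.

    Deterministic for a fixed ``config.rng_seed``. Image-level labels are
    the elementwise OR of the image's per-cell ground-truth labels; per-cell
    masks are disjoint by construction.
    """
    rng = np.random.default_rng(config.rng_seed)
    images: list[ChannelImage] = []
    instance_masks: list[np.ndarray] = []
    cell_rows: list[np.ndarray] = []
    image_rows: list[np.ndarray] = []
    cell_index: list[tuple[str, int]] = []
    capture_ratios: list[float] = []

    for i in range(config.n_images):
        image_id = f"img{i:04d}"
        n_cells = int(rng.integers(config.cells_per_image[0],
                                   config.cells_per_image[1] + 1))
        placed = _place_cells(rng, config, n_cells)
        image_classes = sample_image_label_set(rng, config)
        cell_rows_img = sample_cell_label_rows(rng, config, image_classes, n_cells)
        size = config.image_size
        channels = np.zeros((4, size, size), dtype=np.float64)
        labels_raster = np.zeros((size, size), dtype=np.int32)
        img_label = np.zeros(config.n_classes, dtype=np.float32)
        for j, (mask, geom, visible) in enumerate(placed):
            # captured fraction: border clipping at placement, compounded by
            # a simulated capture defect when one is drawn
            ratio = visible
            if config.defect_rate > 0 and rng.uniform() < config.defect_rate:
                keep = rng.uniform(0.15, 0.75)
                mask = remove_sector(mask, keep, rng)
                ratio = float(visible * keep)
            labels = cell_rows_img[j]
            _render_cell(channels, mask, geom, labels, rng,
                         pattern_indices=config.pattern_indices)
            labels_raster[mask] = j + 1
            cell_rows.append(labels)
            cell_index.append((image_id, j + 1))
            capture_ratios.append(ratio)
            img_label = np.maximum(img_label, labels)
        noise = rng.normal(0.0, config.intensity_noise_sd, size=channels.shape)
        channels = np.clip(channels + noise, 0.0, 255.0).astype(np.float32)
        images.append(ChannelImage(channels, image_id=image_id))
        instance_masks.append(labels_raster)
        image_rows.append(img_label)

    return DatasetManifest(
        images=images,
        instance_masks=instance_masks,
        cell_labels=np.stack(cell_rows),
        image_labels=np.stack(image_rows),
        cell_index=cell_index,
        capture_ratios=np.asarray(capture_ratios, dtype=np.float32),
        provenance={"config": config.__dict__.copy(), "seed": config.rng_seed},
    )


def reference_config(seed: int = 0, n_images: int = 200, defect_rate: float = 0.0) -> SynthConfig:
    """The reference benchmark conditions: imbalanced six-class images of
    twelve cells each, weak labels by union."""
    return SynthConfig(
        n_images=n_images,
        cells_per_image=(12, 12),
        n_classes=6,
        class_frequencies=(0.32, 0.24, 0.17, 0.12, 0.09, 0.06),
        labels_per_cell=(1, 2),
        image_size=128,
        cell_radius=(10.0, 14.0),
        intensity_noise_sd=8.0,
        defect_rate=defect_rate,
        rng_seed=seed,
    )
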