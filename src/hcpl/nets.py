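"""Model families, losses and training.

Three classifier families operate on masked cell crops:

* **DSA** (dual-stream): a shared trunk plus Weibull activation pooling
  produces one descriptor per cell; the image stream max-pools a bag of
  descriptors from one image and classifies the population, while the cell
  stream classifies each descriptor. Trained on the weighted sum
  ``L_f = W1 * L_image + W2 * L_cell`` with ``(W1, W2) = (1, 0.2)`` in the
  first round (weak cell labels) and ``(1, 1)`` after label refinement.
* **CLA** (cell-level actnet): trunk -> Weibull activation -> global average
  pooling -> power normalisation -> logistic head.
* **CLH** (cell-level hybrid): the CLA trunk with hybrid-fusion blocks that
  inject wavelet-scattering coefficients of the input after the early
  downsampling stages.

Multi-label heads are elementwise logistic (independent per-class
probabilities), the form required by binary cross-entropy on multi-label
targets; a softmax head is available for single-label tasks such as the
capture-ratio classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import transform as sk_transform

from .actpool import (GlobalAvgPoolLayer, PowerNormLayer, PowerNormParams,
                      WeibullActivationLayer, WeibullParams)
from .nn import (Adam, Conv2d, Linear, Module, Parameter, ReLU, Sequential,
                 cosine_lr, sigmoid, softmax, softmax_cross_entropy)
from .scattering import Scattering2D

_P_CLIP = 1e-7


# ---------------------------------------------------------------------------
# specs and configs

@dataclass
class BackboneSpec:
    """Configuration of a convolutional trunk.

    The default is the full desk-scale trunk (four stride-2 blocks, 128-d
    features on 128 px inputs); tests and benchmarks shrink it through the
    same interface.
    """

    family: str = "small-conv"
    input_size: int = 128
    feature_dim: int = 128
    n_blocks: int = 4
    base_channels: int = 16
    in_channels: int = 4

    def __post_init__(self) -> None:
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be at least 8")
        if self.family != "small-conv":
            raise ValueError(f"unknown backbone family '{self.family}'")

    def block_channels(self) -> list[int]:
        chans = [int(round(self.base_channels * 2 ** i)) for i in range(self.n_blocks)]
        chans[-1] = self.feature_dim
        return chans


@dataclass
class LossWeights:
    """Stream weights of the dual-stream loss, keyed by training round."""

    w_image: float = 1.0
    w_cell: float = 0.2
    round: int = 1

    @classmethod
    def for_round(cls, round: int) -> "LossWeights":
        if round == 1:
            return cls(1.0, 0.2, 1)
        if round == 2:
            return cls(1.0, 1.0, 2)
        raise ValueError("round must be 1 or 2")


@dataclass
class TrainConfig:
    epochs: int = 6
    batch_size: int = 64
    lr0: float = 2e-4
    lr_floor: float = 1e-6
    seed: int = 0
    use_focal: bool = True
    focal_gamma: float = 2.0
    augment: bool = True
    p_flip: float = 0.5
    p_rot90: float = 0.5
    p_shift: float = 0.5
    max_shift: int = 2
    p_cutout: float = 0.3


@dataclass
class CellBag:
    """A fixed-size batch of cell crops drawn from one image."""

    crops: np.ndarray            # (N, 4, s, s)
    cell_indices: np.ndarray     # indices into the parent cell table
    image_id: str = ""

    def __post_init__(self) -> None:
        if len(self.crops) < 1:
            raise ValueError("a bag needs at least one cell")


def make_bag(crops: np.ndarray, n: int, rng: np.random.Generator,
             image_id: str = "") -> CellBag:
    """Sample a bag of exactly ``n`` cells: without replacement when the
    image has more, with replacement when it has fewer."""
    m = len(crops)
    if m >= n:
        idx = rng.choice(m, size=n, replace=False)
    else:
        idx = rng.choice(m, size=n, replace=True)
    return CellBag(crops=crops[idx], cell_indices=idx, image_id=image_id)


# ---------------------------------------------------------------------------
# losses (functional, probability-level)

def class_weights_from_frequencies(freqs: np.ndarray, cap_factor: float = 100.0) -> np.ndarray:
    """Inverse-frequency class weights, capped and normalised to mean 1.

    Zero-frequency classes inherit the cap (``cap_factor`` times the median
    uncapped weight) instead of an infinite weight.
    """
    freqs = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore"):
        w = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    finite = w[np.isfinite(w)]
    cap = cap_factor * (np.median(finite) if len(finite) else 1.0)
    w = np.minimum(w, cap)
    return w / w.mean()


def weighted_bce(probs: np.ndarray, targets: np.ndarray,
                 class_weights: np.ndarray | None = None) -> float:
    """Mean over cells of the class-weighted binary cross-entropy sum."""
    p = np.clip(np.asarray(probs, dtype=float), _P_CLIP, 1 - _P_CLIP)
    t = np.asarray(targets, dtype=float)
    w = np.ones(p.shape[-1]) if class_weights is None else np.asarray(class_weights, float)
    ce = -(t * np.log(p) + (1 - t) * np.log(1 - p))
    return float((ce * w).sum(axis=-1).mean())


def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma_f: float = 2.0) -> float:
    """Focal modulation ``(1 - p_t)^gamma`` of the binary cross-entropy."""
    if gamma_f < 0:
        raise ValueError("gamma_f must be nonnegative")
    p = np.clip(np.asarray(probs, dtype=float), _P_CLIP, 1 - _P_CLIP)
    t = np.asarray(targets, dtype=float)
    loss = -(t * (1 - p) ** gamma_f * np.log(p)
             + (1 - t) * p ** gamma_f * np.log(1 - p))
    return float(loss.sum(axis=-1).mean())


def combined_loss(l_image: float, l_cell: float, w: LossWeights) -> float:
    """``L_f = W_image * L1 + W_cell * L2``."""
    if not (np.isfinite(l_image) and np.isfinite(l_cell)):
        raise ValueError("losses must be finite")
    return w.w_image * l_image + w.w_cell * l_cell


def _multilabel_loss_grad(logits: np.ndarray, targets: np.ndarray,
                          class_weights: np.ndarray | None,
                          use_focal: bool, focal_gamma: float):
    """Weighted BCE (plus optional focal term) and its gradient in logits."""
    p = sigmoid(logits)
    t = np.asarray(targets, dtype=float)
    n = logits.shape[0]
    w = np.ones(logits.shape[-1]) if class_weights is None else class_weights
    loss = weighted_bce(p, t, w)
    dz = w * (p - t) / n
    if use_focal:
        pc = np.clip(p, _P_CLIP, 1 - _P_CLIP)
        g = focal_gamma
        loss += focal_loss(pc, t, g)
        dldp = (t * (g * (1 - pc) ** (g - 1) * np.log(pc) - (1 - pc) ** g / pc)
                - (1 - t) * (g * pc ** (g - 1) * np.log(1 - pc) - pc ** g / (1 - pc)))
        dz += dldp * pc * (1 - pc) / n
    return loss, dz


# ---------------------------------------------------------------------------
# trunks and models

def build_trunk(spec: BackboneSpec, rng: np.random.Generator) -> list[Sequential]:
    """The convolutional stages of a trunk, one stride-2 block per stage."""
    stages = []
    c_in = spec.in_channels
    for c_out in spec.block_channels():
        stages.append(Sequential(Conv2d(c_in, c_out, k=3, stride=2, pad=1, rng=rng),
                                 ReLU()))
        c_in = c_out
    return stages


def _pooling_head(spec: BackboneSpec, n_classes: int, rng: np.random.Generator,
                  per_channel: bool, zero_head: bool):
    pool = Sequential(
        WeibullActivationLayer(spec.feature_dim, per_channel=per_channel),
        GlobalAvgPoolLayer(),
        PowerNormLayer(),
    )
    head = Linear(spec.feature_dim, n_classes, rng=rng, zero_init=zero_head)
    return pool, head


class CLAModel:
    """Cell-level actnet: trunk -> Weibull pooling -> logistic head."""

    def __init__(self, spec: BackboneSpec, n_classes: int, seed: int = 0,
                 per_channel: bool = False, zero_head: bool = False) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_classes = n_classes
        self.trunk = Sequential(*(layer for st in build_trunk(spec, rng)
                                  for layer in st.layers))
        self.pool, self.head = _pooling_head(spec, n_classes, rng, per_channel, zero_head)
        self.net = Sequential(self.trunk, self.pool, self.head)

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()

    def forward_logits(self, crops: np.ndarray) -> np.ndarray:
        self._check_input(crops)
        return self.net.forward(crops)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def predict_probs(self, crops: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(crops), batch_size):
            out.append(sigmoid(self.forward_logits(crops[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def _check_input(self, crops: np.ndarray) -> None:
        if crops.ndim != 4 or crops.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected (B, {self.spec.in_channels}, s, s) crops, got {crops.shape}"
            )


def cla_forward(crop: np.ndarray, model: CLAModel) -> np.ndarray:
    """Probability vector for a single crop (spec-level convenience)."""
    return sigmoid(model.forward_logits(crop[None]))[0]


class HybridFusionBlock(Module):
    """Inject scattering coefficients into a trunk feature map.

    The (pre-resized) coefficient stack is projected to the trunk width by a
    learnable 1x1 convolution, concatenated with the deep features, reduced
    back to the trunk width by a second 1x1 convolution, and added
    residually. Zeroing the projection makes the block a function of the
    deep features alone; the output shape always equals the trunk shape, so
    the block is insertion-transparent.
    """

    def __init__(self, scat_channels: int, trunk_channels: int,
                 rng: np.random.Generator) -> None:
        self.proj = Conv2d(scat_channels, trunk_channels, k=1, pad=0, rng=rng)
        self.reduce = Conv2d(2 * trunk_channels, trunk_channels, k=1, pad=0, rng=rng)
        self.relu = ReLU()
        self.c = trunk_channels
        self._scat: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return self.proj.parameters() + self.reduce.parameters()

    def set_scattering(self, scat: np.ndarray) -> None:
        self._scat = scat

    def forward(self, deep: np.ndarray) -> np.ndarray:
        if self._scat is None:
            raise RuntimeError("scattering input not set")
        if self._scat.shape[2:] != deep.shape[2:]:
            raise ValueError("scattering stack not resized to the trunk grid")
        mixed = self.proj.forward(self._scat)
        cat = np.concatenate([deep, mixed], axis=1)
        return deep + self.relu.forward(self.reduce.forward(cat))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dcat = self.reduce.backward(self.relu.backward(grad))
        self.proj.backward(dcat[:, self.c:])  # filters are fixed inputs: stop here
        return grad + dcat[:, :self.c]


class CLHModel:
    """Cell-level hybrid: CLA trunk with scattering fusion blocks.

    ``insert_after`` names the trunk stages (0-based) after which fusion
    blocks sit; the default is after the first and second downsampling
    stages. With ``use_fusion=False`` the model is weight-compatible with
    the plain trunk, giving a clean ablation path.
    """

    def __init__(self, spec: BackboneSpec, n_classes: int, seed: int = 0,
                 J: int = 2, L: int = 4, insert_after: tuple[int, ...] = (0, 1),
                 use_fusion: bool = True) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_classes = n_classes
        self.use_fusion = use_fusion
        self.stages = build_trunk(spec, rng)
        self.scattering = Scattering2D(spec.input_size, J=J, L=L, order=2)
        self.insert_after = tuple(insert_after)
        scat_ch = spec.in_channels * self.scattering.n_paths
        chans = spec.block_channels()
        self.fusion = {i: HybridFusionBlock(scat_ch, chans[i], rng)
                       for i in self.insert_after}
        self.pool, self.head = _pooling_head(spec, n_classes, rng,
                                             per_channel=False, zero_head=False)
        self._order: list[Module] = []

    def parameters(self) -> list[Parameter]:
        params = [p for st in self.stages for p in st.parameters()]
        if self.use_fusion:
            for blk in self.fusion.values():
                params += blk.parameters()
        return params + self.pool.parameters() + self.head.parameters()

    def _resized_scat(self, scat: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
        if scat.shape[2:] == hw:
            return scat
        fy = hw[0] // scat.shape[2]
        if fy >= 1 and hw[0] % scat.shape[2] == 0:
            return scat.repeat(fy, axis=2).repeat(hw[1] // scat.shape[3], axis=3)
        out = np.empty(scat.shape[:2] + hw)
        for b in range(scat.shape[0]):
            for c in range(scat.shape[1]):
                out[b, c] = sk_transform.resize(scat[b, c], hw, order=0,
                                                preserve_range=True,
                                                anti_aliasing=False)
        return out

    def forward_logits(self, crops: np.ndarray) -> np.ndarray:
        if crops.shape[1] != self.spec.in_channels:
            raise ValueError("wrong channel count")
        scat = self.scattering.transform_batch(crops) if self.use_fusion else None
        x = crops
        self._order = []
        for i, stage in enumerate(self.stages):
            x = stage.forward(x)
            self._order.append(stage)
            if self.use_fusion and i in self.fusion:
                blk = self.fusion[i]
                blk.set_scattering(self._resized_scat(scat, x.shape[2:]))
                x = blk.forward(x)
                self._order.append(blk)
        x = self.pool.forward(x)
        self._order.append(self.pool)
        x = self.head.forward(x)
        self._order.append(self.head)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self._order):
            grad = layer.backward(grad)

    def predict_probs(self, crops: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(crops), batch_size):
            out.append(sigmoid(self.forward_logits(crops[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))


class DSAModel:
    """Dual-stream actnet over bags of cells from one image."""

    def __init__(self, spec: BackboneSpec, n_classes: int, seed: int = 0,
                 zero_head: bool = False) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_classes = n_classes
        trunk_layers = [layer for st in build_trunk(spec, rng) for layer in st.layers]
        pool, _ = _pooling_head(spec, n_classes, rng, per_channel=False,
                                zero_head=zero_head)
        self.shared = Sequential(Sequential(*trunk_layers), pool)
        self.image_head = Linear(spec.feature_dim, n_classes, rng=rng,
                                 zero_init=zero_head)
        self.cell_head = Linear(spec.feature_dim, n_classes, rng=rng,
                                zero_init=zero_head)
        self._argmax: np.ndarray | None = None
        self._n: int = 0

    def parameters(self) -> list[Parameter]:
        return (self.shared.parameters() + self.image_head.parameters()
                + self.cell_head.parameters())

    def forward_logits(self, bag_crops: np.ndarray):
        """Logits of both streams for one bag: ``((C,), (N, C))``."""
        if len(bag_crops) < 1:
            raise ValueError("a bag needs at least one cell")
        desc = self.shared.forward(bag_crops)            # (N, D)
        self._argmax = desc.argmax(axis=0)               # winner per feature
        self._n = len(desc)
        v = desc[self._argmax, np.arange(desc.shape[1])]  # global max pooling
        image_logits = self.image_head.forward(v[None])[0]
        cell_logits = self.cell_head.forward(desc)
        return image_logits, cell_logits

    def backward(self, d_image_logits: np.ndarray, d_cell_logits: np.ndarray) -> None:
        dv = self.image_head.backward(d_image_logits[None])[0]
        ddesc = self.cell_head.backward(d_cell_logits)
        ddesc[self._argmax, np.arange(len(dv))] += dv  # max routes to winners
        self.shared.backward(ddesc)

    def predict(self, bag_crops: np.ndarray):
        """Probabilities of both streams: ``((C,), (N, C))``."""
        img_logits, cell_logits = self.forward_logits(bag_crops)
        return sigmoid(img_logits), sigmoid(cell_logits)


def dsa_forward(bag: CellBag, model: DSAModel):
    """Spec-level wrapper: image and cell probabilities for a bag."""
    return model.predict(bag.crops)


# ---------------------------------------------------------------------------
# softmax classifier for single-label tasks (capture-ratio model)

class SoftmaxClassifier:
    """Trunk + GAP + linear head with softmax output."""

    def __init__(self, spec: BackboneSpec, n_classes: int, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.n_classes = n_classes
        layers = [layer for st in build_trunk(spec, rng) for layer in st.layers]
        self.net = Sequential(Sequential(*layers), GlobalAvgPoolLayer(),
                              Linear(spec.feature_dim, n_classes, rng=rng))

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()

    def forward_logits(self, crops: np.ndarray) -> np.ndarray:
        return self.net.forward(crops)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits)

    def predict_probs(self, crops: np.ndarray, batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(crops), batch_size):
            out.append(softmax(self.forward_logits(crops[i:i + batch_size])))
        return np.concatenate(out) if out else np.empty((0, self.n_classes))


# ---------------------------------------------------------------------------
# augmentation

def augment_batch(crops: np.ndarray, rng: np.random.Generator,
                  cfg: TrainConfig) -> np.ndarray:
    """Random flips, quarter rotations, small shifts and cutout."""
    out = crops.copy()
    for i in range(len(out)):
        if rng.uniform() < cfg.p_flip:
            out[i] = out[i, :, :, ::-1]
        if rng.uniform() < cfg.p_flip:
            out[i] = out[i, :, ::-1, :]
        if rng.uniform() < cfg.p_rot90:
            out[i] = np.rot90(out[i], k=int(rng.integers(1, 4)), axes=(1, 2))
        if rng.uniform() < cfg.p_shift:
            dy = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
            dx = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
            out[i] = np.roll(out[i], (dy, dx), axis=(1, 2))
        if rng.uniform() < cfg.p_cutout:
            s = out.shape[-1]
            k = max(2, s // 4)
            y0 = int(rng.integers(0, s - k + 1))
            x0 = int(rng.integers(0, s - k + 1))
            out[i, :, y0:y0 + k, x0:x0 + k] = 0.0
    return out


# ---------------------------------------------------------------------------
# training loops

def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"training diverged ({context}): loss = {loss}")


def train_cell_model(model, crops: np.ndarray, targets: np.ndarray,
                     cfg: TrainConfig,
                     class_weights: np.ndarray | None = None) -> dict:
    """Train a cell-level model (CLA or CLH) on crops and multi-label targets.

    Adam with a cosine-annealed learning rate from ``cfg.lr0``; the history
    records per-epoch mean losses. Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    n = len(crops)
    history = {"epoch_loss": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_floor)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = crops[idx]
            if cfg.augment:
                batch = augment_batch(batch, rng, cfg)
            logits = model.forward_logits(batch)
            loss, dz = _multilabel_loss_grad(logits, targets[idx], class_weights,
                                             cfg.use_focal, cfg.focal_gamma)
            _check_finite(loss, f"epoch {epoch}")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        history["epoch_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
    return history


def train_dsa(model: DSAModel, image_bags: list[np.ndarray],
              image_targets: np.ndarray, bag_cell_targets: list[np.ndarray],
              cfg: TrainConfig, loss_weights: LossWeights,
              class_weights: np.ndarray | None = None,
              bag_size: int | None = None) -> dict:
    """Train the dual-stream model on per-image bags.

    ``image_bags[i]`` is the crop stack of image ``i``; each step samples a
    fixed-size bag, computes both stream losses and applies
    ``L_f = W1 * L_image + W2 * L_cell``.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    n_img = len(image_bags)
    history = {"epoch_loss": [], "epoch_l_image": [], "epoch_l_cell": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_floor)
        opt.lr = lr
        order = rng.permutation(n_img)
        tot, tot1, tot2 = [], [], []
        for i in order:
            crops = image_bags[i]
            n = bag_size or len(crops)
            bag = make_bag(crops, n, rng, image_id=str(i))
            batch = bag.crops
            if cfg.augment:
                batch = augment_batch(batch, rng, cfg)
            img_logits, cell_logits = model.forward_logits(batch)
            l1, dz1 = _multilabel_loss_grad(img_logits[None], image_targets[i][None],
                                            class_weights, cfg.use_focal,
                                            cfg.focal_gamma)
            l2, dz2 = _multilabel_loss_grad(cell_logits,
                                            bag_cell_targets[i][bag.cell_indices],
                                            class_weights, cfg.use_focal,
                                            cfg.focal_gamma)
            lf = combined_loss(l1, l2, loss_weights)
            _check_finite(lf, f"epoch {epoch}")
            opt.zero_grad()
            model.backward(loss_weights.w_image * dz1[0], loss_weights.w_cell * dz2)
            opt.step()
            tot.append(lf)
            tot1.append(l1)
            tot2.append(l2)
        history["epoch_loss"].append(float(np.mean(tot)))
        history["epoch_l_image"].append(float(np.mean(tot1)))
        history["epoch_l_cell"].append(float(np.mean(tot2)))
        history["lr"].append(lr)
    return history


def train_softmax_classifier(model: SoftmaxClassifier, crops: np.ndarray,
                             labels: np.ndarray, cfg: TrainConfig) -> dict:
    """Cross-entropy training for single-label classifiers."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr0)
    n = len(crops)
    history = {"epoch_loss": [], "lr": []}
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_floor)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            batch = crops[idx]
            if cfg.augment:
                batch = augment_batch(batch, rng, cfg)
            logits = model.forward_logits(batch)
            loss, dz = softmax_cross_entropy(logits, labels[idx])
            _check_finite(loss, f"epoch {epoch}")
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        history["epoch_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
    return history


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model, path: str, meta: dict | None = None) -> None:
    """Serialise all parameters (including activation-pooling scalars)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.parameters())}
    arrays["_meta"] = np.array([repr(meta or {})])
    np.savez(path, **arrays)


def load_model(model, path: str) -> None:
    """Load parameters into an architecture-compatible model in place."""
    data = np.load(path, allow_pickle=False)
    params = model.parameters()
    for i, p in enumerate(params):
        stored = data[f"p{i}"]
        if stored.shape != p.value.shape:
            raise ValueError(f"parameter {i} shape mismatch: "
                             f"{stored.shape} vs {p.value.shape}")
        p.value[...] = stored
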