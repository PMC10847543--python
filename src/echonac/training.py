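"""Preprocessing, augmentation and the seeded training loop.

Training hyperparameters default to the regime used for the clinical-scale
model: Adam with betas (0.5, 0.999), learning rate 0.002, batch size 4,
up to 100 epochs, images rescaled to a fixed 448x384 resolution; the
checkpoint with the best validation metric (mean lesion IoU by default) is
returned rather than the last epoch.  Smoke-scale runs shrink the image
size, channel widths and epoch count but keep the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .losses import LossWeights, hybrid_loss
from .model import SegmentationNetwork
from .nn import Adam, Tensor
from .segmetrics import confusion_counts, metrics_from_counts


@dataclass(frozen=True)
class AugmentConfig:
    crop: bool = True
    rotation: bool = True
    brightness: bool = True
    contrast: bool = True
    crop_fraction: float = 0.85     # minimum retained side fraction
    brightness_range: float = 0.1   # additive shift, intensity units
    contrast_range: float = 0.2     # multiplicative range around 1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-3
    batch_size: int = 4
    epochs: int = 100
    adam_betas: tuple[float, float] = (0.5, 0.999)
    input_size: tuple[int, int] = (448, 384)
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    checkpoint_metric: str = "iou"
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def preprocess(image, input_size: tuple[int, int] = (448, 384)) -> np.ndarray:
    """Rescale a grayscale image to the network resolution, intensities in [0,1].

    Aspect ratio is not preserved: the resolution is fixed, bilinear
    interpolation for images.
    """
    pixels = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    lo, hi = float(pixels.min()), float(pixels.max())
    if lo < 0 or hi > 1:  # e.g. 8-bit input
        pixels = (pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(pixels)
    if pixels.shape != tuple(input_size):
        pixels = resize(pixels, input_size, order=1, mode="edge",
                        anti_aliasing=pixels.shape[0] > input_size[0])
    return np.clip(pixels, 0.0, 1.0)


def _resize_mask(mask: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if mask.shape == tuple(size):
        return mask.astype(np.uint8)
    out = resize(mask.astype(np.float64), size, order=0, mode="edge",
                 anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def augment(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
            seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Co-apply geometric transforms to image and mask; photometric to image.

    Geometric: right-angle rotation (exact, mask-count preserving) and random
    crop-with-resize (nearest neighbour for the mask).  Photometric:
    brightness shift and contrast scaling, clipped to [0,1].
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    rng = np.random.default_rng([int(seed), 2**22])

    if config.rotation:
        k = int(rng.integers(0, 4))
        if image.shape[0] != image.shape[1]:
            # keep the grid shape: quarter-turns only for square images,
            # otherwise half-turns plus axis flips
            image, mask = np.rot90(image, 2 * (k // 2)), np.rot90(mask, 2 * (k // 2))
            if k % 2:
                image, mask = image[:, ::-1], mask[:, ::-1]
        else:
            image, mask = np.rot90(image, k), np.rot90(mask, k)

    if config.crop:
        h, w = image.shape
        fh = rng.uniform(config.crop_fraction, 1.0)
        fw = rng.uniform(config.crop_fraction, 1.0)
        ch, cw = max(int(round(fh * h)), 1), max(int(round(fw * w)), 1)
        if ch > h or cw > w:
            raise ValueError("crop larger than image")
        r0 = int(rng.integers(0, h - ch + 1))
        c0 = int(rng.integers(0, w - cw + 1))
        image = resize(image[r0:r0 + ch, c0:c0 + cw], (h, w), order=1, mode="edge",
                       anti_aliasing=False)
        mask = _resize_mask(mask[r0:r0 + ch, c0:c0 + cw], (h, w))

    if config.brightness:
        image = image + rng.uniform(-config.brightness_range, config.brightness_range)
    if config.contrast:
        scale = 1.0 + rng.uniform(-config.contrast_range, config.contrast_range)
        image = (image - 0.5) * scale + 0.5
    return np.clip(image, 0.0, 1.0), np.ascontiguousarray(mask)


@dataclass
class TrainingHistory:
    """Per-epoch train loss and validation metrics; best-checkpoint index."""

    train_loss: list[float] = field(default_factory=list)
    val_metric: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_metric(self) -> float:
        return self.val_metric[self.best_epoch]


def validation_iou(network: SegmentationNetwork, val_set,
                   threshold: float = 0.5) -> float:
    """Pooled-count lesion IoU over a validation set at the network resolution."""
    tp = fp = fn = tn = 0
    network.eval()
    size = network.config.input_size
    for image, mask in val_set:
        x = preprocess(image, size)
        t = _resize_mask(np.asarray(getattr(mask, "pixels", mask)), size)
        prob = network(Tensor(x[None, None].astype(np.float32))).data[0, 0]
        c = confusion_counts(prob >= threshold, t)
        tp, fp, fn, tn = tp + c.tp, fp + c.fp, fn + c.fn, tn + c.tn
    network.train()
    from .segmetrics import ConfusionCounts
    m = metrics_from_counts(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return 1.0 if np.isnan(m.iou) else m.iou


def train(network: SegmentationNetwork, train_set, val_set,
          loss_weights: LossWeights = LossWeights(),
          config: TrainConfig = TrainConfig()):
    """Fit the network, returning ``(network, history)`` with the best
    validation checkpoint restored.

    ``train_set``/``val_set`` are sequences of ``(image, mask)`` pairs (any
    resolution; they are rescaled to ``config.input_size``).  Aborts with a
    diagnostic on an empty dataset or a NaN loss.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    size = config.input_size
    xs = np.stack([preprocess(img, size) for img, _ in train_set]).astype(np.float32)
    ys = np.stack([_resize_mask(np.asarray(getattr(m, "pixels", m)), size)
                   for _, m in train_set]).astype(np.float32)

    optimizer = Adam(network.parameters(), lr=config.learning_rate,
                     betas=config.adam_betas)
    rng = np.random.default_rng([int(config.seed), 2**23])
    history = TrainingHistory()
    best_metric, best_state = -np.inf, network.state_dict()

    n = len(xs)
    network.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = np.empty((len(idx), *size), dtype=np.float32)
            yb = np.empty((len(idx), *size), dtype=np.float32)
            for k, i in enumerate(idx):
                aug_seed = int(rng.integers(2**31))
                xb[k], yb[k] = augment(xs[i], ys[i], config.augmentation, aug_seed)
            prob = network(Tensor(xb[:, None]))
            loss = hybrid_loss(prob, Tensor(yb[:, None]), loss_weights)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {value}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)
        history.train_loss.append(float(np.mean(losses)))
        metric = validation_iou(network, val_set, threshold=config.threshold)
        history.val_metric.append(metric)
        if metric > best_metric:
            best_metric, best_state = metric, network.state_dict()
            history.best_epoch = epoch
    network.load_state_dict(best_state)
    network.eval()
    return network, history


def split_by_patient(items, val_fraction: float = 0.2, seed: int = 0):
    """Seeded 80/20 split (no overlap between the two subsets)."""
    idx = np.random.default_rng([int(seed), 2**24]).permutation(len(items))
    n_val = max(1, int(round(val_fraction * len(items))))
    val_ids = set(idx[:n_val].tolist())
    train_items = [it for i, it in enumerate(items) if i not in val_ids]
    val_items = [it for i, it in enumerate(items) if i in val_ids]
    return train_items, val_items
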