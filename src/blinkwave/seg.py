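"""Eyelid-region segmentation: U-Net, Dice-loss training, IPH extraction.

The segmentation target is the interpalpebral region — the closed area
between the upper and lower eyelid margins.  The network is the classic
U-Net: an encoder of four (conv 3×3 ×2, max-pool 2×2) blocks with channel
doubling, a two-convolution bottleneck, and a mirrored decoder of ×2
nearest-neighbour upsampling with skip concatenation, closed by a 1×1
per-pixel classifier.  Training minimizes the soft Dice loss with SGD
(lr 0.01, momentum 0.9, ×0.1 decay every 20 epochs, batch 4) and early
stopping on validation DSC; the best-validation checkpoint is returned.

The interpalpebral height (IPH) of a mask is the maximum over columns of
the vertical extent (last foreground row − first foreground row + 1).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from scipy.special import expit

from ._nn import SGD, BatchNorm2d, Conv2d, Module, Tensor, no_grad
from .split import three_way_split

__all__ = [
    "SegTrainConfig",
    "SegMetrics",
    "UNet",
    "train_segmentation",
    "segment_frame",
    "compute_iph",
    "evaluate_segmentation",
    "dice_coefficient",
]


@dataclass
class SegTrainConfig:
    """Training protocol for the eyelid-region U-Net.

    Defaults follow the reference protocol (512×512 inputs, base width 64,
    SGD lr 0.01 / momentum 0.9, ×0.1 decay every 20 epochs, batch 4, up to
    100 epochs, patience 20, 8:1:1 split).  Desk-scale runs shrink
    ``input_size``/``base_width``/``max_epochs``.
    """

    input_size: int = 512
    base_width: int = 64
    depth: int = 4
    lr: float = 0.01
    momentum: float = 0.9
    lr_decay: float = 0.1
    lr_step_epochs: int = 20
    max_epochs: int = 100
    batch_size: int = 4
    patience: int = 20
    split: tuple[int, int, int] = (8, 1, 1)
    threshold: float = 0.5
    augment: bool = True
    seed: int = 0
    stop_dsc: float | None = None  # optional convergence short-circuit

    def __post_init__(self) -> None:
        if min(self.input_size, self.base_width, self.depth, self.max_epochs,
               self.batch_size, self.patience) <= 0:
            raise ValueError("all config sizes must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError("input_size must be divisible by 2**depth")


@dataclass
class SegMetrics:
    """Mean ± sd of per-frame overlap metrics (DSC, IOU, BAC, SEN)."""

    dsc: float
    iou: float
    bac: float
    sen: float
    dsc_sd: float = 0.0
    iou_sd: float = 0.0
    bac_sd: float = 0.0
    sen_sd: float = 0.0
    per_frame: pd.DataFrame | None = field(default=None, repr=False)


class _DoubleConv(Module):
    """(conv 3×3 -> batch norm -> ReLU) twice."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.n1 = BatchNorm2d(out_ch)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.n2 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return self.n2(self.c2(self.n1(self.c1(x)).relu())).relu()


class UNet(Module):
    """Encoder/decoder segmentation network with skip connections."""

    def __init__(self, base_width: int = 64, depth: int = 4, in_ch: int = 1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        widths = [base_width * 2**i for i in range(depth + 1)]
        self.enc = [_DoubleConv(in_ch if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.bottleneck = _DoubleConv(widths[depth - 1], widths[depth], rng)
        self.dec = [_DoubleConv(widths[i + 1] + widths[i], widths[i], rng)
                    for i in reversed(range(depth))]
        self.head = Conv2d(base_width, 1, 1, rng)
        self.trained = False

    def forward(self, x: Tensor) -> Tensor:
        """Logit map of the same spatial size as the input (N,1,H,W)."""
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = x.max_pool2d()
        x = self.bottleneck(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = x.upsample2x()
            x = Tensor.concat([skip, x], axis=1)
            x = block(x)
        return self.head(x)


def dice_loss(logits: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Soft Dice loss, 1 − DSC of sigmoid probabilities, averaged per sample."""
    p = logits.sigmoid()
    t = Tensor(target.astype(np.float32))
    inter = (p * t).sum(axis=(1, 2, 3))
    denom = p.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3))
    return (1.0 - (2.0 * inter + eps) / (denom + eps)).mean()


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Hard DSC of two binary masks; 1.0 when both are empty."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    ps, ts = pred.sum(), truth.sum()
    if ps + ts == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, truth).sum() / (ps + ts)


def _to_gray01(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    img = img.astype(np.float32)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def preprocess_frame(image: np.ndarray, input_size: int) -> np.ndarray:
    """Grayscale + nearest-neighbour resize to the network input grid."""
    img = _to_gray01(image)
    if img.shape != (input_size, input_size):
        img = resize(img, (input_size, input_size), order=0,
                     preserve_range=True, anti_aliasing=False).astype(np.float32)
    return img


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if mask.shape == shape:
        return mask
    return resize(mask.astype(np.float32), shape, order=0,
                  preserve_range=True, anti_aliasing=False) > 0.5


def train_segmentation(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: SegTrainConfig,
) -> tuple[UNet, pd.DataFrame]:
    """Train the U-Net on (frame, mask) pairs; return the best checkpoint.

    The dataset is split 8:1:1 (train/val/test) with a seeded shuffle; random
    horizontal/vertical flips augment the training split only.  History has
    one row per epoch (epoch, lr, train_loss, val_dsc).  With fewer than 3
    pairs the same data serves as its own validation split (overfit runs).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    for frame, mask in dataset:
        if np.asarray(frame).shape[:2] != np.asarray(mask).shape[:2]:
            raise ValueError("mask shape must match its frame")

    s = config.input_size
    xs = np.stack([preprocess_frame(f, s) for f, _ in dataset])[:, None]
    ys = np.stack(
        [_resize_mask(np.asarray(m) > 0, (s, s)) for _, m in dataset]
    )[:, None].astype(np.float32)

    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    if n >= 3:
        tr_idx, va_idx, _ = three_way_split(n, config.split, rng)
    else:
        tr_idx = va_idx = np.arange(n)

    model = UNet(base_width=config.base_width, depth=config.depth,
                 seed=config.seed)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum)

    best_dsc = -1.0
    best_state = model.state_dict()
    best_epoch = -1
    rows = []
    for epoch in range(config.max_epochs):
        model.train()
        opt.lr = config.lr * config.lr_decay ** (epoch // config.lr_step_epochs)
        order = rng.permutation(tr_idx)
        losses = []
        for i in range(0, order.size, config.batch_size):
            batch = order[i : i + config.batch_size]
            xb, yb = xs[batch], ys[batch]
            if config.augment:
                flips = rng.integers(0, 2, size=(batch.size, 2))
                xb, yb = xb.copy(), yb.copy()
                for j, (fh, fv) in enumerate(flips):
                    if fh:
                        xb[j], yb[j] = xb[j, :, :, ::-1], yb[j, :, :, ::-1]
                    if fv:
                        xb[j], yb[j] = xb[j, :, ::-1], yb[j, :, ::-1]
            model.zero_grad()
            loss = dice_loss(model(Tensor(np.ascontiguousarray(xb))),
                             np.ascontiguousarray(yb))
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_dsc = _validation_dsc(model, xs[va_idx], ys[va_idx],
                                  config.threshold)
        rows.append(
            {"epoch": epoch, "lr": opt.lr,
             "train_loss": float(np.mean(losses)), "val_dsc": val_dsc}
        )
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_state = model.state_dict()
            best_epoch = epoch
        if config.stop_dsc is not None and best_dsc >= config.stop_dsc:
            break
        if epoch - best_epoch >= config.patience:
            break

    model.load_state_dict(best_state)
    model.trained = True
    model.input_size = s
    model.threshold = config.threshold
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best_epoch
    history.attrs["best_val_dsc"] = best_dsc
    return model, history


def _validation_dsc(model: UNet, xs: np.ndarray, ys: np.ndarray,
                    threshold: float) -> float:
    scores = []
    model.eval()
    with no_grad():
        for i in range(xs.shape[0]):
            logits = model(Tensor(xs[i : i + 1])).data[0, 0]
            scores.append(
                dice_coefficient(expit(logits) >= threshold, ys[i, 0] > 0.5)
            )
    return float(np.mean(scores)) if scores else float("nan")


def segment_frame(model: UNet, image: np.ndarray) -> np.ndarray:
    """Predict the eyelid-region mask of one frame, at frame resolution.

    The frame is grayscaled and nearest-neighbour-resized to the network
    grid; the thresholded prediction is nearest-neighbour-resized back to
    the original resolution before any IPH computation.
    """
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    orig_shape = np.asarray(image).shape[:2]
    x = preprocess_frame(image, model.input_size)[None, None]
    model.eval()
    with no_grad():
        logits = model(Tensor(x)).data[0, 0]
    mask = expit(logits) >= model.threshold
    return _resize_mask(mask, tuple(orig_shape)).astype(np.uint8)


def compute_iph(mask: np.ndarray, image_h: int) -> tuple[int, float]:
    """Interpalpebral height of a mask: max column-wise vertical extent.

    Returns ``(iph_px, iph_frac)`` with ``iph_frac = iph_px / image_h``;
    ``(0, 0.0)`` for an empty mask.
    """
    if image_h <= 0:
        raise ValueError("image_h must be positive")
    m = np.asarray(mask) > 0
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    cols = m.any(axis=0)
    if not cols.any():
        return 0, 0.0
    first = np.argmax(m, axis=0)
    last = m.shape[0] - 1 - np.argmax(m[::-1], axis=0)
    extent = (last - first + 1)[cols]
    iph_px = int(extent.max())
    return iph_px, iph_px / image_h


def _frame_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    p = np.asarray(pred).astype(bool)
    g = np.asarray(truth).astype(bool)
    tp = np.logical_and(p, g).sum()
    fp = np.logical_and(p, ~g).sum()
    fn = np.logical_and(~p, g).sum()
    tn = np.logical_and(~p, ~g).sum()
    if p.sum() + g.sum() == 0:
        dsc = iou = 1.0  # agreement on absence
    else:
        dsc = 2.0 * tp / (p.sum() + g.sum())
        iou = tp / (tp + fp + fn)
    sen = tp / (tp + fn) if tp + fn > 0 else 1.0
    spe = tn / (tn + fp) if tn + fp > 0 else 1.0
    return {"dsc": dsc, "iou": iou, "sen": sen, "bac": 0.5 * (sen + spe)}


def evaluate_segmentation(
    pred_masks: Sequence[np.ndarray],
    truth_masks: Sequence[np.ndarray],
) -> SegMetrics:
    """Per-frame DSC/IOU/BAC/SEN, reported as mean ± sd over frames."""
    if len(pred_masks) != len(truth_masks):
        raise ValueError("prediction and truth lists must have equal length")
    if len(pred_masks) == 0:
        raise ValueError("nothing to evaluate")
    rows = []
    for p, g in zip(pred_masks, truth_masks):
        if np.asarray(p).shape != np.asarray(g).shape:
            raise ValueError("mask shapes must match")
        rows.append(_frame_metrics(p, g))
    df = pd.DataFrame(rows)
    return SegMetrics(
        dsc=float(df.dsc.mean()), iou=float(df.iou.mean()),
        bac=float(df.bac.mean()), sen=float(df.sen.mean()),
        dsc_sd=float(df.dsc.std(ddof=1)) if len(df) > 1 else 0.0,
        iou_sd=float(df.iou.std(ddof=1)) if len(df) > 1 else 0.0,
        bac_sd=float(df.bac.std(ddof=1)) if len(df) > 1 else 0.0,
        sen_sd=float(df.sen.std(ddof=1)) if len(df) > 1 else 0.0,
        per_frame=df,
    )
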