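"""Frame-state classification and the IPH correction rule.

Each video frame is classified as *palpebral fissure existence* (some
aperture visible) or *palpebral fissure disappearance* (eye fully closed).
The classifier is a four-stage hierarchical vision transformer: the frame is
cut into patches, linearly embedded, and processed by windowed multi-head
self-attention blocks; between stages a patch-merging layer halves the token
grid and doubles the channel width.  Alternate blocks use cyclically shifted
windows with the standard boundary attention mask.  (Relative-position bias
is omitted; attention is plain scaled dot-product.)

The classifier's verdict corrects the segmentation-derived IPH: a frame
classified as disappearance has its IPH forced to zero; all other frames
keep the segmented value.  With the "disappearance" class taken as positive,
this correction is what lifts the frame-state sensitivity of the whole
system above segmentation alone, whose residual false-positive pixels on
closed frames otherwise masquerade as small apertures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from ._nn import AdamW, LayerNorm, Linear, Module, Tensor, no_grad
from .split import three_way_split

__all__ = [
    "STATES",
    "FrameLabel",
    "ClsTrainConfig",
    "SwinClassifier",
    "train_classifier",
    "classify_frame",
    "correct_iph",
    "evaluate_frame_classification",
]

STATES = ("existence", "disappearance")
#: the positive class of all frame-state metrics
POSITIVE_STATE = "disappearance"

# channel normalization applied after replicating grayscale to 3 channels
DEFAULT_MEAN = (0.485, 0.456, 0.406)
DEFAULT_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class FrameLabel:
    """Predicted frame state with the normalized score of that state."""

    state: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class ClsTrainConfig:
    """Training protocol for the frame-state classifier.

    Defaults mirror the reference protocol (224×224×3 inputs, tiny stage
    configuration: embed 96, depths 2/2/6/2, window 7; AdamW lr 1e-4,
    weight decay 5e-2, batch 8, 10 epochs, 8:1:1 split).  Desk-scale runs
    shrink the input and stage configuration.
    """

    input_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    window: int = 7
    mlp_ratio: float = 4.0
    lr: float = 1e-4
    weight_decay: float = 5e-2
    batch_size: int = 8
    epochs: int = 10
    split: tuple[int, int, int] = (8, 1, 1)
    mean: tuple[float, float, float] = DEFAULT_MEAN
    std: tuple[float, float, float] = DEFAULT_STD
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("the classifier has exactly 4 stages")
        if self.input_size % (self.patch_size * 8) != 0:
            raise ValueError(
                "input_size must be divisible by patch_size * 8 "
                "(three patch mergings)"
            )
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2**i) % h != 0:
                raise ValueError(f"stage {i+1} width not divisible by its heads")


# ---------------------------------------------------------------------------
# model


class _WindowAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.heads = heads
        self.scale = 1.0 / math.sqrt(dim // heads)

    def forward(self, xw: Tensor, attn_mask: np.ndarray | None) -> Tensor:
        # xw: (B*nW, N, C) tokens of each window
        bw, n, c = xw.shape
        h = self.heads
        d = c // h
        qkv = self.qkv(xw).reshape(bw, n, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B*nW, h, N, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        if attn_mask is not None:
            nw = attn_mask.shape[0]
            attn = attn.reshape(bw // nw, nw, h, n, n) + Tensor(
                attn_mask[None, :, None].astype(np.float32)
            )
            attn = attn.reshape(bw, h, n, n)
        out = attn.softmax(-1) @ v  # (B*nW, h, N, d)
        out = out.transpose(0, 2, 1, 3).reshape(bw, n, c)
        return self.proj(out)


class _Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def _window_partition(x: Tensor, grid: int, ws: int) -> Tensor:
    b = x.shape[0]
    c = x.shape[-1]
    x = x.reshape(b, grid // ws, ws, grid // ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b * (grid // ws) ** 2, ws * ws, c)


def _window_reverse(xw: Tensor, grid: int, ws: int, b: int) -> Tensor:
    c = xw.shape[-1]
    x = xw.reshape(b, grid // ws, grid // ws, ws, ws, c)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, grid, grid, c)


def _shift_attn_mask(grid: int, ws: int, shift: int) -> np.ndarray:
    """Additive mask blocking attention across wrapped window boundaries."""
    img = np.zeros((grid, grid), dtype=np.int64)
    region = 0
    slices = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None))
    for hs in slices:
        for wsl in slices:
            img[hs, wsl] = region
            region += 1
    # the slice regions are already in shifted coordinates
    win = img.reshape(grid // ws, ws, grid // ws, ws).transpose(0, 2, 1, 3)
    win = win.reshape(-1, ws * ws)
    mask = (win[:, :, None] != win[:, None, :]).astype(np.float32) * -100.0
    return mask


class _SwinBlock(Module):
    def __init__(self, dim: int, heads: int, grid: int, window: int,
                 shifted: bool, mlp_ratio: float, rng: np.random.Generator):
        self.ws = min(window, grid)
        self.shift = self.ws // 2 if (shifted and self.ws < grid) else 0
        self.grid = grid
        self.norm1 = LayerNorm(dim)
        self.attn = _WindowAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = _Mlp(dim, int(dim * mlp_ratio), rng)
        self._mask = (
            _shift_attn_mask(grid, self.ws, self.shift) if self.shift else None
        )

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, grid, grid, C)
        b = x.shape[0]
        y = self.norm1(x)
        if self.shift:
            y = y.roll((-self.shift, -self.shift), axis=(1, 2))
        yw = _window_partition(y, self.grid, self.ws)
        yw = self.attn(yw, self._mask)
        y = _window_reverse(yw, self.grid, self.ws, b)
        if self.shift:
            y = y.roll((self.shift, self.shift), axis=(1, 2))
        x = x + y
        return x + self.mlp(self.norm2(x))


class _PatchMerging(Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        # (B, H, W, C) -> (B, H/2, W/2, 2C)
        parts = [
            x[:, 0::2, 0::2, :], x[:, 1::2, 0::2, :],
            x[:, 0::2, 1::2, :], x[:, 1::2, 1::2, :],
        ]
        return self.reduce(self.norm(Tensor.concat(parts, axis=-1)))


class SwinClassifier(Module):
    """Four-stage windowed-attention frame classifier (2 classes)."""

    def __init__(self, config: ClsTrainConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        p = config.patch_size
        grid = config.input_size // p
        self.patch_embed = Linear(3 * p * p, config.embed_dim, rng)
        self.embed_norm = LayerNorm(config.embed_dim)
        self.stages = []
        self.mergers = []
        dim = config.embed_dim
        for s in range(4):
            blocks = [
                _SwinBlock(dim, config.heads[s], grid, config.window,
                           shifted=(b % 2 == 1), mlp_ratio=config.mlp_ratio,
                           rng=rng)
                for b in range(config.depths[s])
            ]
            self.stages.append(blocks)
            if s < 3:
                self.mergers.append(_PatchMerging(dim, rng))
                dim *= 2
                grid //= 2
        self.head_norm = LayerNorm(dim)
        self.head = Linear(dim, 2, rng)
        self.trained = False

    def named_parameters(self, prefix: str = ""):
        out = super().named_parameters(prefix)
        for s, blocks in enumerate(self.stages):
            for b, block in enumerate(blocks):
                out.extend(block.named_parameters(f"{prefix}stages.{s}.{b}."))
        return out

    def forward(self, x: Tensor) -> Tensor:
        """(B, 3, H, W) normalized images -> (B, 2) class logits."""
        b = x.shape[0]
        p = self.config.patch_size
        grid = self.config.input_size // p
        # patch partition: (B,3,H,W) -> (B, grid, grid, 3*p*p)
        x = x.reshape(b, 3, grid, p, grid, p).transpose(0, 2, 4, 1, 3, 5)
        x = x.reshape(b, grid, grid, 3 * p * p)
        x = self.embed_norm(self.patch_embed(x))
        for s, blocks in enumerate(self.stages):
            for block in blocks:
                x = block(x)
            if s < 3:
                x = self.mergers[s](x)
        g = x.shape[1]
        tokens = self.head_norm(x.reshape(b, g * g, x.shape[-1]))
        return self.head(tokens.mean(axis=1))


# ---------------------------------------------------------------------------
# preprocessing


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.max() > 1.5:
        img = img / 255.0
    return img


def preprocess_frame(
    image: np.ndarray,
    config: ClsTrainConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Grayscale -> (random crop while training) -> resize -> 3ch -> normalize.

    With ``rng`` given (training), a random sub-window of 70–100% linear
    extent is cropped and a horizontal flip applied half the time; inference
    is a deterministic full-frame resize.
    """
    img = _to_gray(image)
    if rng is not None:
        h, w = img.shape
        fr = rng.uniform(0.7, 1.0)
        ch, cw = max(8, int(h * fr)), max(8, int(w * fr))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        img = img[top : top + ch, left : left + cw]
        if rng.integers(0, 2):
            img = img[:, ::-1]
    s = config.input_size
    if img.shape != (s, s):
        img = resize(img, (s, s), order=1, preserve_range=True,
                     anti_aliasing=False).astype(np.float32)
    mean = np.asarray(config.mean, dtype=np.float32)[:, None, None]
    std = np.asarray(config.std, dtype=np.float32)[:, None, None]
    x = np.repeat(img[None], 3, axis=0)
    return (x - mean) / std


def _encode_states(states: Sequence[str]) -> np.ndarray:
    out = np.empty(len(states), dtype=np.int64)
    for i, s in enumerate(states):
        st = s.state if isinstance(s, FrameLabel) else s
        if st not in STATES:
            raise ValueError(f"unknown state {st!r}")
        out[i] = STATES.index(st)
    return out


# ---------------------------------------------------------------------------
# training / inference


def train_classifier(
    dataset: Sequence[tuple[np.ndarray, str]],
    config: ClsTrainConfig,
) -> tuple[SwinClassifier, pd.DataFrame]:
    """Train on (frame, state) pairs; return the best-validation checkpoint.

    The split is 8:1:1 with a seeded shuffle; augmentation (random crop +
    horizontal flip) touches the training split only.  Raises if the
    training split does not contain both frame states.  History has one row
    per epoch (epoch, train_loss, val_acc); identical data and seed give an
    identical history.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    states = _encode_states([s for _, s in dataset])
    frames = [f for f, _ in dataset]

    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    if n >= 3:
        tr_idx, va_idx, _ = three_way_split(n, config.split, rng)
    else:
        tr_idx = va_idx = np.arange(n)
    if np.unique(states[tr_idx]).size < 2:
        raise ValueError("training split must contain both frame states")

    model = SwinClassifier(config)
    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)

    # inference-preprocessed copies for validation
    xs_val = np.stack([preprocess_frame(frames[i], config) for i in va_idx])
    ys_val = states[va_idx]

    best_acc = -1.0
    best_state = model.state_dict()
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for i in range(0, order.size, config.batch_size):
            batch = order[i : i + config.batch_size]
            aug_rng = rng if config.augment else None
            xb = np.stack(
                [preprocess_frame(frames[j], config, rng=aug_rng) for j in batch]
            )
            yb = states[batch]
            model.zero_grad()
            logits = model(Tensor(xb.astype(np.float32)))
            logp = logits.log_softmax(-1)
            loss = -(logp[np.arange(yb.size), yb].mean())
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = _validation_accuracy(model, xs_val, ys_val, config.batch_size)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.trained = True
    history = pd.DataFrame(rows)
    history.attrs["best_val_acc"] = best_acc
    return model, history


def _validation_accuracy(model: SwinClassifier, xs: np.ndarray,
                         ys: np.ndarray, batch: int) -> float:
    if xs.shape[0] == 0:
        return float("nan")
    hits = 0
    with no_grad():
        for i in range(0, xs.shape[0], batch):
            logits = model(Tensor(xs[i : i + batch].astype(np.float32))).data
            hits += int((logits.argmax(axis=1) == ys[i : i + batch]).sum())
    return hits / xs.shape[0]


def classify_frame(model: SwinClassifier, image: np.ndarray) -> FrameLabel:
    """Classify one frame; confidence is the softmax score of the winner."""
    if not getattr(model, "trained", False):
        raise ValueError("model has not been trained")
    x = preprocess_frame(image, model.config)[None]
    with no_grad():
        logits = model(Tensor(x.astype(np.float32))).data[0]
    z = logits - logits.max()
    p = np.exp(z) / np.exp(z).sum()
    k = int(p.argmax())
    return FrameLabel(state=STATES[k], confidence=float(p[k]))


# ---------------------------------------------------------------------------
# correction rule and metrics


def correct_iph(label: FrameLabel | str, iph_px: int | float) -> int | float:
    """Zero the IPH of frames classified as palpebral fissure disappearance.

    Frames classified as existence keep their segmented IPH unchanged.  The
    rule is idempotent.
    """
    if iph_px < 0:
        raise ValueError("iph_px must be >= 0")
    state = label.state if isinstance(label, FrameLabel) else label
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    if state == POSITIVE_STATE and iph_px > 0:
        return type(iph_px)(0)
    return iph_px


def evaluate_frame_classification(
    pred_states: Sequence[str],
    truth_states: Sequence[str],
) -> dict[str, float]:
    """Confusion-matrix metrics with 'disappearance' as the positive class.

    Returns accuracy, precision, sensitivity, specificity and F1
    (= harmonic mean of precision and sensitivity).
    """
    if len(pred_states) == 0:
        raise ValueError("nothing to evaluate")
    if len(pred_states) != len(truth_states):
        raise ValueError("prediction and truth lists must have equal length")
    pred = _encode_states(pred_states) == STATES.index(POSITIVE_STATE)
    truth = _encode_states(truth_states) == STATES.index(POSITIVE_STATE)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return {
        "accuracy": (tp + tn) / len(pred_states),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
    }
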