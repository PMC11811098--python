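"""Shared synthetic fixtures and (expensive) trained-model fixtures."""

import numpy as np
import pytest

from blinkwave.cls import ClsTrainConfig, train_classifier
from blinkwave.seg import SegTrainConfig, train_segmentation
from blinkwave.synth import SyntheticSpec, render_frame

TOY_CLS_CONFIG = dict(
    input_size=64, patch_size=4, embed_dim=16, depths=(1, 1, 1, 1),
    heads=(2, 2, 4, 4), window=4, batch_size=8, epochs=4, lr=1e-3,
)


def render_pairs(n, image_size, seed, closed_frac=0.15, pixel_noise_sd=6.0):
    """(frame, mask, iph_frac) triples spanning closed to wide-open eyes."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(image_w=image_size, image_h=image_size,
                         pixel_noise_sd=pixel_noise_sd, seed=seed)
    n_closed = max(1, int(round(closed_frac * n)))
    fracs = np.concatenate(
        [np.zeros(n_closed), rng.uniform(0.02, 0.5, size=n - n_closed)]
    )
    rng.shuffle(fracs)
    out = []
    for f in fracs:
        img, mask = render_frame(float(f), spec, rng=rng)
        out.append((img, mask, float(f)))
    return out


@pytest.fixture(scope="session")
def seg_pairs_small():
    return render_pairs(24, 64, seed=11)


@pytest.fixture(scope="session")
def trained_unet_small(seg_pairs_small):
    """Small U-Net (64×64, width 8) trained on 24 synthetic pairs."""
    config = SegTrainConfig(input_size=64, base_width=8, max_epochs=25,
                            patience=8, seed=0, stop_dsc=0.98)
    pairs = [(img, mask) for img, mask, _ in seg_pairs_small]
    model, history = train_segmentation(pairs, config)
    return model, history


@pytest.fixture(scope="session")
def cls_frames():
    """Labelled open/closed frames for classifier training (64×64)."""
    triples = render_pairs(120, 64, seed=21, closed_frac=0.4)
    return [
        (img, "disappearance" if f == 0.0 else "existence")
        for img, _, f in triples
    ]


@pytest.fixture(scope="session")
def trained_classifier(cls_frames):
    config = ClsTrainConfig(seed=0, **TOY_CLS_CONFIG)
    model, history = train_classifier(cls_frames, config)
    return model, history
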