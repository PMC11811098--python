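"""End-to-end orchestration: video -> masks -> frame states -> blink report.

``analyze_video`` chains the segmentation and classification models over a
recording: each frame is segmented, its IPH measured, the frame state
classified, the IPH corrected to zero on disappearance frames, and the
resulting blink wave run through event detection and summary metrics.

``evaluate_system`` reproduces the two-row system comparison: row one scores
segmentation alone (a frame is called "disappearance" iff its segmented IPH
is exactly zero), row two scores the combined system after classifier
correction.

Both segmenter and classifier are passed as callables ``fn(frame, index)``
so that trained models and ground-truth oracles plug in interchangeably.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import seg as seg_mod
from .cls import FrameLabel, classify_frame, correct_iph, evaluate_frame_classification
from .seg import compute_iph, segment_frame
from .split import split_sizes
from .synth import SyntheticSpec, synthesize_video, write_dataset_png
from .wave import (
    BlinkEvent,
    BlinkMetrics,
    BlinkWave,
    analyze_wave,
    write_report_json,
    write_wave_csv,
)

__all__ = [
    "AnalysisReport",
    "analyze_video",
    "evaluate_system",
    "generate_dataset",
    "load_frames",
    "model_segmenter",
    "model_classifier",
    "oracle_segmenter",
    "oracle_classifier",
]

Segmenter = Callable[[np.ndarray, int], np.ndarray]
Classifier = Callable[[np.ndarray, int], FrameLabel]


@dataclass
class AnalysisReport:
    """One recording's wave, events, metrics, and run provenance."""

    wave: BlinkWave
    events: list[BlinkEvent]
    metrics: BlinkMetrics
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "wave": {"fps": self.wave.fps, "iph_pct": self.wave.iph_pct.tolist()},
            "events": [dataclasses.asdict(e) for e in self.events],
            "metrics": dataclasses.asdict(self.metrics),
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_wave_csv(self.wave, out / "wave.csv")
        write_report_json(self.events, self.metrics, out / "report.json",
                          provenance=self.provenance)


def model_segmenter(model) -> Segmenter:
    """Adapt a trained U-Net to the ``fn(frame, index)`` interface."""

    def fn(frame: np.ndarray, index: int) -> np.ndarray:
        return segment_frame(model, frame)

    return fn


def model_classifier(model) -> Classifier:
    def fn(frame: np.ndarray, index: int) -> FrameLabel:
        return classify_frame(model, frame)

    return fn


def oracle_segmenter(masks: Sequence[np.ndarray]) -> Segmenter:
    """Ground-truth segmenter for round-trip tests (synthetic; index-based)."""

    def fn(frame: np.ndarray, index: int) -> np.ndarray:
        return masks[index]

    return fn


def oracle_classifier(states: Sequence[str]) -> Classifier:
    """Ground-truth classifier for round-trip tests (synthetic; index-based)."""

    def fn(frame: np.ndarray, index: int) -> FrameLabel:
        return FrameLabel(state=states[index], confidence=1.0)

    return fn


def load_frames(source, max_seconds: float | None = 20.0,
                fps: float | None = None) -> tuple[np.ndarray, float]:
    """Load frames from a directory of numbered PNGs, a video file, or an array.

    Returns ``(frames, fps)``; recordings longer than ``max_seconds`` are
    trimmed to their first ``max_seconds``.  For PNG directories and arrays
    the fps must be supplied.
    """
    if isinstance(source, np.ndarray):
        frames = source
        if fps is None:
            raise ValueError("fps must be supplied for frame arrays")
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(str(path))
        import imageio.v3 as iio

        if path.is_dir():
            files = sorted(path.glob("*.png"))
            if not files:
                raise ValueError(f"no PNG frames under {path}")
            frames = np.stack([iio.imread(f) for f in files])
            if fps is None:
                raise ValueError("fps must be supplied for frame directories")
        else:
            frames = iio.imread(path)
            if fps is None:
                meta = iio.immeta(path)
                fps = meta.get("fps")
                if fps is None:
                    raise ValueError("fps missing from metadata; pass fps=")
    if max_seconds is not None:
        frames = frames[: int(round(max_seconds * fps))]
    return frames, float(fps)


def analyze_video(
    source,
    segmenter: Segmenter,
    classifier: Classifier,
    fps: float | None = None,
    k: int = 5,
    reject_frac: float = 0.8,
    max_seconds: float | None = 20.0,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Full pipeline on one recording.

    frames -> masks -> IPH -> frame states -> corrected wave -> events ->
    metrics.  Deterministic given fixed models and configuration.
    """
    frames, fps = load_frames(source, max_seconds=max_seconds, fps=fps)
    image_h = frames.shape[1]
    iph = np.empty(frames.shape[0], dtype=float)
    for i, frame in enumerate(frames):
        mask = segmenter(frame, i)
        px, _ = compute_iph(mask, image_h)
        label = classifier(frame, i)
        iph[i] = correct_iph(label, px) / image_h
    wave = BlinkWave(iph_frac=iph, fps=fps)
    events, metrics = analyze_wave(wave, k=k, reject_frac=reject_frac)
    prov = {
        "n_frames": int(frames.shape[0]),
        "fps": fps,
        "k": k,
        "reject_frac": reject_frac,
        "wave_sha1": hashlib.sha1(
            np.ascontiguousarray(iph).tobytes()
        ).hexdigest(),
    }
    if provenance:
        prov.update(provenance)
    return AnalysisReport(wave=wave, events=events, metrics=metrics,
                          provenance=prov)


def evaluate_system(
    frames: Sequence[np.ndarray],
    truth_states: Sequence[str],
    segmenter: Segmenter,
    classifier: Classifier,
) -> pd.DataFrame:
    """Frame-state metrics of segmentation alone vs the corrected system.

    Row ``unet``: a frame is "disappearance" iff its segmented IPH is 0.
    Row ``unet_swin``: the classifier's correction is applied first, so a
    frame is "disappearance" iff the corrected IPH is 0.
    """
    if len(truth_states) != len(frames):
        raise ValueError("every frame needs a ground-truth state")
    if len(frames) == 0:
        raise ValueError("nothing to evaluate")
    image_h = np.asarray(frames[0]).shape[0]
    seg_states, combined_states = [], []
    for i, frame in enumerate(frames):
        mask = segmenter(frame, i)
        px, _ = compute_iph(mask, image_h)
        seg_states.append("disappearance" if px == 0 else "existence")
        corrected = correct_iph(classifier(frame, i), px)
        combined_states.append("disappearance" if corrected == 0 else "existence")
    rows = {
        "unet": evaluate_frame_classification(seg_states, list(truth_states)),
        "unet_swin": evaluate_frame_classification(
            combined_states, list(truth_states)
        ),
    }
    return pd.DataFrame(rows).T


def generate_dataset(spec: SyntheticSpec | str | Path, out_dir: str | Path,
                     seed: int | None = None) -> pd.DataFrame:
    """Render a synthetic recording to disk with labels and a split manifest.

    Writes numbered frame/mask PNGs, a labels CSV (frame_path, state,
    split), a manifest CSV (frame_path, mask_path, split), the ground truth
    (JSON events + per-frame CSV) and the generating spec as YAML.  The
    8:1:1 split uses largest-remainder rounding with a seeded shuffle.
    """
    if not isinstance(spec, SyntheticSpec):
        spec = SyntheticSpec.from_yaml(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames, masks, truth = synthesize_video(spec)
    fpaths, mpaths = write_dataset_png(frames, masks, out)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = frames.shape[0]
    sizes = split_sizes(n, (8, 1, 1))
    perm = rng.permutation(n)
    split = np.empty(n, dtype=object)
    split[perm[: sizes[0]]] = "train"
    split[perm[sizes[0] : sizes[0] + sizes[1]]] = "val"
    split[perm[sizes[0] + sizes[1] :]] = "test"
    manifest = pd.DataFrame(
        {
            "frame_path": [str(p) for p in fpaths],
            "mask_path": [str(p) for p in mpaths],
            "state": truth.labels,
            "split": split,
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    manifest[["frame_path", "state", "split"]].to_csv(
        out / "labels.csv", index=False
    )
    truth.to_json(out / "ground_truth.json")
    truth.to_csv(out / "ground_truth.csv", fps=spec.fps)
    spec.to_yaml(out / "spec.yaml")
    return manifest
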