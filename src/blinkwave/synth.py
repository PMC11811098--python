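"""Synthetic eye recordings with exact blink ground truth.

Emulates the acquisition protocol of a tear-film interferometer: a 20 s
recording at 30 frames per second, 800×600 pixels, showing a single eye
whose lens-shaped interpalpebral aperture opens and closes on a schedule of
complete and incomplete blinks over a constant open-eye baseline.

Every blink is piecewise-linear in IPH%: a descent over the closing phase,
an optional hold at full closure (complete blinks only), and an ascent back
to baseline over the opening phase.  Event boundaries are quantized to the
frame grid, so the ground-truth start/trough/end frames, phase durations and
closed-frame labels are exact by construction.  Rendering draws the aperture
as the region between two parabolic arcs that meet at fixed canthi; eyelid
closure moves the upper arc down.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .wave import BlinkWave

__all__ = [
    "BlinkEventSpec",
    "SyntheticSpec",
    "GroundTruth",
    "MAX_APERTURE_FRAC",
    "sample_schedule",
    "synthesize_wave",
    "render_frame",
    "synthesize_video",
    "iter_video",
]

#: the rendering geometry cannot open the aperture beyond half the image height
MAX_APERTURE_FRAC = 0.5

# default per-event duration ranges (seconds); chosen to bracket reported
# group means (closing ~0.15-0.18 s, opening ~0.28-0.35 s) while keeping both
# ramps at least 6 frames at 30 fps so the k=5 run rule can resolve them
CLOSING_RANGE_S = (0.20, 0.40)
CLOSED_RANGE_S = (0.07, 0.20)
OPENING_RANGE_S = (0.23, 0.50)
TROUGH_RANGE = (0.10, 0.70)  # incomplete-blink trough, as fraction of baseline


@dataclass(frozen=True)
class BlinkEventSpec:
    """One scheduled blink: onset, phase durations, trough depth, label."""

    onset_s: float
    closing_s: float
    closed_s: float
    opening_s: float
    trough_frac: float  # fraction of baseline; 0 for a complete blink
    label: str  # "complete" | "incomplete"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.closing_s <= 0 or self.opening_s <= 0:
            raise ValueError("closing_s and opening_s must be positive")
        if self.closed_s < 0:
            raise ValueError("closed_s must be >= 0")
        if not 0.0 <= self.trough_frac <= 1.0:
            raise ValueError("trough_frac must lie in [0, 1]")
        if self.label not in ("complete", "incomplete"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.trough_frac == 0.0) != (self.label == "complete"):
            raise ValueError("trough_frac == 0 exactly for complete blinks")
        if self.closed_s > 0 and self.label != "complete":
            raise ValueError("only complete blinks hold a closed phase")

    @property
    def duration_s(self) -> float:
        return self.closing_s + self.closed_s + self.opening_s


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of one synthetic recording."""

    duration_s: float = 20.0
    fps: float = 30.0
    baseline_iph_frac: float = 0.35
    events: tuple[BlinkEventSpec, ...] = ()
    wave_noise_sd: float = 0.0  # additive Gaussian on IPH fraction
    pixel_noise_sd: float = 0.0  # additive Gaussian, gray levels
    image_w: int = 800
    image_h: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not 0.0 < self.baseline_iph_frac <= MAX_APERTURE_FRAC:
            raise ValueError(
                f"baseline_iph_frac must lie in (0, {MAX_APERTURE_FRAC}]"
            )
        if self.image_w < 8 or self.image_h < 8:
            raise ValueError("image too small to render an eye")
        if self.wave_noise_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        spans = sorted(
            (e.onset_s, e.onset_s + e.duration_s) for e in self.events
        )
        gap = 1.0 / self.fps  # at least one baseline frame between events
        prev_end = None
        for lo, hi in spans:
            if hi > self.duration_s:
                raise ValueError("event extends past the recording")
            if prev_end is not None and lo < prev_end + gap:
                raise ValueError("events overlap or touch (need >= 1 baseline frame)")
            prev_end = hi

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["events"] = [dataclasses.asdict(e) for e in self.events]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["events"] = tuple(BlinkEventSpec(**e) for e in d.get("events", ()))
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact per-frame and per-event truth for one synthetic recording."""

    iph_frac: np.ndarray  # noise-free per-frame IPH fraction
    closed: np.ndarray  # bool; True where noise-free IPH == 0
    events: list[dict] = field(default_factory=list)
    # each: {start_f, trough_f, end_f, type, closing_s, closed_s, opening_s}

    @property
    def labels(self) -> list[str]:
        """Frame states: 'disappearance' where closed, else 'existence'."""
        return ["disappearance" if c else "existence" for c in self.closed]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"events": self.events}, indent=2, sort_keys=True)
        )

    def to_csv(self, path: str | Path, fps: float) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "frame": np.arange(self.iph_frac.size),
                "time_s": np.arange(self.iph_frac.size) / fps,
                "iph_pct": self.iph_frac * 100.0,
                "closed_label": self.closed.astype(int),
            }
        ).to_csv(path, index=False)


def _quantize(seconds: float, fps: float, minimum: int = 1) -> int:
    return max(minimum, int(round(seconds * fps)))


def sample_schedule(
    n_events: int,
    duration_s: float = 20.0,
    fps: float = 30.0,
    mix: float = 0.5,
    seed: int = 0,
    closing_range_s: tuple[float, float] = CLOSING_RANGE_S,
    closed_range_s: tuple[float, float] = CLOSED_RANGE_S,
    opening_range_s: tuple[float, float] = OPENING_RANGE_S,
    trough_range: tuple[float, float] = TROUGH_RANGE,
) -> list[BlinkEventSpec]:
    """Draw a feasible, frame-aligned schedule of blinks.

    ``mix`` is the fraction of incomplete blinks (rounded to a count).  All
    onsets and phase durations are quantized to whole frames; events are
    separated by at least one baseline frame.  Identical arguments always
    produce an identical schedule.

    Raises ``ValueError`` when the requested events cannot be packed into
    the recording.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    if n_events == 0:
        return []
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))

    n_inc = int(round(mix * n_events))
    labels = ["incomplete"] * n_inc + ["complete"] * (n_events - n_inc)
    rng.shuffle(labels)

    lengths = []  # event lengths in frames (descent + hold + ascent)
    phases = []
    for lab in labels:
        c = _quantize(rng.uniform(*closing_range_s), fps)
        o = _quantize(rng.uniform(*opening_range_s), fps)
        z = _quantize(rng.uniform(*closed_range_s), fps) if lab == "complete" else 0
        trough = float(rng.uniform(*trough_range)) if lab == "incomplete" else 0.0
        phases.append((c, z, o, trough, lab))
        lengths.append(c + z + o)

    # packing: each event needs its frames plus a 1-frame baseline separator,
    # and one baseline frame at the very start so the first descent has a
    # baseline frame before it
    need = sum(lengths) + n_events  # separators (incl. leading frame)
    free = n_frames - 1 - need  # frame n_frames-1 must still exist for the end
    if free < 0:
        raise ValueError(
            f"cannot pack {n_events} events ({need} frames + margins) "
            f"into {n_frames} frames"
        )
    # distribute the free frames among the n_events+1 gaps
    cuts = np.sort(rng.integers(0, free + 1, size=n_events + 1))
    extra = np.diff(np.concatenate(([0], cuts)))  # n_events+1 non-negative ints

    events: list[BlinkEventSpec] = []
    cursor = 1 + int(extra[0])  # first baseline frame(s)
    for i, (c, z, o, trough, lab) in enumerate(phases):
        onset_f = cursor
        events.append(
            BlinkEventSpec(
                onset_s=onset_f / fps,
                closing_s=c / fps,
                closed_s=z / fps,
                opening_s=o / fps,
                trough_frac=trough,
                label=lab,
            )
        )
        cursor = onset_f + lengths[i] + 1 + int(extra[i + 1])
    return events


def synthesize_wave(spec: SyntheticSpec) -> tuple[BlinkWave, GroundTruth]:
    """Piecewise-linear IPH% wave plus exact ground truth.

    Outside events the noise-free wave sits at the open-eye baseline; within
    an event it descends linearly to the trough over the closing phase,
    holds for the closed phase, and ascends over the opening phase.
    Gaussian noise of sd ``wave_noise_sd`` is added to the returned wave
    (clipped to [0, 1]); the ground truth stays noise-free.
    """
    n = spec.n_frames
    fps = spec.fps
    base = spec.baseline_iph_frac
    clean = np.full(n, base, dtype=float)
    gt_events: list[dict] = []
    for ev in spec.events:
        f0 = int(round(ev.onset_s * fps))
        c = _quantize(ev.closing_s, fps)
        z = int(round(ev.closed_s * fps))
        o = _quantize(ev.opening_s, fps)
        trough = ev.trough_frac * base
        end = f0 + c + z + o
        if end >= n:
            raise ValueError("event extends past the recording")
        clean[f0 + 1 : f0 + c + 1] = base + (trough - base) * (
            np.arange(1, c + 1) / c
        )
        clean[f0 + c : f0 + c + z + 1] = trough
        clean[f0 + c + z + 1 : end + 1] = trough + (base - trough) * (
            np.arange(1, o + 1) / o
        )
        gt_events.append(
            {
                "start_f": f0,
                "trough_f": f0 + c,
                "end_f": end,
                "type": ev.label,
                "closing_s": c / fps,
                "closed_s": z / fps,
                "opening_s": o / fps,
            }
        )
    truth = GroundTruth(iph_frac=clean, closed=clean == 0.0, events=gt_events)
    noisy = clean
    if spec.wave_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy = np.clip(
            clean + rng.normal(0.0, spec.wave_noise_sd, size=n), 0.0, 1.0
        )
    return BlinkWave(iph_frac=noisy, fps=fps), truth


# ---------------------------------------------------------------------------
# rendering


def _eye_geometry(spec: SyntheticSpec):
    """Canthi, centerline and lower-lid sag used by the renderer."""
    w, h = spec.image_w, spec.image_h
    x_lo = int(round(0.10 * w))
    x_hi = int(round(0.90 * w))
    y_c = 0.5 * h
    sag = 0.12 * h  # lower-lid vertex depth below the canthus line
    return x_lo, x_hi, y_c, sag


def render_frame(
    iph_frac: float,
    spec: SyntheticSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one grayscale frame and its exact aperture mask.

    The aperture is the region between an upper and a lower parabolic lid
    arc meeting at the canthi; its maximum column-wise vertical extent is
    ``round(iph_frac * image_h)`` within one pixel.  ``iph_frac = 0`` gives
    an empty mask (eye fully closed).
    """
    if iph_frac < 0:
        raise ValueError("iph_frac must be >= 0")
    if iph_frac > MAX_APERTURE_FRAC:
        raise ValueError(
            f"iph_frac {iph_frac} exceeds the geometric maximum {MAX_APERTURE_FRAC}"
        )
    w, h = spec.image_w, spec.image_h
    x_lo, x_hi, y_c, sag = _eye_geometry(spec)
    xc = 0.5 * (x_lo + x_hi)
    half = 0.5 * (x_hi - x_lo)

    x = np.arange(w, dtype=float)
    s2 = np.clip(((x - xc) / half) ** 2, 0.0, 1.0)
    shape = np.where((x >= x_lo) & (x <= x_hi), 1.0 - s2, 0.0)
    y_lower = y_c + sag * shape
    y_upper = y_lower - (iph_frac * h) * shape

    rows = np.arange(h, dtype=float)[:, None]
    mask = (rows >= y_upper[None, :]) & (rows < y_lower[None, :])
    mask = mask.astype(np.uint8)

    img = np.full((h, w), 95.0, dtype=np.float32)  # skin
    # lid margins: a dark band just outside each arc
    band = max(2, h // 150)
    upper_band = (rows >= y_upper[None, :] - band) & (rows < y_upper[None, :])
    lower_band = (rows >= y_lower[None, :]) & (rows < y_lower[None, :] + band)
    in_eye_cols = shape > 0
    img[upper_band & in_eye_cols[None, :]] = 45.0
    img[lower_band & in_eye_cols[None, :]] = 45.0
    img[mask.astype(bool)] = 225.0  # exposed ocular surface
    if spec.pixel_noise_sd > 0:
        if rng is None:
            rng = spec.seed
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        img = img + rng.normal(0.0, spec.pixel_noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0).astype(np.uint8), mask


def iter_video(
    spec: SyntheticSpec,
) -> tuple[Iterator[tuple[np.ndarray, np.ndarray]], BlinkWave, GroundTruth]:
    """Lazy variant of :func:`synthesize_video` (frame, mask) iterator."""
    wave, truth = synthesize_wave(spec)
    rng = np.random.default_rng(spec.seed + 1)

    def gen():
        for frac in truth.iph_frac:
            yield render_frame(float(frac), spec, rng=rng)

    return gen(), wave, truth


def synthesize_video(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render all frames and masks of a recording.

    Frames are rendered from the *noise-free* wave (pixel noise is added to
    the images only); masks stay exact, so ground-truth closed frames are
    precisely the frames with empty masks.
    """
    frames_it, _, truth = iter_video(spec)
    n = truth.iph_frac.size
    frames = np.empty((n, spec.image_h, spec.image_w), dtype=np.uint8)
    masks = np.empty((n, spec.image_h, spec.image_w), dtype=np.uint8)
    for i, (img, mask) in enumerate(frames_it):
        frames[i] = img
        masks[i] = mask
    return frames, masks, truth


def write_dataset_png(
    frames: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    out_dir: str | Path,
) -> tuple[list[Path], list[Path]]:
    """Write numbered frame and 0/255 mask PNGs; returns the paths."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    fpaths, mpaths = [], []
    for i, (img, mask) in enumerate(zip(frames, masks)):
        fp = out / "frames" / f"frame_{i:05d}.png"
        mp = out / "masks" / f"mask_{i:05d}.png"
        iio.imwrite(fp, np.asarray(img, dtype=np.uint8))
        iio.imwrite(mp, (np.asarray(mask) > 0).astype(np.uint8) * 255)
        fpaths.append(fp)
        mpaths.append(mp)
    return fpaths, mpaths
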