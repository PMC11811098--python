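"""Blink-wave analysis: IPH% time series -> blink events, phases, metrics.

The blink wave is the per-frame interpalpebral height, normalized by image
height (IPH%), plotted over time.  A blink appears as a trough: the eyelids
close (IPH% falls), optionally hold fully closed (IPH% = 0), and reopen
(IPH% rises).  Events are found with a run-length rule on the frame-to-frame
change ΔIPH%[t] = IPH%[t-1] − IPH%[t], oriented so that Δ > 0 while the eye
is closing:

* a blink START is the frame preceding the first run of ``k`` consecutive
  strictly positive Δ (eyelid descending);
* a blink END is confirmed by the first run of ``k`` consecutive strictly
  negative Δ after the start and placed at the last frame of that maximal
  falling run, i.e. where the reopening stops.

Detected candidates are then classified: a blink is *complete* if its
minimum IPH% is exactly 0, *incomplete* if the minimum is positive but no
more than 80% of the pre-blink baseline, and *rejected* (not a blink) if the
dip stays above 80% of baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlinkWave",
    "BlinkEvent",
    "BlinkMetrics",
    "wave_from_masks",
    "detect_blink_events",
    "filter_and_classify_events",
    "phase_durations",
    "relative_iph",
    "summarize_metrics",
    "analyze_wave",
    "read_wave_csv",
    "write_wave_csv",
    "write_report_json",
    "plot_wave",
]

#: default run length of the ΔIPH% rule (five consecutive deltas)
DEFAULT_RUN_LENGTH = 5
#: dips that stay above this fraction of baseline are not blinks
REJECT_BASELINE_FRAC = 0.8


@dataclass(frozen=True)
class BlinkWave:
    """Per-frame IPH% series (as fractions of image height) at a frame rate."""

    iph_frac: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.iph_frac, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a blink wave needs at least 2 frames")
        if not np.isfinite(arr).all():
            raise ValueError("wave contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("IPH fractions must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "iph_frac", arr)

    def __len__(self) -> int:
        return int(self.iph_frac.size)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    @property
    def iph_pct(self) -> np.ndarray:
        """IPH% on the 0–100 scale."""
        return self.iph_frac * 100.0


@dataclass
class BlinkEvent:
    """One detected blink candidate with its classification and phases.

    ``closing_s``/``closed_s``/``opening_s`` are None for rejected events.
    """

    start_f: int
    end_f: int
    trough_f: int
    baseline_frac: float
    trough_frac: float
    type: str  # "complete" | "incomplete" | "rejected"
    closing_s: float | None = None
    closed_s: float | None = None
    opening_s: float | None = None


@dataclass
class BlinkMetrics:
    """Per-recording blink summary: counts, incomplete-blink rate, relative IPH%."""

    ib: int
    cb: int
    tb: int
    ibr: float | None
    relative_iph: float | None


def wave_from_masks(
    masks: Sequence[np.ndarray],
    image_h: int,
    fps: float,
    labels: Sequence[str] | None = None,
) -> BlinkWave:
    """Build the blink wave from per-frame masks (+ optional frame states).

    Each frame's IPH is the maximum column-wise vertical extent of its
    eyelid-region mask; if a frame state is given and equals
    ``"disappearance"`` the IPH is corrected to zero before normalizing.
    """
    from .cls import correct_iph
    from .seg import compute_iph

    if len(masks) == 0:
        raise ValueError("empty mask sequence")
    if labels is not None and len(labels) != len(masks):
        raise ValueError("labels and masks must align")
    frac = np.empty(len(masks), dtype=float)
    for i, mask in enumerate(masks):
        iph_px, _ = compute_iph(mask, image_h)
        if labels is not None:
            iph_px = correct_iph(labels[i], iph_px)
        frac[i] = iph_px / image_h
    return BlinkWave(iph_frac=frac, fps=fps)


def _median3(x: np.ndarray) -> np.ndarray:
    from scipy.ndimage import median_filter

    return median_filter(x, size=3, mode="nearest")


def detect_blink_events(
    wave: BlinkWave,
    k: int = DEFAULT_RUN_LENGTH,
    median_prefilter: bool = False,
) -> list[tuple[int, int]]:
    """Find candidate blink intervals with the ΔIPH% run rule.

    Returns ordered, pairwise-disjoint ``(start_f, end_f)`` frame-index
    pairs.  Ties (Δ = 0) break a run.  A start with no confirmed end before
    the recording finishes is dropped; a second start arriving before any
    end supersedes the first (keep-latest).
    """
    if k < 1:
        raise ValueError("run length k must be >= 1")
    x = wave.iph_frac
    if median_prefilter:
        x = _median3(x)
    delta = x[:-1] - x[1:]  # delta[t-1] = iph[t-1] - iph[t]; >0 closing
    sign = np.sign(delta)

    events: list[tuple[int, int]] = []
    pending: int | None = None
    n = sign.size
    t = 0
    while t < n:
        s = sign[t]
        u = t
        while u < n and sign[u] == s:
            u += 1
        run_len = u - t  # deltas t..u-1 share this sign
        if s > 0 and run_len >= k:
            # delta index t corresponds to the step from frame t to t+1
            pending = t  # start = first frame of the spanning window
        elif s < 0 and run_len >= k and pending is not None:
            events.append((pending, u))  # last frame of the maximal run
            pending = None
        t = u
    return events


def filter_and_classify_events(
    candidates: Sequence[tuple[int, int]],
    wave: BlinkWave,
    reject_frac: float = REJECT_BASELINE_FRAC,
) -> list[BlinkEvent]:
    """Classify candidate intervals as complete / incomplete / rejected.

    Baseline is the IPH% at the start frame.  The trough is the interval
    minimum; its frame is the first frame attaining it.  Dips whose trough
    stays above ``reject_frac`` of baseline are kept in the output with
    type ``"rejected"`` but excluded from blink counts; phase durations are
    attached to the non-rejected events.
    """
    out: list[BlinkEvent] = []
    x = wave.iph_frac
    for start_f, end_f in candidates:
        seg = x[start_f : end_f + 1]
        trough_rel = int(np.argmin(seg))
        trough_f = start_f + trough_rel
        baseline = float(x[start_f])
        trough = float(seg[trough_rel])
        if trough > reject_frac * baseline:
            kind = "rejected"
        elif trough == 0.0:
            kind = "complete"
        else:
            kind = "incomplete"
        ev = BlinkEvent(
            start_f=start_f,
            end_f=end_f,
            trough_f=trough_f,
            baseline_frac=baseline,
            trough_frac=trough,
            type=kind,
        )
        if kind != "rejected":
            ev.closing_s, ev.closed_s, ev.opening_s = phase_durations(ev, wave)
        out.append(ev)
    return out


def phase_durations(event: BlinkEvent, wave: BlinkWave) -> tuple[float, float, float]:
    """Closing / closed / opening durations (s) of a non-rejected blink.

    Complete blink: the closed phase spans the zero run containing the
    trough; closing ends at its first frame, opening starts at its last.
    Incomplete blink: the closed phase is absent; the boundary is the first
    frame attaining the trough.  The three durations always telescope to
    the full event duration ``(end_f - start_f) / fps``.
    """
    if event.type == "rejected":
        raise ValueError("phase durations are undefined for rejected events")
    x = wave.iph_frac
    fps = wave.fps
    if event.type == "complete":
        lo = hi = event.trough_f
        while lo - 1 >= event.start_f and x[lo - 1] == 0.0:
            lo -= 1
        while hi + 1 <= event.end_f and x[hi + 1] == 0.0:
            hi += 1
        closing = (lo - event.start_f) / fps
        closed = (hi - lo) / fps
        opening = (event.end_f - hi) / fps
    else:
        closing = (event.trough_f - event.start_f) / fps
        closed = 0.0
        opening = (event.end_f - event.trough_f) / fps
    return closing, closed, opening


def relative_iph(wave: BlinkWave) -> float:
    """Mean IPH% over the recording divided by its maximum IPH%.

    A proxy for the extent of incomplete blinking: 1.0 for an eye that never
    moves, lower when the lids spend time below the widest opening.
    """
    m = float(wave.iph_frac.max())
    if m <= 0.0:
        raise ValueError("relative IPH% is undefined for an all-zero wave")
    return float(wave.iph_frac.mean()) / m


def summarize_metrics(events: Sequence[BlinkEvent], wave: BlinkWave) -> BlinkMetrics:
    """Count incomplete/complete/total blinks and attach IBR and relative IPH%."""
    ib = sum(1 for e in events if e.type == "incomplete")
    cb = sum(1 for e in events if e.type == "complete")
    tb = ib + cb
    ibr = ib / tb if tb > 0 else None
    try:
        rel = relative_iph(wave)
    except ValueError:
        rel = None
    return BlinkMetrics(ib=ib, cb=cb, tb=tb, ibr=ibr, relative_iph=rel)


def analyze_wave(
    wave: BlinkWave,
    k: int = DEFAULT_RUN_LENGTH,
    reject_frac: float = REJECT_BASELINE_FRAC,
    median_prefilter: bool = False,
) -> tuple[list[BlinkEvent], BlinkMetrics]:
    """Convenience pipeline: detect -> classify -> summarize."""
    candidates = detect_blink_events(wave, k=k, median_prefilter=median_prefilter)
    events = filter_and_classify_events(candidates, wave, reject_frac=reject_frac)
    return events, summarize_metrics(events, wave)


# ---------------------------------------------------------------------------
# IO


def read_wave_csv(path: str | Path, fps: float | None = None) -> BlinkWave:
    """Read a wave CSV with columns (frame, time_s, iph_pct).

    ``fps`` is inferred from the time column when not supplied.
    """
    df = pd.read_csv(path)
    if "iph_pct" not in df.columns:
        raise ValueError("wave CSV must have an iph_pct column")
    if fps is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError("cannot infer fps: provide fps or a time_s column")
        dt = np.diff(df["time_s"].to_numpy())
        fps = 1.0 / float(np.median(dt))
    return BlinkWave(iph_frac=df["iph_pct"].to_numpy(dtype=float) / 100.0, fps=fps)


def write_wave_csv(wave: BlinkWave, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(wave)),
            "time_s": wave.time_s,
            "iph_pct": wave.iph_pct,
        }
    )
    df.to_csv(path, index=False)


def write_report_json(
    events: Sequence[BlinkEvent],
    metrics: BlinkMetrics,
    path: str | Path,
    provenance: dict | None = None,
) -> None:
    report = {
        "events": [dataclasses.asdict(e) for e in events],
        "metrics": dataclasses.asdict(metrics),
    }
    if provenance is not None:
        report["provenance"] = provenance
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def events_to_frame(events: Sequence[BlinkEvent]) -> pd.DataFrame:
    """Per-event table suitable for CSV export."""
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


def plot_wave(
    wave: BlinkWave,
    events: Sequence[BlinkEvent] = (),
    path: str | Path | None = None,
    ax=None,
):
    """Plot the blink wave with start (purple), trough (red), end (black) dots."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    t = wave.time_s
    ax.plot(t, wave.iph_pct, lw=1, color="steelblue")
    for e in events:
        if e.type == "rejected":
            continue
        ax.plot(t[e.start_f], wave.iph_pct[e.start_f], "o", color="purple")
        ax.plot(t[e.trough_f], wave.iph_pct[e.trough_f], "o", color="red")
        ax.plot(t[e.end_f], wave.iph_pct[e.end_f], "o", color="black")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("IPH%")
    ax.set_ylim(-2, 102)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
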