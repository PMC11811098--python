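"""Blink-wave engine: run rule, classification, phases, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from blinkwave.wave import (
    BlinkWave,
    analyze_wave,
    detect_blink_events,
    filter_and_classify_events,
    phase_durations,
    relative_iph,
    summarize_metrics,
)

HAND_TRACE = [0.10, 0.10, 0.10, 0.08, 0.06, 0.04, 0.02, 0.00,
              0.00, 0.02, 0.04, 0.06, 0.08, 0.10, 0.10, 0.10]


def brute_force_events(x: np.ndarray, k: int = 5) -> list[tuple[int, int]]:
    """Independent O(n·k) rescan of the run rule, written position by position.

    A start candidate at frame t requires iph[t] > iph[t+1] > ... > iph[t+k]
    (k strictly falling steps); an end requires k strictly rising steps and
    extends while the rise continues.  Keep-latest start, first matching end.
    """
    n = len(x)
    events = []
    pending = None
    t = 0
    while t < n - 1:
        if all(x[t + j] > x[t + j + 1] for j in range(k)) if t + k < n else False:
            # only a *new* falling run can open a start
            if t == 0 or not x[t - 1] > x[t]:
                pending = t
                # skip to the end of this falling run
                while t + 1 < n and x[t] > x[t + 1]:
                    t += 1
                continue
        if pending is not None and t + k < n and all(
            x[t + j] < x[t + j + 1] for j in range(k)
        ):
            if t == 0 or not x[t - 1] < x[t]:
                e = t
                while e + 1 < n and x[e] < x[e + 1]:
                    e += 1
                events.append((pending, e))
                pending = None
                t = e
                continue
        t += 1
    return events


class TestDetect:
    def test_hand_trace(self):
        wave = BlinkWave(np.array(HAND_TRACE), fps=30)
        assert detect_blink_events(wave) == [(2, 13)]

    def test_constant_wave_has_no_events(self):
        wave = BlinkWave(np.full(60, 0.3), fps=30)
        assert detect_blink_events(wave) == []

    def test_short_dip_rejected_by_run_length(self):
        x = np.full(30, 0.3)
        x[10:13] = [0.25, 0.20, 0.15]  # only 3 falling steps
        x[13:16] = [0.20, 0.25, 0.30]
        wave = BlinkWave(x, fps=30)
        assert detect_blink_events(wave, k=5) == []
        assert len(detect_blink_events(wave, k=3)) == 1

    def test_bad_run_length(self):
        with pytest.raises(ValueError):
            detect_blink_events(BlinkWave(np.full(10, 0.3), 30), k=0)

    @pytest.mark.parametrize("seed", range(40))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 600))
        x = np.clip(rng.normal(0.3, 0.12, size=n), 0, 1)
        if rng.random() < 0.3:  # inject plateaus and zeros
            x[rng.integers(0, n, size=n // 4)] = 0.0
        wave = BlinkWave(x, fps=30)
        assert detect_blink_events(wave) == brute_force_events(x)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        st.integers(min_value=2, max_value=120),
        elements=st.sampled_from([0.0, 0.1, 0.2, 0.25, 0.3, 0.35, 0.4]),
    )
)
def test_run_rule_property_matches_brute_force(x):
    """Quantized waves (many ties and plateaus) exercise the run-rule edges."""
    wave = BlinkWave(x, fps=30)
    assert detect_blink_events(wave) == brute_force_events(x)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        st.integers(min_value=2, max_value=200),
        elements=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    )
)
def test_relative_iph_always_in_unit_interval(x):
    wave = BlinkWave(x, fps=30)
    if x.max() == 0:
        with pytest.raises(ValueError):
            relative_iph(wave)
    else:
        assert 0.0 <= relative_iph(wave) <= 1.0


class TestClassify:
    @pytest.mark.parametrize(
        "trough,expected",
        [(0.0, "complete"), (0.04, "incomplete"), (0.09, "rejected")],
    )
    def test_threshold_arithmetic(self, trough, expected):
        # baseline 0.10: the 80% rule rejects troughs above 0.08
        x = np.concatenate([
            np.full(3, 0.10),
            np.linspace(0.10, trough, 7)[1:],
            np.linspace(trough, 0.10, 7)[1:],
            np.full(3, 0.10),
        ])
        wave = BlinkWave(x, fps=30)
        events = filter_and_classify_events(detect_blink_events(wave), wave)
        assert [e.type for e in events] == [expected]

    def test_lowering_threshold_never_adds_blinks(self):
        rng = np.random.default_rng(3)
        x = np.clip(rng.normal(0.3, 0.1, size=400), 0, 1)
        wave = BlinkWave(x, fps=30)
        cands = detect_blink_events(wave)
        counts = []
        for frac in (0.9, 0.8, 0.5, 0.2):
            evs = filter_and_classify_events(cands, wave, reject_frac=frac)
            counts.append(sum(e.type != "rejected" for e in evs))
        assert counts == sorted(counts, reverse=True)


class TestPhases:
    def test_hand_trace_phases(self):
        wave = BlinkWave(np.array(HAND_TRACE), fps=30)
        (event,) = filter_and_classify_events(detect_blink_events(wave), wave)
        assert event.type == "complete"
        assert event.closing_s == pytest.approx(5 / 30)
        assert event.closed_s == pytest.approx(1 / 30)
        assert event.opening_s == pytest.approx(5 / 30)

    def test_incomplete_phase_split_at_trough(self):
        x = np.concatenate([
            np.full(11, 0.30),
            np.linspace(0.30, 0.10, 7)[1:],   # trough at frame 16
            np.linspace(0.10, 0.30, 7)[1:],   # end at frame 22
            np.full(8, 0.30),
        ])
        wave = BlinkWave(x, fps=30)
        (event,) = filter_and_classify_events(detect_blink_events(wave), wave)
        assert (event.start_f, event.trough_f, event.end_f) == (10, 16, 22)
        assert event.closing_s == pytest.approx(0.2)
        assert event.closed_s == 0.0
        assert event.opening_s == pytest.approx(0.2)

    def test_phase_conservation(self):
        rng = np.random.default_rng(11)
        x = np.clip(rng.normal(0.3, 0.15, size=500), 0, 1)
        wave = BlinkWave(x, fps=30)
        events = filter_and_classify_events(detect_blink_events(wave), wave)
        for e in events:
            if e.type == "rejected":
                continue
            total = (e.end_f - e.start_f) / wave.fps
            assert e.closing_s + e.closed_s + e.opening_s == pytest.approx(total)

    def test_rejected_event_has_no_phases(self):
        wave = BlinkWave(np.array(HAND_TRACE), fps=30)
        (event,) = filter_and_classify_events(detect_blink_events(wave), wave)
        event.type = "rejected"
        with pytest.raises(ValueError):
            phase_durations(event, wave)


class TestMetrics:
    def test_relative_iph_examples(self):
        assert relative_iph(BlinkWave(np.full(10, 0.2), 30)) == 1.0
        assert relative_iph(
            BlinkWave(np.array([0.1, 0.1, 0.0, 0.2]), 30)
        ) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            relative_iph(BlinkWave(np.zeros(10), 30))

    def test_counts_and_ibr(self):
        wave = BlinkWave(np.array(HAND_TRACE), fps=30)
        events = filter_and_classify_events(detect_blink_events(wave), wave)
        events = events * 1  # one complete
        from blinkwave.wave import BlinkEvent

        events.append(BlinkEvent(0, 5, 3, 0.1, 0.02, "incomplete", 0.1, 0, 0.07))
        events.append(BlinkEvent(0, 5, 3, 0.1, 0.02, "incomplete", 0.1, 0, 0.07))
        events.append(BlinkEvent(0, 5, 3, 0.1, 0.09, "rejected"))
        m = summarize_metrics(events, wave)
        assert (m.ib, m.cb, m.tb) == (2, 1, 3)
        assert m.ibr == pytest.approx(2 / 3)

    def test_no_events(self):
        wave = BlinkWave(np.full(10, 0.3), 30)
        m = summarize_metrics([], wave)
        assert (m.ib, m.cb, m.tb) == (0, 0, 0)
        assert m.ibr is None

    def test_all_complete_gives_zero_ibr(self):
        wave = BlinkWave(np.array(HAND_TRACE), fps=30)
        events, metrics = analyze_wave(wave)
        assert metrics.cb == 1 and metrics.ibr == 0.0


class TestValidation:
    def test_wave_value_range(self):
        with pytest.raises(ValueError):
            BlinkWave(np.array([0.1, 1.2]), 30)
        with pytest.raises(ValueError):
            BlinkWave(np.array([0.1]), 30)
        with pytest.raises(ValueError):
            BlinkWave(np.array([0.1, 0.2]), 0)
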