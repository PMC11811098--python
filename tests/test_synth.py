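"""Synthetic recordings: schedules, waves, rendering, ground truth."""

import numpy as np
import pytest

from blinkwave.synth import (
    MAX_APERTURE_FRAC,
    BlinkEventSpec,
    SyntheticSpec,
    render_frame,
    sample_schedule,
    synthesize_video,
    synthesize_wave,
)
from blinkwave.wave import analyze_wave, wave_from_masks


class TestSchedule:
    def test_zero_events(self):
        assert sample_schedule(0, 20, 30, 0.5, seed=7) == []

    def test_all_incomplete_and_disjoint(self):
        events = sample_schedule(3, 20, 30, mix=1.0, seed=7)
        assert len(events) == 3
        assert all(e.label == "incomplete" for e in events)
        # brute-force pairwise interval disjointness
        spans = [(e.onset_s, e.onset_s + e.duration_s) for e in events]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                lo1, hi1 = spans[i]
                lo2, hi2 = spans[j]
                assert hi1 <= lo2 or hi2 <= lo1

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            sample_schedule(50, 20, 30, 0.5, seed=7,
                            closing_range_s=(0.25, 0.3),
                            opening_range_s=(0.25, 0.3))

    def test_determinism(self):
        a = sample_schedule(4, 20, 30, 0.5, seed=13)
        b = sample_schedule(4, 20, 30, 0.5, seed=13)
        assert a == b

    def test_mix_rounding(self):
        events = sample_schedule(4, 20, 30, mix=0.5, seed=3)
        assert sum(e.label == "incomplete" for e in events) == 2


class TestWave:
    def test_constant_without_events(self):
        spec = SyntheticSpec(events=())
        wave, truth = synthesize_wave(spec)
        assert len(wave) == 600
        assert np.all(wave.iph_frac == spec.baseline_iph_frac)
        assert not truth.closed.any()

    def test_complete_event_zero_run(self):
        ev = BlinkEventSpec(onset_s=1.0, closing_s=0.2, closed_s=0.1,
                            opening_s=0.3, trough_frac=0.0, label="complete")
        spec = SyntheticSpec(events=(ev,))
        wave, truth = synthesize_wave(spec)
        assert wave.iph_frac.min() == 0.0
        zero_run = int((wave.iph_frac == 0).sum())
        assert abs(zero_run - (round(0.1 * 30) + 1)) <= 1
        assert truth.closed.sum() == zero_run

    def test_same_seed_same_wave(self):
        ev = BlinkEventSpec(1.0, 0.2, 0.0, 0.3, 0.3, "incomplete")
        spec = SyntheticSpec(events=(ev,), wave_noise_sd=0.01, seed=5)
        w1, _ = synthesize_wave(spec)
        w2, _ = synthesize_wave(spec)
        assert np.array_equal(w1.iph_frac, w2.iph_frac)

    def test_overlapping_events_rejected(self):
        e1 = BlinkEventSpec(1.0, 0.2, 0.1, 0.3, 0.0, "complete")
        e2 = BlinkEventSpec(1.3, 0.2, 0.0, 0.3, 0.4, "incomplete")
        with pytest.raises(ValueError, match="overlap"):
            SyntheticSpec(events=(e1, e2))

    def test_round_trip_schedule_recovery(self):
        """Noise-free generated waves are recovered exactly by the wave engine."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sched = sample_schedule(int(rng.integers(1, 7)), 20, 30,
                                    mix=float(rng.uniform(0, 1)),
                                    seed=seed + 100)
            spec = SyntheticSpec(events=tuple(sched), seed=seed)
            wave, truth = synthesize_wave(spec)
            events, metrics = analyze_wave(wave)
            kept = [e for e in events if e.type != "rejected"]
            assert len(kept) == len(truth.events)
            for got, want in zip(kept, truth.events):
                assert got.type == want["type"]
                assert abs(got.start_f - want["start_f"]) <= 1
                assert abs(got.end_f - want["end_f"]) <= 1
                assert abs(got.closing_s - want["closing_s"]) <= 1 / 30
                assert abs(got.closed_s - want["closed_s"]) <= 1 / 30
                assert abs(got.opening_s - want["opening_s"]) <= 1 / 30


class TestRender:
    SPEC = SyntheticSpec(image_w=200, image_h=150)

    def test_closed_eye_empty_mask(self):
        _, mask = render_frame(0.0, self.SPEC)
        assert mask.sum() == 0

    def test_mask_extent_matches_iph(self):
        from blinkwave.seg import compute_iph

        spec = SyntheticSpec()  # 800×600
        _, mask = render_frame(0.20, spec)
        px, frac = compute_iph(mask, 600)
        assert abs(px - 120) <= 1

    def test_geometric_maximum_enforced(self):
        with pytest.raises(ValueError, match="maximum"):
            render_frame(0.95, self.SPEC)

    def test_mask_binary_and_shaped(self):
        img, mask = render_frame(0.3, self.SPEC)
        assert img.shape == mask.shape == (150, 200)
        assert set(np.unique(mask)) <= {0, 1}


class TestVideo:
    def _small_spec(self, **kw):
        sched = sample_schedule(kw.pop("n_events", 1), kw.pop("dur", 3.0), 30,
                                kw.pop("mix", 0.0), seed=kw.pop("sched_seed", 4))
        return SyntheticSpec(duration_s=3.0, image_w=160, image_h=120,
                             events=tuple(sched), **kw)

    def test_no_events_identical_masks(self):
        spec = SyntheticSpec(duration_s=1.0, image_w=80, image_h=64, events=())
        frames, masks, _ = synthesize_video(spec)
        assert (masks == masks[0]).all()

    def test_empty_masks_equal_closed_frames(self):
        spec = self._small_spec(n_events=1, mix=0.0)  # one complete blink
        frames, masks, truth = synthesize_video(spec)
        empty = masks.reshape(masks.shape[0], -1).sum(axis=1) == 0
        assert np.array_equal(empty, truth.closed)

    def test_mask_wave_round_trip(self):
        spec = self._small_spec(n_events=2, mix=0.5, sched_seed=9)
        frames, masks, truth = synthesize_video(spec)
        wave = wave_from_masks(list(masks), spec.image_h, spec.fps)
        assert np.abs(wave.iph_frac - truth.iph_frac).max() <= 1.0 / spec.image_h

    def test_determinism(self):
        spec = self._small_spec(pixel_noise_sd=5.0)
        f1, m1, _ = synthesize_video(spec)
        f2, m2, _ = synthesize_video(spec)
        assert np.array_equal(f1, f2) and np.array_equal(m1, m2)


class TestSpecValidation:
    def test_event_past_end(self):
        ev = BlinkEventSpec(19.8, 0.2, 0.0, 0.3, 0.4, "incomplete")
        with pytest.raises(ValueError):
            SyntheticSpec(events=(ev,))

    def test_trough_label_consistency(self):
        with pytest.raises(ValueError):
            BlinkEventSpec(1.0, 0.2, 0.0, 0.3, 0.0, "incomplete")
        with pytest.raises(ValueError):
            BlinkEventSpec(1.0, 0.2, 0.1, 0.3, 0.5, "complete")
        with pytest.raises(ValueError):
            BlinkEventSpec(1.0, 0.2, 0.1, 0.3, 0.5, "incomplete")

    def test_baseline_bounds(self):
        with pytest.raises(ValueError):
            SyntheticSpec(baseline_iph_frac=MAX_APERTURE_FRAC + 0.01)

    def test_yaml_round_trip(self, tmp_path):
        sched = sample_schedule(2, 20, 30, 0.5, seed=2)
        spec = SyntheticSpec(events=tuple(sched), seed=3)
        spec.to_yaml(tmp_path / "spec.yaml")
        assert SyntheticSpec.from_yaml(tmp_path / "spec.yaml") == spec
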