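"""Filtering, thresholding, closing and fixed-length extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dusbeat.synth import DusRecording, SynthConfig, generate_recording
from dusbeat.segmentation import (
    SegmenterConfig,
    bandpass_filter,
    binarize_and_close,
    compute_envelope,
    dynamic_threshold,
    extract_low_level_segments,
    extract_segments,
    segment_recording,
)
from conftest import overlap_ms


def _tone(freq_hz, n=4000, amp=0.5):
    t = np.arange(n) / 1000.0
    return amp * np.sin(2 * np.pi * freq_hz * t)


class TestBandpass:
    def test_passband_tone_nearly_unattenuated(self):
        x = _tone(200.0)
        y = bandpass_filter(x)
        gain_db = 20 * np.log10(np.std(y[500:-500]) / np.std(x[500:-500]))
        assert gain_db > -1.0

    def test_dc_offset_removed(self):
        y = bandpass_filter(np.full(3000, 0.4))
        assert abs(np.mean(y[500:-500])) < 1e-6

    def test_stopband_tone_heavily_attenuated(self):
        # low-pass edge 300 Hz; 10x above is aliased, use 30 Hz below highpass
        x = _tone(10.0)
        y = bandpass_filter(x)
        gain_db = 20 * np.log10(np.std(y[500:-500]) / np.std(x[500:-500]))
        assert gain_db < -20.0

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError, match="band edges"):
            SegmenterConfig(highpass_hz=100.0, lowpass_hz=600.0)


class TestEnvelope:
    def test_zero_in_zero_out(self):
        assert np.all(compute_envelope(np.zeros(1000)) == 0.0)

    def test_constant_tone_gives_flat_envelope(self):
        env = compute_envelope(_tone(200.0, n=6000))
        core = env[1000:-1000]
        assert np.std(core) / np.mean(core) < 0.05

    def test_homogeneous_in_amplitude(self):
        x = bandpass_filter(_tone(180.0))
        np.testing.assert_allclose(
            compute_envelope(3.0 * x), 3.0 * compute_envelope(x), atol=1e-9
        )

    def test_non_negative(self):
        rng = np.random.default_rng(0)
        env = compute_envelope(rng.standard_normal(5000))
        assert np.all(env >= 0.0)


class TestDynamicThreshold:
    def test_constant_envelope_constant_threshold(self):
        cfg = SegmenterConfig(threshold_statistic="rms", threshold_factor=1.5)
        env = np.full(9000, 0.2)
        track = dynamic_threshold(env, cfg)
        np.testing.assert_allclose(track, 1.5 * 0.2)

    def test_per_interval_scaling(self):
        """Doubling the envelope in one interval doubles only its threshold."""
        cfg = SegmenterConfig(threshold_statistic="rms")
        step = int(cfg.threshold_update_interval_ms)
        env = np.concatenate([np.full(step, 0.1), np.full(step, 0.2)])
        track = dynamic_threshold(env, cfg)
        assert np.allclose(track[:step], cfg.threshold_factor * 0.1)
        assert np.allclose(track[step:], cfg.threshold_factor * 0.2)

    def test_percentile_statistic_tracks_quiet_floor(self):
        # 70% duty-cycle bursts: percentile sits at the noise floor, rms inside
        env = np.tile(np.concatenate([np.full(700, 0.5), np.full(300, 0.05)]), 4)
        cfg = SegmenterConfig(threshold_percentile=20.0, threshold_factor=2.0)
        track = dynamic_threshold(env, cfg)
        assert np.all(track <= 0.2)  # 2 x 0.05-ish, far below burst level

    def test_tail_carries_last_value(self):
        cfg = SegmenterConfig(threshold_statistic="rms")
        step = int(cfg.threshold_update_interval_ms)
        env = np.concatenate([np.full(step, 0.3), np.full(100, 0.3)])
        track = dynamic_threshold(env, cfg)
        assert track[-1] == pytest.approx(cfg.threshold_factor * 0.3)


class TestClosing:
    def test_short_gap_merged(self):
        env = np.concatenate([np.ones(100), np.zeros(40), np.ones(100)])
        mask = binarize_and_close(env, np.full(env.size, 0.5), 60)
        assert mask.all()

    def test_long_gap_preserved(self):
        env = np.concatenate([np.ones(100), np.zeros(80), np.ones(100)])
        mask = binarize_and_close(env, np.full(env.size, 0.5), 60)
        assert not mask[100:180].any()
        assert mask[:100].all() and mask[180:].all()

    def test_all_below_threshold_empty_mask(self):
        mask = binarize_and_close(np.zeros(500), np.full(500, 0.5), 60)
        assert not mask.any()

    def test_leading_and_trailing_gaps_untouched(self):
        env = np.concatenate([np.zeros(30), np.ones(100), np.zeros(30)])
        mask = binarize_and_close(env, np.full(env.size, 0.5), 60)
        assert not mask[:30].any() and not mask[-30:].any()


def _recording_from(samples):
    return DusRecording(samples=samples, sample_rate=1000, condition="nst",
                        annotations=[], seed=0)


class TestExtraction:
    def test_run_shorter_than_min_discarded(self):
        mask = np.zeros(2000, dtype=bool)
        mask[100:200] = True  # 100 ms
        segs = extract_segments(mask, _recording_from(np.ones(2000) * 0.1))
        assert segs == []

    def test_long_run_truncated_to_350(self):
        mask = np.zeros(2000, dtype=bool)
        mask[100:600] = True  # 500 ms
        segs = extract_segments(mask, _recording_from(np.ones(2000) * 0.1))
        assert len(segs) == 1
        assert segs[0].raw_length_ms == 350.0
        assert segs[0].start_ms == 100.0

    def test_padding_is_exact_zeros(self):
        mask = np.zeros(2000, dtype=bool)
        mask[100:400] = True  # 300 ms
        segs = extract_segments(mask, _recording_from(np.ones(2000) * 0.1))
        (seg,) = segs
        assert seg.samples.size == 350
        assert np.all(seg.samples[:300] == 0.1)
        assert np.all(seg.samples[300:] == 0.0)

    def test_low_level_count_follows_span_rule(self):
        mask = np.zeros(3500, dtype=bool)  # all below threshold
        segs = extract_low_level_segments(mask, _recording_from(np.zeros(3500)))
        assert len(segs) == 3500 // 350
        starts = [s.start_ms for s in segs]
        assert starts == sorted(starts)

    def test_all_above_threshold_gives_no_low_level(self):
        mask = np.ones(2000, dtype=bool)
        segs = extract_low_level_segments(mask, _recording_from(np.zeros(2000)))
        assert segs == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5000), st.integers(1, 800)),
                    min_size=0, max_size=8))
    def test_segment_invariants_on_random_masks(self, spans):
        """Every emitted segment is 250-350 ms raw, 350 samples padded."""
        mask = np.zeros(6000, dtype=bool)
        for start, length in spans:
            mask[start : start + length] = True
        rec = _recording_from(np.random.default_rng(0).uniform(-1, 1, 6000))
        for seg in extract_segments(mask, rec):
            assert 250 <= seg.raw_length_ms <= 350
            assert seg.samples.size == 350
            assert np.all(seg.samples[int(seg.raw_length_ms):] == 0.0)


class TestOnCleanRecordings:
    @pytest.mark.parametrize("fixture", ["clean_labor_recording", "clean_nst_recording"])
    def test_beat_recall_and_precision(self, fixture, request):
        """Artifact-free recordings: >=90% of beats found, no false segments."""
        rec = request.getfixturevalue(fixture)
        above, below, _ = segment_recording(rec)
        beats = rec.events("heartbeat")
        hit = sum(
            1 for b in beats if any(overlap_ms(s, b) > 0 for s in above)
        )
        assert hit / len(beats) >= 0.9
        for s in above:
            assert any(overlap_ms(s, b) > 0 for b in beats)

    def test_segmentation_deterministic(self, clean_labor_recording):
        a1, b1, _ = segment_recording(clean_labor_recording)
        a2, b2, _ = segment_recording(clean_labor_recording)
        assert [s.start_ms for s in a1] == [s.start_ms for s in a2]
        np.testing.assert_array_equal(a1[0].samples, a2[0].samples)
        assert len(b1) == len(b2)
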