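"""Envelope-based segmentation of DUS recordings.

Stage one of the semi-automatic labeling pipeline: band-pass filter the
audio to the Doppler band of cardiac motion, form a smoothed magnitude
envelope, threshold it with a dynamically updated (per analysis
interval) level, close short gaps so a single heartbeat is not split,
and cut fixed-length excerpts:

* above-threshold runs of 250-350 ms become candidate heartbeat /
  artifact segments;
* below-threshold spans yield "low-level" (noise) segments.

All segments are zero-padded on the right to exactly 350 ms so that a
fixed-length classifier can consume them; the excerpt is cut from the
normalized raw waveform, not the filtered one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.signal import butter, sosfiltfilt

from dusbeat.synth import DusRecording, SAMPLE_RATE

#: canonical category order used everywhere downstream
CATEGORIES = (
    "low_level_signal",
    "single_fetal_heartbeat",
    "multiple_heartbeats",
    "artifact",
)

LABELS = CATEGORIES + ("unlabeled",)


@dataclass
class SegmenterConfig:
    highpass_hz: float = 100.0
    lowpass_hz: float = 300.0
    envelope_cutoff_hz: float = 25.0
    threshold_factor: float = 2.0
    threshold_statistic: str = "percentile"  # or "rms"
    threshold_percentile: float = 20.0
    threshold_update_interval_ms: float = 3000.0
    closing_length_ms: float = 60.0
    min_segment_ms: float = 250.0
    max_segment_ms: float = 350.0
    fixed_length_ms: float = 350.0
    cut_from_filtered: bool = False

    def __post_init__(self) -> None:
        nyquist = SAMPLE_RATE / 2.0
        if not (0.0 < self.highpass_hz < self.lowpass_hz < nyquist):
            raise ValueError(
                f"band edges ({self.highpass_hz}, {self.lowpass_hz}) must satisfy "
                f"0 < high-pass < low-pass < {nyquist} Hz"
            )
        if not (self.min_segment_ms < self.max_segment_ms == self.fixed_length_ms):
            raise ValueError("require min_segment < max_segment == fixed_length")
        if self.threshold_update_interval_ms <= self.max_segment_ms:
            raise ValueError("threshold update interval must exceed the max segment length")
        if self.threshold_statistic not in ("percentile", "rms"):
            raise ValueError("threshold_statistic must be 'percentile' or 'rms'")


@dataclass
class Segment:
    """A fixed-length (350 ms at 1 kHz) zero-padded excerpt."""

    recording_id: str
    start_ms: float
    raw_length_ms: float
    samples: np.ndarray
    label: str = "unlabeled"
    provenance: str = "auto"
    condition: str = "nst"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        n_fixed = int(round(350.0))
        if self.samples.size != n_fixed:
            raise ValueError(f"segment must hold exactly {n_fixed} samples")

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.raw_length_ms


def bandpass_filter(
    samples: np.ndarray, config: SegmenterConfig | None = None
) -> np.ndarray:
    """Zero-phase band-pass in the configured Doppler band."""
    config = config or SegmenterConfig()
    sos = butter(
        4,
        [config.highpass_hz, config.lowpass_hz],
        btype="bandpass",
        fs=SAMPLE_RATE,
        output="sos",
    )
    return sosfiltfilt(sos, np.asarray(samples, dtype=np.float64))


def compute_envelope(
    filtered: np.ndarray, config: SegmenterConfig | None = None
) -> np.ndarray:
    """Non-negative smoothed magnitude (rectify + low-pass)."""
    config = config or SegmenterConfig()
    rectified = np.abs(np.asarray(filtered, dtype=np.float64))
    if rectified.size == 0:
        return rectified
    sos = butter(4, config.envelope_cutoff_hz, btype="lowpass", fs=SAMPLE_RATE, output="sos")
    env = sosfiltfilt(sos, rectified)
    return np.maximum(env, 0.0)


def dynamic_threshold(
    envelope: np.ndarray, config: SegmenterConfig | None = None
) -> np.ndarray:
    """Piecewise-constant threshold track, one value per analysis interval.

    Each interval's threshold is ``threshold_factor`` times a running
    envelope statistic, recomputed per interval so it tracks slow gain
    drift. The default statistic is a low percentile of the envelope,
    which estimates the noise floor: heartbeat packets occupy most of a
    cardiac cycle, so a quiet-time statistic separates signal from
    noise where a whole-interval RMS would sit inside the beats.
    ``rms`` remains available for low-duty-cycle signals. A trailing
    partial interval carries the last full interval's value when empty.
    """
    config = config or SegmenterConfig()
    envelope = np.asarray(envelope, dtype=np.float64)
    n = envelope.size
    track = np.empty(n)
    step = int(round(config.threshold_update_interval_ms))
    last = 0.0
    for i0 in range(0, n, step):
        chunk = envelope[i0 : i0 + step]
        if chunk.size:
            if config.threshold_statistic == "rms":
                stat = float(np.sqrt(np.mean(chunk**2)))
            else:
                stat = float(np.percentile(chunk, config.threshold_percentile))
            last = config.threshold_factor * stat
        track[i0 : i0 + step] = last
    return track


def binarize_and_close(
    envelope: np.ndarray,
    threshold_track: np.ndarray,
    closing_length_ms: float,
) -> np.ndarray:
    """Active mask with morphological closing.

    The mask is true where envelope >= threshold; gaps strictly shorter
    than ``closing_length_ms`` between active runs are filled so that the
    quiet spell between the two sub-bursts of one heartbeat does not
    split the beat in two.
    """
    mask = np.asarray(envelope) >= np.asarray(threshold_track)
    closing = int(round(closing_length_ms))
    if closing <= 0 or not mask.any():
        return mask
    mask = mask.copy()
    # fill short False runs that are flanked by True on both sides
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    # edges[i] is last index before a flip; runs alternate
    starts = edges + 1
    for i in range(starts.size - 1):
        s, e = starts[i], starts[i + 1]
        if not mask[s] and (e - s) < closing:
            mask[s:e] = True
    return mask


def _runs(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    """Maximal [start, end) runs where mask == value."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    matches = mask == value
    padded = np.concatenate(([False], matches, [False]))
    flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(flips[2 * i], flips[2 * i + 1]) for i in range(flips.size // 2)]


def _cut_fixed(
    source: np.ndarray, i0: int, raw_len: int, fixed: int
) -> np.ndarray:
    out = np.zeros(fixed)
    chunk = source[i0 : i0 + raw_len]
    out[: chunk.size] = chunk
    return out


def extract_segments(
    mask: np.ndarray,
    recording: DusRecording,
    config: SegmenterConfig | None = None,
    source: np.ndarray | None = None,
) -> list[Segment]:
    """Above-threshold segments (unlabeled candidates).

    Active runs shorter than ``min_segment_ms`` are discarded; runs
    longer than ``max_segment_ms`` are truncated to their leading
    ``max_segment_ms`` (the onset carries the timing information).
    """
    config = config or SegmenterConfig()
    if source is None:
        source = bandpass_filter(recording.samples, config) if config.cut_from_filtered \
            else recording.samples
    min_len = int(round(config.min_segment_ms))
    max_len = int(round(config.max_segment_ms))
    fixed = int(round(config.fixed_length_ms))
    segments = []
    for s, e in _runs(mask, True):
        run_len = e - s
        if run_len < min_len:
            continue
        raw_len = min(run_len, max_len)
        segments.append(
            Segment(
                recording_id=recording.recording_id,
                start_ms=float(s),
                raw_length_ms=float(raw_len),
                samples=_cut_fixed(source, s, raw_len, fixed),
                condition=recording.condition,
            )
        )
    return segments


def extract_low_level_segments(
    mask: np.ndarray,
    recording: DusRecording,
    config: SegmenterConfig | None = None,
    source: np.ndarray | None = None,
) -> list[Segment]:
    """Below-threshold (noise-level) segments.

    Each maximal below-threshold span is tiled with non-overlapping
    fixed-length windows; a span yields floor(span / fixed_length)
    segments, each of full raw length.
    """
    config = config or SegmenterConfig()
    if source is None:
        source = bandpass_filter(recording.samples, config) if config.cut_from_filtered \
            else recording.samples
    fixed = int(round(config.fixed_length_ms))
    segments = []
    for s, e in _runs(mask, False):
        span = e - s
        for k in range(span // fixed):
            i0 = s + k * fixed
            segments.append(
                Segment(
                    recording_id=recording.recording_id,
                    start_ms=float(i0),
                    raw_length_ms=float(fixed),
                    samples=_cut_fixed(source, i0, fixed, fixed),
                    condition=recording.condition,
                )
            )
    return segments


def segment_recording(
    recording: DusRecording, config: SegmenterConfig | None = None
) -> tuple[list[Segment], list[Segment], np.ndarray]:
    """Full first/second-stage pass over one recording.

    Returns (above-threshold segments, low-level segments, active mask).
    """
    config = config or SegmenterConfig()
    filtered = bandpass_filter(recording.samples, config)
    envelope = compute_envelope(filtered, config)
    track = dynamic_threshold(envelope, config)
    mask = binarize_and_close(envelope, track, config.closing_length_ms)
    above = extract_segments(mask, recording, config)
    below = extract_low_level_segments(mask, recording, config)
    return above, below, mask
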