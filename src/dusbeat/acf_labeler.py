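"""Autocorrelation-based semi-automatic category assignment.

Clinical FHR monitors decide whether an interval of DUS audio carries a
usable heart rhythm by autocorrelating it: a periodic beat train gives a
clear ACF peak at the inter-beat lag (tau_max), artifacts and noise do
not. The same criterion drives the labeling here:

* above-threshold segment, tau_max exists in its analysis interval
  -> "single_fetal_heartbeat";
* above-threshold segment, no tau_max -> "artifact";
* below-threshold segment, no tau_max -> "low_level_signal";
* a fourth class, "multiple_heartbeats", is synthesized from every pair
  of consecutive single beats by re-cutting a window that starts half a
  beat (half the first segment's length) into the first beat, so it
  straddles both.

The ACF is the plain lagged product sum

    ACF(tau) = sum_{j=0}^{N-tau} x[n+j] * x[n+j+tau],   0 <= tau <= N

with inclusive upper limit. For tau_max detection the signal fed to the
ACF is the mean-removed magnitude envelope of the analysis interval:
raw Doppler audio is not phase-coherent from beat to beat, so - as in
hardware FHR autocorrelators - periodicity lives in the demodulated
envelope, not the carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from dusbeat.synth import DusRecording
from dusbeat.segmentation import (
    Segment,
    SegmenterConfig,
    bandpass_filter,
    compute_envelope,
)


@dataclass
class LabelingConfig:
    acf_window_ms: float = 2000.0       # N: >=2 beats must fit for a peak to exist
    tau_min_ms: float = 250.0           # 240 bpm
    tau_max_ms: float = 1200.0          # 50 bpm
    peak_acceptance: float = 0.45       # normalized ACF peak needed for tau_max to exist
    use_envelope: bool = True
    inclusive_upper: bool = True
    max_pair_gap_ms: float = 1200.0     # beats further apart are not "consecutive"

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_min_ms < self.tau_max_ms):
            raise ValueError("require 0 < tau_min < tau_max")
        if not (250.0 <= self.tau_min_ms and self.tau_max_ms <= 1200.0):
            raise ValueError("tau bounds must map to FHR within [50, 240] bpm")


@dataclass
class AcfWindow:
    """One evaluated autocorrelation window."""

    x: np.ndarray
    n: int
    N: int
    tau_range: tuple[int, int]
    values: np.ndarray
    tau_max: int | None


def acf(
    x: np.ndarray, n: int, N: int, tau: int, inclusive_upper: bool = True
) -> float:
    """Lagged product sum over one window.

    With ``inclusive_upper`` (the default) the sum runs j = 0 .. N - tau
    inclusive; the flag exists because the exclusive reading differs only
    by one term and never moves the argmax in practice.
    """
    x = np.asarray(x, dtype=np.float64)
    if not (0 <= tau <= N):
        raise ValueError(f"tau {tau} outside [0, N={N}]")
    if n < 0 or n + N >= x.size + (0 if inclusive_upper else 1):
        raise ValueError(
            f"window [n={n}, n+N={n + N}] out of bounds for signal of length {x.size}"
        )
    upper = N - tau + (1 if inclusive_upper else 0)  # number of terms
    return float(np.dot(x[n : n + upper], x[n + tau : n + tau + upper]))


def acf_curve(
    x: np.ndarray, n: int, N: int, taus: np.ndarray, inclusive_upper: bool = True
) -> np.ndarray:
    return np.array([acf(x, n, N, int(t), inclusive_upper) for t in taus])


def find_tau_max(
    x: np.ndarray,
    n: int,
    N: int,
    config: LabelingConfig | None = None,
) -> AcfWindow:
    """Locate the ACF peak lag within the plausible inter-beat range.

    tau_max "exists" when the peak, normalized by the zero-lag energy
    ACF(0), reaches ``peak_acceptance`` AND sits at an interior local
    maximum of the curve. The interior requirement separates true
    periodicity from mere self-similarity: a single wide transient
    yields an ACF that only decays with lag, so its maximum leans on
    the lag-range boundary and is rejected. Ties break toward the
    smaller lag (np.argmax takes the first maximum).
    """
    config = config or LabelingConfig()
    tau_lo = int(round(config.tau_min_ms))
    tau_hi = min(int(round(config.tau_max_ms)), N)
    taus = np.arange(tau_lo, tau_hi + 1)
    values = acf_curve(x, n, N, taus, config.inclusive_upper)
    energy = acf(x, n, N, 0, config.inclusive_upper)
    tau_max: int | None = None
    if energy > 0 and taus.size:
        k = int(np.argmax(values))
        interior = 0 < k < taus.size - 1
        if interior and values[k] / energy >= config.peak_acceptance:
            tau_max = int(taus[k])
    return AcfWindow(x=np.asarray(x, float), n=n, N=N,
                     tau_range=(tau_lo, tau_hi), values=values, tau_max=tau_max)


def _analysis_signal(
    recording: DusRecording,
    seg_config: SegmenterConfig,
    config: LabelingConfig,
) -> np.ndarray:
    """Signal the ACF runs on: mean-removed envelope (default) or raw."""
    if config.use_envelope:
        env = compute_envelope(bandpass_filter(recording.samples, seg_config), seg_config)
        return env - np.mean(env)
    return recording.samples


def interval_has_tau_max(
    analysis_signal: np.ndarray,
    center_ms: float,
    config: LabelingConfig | None = None,
) -> bool:
    """Evaluate tau_max existence in the window around one segment."""
    config = config or LabelingConfig()
    N = int(round(config.acf_window_ms))
    total = analysis_signal.size
    if total <= N:
        n = 0
        N = total - 1
    else:
        n = int(np.clip(round(center_ms - N / 2.0), 0, total - N - 1))
    return find_tau_max(analysis_signal, n, N, config).tau_max is not None


def categorize_segments(
    above: list[Segment],
    below: list[Segment],
    recording: DusRecording,
    config: LabelingConfig | None = None,
    seg_config: SegmenterConfig | None = None,
) -> list[Segment]:
    """Assign the three directly observable categories in place.

    The ACF is evaluated on the analysis interval surrounding each
    segment (not the 350 ms excerpt alone - two beats must fit for a
    period to be measurable). All labels get provenance "auto".
    """
    config = config or LabelingConfig()
    seg_config = seg_config or SegmenterConfig()
    signal = _analysis_signal(recording, seg_config, config)
    for seg in above:
        periodic = interval_has_tau_max(
            signal, seg.start_ms + seg.raw_length_ms / 2.0, config
        )
        seg.label = "single_fetal_heartbeat" if periodic else "artifact"
        seg.provenance = "auto"
    for seg in below:
        periodic = interval_has_tau_max(
            signal, seg.start_ms + seg.raw_length_ms / 2.0, config
        )
        seg.label = "low_level_signal" if not periodic else "unlabeled"
        seg.provenance = "auto"
    return above + [s for s in below if s.label != "unlabeled"]


def synthesize_multiple_heartbeats(
    beats: list[Segment],
    recording: DusRecording,
    config: LabelingConfig | None = None,
    seg_config: SegmenterConfig | None = None,
) -> list[Segment]:
    """Build "multiple_heartbeats" segments from consecutive beat pairs.

    For each pair of consecutive single-fetal-heartbeat segments, the
    extraction start shifts by half the first beat's length (half a
    wavelength, the segment being one cardiac cycle), so the new window
    carries the tail of the first beat and the head of the second.
    Isolated beats produce nothing.
    """
    config = config or LabelingConfig()
    seg_config = seg_config or SegmenterConfig()
    fixed = int(round(seg_config.fixed_length_ms))
    source = recording.samples
    beats = sorted(
        (b for b in beats if b.label == "single_fetal_heartbeat"),
        key=lambda b: b.start_ms,
    )
    out = []
    for first, second in zip(beats, beats[1:]):
        if second.start_ms - first.end_ms > config.max_pair_gap_ms:
            continue
        start = first.start_ms + first.raw_length_ms / 2.0
        # a second "fragment" must genuinely sit inside the shifted window:
        # require at least 50 ms of the second segment before the window ends,
        # otherwise the pair is too far apart for two beats in one segment
        if second.start_ms + 50.0 > start + fixed:
            continue
        span = second.end_ms - start
        raw_len = min(float(fixed), span, recording.duration_ms - start)
        if raw_len < seg_config.min_segment_ms:
            continue
        i0 = int(round(start))
        out.append(
            Segment(
                recording_id=recording.recording_id,
                start_ms=start,
                raw_length_ms=raw_len,
                samples=np.array(
                    np.pad(
                        source[i0 : i0 + int(round(raw_len))],
                        (0, fixed - int(round(raw_len))) if int(round(raw_len)) < fixed else (0, 0),
                    )[:fixed]
                ),
                label="multiple_heartbeats",
                provenance="auto",
                condition=recording.condition,
            )
        )
    return out


def label_recording(
    recording: DusRecording,
    config: LabelingConfig | None = None,
    seg_config: SegmenterConfig | None = None,
) -> list[Segment]:
    """Segmentation + ACF labeling + multiple-heartbeat synthesis."""
    from dusbeat.segmentation import segment_recording

    seg_config = seg_config or SegmenterConfig()
    above, below, _ = segment_recording(recording, seg_config)
    labeled = categorize_segments(above, below, recording, config, seg_config)
    beats = [s for s in labeled if s.label == "single_fetal_heartbeat"]
    multiples = synthesize_multiple_heartbeats(beats, recording, config, seg_config)
    return labeled + multiples
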