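import numpy as np
import pytest

from dusbeat.synth import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def clean_labor_recording():
    """30 s labor-preset recording without artifacts or dropout."""
    cfg = SynthConfig.labor(dropout_fraction=0.0, artifact_rate_per_min=0.0)
    return generate_recording(cfg, 30000, seed=11)


@pytest.fixture(scope="session")
def clean_nst_recording():
    cfg = SynthConfig.nst(dropout_fraction=0.0, artifact_rate_per_min=0.0)
    return generate_recording(cfg, 30000, seed=12)


@pytest.fixture(scope="session")
def mixed_recordings():
    """Both presets with artifacts, dropout and noise, several seeds."""
    recs = []
    for preset in ("labor", "nst"):
        for seed in (21, 22):
            cfg = getattr(SynthConfig, preset)()
            recs.append(generate_recording(cfg, 30000, seed=seed))
    return recs


def overlap_ms(seg, ev) -> float:
    return min(seg.end_ms, ev.end_ms) - max(seg.start_ms, ev.onset_ms)


def ground_truth_label(seg, rec, min_overlap_ms: float = 50.0) -> str:
    """Category a segment should get, judged from the generator's events."""
    nb = sum(1 for b in rec.events("heartbeat") if overlap_ms(seg, b) >= min_overlap_ms)
    na = sum(1 for a in rec.events("artifact") if overlap_ms(seg, a) >= min_overlap_ms)
    if nb >= 2:
        return "multiple_heartbeats"
    if nb == 1:
        return "single_fetal_heartbeat"
    if na >= 1:
        return "artifact"
    return "low_level_signal"
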