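"""Balanced dataset construction, fold splits and label-budget subsets.

The classifier sees a category-balanced corpus: the labeled pool holds
the same number of segments per category (downsampled to the smallest
category), split into k folds whose validation parts partition the pool
with a fixed per-category count; a roughly five-times-larger unlabeled
pool feeds the consistency objective. Label-budget subsets are nested: the 240-segment subset is
contained in the 500-segment subset, and so on, so that accuracy-vs-
budget curves are not confounded by independent resampling noise.

`synthesize_corpus` builds a segment corpus directly from the generator
primitives (one beat, beat pair re-cut at half wavelength, broadband
transient, noise floor), matching the morphology the segmentation +
ACF pipeline emits, at a fraction of the cost of synthesizing and
re-segmenting hours of audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from dusbeat.segmentation import CATEGORIES, Segment
from dusbeat.synth import BeatBurstParams, SynthConfig, generate_beat, _artifact_waveform

FIXED_LEN = 350


@dataclass
class DatasetSpec:
    labeled_per_category: int = 2400
    unlabeled_per_category: int = 12000
    validation_per_category_per_fold: int = 400
    folds: int = 6
    budgets: tuple[int, ...] = (8000, 4000, 2000, 1000, 500, 240)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b % len(CATEGORIES) for b in self.budgets):
            raise ValueError("budgets must be divisible by the number of categories")
        if self.labeled_per_category != self.folds * self.validation_per_category_per_fold:
            raise ValueError(
                "labeled_per_category must equal folds * validation_per_category_per_fold"
            )

    def scaled(self, factor: float) -> "DatasetSpec":
        """Proportionally smaller spec for desk-scale experiments."""
        val = max(1, int(round(self.validation_per_category_per_fold * factor)))
        return DatasetSpec(
            labeled_per_category=self.folds * val,
            unlabeled_per_category=max(1, int(round(self.unlabeled_per_category * factor))),
            validation_per_category_per_fold=val,
            folds=self.folds,
            budgets=tuple(max(len(CATEGORIES), int(round(b * factor)) // 4 * 4)
                          for b in self.budgets),
            seed=self.seed,
        )


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: np.ndarray
    validation_ids: np.ndarray
    unlabeled_ids: np.ndarray


class SegmentCorpus:
    """Fixed-length segment arrays plus a tabular index.

    ``index`` columns: segment_id, recording_id, label, condition,
    start_ms, raw_length_ms, provenance. Row order matches ``samples``.
    """

    def __init__(self, samples: np.ndarray, index: pd.DataFrame):
        samples = np.asarray(samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[1] != FIXED_LEN:
            raise ValueError(f"samples must be (n, {FIXED_LEN})")
        if len(index) != samples.shape[0]:
            raise ValueError("index length must match samples")
        self.samples = samples
        self.index = index.reset_index(drop=True)

    @classmethod
    def from_segments(cls, segments: list[Segment]) -> "SegmentCorpus":
        rows = [
            dict(
                segment_id=i,
                recording_id=s.recording_id,
                label=s.label,
                condition=s.condition,
                start_ms=s.start_ms,
                raw_length_ms=s.raw_length_ms,
                provenance=s.provenance,
            )
            for i, s in enumerate(segments)
        ]
        samples = np.stack([s.samples for s in segments]) if segments else \
            np.empty((0, FIXED_LEN))
        return cls(samples, pd.DataFrame(rows))

    def subset(self, ids: np.ndarray) -> "SegmentCorpus":
        pos = self.index.set_index("segment_id").index.get_indexer(ids)
        if (pos < 0).any():
            raise KeyError("unknown segment ids in subset request")
        return SegmentCorpus(self.samples[pos], self.index.iloc[pos])

    def X(self, ids: np.ndarray) -> np.ndarray:
        return self.subset(ids).samples

    def y(self, ids: np.ndarray) -> np.ndarray:
        labels = self.subset(ids).index["label"].to_numpy()
        return np.array([CATEGORIES.index(l) for l in labels])

    def save(self, h5_path: str | Path) -> None:
        h5_path = Path(h5_path)
        with h5py.File(h5_path, "w") as f:
            f.create_dataset("samples", data=self.samples)
        self.index.to_csv(h5_path.with_suffix(".csv"), index=False)

    @classmethod
    def load(cls, h5_path: str | Path) -> "SegmentCorpus":
        h5_path = Path(h5_path)
        with h5py.File(h5_path, "r") as f:
            samples = f["samples"][:]
        index = pd.read_csv(h5_path.with_suffix(".csv"))
        return cls(samples, index)


def balance_categories(index: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample every category to the smallest category count."""
    rng = np.random.default_rng(seed)
    counts = index["label"].value_counts()
    target = int(counts.min())
    parts = []
    for label in CATEGORIES:
        rows = index[index["label"] == label]
        if len(rows) == 0:
            continue
        take = rng.choice(len(rows), size=target, replace=False)
        parts.append(rows.iloc[np.sort(take)])
    return pd.concat(parts).reset_index(drop=True)


def make_folds(
    labeled_index: pd.DataFrame,
    spec: DatasetSpec,
    unlabeled_ids: np.ndarray | None = None,
) -> list[FoldSplit]:
    """Rotate a per-category partition into k validation blocks.

    Every labeled segment lands in exactly one fold's validation set;
    each fold's validation holds exactly
    ``validation_per_category_per_fold`` segments per category. The
    unlabeled pool is shared across folds.
    """
    rng = np.random.default_rng(spec.seed)
    if unlabeled_ids is None:
        unlabeled_ids = np.array([], dtype=int)
    per_cat_chunks: dict[str, list[np.ndarray]] = {}
    v = spec.validation_per_category_per_fold
    for label in CATEGORIES:
        ids = labeled_index.loc[labeled_index["label"] == label, "segment_id"].to_numpy()
        if ids.size != spec.folds * v:
            raise ValueError(
                f"category {label}: {ids.size} labeled segments, "
                f"need exactly {spec.folds * v}"
            )
        ids = rng.permutation(ids)
        per_cat_chunks[label] = [ids[i * v : (i + 1) * v] for i in range(spec.folds)]
    splits = []
    for k in range(spec.folds):
        val = np.concatenate([per_cat_chunks[l][k] for l in CATEGORIES])
        train = np.concatenate(
            [per_cat_chunks[l][j] for l in CATEGORIES for j in range(spec.folds) if j != k]
        )
        splits.append(
            FoldSplit(
                fold_index=k,
                train_ids=np.sort(train),
                validation_ids=np.sort(val),
                unlabeled_ids=np.asarray(unlabeled_ids, dtype=int),
            )
        )
    return splits


def make_budget_subsets(
    train_index: pd.DataFrame,
    budgets: tuple[int, ...],
    seed: int,
) -> dict[int, np.ndarray]:
    """Nested category-balanced subsets of a fold's training pool.

    One shuffled order per category is drawn once; budget B takes the
    first B/4 segments of each category, so smaller budgets are subsets
    of larger ones.
    """
    rng = np.random.default_rng(seed)
    per_cat = {}
    for label in CATEGORIES:
        ids = train_index.loc[train_index["label"] == label, "segment_id"].to_numpy()
        per_cat[label] = rng.permutation(ids)
    out = {}
    for b in sorted(budgets):
        k = b // len(CATEGORIES)
        if any(per_cat[l].size < k for l in CATEGORIES):
            raise ValueError(f"budget {b} exceeds the training pool")
        out[b] = np.sort(np.concatenate([per_cat[l][:k] for l in CATEGORIES]))
    return out


# ---------------------------------------------------------------------------
# direct corpus synthesis

def _synth_segment(label: str, config: SynthConfig, rng: np.random.Generator) -> Segment:
    """One training segment with the nuisances the extraction stage leaves in.

    Segments cut by the envelope segmenter do not start exactly at the
    beat onset (threshold-crossing jitter), carry slow gain drift, and
    sit on a noise floor whose level varies between recordings; all
    three are emulated so the classifier cannot rely on an artificially
    clean registration.
    """
    bp = config.beat_burst_params
    gain = rng.uniform(0.7, 1.3)                    # slow gain drift surrogate
    noise_rms = config.noise_floor_rms * rng.uniform(0.7, 1.4)
    noise = rng.normal(0.0, noise_rms, FIXED_LEN)
    period = float(np.clip(
        60000.0 / config.fhr_bpm_mean + rng.normal(0.0, 60000.0 * config.fhr_bpm_sd
                                                   / config.fhr_bpm_mean**2),
        350.0, 700.0,
    ))
    x = noise
    raw_len = float(FIXED_LEN)
    if label == "single_fetal_heartbeat":
        beat = gain * generate_beat(bp, period, rng)
        onset = int(rng.uniform(0.0, 40.0))         # threshold-crossing jitter
        raw_len = float(min(FIXED_LEN, onset + beat.size))
        x = noise.copy()
        m = min(beat.size, FIXED_LEN - onset)
        x[onset : onset + m] += beat[:m]
        x[int(raw_len):] = 0.0  # zero-padded tail, as the pipeline emits
    elif label == "multiple_heartbeats":
        first = gain * generate_beat(bp, period, rng)
        second = gain * generate_beat(bp, period, rng)
        span = int(round(period)) + second.size
        mini = rng.normal(0.0, noise_rms, span + 1)
        mini[: first.size] += first
        p0 = int(round(period))
        mini[p0 : p0 + second.size] += second
        start = max(0, first.size // 2 + int(rng.uniform(-30.0, 30.0)))
        x = mini[start : start + FIXED_LEN]
        raw_len = float(min(FIXED_LEN, span - start))
        if x.size < FIXED_LEN:
            x = np.pad(x, (0, FIXED_LEN - x.size))
        x = x.copy()
        x[int(raw_len):] = 0.0
    elif label == "artifact":
        dur = int(round(rng.uniform(250.0, 350.0)))
        amp = gain * config.artifact_amplitude * bp.amplitude * rng.uniform(0.8, 1.3)
        raw_len = float(dur)
        x = noise.copy()
        x[:dur] += amp * _artifact_waveform(dur, rng)
        x[dur:] = 0.0
    elif label != "low_level_signal":
        raise ValueError(f"unknown category {label!r}")
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return Segment(
        recording_id=f"synthcorpus-{config.condition}",
        start_ms=0.0,
        raw_length_ms=raw_len,
        samples=x,
        label=label,
        provenance="auto",
        condition=config.condition,
    )


def synthesize_corpus(
    n_labeled_per_category: int,
    n_unlabeled_per_category: int,
    seed: int,
    labor_fraction: float = 0.5,
) -> tuple[SegmentCorpus, np.ndarray, np.ndarray]:
    """Generate a balanced labeled + unlabeled corpus.

    Conditions are mixed (default half labor, half NST — close to the
    roughly even clinical composition); the unlabeled rows keep their
    true category in the index for ground-truth bookkeeping but are
    returned through a separate id array and must not be used as
    training labels.

    Returns (corpus, labeled_ids, unlabeled_ids).
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    labeled_ids, unlabeled_ids = [], []
    presets = {"labor": SynthConfig.labor(), "nst": SynthConfig.nst()}
    for pool, n_per_cat, bucket in (
        ("labeled", n_labeled_per_category, labeled_ids),
        ("unlabeled", n_unlabeled_per_category, unlabeled_ids),
    ):
        for label in CATEGORIES:
            for i in range(n_per_cat):
                cond = "labor" if rng.random() < labor_fraction else "nst"
                seg = _synth_segment(label, presets[cond], rng)
                bucket.append(len(segments))
                segments.append(seg)
    corpus = SegmentCorpus.from_segments(segments)
    return corpus, np.array(labeled_ids), np.array(unlabeled_ids)
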