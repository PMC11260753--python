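# Methods

## Problem

Cardiotocography monitors derive the fetal heart rate (FHR) by
autocorrelating the Doppler-ultrasound (DUS) audio signal: the lag of
the autocorrelation peak estimates the inter-beat interval. The
procedure fails when the signal contains movement artifacts, noise-only
stretches, or two beats inside one analysis window — producing signal
loss, double counting and half counting. `dusbeat` implements a
four-category classification of fixed-length DUS excerpts — *single
fetal heartbeat*, *artifact*, *multiple heartbeats*, *low-level
signal* — with a 1-D CNN that can be trained semi-supervised, plus the
semi-automatic labeling pipeline that produces its training data, and a
synthetic DUS generator that stands in for clinical recordings, which
are not publicly available.

## Synthetic DUS generator (`synth`)

Recordings are mono, 1 kHz, 16-bit, normalized to [−1, 1].

* **Beat model.** One heartbeat is two Gaussian-windowed tone bursts on
  a shared carrier drawn from 150–300 Hz — surrogates for the paired
  valve/wall motions inside one cardiac cycle. Envelope widths default
  to 130 and 150 ms at 26% and 74% of the beat, so the packet is
  continuous (as in real Doppler audio) rather than two isolated
  clicks. Beat duration is 250–350 ms, drawn per beat around a
  per-recording base of 295–335 ms. Within one recording the carrier
  and duration vary only mildly beat-to-beat, because they come from
  one fetal heart.
* **Rhythm.** Instantaneous FHR follows AR(1) jitter around a 140 bpm
  mean (SD 8 bpm, coefficient 0.85), clipped to the physiological
  50–240 bpm band; successive beats are placed 60000/FHR(t) ms apart.
* **Signal loss.** Dropout intervals (1–3 s) are placed without overlap
  until they cover the configured fraction of the recording; beats
  inside them are suppressed. Presets: 4.6% for antenatal non-stress
  tests (NST), 20.5% for labor.
* **Artifacts** are band-limited noise transients (50–600 ms, Hann
  windowed) arriving as a Poisson process (default 4–6/min), at
  amplitudes comparable to beats — so some satisfy the 250–350 ms
  extraction rule and some do not.
* **Noise and SNR.** A Gaussian noise floor is added everywhere. The
  presets differ: NST (rms 0.10, beat amplitude 0.55) is the low-SNR
  regime, labor (rms 0.04, amplitude 0.75) the high-SNR one, matching
  the clinical observation that labor recordings are cleaner while NST
  recordings are quieter and more variable.
* If the summed waveform exceeds full scale, the recording is
  renormalized (not clipped), preserving the amplitude convention.

What the generator does *not* model: hemodynamics, maternal heartbeat
contamination, uterine-contraction signals, probe repositioning,
gestational-age effects. Passing tests on this corpus demonstrate the
pipeline's internal correctness and the relative behavior of the
training schemes, not clinical-grade absolute accuracy.

## Segmentation (`segmentation`)

1. Zero-phase 4th-order Butterworth band-pass, 100–300 Hz (the
   synthetic carrier band; classical Doppler-audio practice).
2. Envelope: rectification + 25 Hz zero-phase low-pass, floored at 0.
3. Dynamic threshold, updated every 3,000 ms: `factor ×` an envelope
   statistic per interval. The default statistic is the **20th
   percentile** with factor 2.0 — a noise-floor tracker. An interval
   RMS (also available, `threshold_statistic="rms"`) fails here for a
   structural reason: heartbeat packets occupy ~70% of a cardiac cycle
   at 140 bpm, so the RMS sits inside the beats and only envelope peaks
   cross `1.5 × RMS`, yielding 40–60 ms runs that the 250 ms length
   floor then discards. A low percentile of the envelope lands in the
   inter-beat quiet time and separates packet from floor. A trailing
   partial interval reuses the last full interval's threshold.
4. Binary closing with a flat element: gaps shorter than 60 ms between
   active runs are filled, so the mid-beat envelope dip cannot split a
   single heartbeat. 60 ms is deliberately below the smallest
   inter-beat gap the rhythm model produces (~80 ms at the fast-FHR
   tail), so consecutive beats are not merged.
5. Above-threshold runs of 250–350 ms become segments; shorter runs are
   discarded; longer runs are truncated to their leading 350 ms (onset
   timing is the information that matters downstream). Below-threshold
   spans are tiled with non-overlapping 350 ms windows (`floor(span /
   350)` segments per span). All segments are cut from the normalized
   raw waveform (config switch `cut_from_filtered` exists) and
   right-padded with exact zeros to 350 samples.

Measured on artifact-free synthetic recordings: beat recall 0.96–0.98,
precision 1.0 (every emitted segment overlaps a true beat).

## ACF labeling (`acf_labeler`)

The autocorrelation is the plain lagged product sum
`ACF(τ) = Σ_{j=0}^{N−τ} x[n+j]·x[n+j+τ]`, upper limit inclusive (an
exclusive variant is a flag; it differs by one term and never moves the
argmax in practice).

**τ_max detection.** For category assignment the ACF runs on the
mean-removed magnitude envelope of a 2,000 ms analysis interval
centred on the segment — not on the raw audio, which is not
phase-coherent from beat to beat (hardware FHR autocorrelators likewise
work on the demodulated signal), and not on the 350 ms excerpt alone,
since two beats must fit for a period to exist. τ_max exists when the
normalized peak ACF(τ)/ACF(0) within the 250–1,200 ms lag band (FHR
50–240 bpm) reaches **0.45** *and* the argmax is an interior local
maximum of the curve. The interior condition separates periodicity from
self-similarity: a single wide transient has a decay-only ACF whose
maximum leans on the band edge. The 0.45 floor sits between the
measured distributions (heartbeat windows ≥ 0.45; artifact-window
median 0.19). Ties break toward the smaller lag.

**Categories.** Above-threshold segments in intervals with τ_max →
single fetal heartbeat; without → artifact. Below-threshold segments
without τ_max → low-level signal. Multiple-heartbeat segments are
synthesized from each pair of consecutive single beats by shifting the
extraction start half the first segment's length (the segment being one
cardiac cycle, this is half a wavelength); a pair is skipped unless at
least 50 ms of the second segment falls inside the shifted 350 ms
window — the category is defined by *two fragments present in one
segment*, and the margin absorbs the ±25 ms onset offset between
envelope threshold crossings and true beat onsets. On heartbeat-dense
recordings this yields multiple:single near 1:1 (0.75–0.9:1; distant
pairs at the slow-FHR tail are skipped).

Auto-labels agree with ground-truth-derived labels at 96–98% on mixed
synthetic corpora; the residual disagreement is concentrated in
artifact intervals whose transients happen to be pseudo-periodic —
the same SNR-driven imperfection semi-automatic labeling shows on real
recordings.

## Dataset construction (`dataset_builder`)

Default study conditions: 2,400 labeled + 12,000 unlabeled segments per
category (1:5), 6 folds, 400 validation segments per category per fold,
budgets {8,000, 4,000, 2,000, 1,000, 500, 240}. Balancing downsamples
every category to the smallest count. Folds rotate the validation block
only; one unlabeled pool is shared across folds. Budget subsets are
**nested** (one shuffled order per category, budget B takes the first
B/4), so budget curves are not confounded by independent resampling.

For classifier experiments the corpus is synthesized directly from the
generator primitives (a beat, a half-wavelength-shifted beat pair, a
transient, a noise window) instead of re-segmenting hours of audio —
with the nuisances the extraction stage leaves in real output: onset
jitter (0–40 ms), per-segment gain 0.7–1.3, noise-floor variation
0.7–1.4×, mixed 50/50 labor/NST conditions. Without these nuisances the
task saturates near 100% accuracy at moderate budgets and comparisons
between training schemes degenerate into ±1-segment noise.

## Classifier and training (`ssl_model`)

Four blocks of (1-D convolution, ReLU, max-pool 2) then a dense softmax
over the four categories; default channels (16, 32, 64, 64), kernel 7,
same padding; 350 → 21 temporal samples after pooling. The network,
backpropagation and Adam (lr 10⁻³) are implemented on numpy arrays —
at this scale vectorized numpy is fast on one CPU core and keeps runs
bit-reproducible under fixed seeds.

Supervised mode minimizes cross-entropy. Semi-supervised mode
alternates per batch: one supervised step, then one consistency step on
an unlabeled batch — the clean prediction is a fixed target (no
gradient) and KL(p_clean ‖ p_noisy) is minimized through the noisy
branch (the Π-model/VAT convention; the direction is a config option).
The perturbation is per-sample uniform noise with a hard amplitude
bound (default 0.05; Gaussian-clipped available); the zero-padded tail
is perturbed too, so padding cannot become a class cue. With
consistency weight 0 the consistency step leaves parameters and
optimizer state untouched, making the run bit-identical to supervised
training — a useful degenerate-equivalence check. Batch shuffling and
noise use separate RNG streams for the same reason.

## Evaluation (`evaluation`)

Confusion matrices use the fixed category order (low-level, single,
multiple, artifact), rows = true. Accuracy is trace/total × 100 — the
multiclass reading consistent with the published tables' arithmetic;
precision/recall/F-measure are one-vs-rest per class. Degenerate
denominators return 0 with a warning so sweep tables stay total.
Display rounding is half-away-from-zero to one decimal (84.25 → 84.3);
machine output keeps raw values. With equal-sized balanced folds,
pooled accuracy equals the mean of fold accuracies exactly; per-fold
spread is reported as max − min. `compare_methods` runs a paired t-test
on matched per-segment probabilities assigned to the true class
(identical inputs return statistic 0, p = 1). The noise-amplitude sweep
defaults to {0.01, 0.03, 0.05, 0.07, 0.1, 0.3, 0.5}.

## Desk-scale experiment sizes

Full-epoch training of the default network at every budget × 6 folds ×
2 modes × 3 seeds is not a desk-scale computation, so the packaged
budget-sweep experiments use a compact variant chosen as the package's
standard benchmark configuration: channels (4, 8, 8, 8), kernel 5,
batch 64, an unlabeled pool of 1,500/category, and a per-budget epoch
schedule {8,000: 2, 4,000: 2, 2,000: 3, 1,000: 4, 500: 6, 240: 8} that
gives small budgets a workable number of optimizer steps. The
qualitative findings (semi ≥ supervised at every budget, the gap and
the fold-spread advantage concentrating at small budgets) are stable
across seeds at this scale.

## Known limitations

* The generator's artifact and beat morphologies are plausible
  surrogates, not fitted to clinical data; absolute accuracies on this
  corpus do not transfer to real recordings.
* The labeler's artifact/heartbeat distinction degrades when transients
  arrive pseudo-periodically; raising `peak_acceptance` trades artifact
  leakage against missed beats.
* Human label verification is represented only by the
  `provenance` flag ("auto" vs "checked"); no reviewing workflow is
  included.
* Variable-length segments, fetal arrhythmia waveforms and
  maternal-source discrimination are out of scope.
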