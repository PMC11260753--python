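"""1-D CNN classifier with KL-consistency semi-supervised training.

Architecture: four repeated blocks of (convolution, ReLU, max-pooling)
over the 350-sample segment, then one fully connected layer with
softmax over the four categories.

Training comes in two modes:

* ``supervised`` — plain cross-entropy on labeled segments;
* ``semi`` — per batch, a supervised step is followed by a consistency
  step on unlabeled segments: the model's prediction on the clean
  segment is treated as a fixed target (no gradient) and the prediction
  on a copy perturbed with bounded white noise is pulled toward it by
  minimizing the Kullback-Leibler divergence KL(p_clean || p_noisy).
  The noise is uniform per sample with a hard amplitude bound; the
  zero-padded tail is perturbed too, so padding cannot act as a class
  cue.

The network, backpropagation and Adam are implemented directly on
numpy arrays; at this input size (350 samples, tens of thousands of
parameters) vectorized numpy is entirely adequate on a CPU and keeps
the training loop bit-reproducible under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from dusbeat.segmentation import CATEGORIES


@dataclass
class ModelConfig:
    n_blocks: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 64)
    kernel: int = 7
    pool: int = 2
    activation: str = "relu"
    n_classes: int = 4
    input_length: int = 350

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("need one channel count per block")
        if self.activation != "relu":
            raise ValueError("only relu is implemented")
        if self.kernel % 2 != 1:
            raise ValueError("kernel length must be odd (same padding)")
        if self.final_length() < 1:
            raise ValueError("temporal dimension collapses below 1 after pooling")

    def final_length(self) -> int:
        L = self.input_length
        for _ in range(self.n_blocks):
            L = L // self.pool
        return L


@dataclass
class TrainConfig:
    noise_amplitude: float = 0.05
    consistency_weight: float = 1.0
    learning_rate: float = 1e-3
    batch_size_labeled: int = 32
    batch_size_unlabeled: int = 32
    epochs: int = 50
    unlabeled_steps_per_batch: int = 1
    noise_distribution: str = "uniform"  # or "gaussian" (clipped at the bound)
    kl_direction: str = "clean_to_noisy"  # or "noisy_to_clean"
    noise_in_padding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if not np.isfinite(self.consistency_weight):
            raise ValueError("consistency_weight must be finite")
        if self.noise_distribution not in ("uniform", "gaussian"):
            raise ValueError("noise_distribution must be 'uniform' or 'gaussian'")
        if self.kl_direction not in ("clean_to_noisy", "noisy_to_clean"):
            raise ValueError("unknown kl_direction")


@dataclass
class Prediction:
    probabilities: np.ndarray  # (n, 4)
    labels: np.ndarray         # (n,) integer category indices

    def label_names(self) -> list[str]:
        return [CATEGORIES[i] for i in self.labels]


class Adam:
    """Standard Adam on a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


class Conv1dNet:
    """Four conv/ReLU/max-pool blocks + dense softmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, c_out in enumerate(config.channels):
            fan_in = c_in * config.kernel
            self.params[f"W{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, config.kernel)
            )
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        flat = c_in * config.final_length()
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, config.n_classes))
        self.params["bd"] = np.zeros(config.n_classes)

    # -- forward ----------------------------------------------------------
    def _forward(self, X: np.ndarray, keep_cache: bool):
        cfg = self.config
        x = np.ascontiguousarray(X, dtype=np.float64)[:, None, :]  # (B, 1, L)
        cache = {"inputs": [], "windows": [], "relu": [], "pool": []} if keep_cache else None
        pad = cfg.kernel // 2
        for i in range(cfg.n_blocks):
            W, b = self.params[f"W{i}"], self.params[f"b{i}"]
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
            win = sliding_window_view(xp, cfg.kernel, axis=2)  # (B, C_in, L, k)
            z = np.tensordot(win, W, axes=([1, 3], [1, 2]))     # (B, L, C_out)
            z = np.ascontiguousarray(z.transpose(0, 2, 1)) + b[None, :, None]
            a = np.maximum(z, 0.0)
            B, C, L = a.shape
            Lp = L // cfg.pool
            ar = a[:, :, : Lp * cfg.pool].reshape(B, C, Lp, cfg.pool)
            pooled = ar.max(axis=3)
            if keep_cache:
                cache["windows"].append(win)
                cache["relu"].append(z > 0)
                cache["pool"].append((ar.argmax(axis=3), a.shape))
            x = pooled
        B = x.shape[0]
        flat = x.reshape(B, -1)
        logits = flat @ self.params["Wd"] + self.params["bd"]
        if keep_cache:
            cache["flat"] = flat
            cache["pooled_shape"] = x.shape
        return logits, cache

    def forward_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X, keep_cache=False)
        return logits

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            out.append(softmax(self.forward_logits(X[i : i + batch_size])))
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    # -- backward ---------------------------------------------------------
    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        grads["Wd"] = cache["flat"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dx = (dlogits @ self.params["Wd"].T).reshape(cache["pooled_shape"])
        pad = cfg.kernel // 2
        for i in range(cfg.n_blocks - 1, -1, -1):
            argmax, a_shape = cache["pool"][i]
            B, C, L = a_shape
            Lp = argmax.shape[2]
            da_r = np.zeros((B, C, Lp, cfg.pool))
            np.put_along_axis(da_r, argmax[..., None], dx[..., None], axis=3)
            da = np.zeros(a_shape)
            da[:, :, : Lp * cfg.pool] = da_r.reshape(B, C, Lp * cfg.pool)
            dz = da * cache["relu"][i]
            win = cache["windows"][i]
            grads[f"W{i}"] = np.tensordot(dz, win, axes=([0, 2], [0, 2]))
            grads[f"b{i}"] = dz.sum(axis=(0, 2))
            # gradient w.r.t. the (padded) input of this block
            C_in = win.shape[1]
            dxp = np.zeros((B, C_in, L + 2 * pad))
            W = self.params[f"W{i}"]
            for j in range(cfg.kernel):
                dxp[:, :, j : j + L] += np.einsum("bol,oc->bcl", dz, W[:, :, j])
            dx = dxp[:, :, pad : pad + L]
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Conv1dNet:
    return Conv1dNet(config or ModelConfig(), seed=seed)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def add_bounded_noise(
    batch: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    distribution: str = "uniform",
    noise_in_padding: bool = True,
) -> np.ndarray:
    """Additive white noise with a hard per-sample amplitude bound."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if distribution == "uniform":
        delta = rng.uniform(-amplitude, amplitude, batch.shape)
    elif distribution == "gaussian":
        delta = np.clip(rng.normal(0.0, amplitude / 2.0, batch.shape),
                        -amplitude, amplitude)
    else:
        raise ValueError(f"unknown noise distribution {distribution!r}")
    if not noise_in_padding:
        delta = np.where(batch == 0.0, 0.0, delta)
    return batch + delta


def cross_entropy_and_grad(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its logit gradient."""
    p = softmax(logits)
    B = logits.shape[0]
    loss = float(-np.mean(np.log(np.clip(p[np.arange(B), y], 1e-300, None))))
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Row-wise KL(p || q) = sum p * ln(p / q); non-negative, 0 iff p == q."""
    p = np.clip(p, eps, None)
    q = np.clip(q, eps, None)
    return np.sum(p * (np.log(p) - np.log(q)), axis=1)


def supervised_step(model: Conv1dNet, optimizer: Adam,
                    X: np.ndarray, y: np.ndarray) -> float:
    logits, cache = model._forward(X, keep_cache=True)
    loss, dlogits = cross_entropy_and_grad(logits, y)
    grads = model.backward(cache, dlogits)
    optimizer.step(grads)
    return loss


def consistency_step(
    model: Conv1dNet,
    optimizer: Adam,
    X_unlabeled: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> float:
    """One KL-consistency update on an unlabeled batch.

    The clean prediction is a fixed target (no gradient flows through
    it); only the noisy branch is backpropagated. With
    ``consistency_weight`` zero the parameters (and the optimizer's
    moment/step state) are left untouched so the run coincides exactly
    with plain supervised training.
    """
    p_clean = softmax(model.forward_logits(X_unlabeled))
    X_noisy = add_bounded_noise(
        X_unlabeled, config.noise_amplitude, rng,
        config.noise_distribution, config.noise_in_padding,
    )
    logits_q, cache = model._forward(X_noisy, keep_cache=True)
    q = softmax(logits_q)
    B = X_unlabeled.shape[0]
    if config.kl_direction == "clean_to_noisy":
        kl = kl_divergence(p_clean, q)
        # d/dlogits_q of -sum p ln q  is  q - p
        dlogits = (q - p_clean) / B
    else:
        kl = kl_divergence(q, p_clean)
        log_ratio = np.log(np.clip(q, 1e-12, None)) - np.log(np.clip(p_clean, 1e-12, None))
        inner = log_ratio + 1.0
        dlogits = q * (inner - np.sum(q * inner, axis=1, keepdims=True)) / B
    loss = float(config.consistency_weight * np.mean(kl))
    if config.consistency_weight != 0.0:
        grads = model.backward(cache, config.consistency_weight * dlogits)
        optimizer.step(grads)
    return loss


def _batches(n: int, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    model: Conv1dNet,
    X_labeled: np.ndarray,
    y_labeled: np.ndarray,
    X_unlabeled: np.ndarray | None,
    mode: str,
    config: TrainConfig,
) -> dict:
    """Train in place; returns a history of both loss streams.

    ``semi`` mode alternates per batch: one supervised step on a
    labeled batch, then one consistency step on an unlabeled batch.
    The batch-shuffling RNG stream is separate from the noise RNG so a
    semi run with consistency weight 0 follows the supervised
    trajectory exactly.
    """
    if mode not in ("supervised", "semi"):
        raise ValueError(f"mode must be 'supervised' or 'semi', got {mode!r}")
    if mode == "semi" and (X_unlabeled is None or len(X_unlabeled) == 0):
        raise ValueError("semi mode requires a non-empty unlabeled pool")
    rng_shuffle = np.random.default_rng(config.seed)
    rng_noise = np.random.default_rng((config.seed + 777) % 2**31)
    optimizer = Adam(model.params, config.learning_rate)
    history = {"supervised_loss": [], "consistency_loss": []}
    n_unl = 0 if X_unlabeled is None else len(X_unlabeled)
    unl_order = np.array([], dtype=int)
    unl_pos = 0
    for _epoch in range(config.epochs):
        for idx in _batches(len(X_labeled), config.batch_size_labeled, rng_shuffle):
            loss = supervised_step(model, optimizer, X_labeled[idx], y_labeled[idx])
            history["supervised_loss"].append(loss)
            if mode != "semi":
                continue
            for _ in range(config.unlabeled_steps_per_batch):
                if unl_pos + config.batch_size_unlabeled > unl_order.size:
                    unl_order = rng_noise.permutation(n_unl)
                    unl_pos = 0
                uidx = unl_order[unl_pos : unl_pos + config.batch_size_unlabeled]
                unl_pos += config.batch_size_unlabeled
                closs = consistency_step(
                    model, optimizer, X_unlabeled[uidx], config, rng_noise
                )
                history["consistency_loss"].append(closs)
    return history


def predict(model: Conv1dNet, X: np.ndarray) -> Prediction:
    """Probabilities and argmax labels; ties break to the lowest index."""
    probs = model.predict_proba(np.asarray(X, dtype=np.float64))
    return Prediction(probabilities=probs, labels=np.argmax(probs, axis=1))
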