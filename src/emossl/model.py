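"""Recurrent backbone and emotion head.

Architecture
------------
The backbone maps a standardized feature sequence (T x 74) to a per-timestep
74-dimensional output: two stacked unidirectional GRU layers with 256 hidden
units each (configurable), followed by a per-timestep 74-unit dense
projection.  During self-supervised pre-training the backbone's output is the
reconstruction of the original (unmasked) sequence.

For emotion prediction a single 6-unit dense head is applied to a fixed-size
temporal summary of the backbone output — by default the mean over valid
(non-padded) timesteps; the last valid timestep is available as an
alternative summary.  The head outputs one intensity per Ekman emotion
(happiness, sadness, anger, surprise, disgust, fear), no output activation.

Freezing
--------
``freeze_backbone`` marks every backbone parameter non-trainable; optimizers
built afterwards update only the 450 head parameters (74*6 weights + 6
biases).  Frozen parameters are guaranteed bitwise unchanged by training.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, sigmoid, tanh, stack

N_FEATURES = 74
N_EMOTIONS = 6
DEFAULT_HIDDEN = 256


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_uniform_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(_uniform_init(rng, (n_out,), n_in), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class GRULayer:
    """Single unidirectional GRU layer (Cho et al. gating).

    Gate order in the fused input projection is (update z, reset r,
    candidate n):

        z_t = sigmoid(x_t W_z + h_{t-1} U_z + b_z)
        r_t = sigmoid(x_t W_r + h_{t-1} U_r + b_r)
        n_t = tanh(x_t W_n + r_t * (h_{t-1} U_n) + b_n)
        h_t = z_t * h_{t-1} + (1 - z_t) * n_t
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = self.n_hidden = n_hidden
        self.W = Tensor(_uniform_init(rng, (n_in, 3 * H), n_in), requires_grad=True)
        self.b = Tensor(_uniform_init(rng, (3 * H,), n_in), requires_grad=True)
        self.U_zr = Tensor(_uniform_init(rng, (H, 2 * H), H), requires_grad=True)
        self.U_n = Tensor(_uniform_init(rng, (H, H), H), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, n_in) -> per-timestep hidden states (B, T, H)."""
        B, T, D = x.shape
        H = self.n_hidden
        # input projection for all timesteps in one matmul
        pre = (x.reshape(B * T, D) @ self.W + self.b).reshape(B, T, 3 * H)
        h = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            p = pre[:, t, :]
            zr = sigmoid(p[:, : 2 * H] + h @ self.U_zr)
            z = zr[:, :H]
            r = zr[:, H:]
            n = tanh(p[:, 2 * H :] + r * (h @ self.U_n))
            h = z * h + (1.0 - z) * n
            outs.append(h)
        return stack(outs, axis=1)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b, self.U_zr, self.U_n]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_size`` defaults to the 256 units of the reference architecture;
    ``summary`` selects how a variable-length per-timestep output is reduced
    before the emotion head ('mean' over valid timesteps or 'last' valid
    timestep).
    """

    n_features: int = N_FEATURES
    hidden_size: int = DEFAULT_HIDDEN
    n_layers: int = 2
    summary: str = "mean"

    def fingerprint(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Backbone:
    """Two stacked GRU layers plus a per-timestep dense projection back to
    feature space.  Maps (B, T, F) -> (B, T, F) for any T >= 1."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.grus = []
        n_in = cfg.n_features
        for _ in range(cfg.n_layers):
            self.grus.append(GRULayer(n_in, cfg.hidden_size, rng))
            n_in = cfg.hidden_size
        self.proj = Dense(cfg.hidden_size, cfg.n_features, rng)
        self.frozen = False

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.config.n_features:
            raise ValueError(
                f"expected {self.config.n_features} features, got {x.shape[-1]}"
            )
        h = x
        for gru in self.grus:
            h = gru(h)
        B, T, H = h.shape
        out = (h.reshape(B * T, H) @ self.proj.W + self.proj.b).reshape(
            B, T, self.config.n_features
        )
        return out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for gru in self.grus:
            params.extend(gru.parameters())
        params.extend(self.proj.parameters())
        return params

    def trainable_parameters(self) -> list[Tensor]:
        return [] if self.frozen else self.parameters()


class EmotionHead:
    """Single 6-unit dense layer on a temporal summary of the backbone output."""

    def __init__(self, n_features: int = N_FEATURES, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.dense = Dense(n_features, N_EMOTIONS, rng)

    def __call__(self, summary: Tensor) -> Tensor:
        return self.dense(summary)

    def parameters(self) -> list[Tensor]:
        return self.dense.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def freeze_backbone(backbone: Backbone) -> Backbone:
    """Mark all backbone parameters non-trainable (in place) and return it."""
    backbone.frozen = True
    for p in backbone.parameters():
        p.requires_grad = False
    return backbone


def unfreeze_backbone(backbone: Backbone) -> Backbone:
    backbone.frozen = False
    for p in backbone.parameters():
        p.requires_grad = True
    return backbone


def pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad variable-length (T_i x F) arrays to a (B, T_max, F) batch.

    Returns the batch and a (B, T_max, 1) validity mask (1 on real rows, 0 on
    padding).  Padded rows are excluded from losses and temporal summaries by
    every caller.
    """
    B = len(seqs)
    T = max(s.shape[0] for s in seqs)
    F = seqs[0].shape[1]
    out = np.zeros((B, T, F))
    mask = np.zeros((B, T, 1))
    for i, s in enumerate(seqs):
        out[i, : s.shape[0]] = s
        mask[i, : s.shape[0]] = 1.0
    return out, mask


def summarize(per_step: Tensor, mask: np.ndarray, mode: str = "mean") -> Tensor:
    """Reduce per-timestep output (B, T, F) to (B, F), honouring the padding
    mask."""
    if mode == "mean":
        lengths = mask.sum(axis=1)  # (B, 1)
        return (per_step * mask).sum(axis=1) * (1.0 / lengths)
    if mode == "last":
        idx = mask[:, :, 0].sum(axis=1).astype(int) - 1
        rows = stack([per_step[i, int(t), :] for i, t in enumerate(idx)], axis=0)
        return rows
    raise ValueError(f"unknown summary mode {mode!r}")


def reconstruct(backbone: Backbone, masked: np.ndarray) -> np.ndarray:
    """Predict the original features of a single sentinel-masked clip.

    Input and output are both (T x 74); the network is free to alter
    unmasked positions but is trained to reproduce them.
    """
    masked = np.asarray(masked, dtype=np.float64)
    if masked.ndim != 2:
        raise ValueError("expected a (T x F) matrix")
    out = backbone(Tensor(masked[None]))
    return out.data[0]


def predict_emotions(
    backbone: Backbone, head: EmotionHead, seq: np.ndarray
) -> np.ndarray:
    """Predict the 6 emotion intensities of one unmasked clip."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("expected a non-empty (T x F) matrix")
    batch, mask = pad_batch([seq])
    per_step = backbone(Tensor(batch))
    summary = summarize(per_step, mask, backbone.config.summary)
    return head(summary).data[0]


def predict_emotions_batch(
    backbone: Backbone, head: EmotionHead, seqs: list[np.ndarray], batch_size: int = 32
) -> np.ndarray:
    """Vectorized ``predict_emotions`` over many clips; returns (n, 6)."""
    preds = []
    for i in range(0, len(seqs), batch_size):
        chunk = seqs[i : i + batch_size]
        batch, mask = pad_batch(chunk)
        per_step = backbone(Tensor(batch))
        summary = summarize(per_step, mask, backbone.config.summary)
        preds.append(head(summary).data)
    return np.concatenate(preds, axis=0)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    path,
    backbone: Backbone,
    head: EmotionHead | None = None,
    stats=None,
) -> None:
    """Serialize backbone (and optionally head) parameters plus
    standardization stats to an .npz container with a config fingerprint."""
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(backbone.parameters()):
        arrays[f"backbone_{i}"] = p.data
    if head is not None:
        for i, p in enumerate(head.parameters()):
            arrays[f"head_{i}"] = p.data
    if stats is not None:
        arrays["stats_mean"] = stats.mean
        arrays["stats_sd"] = stats.sd
    arrays["config_json"] = np.frombuffer(
        json.dumps(backbone.config.__dict__).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Backbone, EmotionHead | None, object]:
    """Rebuild a model from :func:`save_checkpoint` output.

    The round trip is bitwise: parameters are restored exactly, so outputs on
    identical inputs match the pre-save model bit for bit.
    """
    from .data_model import StandardizationStats

    with np.load(path) as archive:
        cfg_dict = json.loads(bytes(archive["config_json"]).decode())
        backbone = Backbone(ModelConfig(**cfg_dict), seed=0)
        for i, p in enumerate(backbone.parameters()):
            p.data = archive[f"backbone_{i}"].copy()
        head = None
        if "head_0" in archive:
            head = EmotionHead(cfg_dict["n_features"], seed=0)
            for i, p in enumerate(head.parameters()):
                p.data = archive[f"head_{i}"].copy()
        stats = None
        if "stats_mean" in archive:
            stats = StandardizationStats(
                mean=archive["stats_mean"].copy(), sd=archive["stats_sd"].copy()
            )
    return backbone, head, stats


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3):
        self.params = list(params)
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)
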