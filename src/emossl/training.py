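"""Training loops: self-supervised pre-training, frozen-backbone fine-tuning,
and the no-pretraining baseline.

Both stages optimize mean squared error with Adam at learning rate 0.001 for
30 epochs by default.  Pre-training reconstructs the original clip from a
sentinel-masked copy; it receives feature sequences only, so labels cannot
leak into it by construction.  Fine-tuning freezes every backbone parameter
and trains only the 6-unit emotion head; the baseline trains the identical
architecture end-to-end from random initialization on the same labeled
subset.

Variable-length clips are zero-padded per batch with an explicit validity
mask; padded rows are excluded from the loss and from the temporal mean.
All randomness (initialization, batch order, mask draws) derives from the
config seed, so runs are exactly reproducible in serial execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data_model import Dataset, EmotionLabel, FeatureSequence
from .masking import MASK_LEN, SENTINEL, mask_clip
from .model import (
    Adam,
    Backbone,
    EmotionHead,
    ModelConfig,
    freeze_backbone,
    pad_batch,
    summarize,
)


@dataclass
class TrainConfig:
    epochs: int = 30
    pretrain_epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    mask_len: int = MASK_LEN
    sentinel: float = SENTINEL
    #: 'all' = reconstruction loss over every valid timestep (the default);
    #: 'masked' = loss restricted to the masked block
    pretrain_loss: str = "all"
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.pretrain_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class LossHistory:
    train: list[float] = field(default_factory=list)
    validation: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train)


def _as_arrays(clips) -> list[np.ndarray]:
    return [
        c.values if isinstance(c, FeatureSequence) else np.asarray(c, dtype=np.float64)
        for c in clips
    ]


def _masked_mse(pred: Tensor, target: np.ndarray, weight: np.ndarray) -> Tensor:
    """Weighted MSE: sum(w * (pred - target)^2) / sum(w * F)."""
    diff = (pred - Tensor(target)) * weight
    denom = float(weight.sum() * target.shape[-1] / weight.shape[-1])
    return diff.square().sum() * (1.0 / max(denom, 1.0))


def masked_reconstruction_mse(
    backbone: Backbone, pairs, loss_on: str = "all"
) -> float:
    """Mean reconstruction MSE of a backbone over a list of MaskedPairs
    (no gradient tracking; averaged per valid cell)."""
    total, count = 0.0, 0
    for pair in pairs:
        out = backbone(Tensor(pair.input[None])).data[0]
        if loss_on == "masked":
            sl = slice(pair.mask_start, pair.mask_start + pair.mask_len)
            err = out[sl] - pair.target[sl]
        else:
            err = out - pair.target
        total += float((err**2).sum())
        count += err.size
    return total / max(count, 1)


def pretrain(
    clips: list[FeatureSequence] | list[np.ndarray] | Dataset,
    cfg: TrainConfig | None = None,
) -> tuple[Backbone, LossHistory]:
    """Self-supervised pre-training on unlabeled clips.

    Accepts raw sequences (or a Dataset, from which only the training-split
    clips are taken — labels are never read).  A fresh mask is drawn for
    every clip at every epoch.
    """
    cfg = cfg or TrainConfig()
    if isinstance(clips, Dataset):
        clips = clips.subset("train") if clips.split else clips.clips
    arrays = _as_arrays(clips)
    if not arrays:
        raise ValueError("pre-training requires a non-empty set of clips")

    root = np.random.SeedSequence([cfg.seed, 101])
    init_seed, order_seed, mask_seed = root.generate_state(3) % (2**31)
    backbone = Backbone(cfg.model, seed=int(init_seed))
    optim = Adam(backbone.trainable_parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(int(order_seed))
    mask_rng = np.random.default_rng(int(mask_seed))

    history = LossHistory()
    n = len(arrays)
    for _epoch in range(cfg.pretrain_epochs):
        order = order_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pairs = [mask_clip(arrays[i], mask_rng, cfg.mask_len, cfg.sentinel) for i in idx]
            inputs, mask = pad_batch([p.input for p in pairs])
            targets, _ = pad_batch([p.target for p in pairs])
            if cfg.pretrain_loss == "masked":
                weight = np.zeros_like(mask)
                for b, p in enumerate(pairs):
                    weight[b, p.mask_start : p.mask_start + p.mask_len] = 1.0
            else:
                weight = mask
            out = backbone(Tensor(inputs))
            loss = _masked_mse(out, targets, weight)
            optim.zero_grad()
            loss.backward()
            optim.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.train.append(epoch_loss / n_batches)
    return backbone, history


def compute_embeddings(
    backbone: Backbone, clips: list[np.ndarray], batch_size: int = 32
) -> np.ndarray:
    """Temporal-summary embeddings (n x 74) of clips under a fixed backbone."""
    out = []
    for i in range(0, len(clips), batch_size):
        batch, mask = pad_batch(clips[i : i + batch_size])
        per_step = backbone(Tensor(batch))
        out.append(summarize(per_step, mask, backbone.config.summary).data)
    return np.concatenate(out, axis=0)


def finetune(
    backbone: Backbone,
    labeled: list[tuple[FeatureSequence, EmotionLabel]],
    cfg: TrainConfig | None = None,
) -> tuple[EmotionHead, LossHistory]:
    """Train only the 6-unit emotion head on a frozen backbone.

    Because the backbone is frozen, each clip's temporal-summary embedding is
    computed once up front and the head is fit on those fixed embeddings —
    mathematically identical to backpropagating through the frozen stack,
    at a fraction of the cost.
    """
    cfg = cfg or TrainConfig()
    if not labeled:
        raise ValueError("fine-tuning requires a non-empty labeled set")
    freeze_backbone(backbone)
    clips = _as_arrays([c for c, _ in labeled])
    targets = np.array([lab.intensities for _, lab in labeled])

    embeddings = compute_embeddings(backbone, clips, cfg.batch_size)

    root = np.random.SeedSequence([cfg.seed, 202])
    init_seed, order_seed = root.generate_state(2) % (2**31)
    head = EmotionHead(backbone.config.n_features, seed=int(init_seed))
    optim = Adam(head.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(int(order_seed))

    history = LossHistory()
    n = len(labeled)
    for _epoch in range(cfg.epochs):
        order = order_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = head(Tensor(embeddings[idx]))
            diff = pred - Tensor(targets[idx])
            loss = diff.square().sum() * (1.0 / diff.data.size)
            optim.zero_grad()
            loss.backward()
            optim.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.train.append(epoch_loss / n_batches)
    return head, history


def train_baseline(
    labeled: list[tuple[FeatureSequence, EmotionLabel]],
    cfg: TrainConfig | None = None,
) -> tuple[Backbone, EmotionHead, LossHistory]:
    """Train the identical architecture end-to-end from random init, with no
    pre-training, on the labeled subset only."""
    cfg = cfg or TrainConfig()
    if not labeled:
        raise ValueError("baseline training requires a non-empty labeled set")
    clips = _as_arrays([c for c, _ in labeled])
    targets = np.array([lab.intensities for _, lab in labeled])

    root = np.random.SeedSequence([cfg.seed, 303])
    bb_seed, head_seed, order_seed = root.generate_state(3) % (2**31)
    backbone = Backbone(cfg.model, seed=int(bb_seed))
    head = EmotionHead(cfg.model.n_features, seed=int(head_seed))
    optim = Adam(backbone.parameters() + head.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(int(order_seed))

    history = LossHistory()
    n = len(labeled)
    for _epoch in range(cfg.epochs):
        order = order_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch, mask = pad_batch([clips[i] for i in idx])
            per_step = backbone(Tensor(batch))
            summary = summarize(per_step, mask, cfg.model.summary)
            pred = head(summary)
            diff = pred - Tensor(targets[idx])
            loss = diff.square().sum() * (1.0 / diff.data.size)
            optim.zero_grad()
            loss.backward()
            optim.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.train.append(epoch_loss / n_batches)
    return backbone, head, history
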