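"""Training loop: multi-class cross-entropy, Adam, polynomial LR decay.

The learning rate follows the poly policy

    lr = base_lr * (1 - epoch / max_epoch) ** power

evaluated once per epoch.  Augmentation (right-angle rotation, mirrors,
additive noise) is applied on the fly with a per-epoch seed derived from
the global seed, so runs are reproducible while the augmentation stream is
unbounded.  The checkpoint with the best validation mIoU is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import eval_metrics as em
from . import nn
from .dataset_builder import DatasetManifest, TilePair, random_augment
from .deep_agrinet import DeepAgriNet, NetworkConfig
from .nn.functional import softmax_cross_entropy
from .nn.tensor import Tensor, no_grad


@dataclass
class TrainConfig:
    base_lr: float = 0.001
    batch_size: int = 4
    max_epoch: int = 50
    power: float = 0.9
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0
    augment: bool = True
    noise_sigma: float = 0.01      # augmentation noise, fraction of band range
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.base_lr <= 0 or self.batch_size <= 0 or self.power <= 0 \
                or self.max_epoch < 1:
            raise ValueError("invalid training configuration")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_miou: float
    val_oa: float
    val_recall: float


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)

    def append(self, rec: EpochRecord):
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def best_miou(self) -> float:
        return max(r.val_miou for r in self.records)


def cross_entropy_loss(scores, target) -> Tensor:
    """Mean per-pixel softmax cross-entropy; accepts (C,H,W) or (N,C,H,W)."""
    scores = nn.ensure_tensor(scores)
    target = np.asarray(target)
    if scores.ndim == 3:
        scores = scores.reshape((1,) + tuple(scores.shape))
        target = target[None]
    return softmax_cross_entropy(scores, target)


def poly_lr(epoch: int, cfg: TrainConfig) -> float:
    if epoch < 0 or epoch > cfg.max_epoch:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epoch}]")
    return cfg.base_lr * (1.0 - epoch / cfg.max_epoch) ** cfg.power


def _batches(items, size):
    for i in range(0, len(items), size):
        yield items[i:i + size]


def evaluate(model, tiles, batch_size: int = 4) -> dict:
    """Aggregate confusion over all tiles (micro) and report the metrics."""
    model.eval()
    preds, truths = [], []
    with no_grad():
        for batch in _batches(list(tiles), batch_size):
            x = np.stack([t.image for t in batch])
            pred = model.predict(x)
            preds.extend(pred)
            truths.extend(t.mask for t in batch)
    return em.evaluate_masks(preds, truths, model.config.num_classes)


def save_checkpoint(path, model) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> DeepAgriNet:
    with np.load(path) as data:
        cfg = NetworkConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        model = DeepAgriNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model


def train(model, tiles, manifest: DatasetManifest, cfg: TrainConfig):
    """Run ``cfg.max_epoch`` epochs; returns (history, best checkpoint path
    or None).  Bitwise-reproducible for a fixed seed on one machine."""
    by_id = {t.tile_id: t for t in tiles}
    train_tiles = [by_id[i] for i in manifest.train_ids]
    val_tiles = [by_id[i] for i in manifest.val_ids]
    if not train_tiles or not val_tiles:
        raise ValueError("empty train or validation split")

    opt = nn.Adam(model.parameters(), lr=cfg.base_lr, betas=cfg.adam_betas,
                  eps=cfg.adam_eps)
    history = TrainHistory()
    best_miou, best_path = -1.0, None
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.max_epoch):
        opt.lr = poly_lr(epoch, cfg)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, epoch)))
        order = rng.permutation(len(train_tiles))
        model.train()
        losses = []
        for batch_idx in _batches(order, cfg.batch_size):
            batch = [train_tiles[i] for i in batch_idx]
            if cfg.augment:
                batch = [random_augment(t, rng, cfg.noise_sigma) for t in batch]
            x = np.stack([t.image for t in batch])
            y = np.stack([t.mask.astype(np.int64) for t in batch])
            scores = model(x)
            loss = softmax_cross_entropy(scores, y)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        metrics = evaluate(model, val_tiles, cfg.batch_size)
        history.append(EpochRecord(
            epoch=epoch, lr=opt.lr, train_loss=float(np.mean(losses)),
            val_miou=metrics["miou"], val_oa=metrics["overall_accuracy"],
            val_recall=metrics["recall"]))
        if metrics["miou"] > best_miou:
            best_miou = metrics["miou"]
            if ckpt_dir:
                best_path = ckpt_dir / "best.npz"
                save_checkpoint(best_path, model)
    if ckpt_dir:
        history.to_csv(ckpt_dir / "history.csv")
    return history, best_path
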