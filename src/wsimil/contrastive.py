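"""Momentum-contrast self-supervised pretraining of the tile encoder.

Two stochastic augmentations of the same tile form a positive pair; negatives
come from a FIFO memory queue of keys produced by an exponential-moving-
average (momentum) copy of the encoder.  With sim(z_i, z_j) =
z_i^T z_j / (tau |z_i| |z_j|), the InfoNCE loss of an anchor z with positive
z' against K queued negatives is

    L = -log  exp(sim(z, z')) / ( exp(sim(z, z')) + sum_k exp(sim(z, z_k)) )

i.e. a (K+1)-way softmax including the positive in the denominator; the
variant whose denominator sums only the K negatives is available via
``include_positive=False``.  After pretraining the projection head is
discarded and the backbone embedding h = f(x) is used as the tile feature.

Default optimizer: SGD with lr 0.03, weight decay 1e-4, momentum 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from .autodiff import Tensor, cat
from .nn import SGD, Module, ProjectionHead, SmallCNN

__all__ = ["MemoryQueue", "AugmentationPolicy", "PretrainConfig",
           "EncoderState", "cosine_sim", "info_nce_loss", "momentum_update",
           "pretrain", "embed", "save_checkpoint", "load_checkpoint",
           "prepare_tiles", "subsample_bags"]


def cosine_sim(z_i, z_j, tau: float = 1.0) -> float:
    """Temperature-scaled cosine similarity z_i^T z_j / (tau |z_i| |z_j|)."""
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    ni, nj = np.linalg.norm(z_i), np.linalg.norm(z_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    return float(z_i @ z_j / (tau * ni * nj))


@dataclass
class MemoryQueue:
    """FIFO ring buffer of K unit-norm negative keys."""
    K: int
    dim: int
    buffer: np.ndarray = None
    head: int = 0
    inserted: int = 0

    def __post_init__(self):
        if self.buffer is None:
            self.buffer = np.zeros((self.K, self.dim))

    @classmethod
    def warm(cls, K: int, dim: int, rng: np.random.Generator) -> "MemoryQueue":
        q = cls(K=K, dim=dim)
        init = rng.standard_normal((K, dim))
        q.buffer = init / np.linalg.norm(init, axis=1, keepdims=True)
        return q

    def enqueue(self, keys: np.ndarray):
        keys = np.asarray(keys, dtype=float)
        norms = np.linalg.norm(keys, axis=1, keepdims=True)
        keys = keys / np.where(norms > 0, norms, 1.0)
        for k in keys:
            self.buffer[self.head] = k
            self.head = (self.head + 1) % self.K
            self.inserted += 1

    def snapshot(self) -> np.ndarray:
        """Keys ordered oldest -> newest."""
        return np.roll(self.buffer, -self.head, axis=0)


def info_nce_loss(z, z_pos, queue: MemoryQueue, tau: float,
                  include_positive: bool = True) -> float:
    """InfoNCE loss of one anchor against its positive and the queued
    negatives (see module docstring for the two denominator conventions)."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if queue.K == 0:
        raise ValueError("memory queue is empty")
    s_pos = cosine_sim(z, z_pos, tau)
    s_neg = np.array([cosine_sim(z, k, tau) for k in queue.buffer])
    if include_positive:
        denom = np.logaddexp(s_pos, _logsumexp(s_neg))
    else:
        denom = _logsumexp(s_neg)
    return float(denom - s_pos)


def _logsumexp(v):
    m = np.max(v)
    return m + np.log(np.exp(v - m).sum())


@dataclass
class AugmentationPolicy:
    """MoCo-v2-style stochastic tile augmentation (crop-resize, flips, color
    jitter, random grayscale, Gaussian blur)."""
    crop_scale: tuple = (0.5, 1.0)
    p_flip: float = 0.5
    jitter: float = 0.15
    p_gray: float = 0.2
    p_blur: float = 0.5

    def __call__(self, tile: np.ndarray, out_px: int,
                 rng: np.random.Generator) -> np.ndarray:
        """tile: (H, W, 3) uint8 -> (3, out_px, out_px) float in [-0.5, 0.5]."""
        img = tile.astype(np.float64) / 255.0
        h, w = img.shape[:2]
        scale = rng.uniform(*self.crop_scale)
        side = max(8, int(round(np.sqrt(scale) * min(h, w))))
        y0 = rng.integers(0, h - side + 1)
        x0 = rng.integers(0, w - side + 1)
        img = img[y0:y0 + side, x0:x0 + side]
        img = resize(img, (out_px, out_px), order=1, anti_aliasing=False)
        if rng.uniform() < self.p_flip:
            img = img[:, ::-1]
        if rng.uniform() < self.p_flip:
            img = img[::-1, :]
        if self.jitter > 0:
            gains = rng.uniform(1 - self.jitter, 1 + self.jitter, 3)
            shift = rng.uniform(-self.jitter, self.jitter)
            img = img * gains + shift
        if rng.uniform() < self.p_gray:
            lum = img @ np.array([0.299, 0.587, 0.114])
            img = np.repeat(lum[:, :, None], 3, axis=2)
        if rng.uniform() < self.p_blur:
            img = gaussian_filter(img, sigma=(rng.uniform(0.1, 1.0),) * 2 + (0.0,))
        img = np.clip(img, 0.0, 1.0) - 0.5
        return np.ascontiguousarray(img.transpose(2, 0, 1))


@dataclass
class PretrainConfig:
    epochs: int = 5
    batch_size: int = 64
    lr: float = 0.03
    weight_decay: float = 1e-4
    momentum: float = 0.9
    tau: float = 0.07
    queue_size: int = 256
    ema: float = 0.999
    in_px: int = 32
    channels: tuple = (16, 32)
    embed_dim: int = 32
    proj_dim: int = 16
    include_positive: bool = True
    sample_fraction: float = 1.0     # per-slide tile subsample for fine-tune sets
    max_slides: int | None = None    # cap on slides contributing tiles
    seed: int = 0


class EncoderState(Module):
    """Online encoder (backbone + projection head), its momentum copy, the
    negative-key queue and the training configuration."""

    def __init__(self, config: PretrainConfig):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE0C0]))
        self.backbone = SmallCNN(channels=config.channels,
                                 embed_dim=config.embed_dim, rng=rng)
        self.head = ProjectionHead(config.embed_dim, config.proj_dim, rng)
        self.m_backbone = SmallCNN(channels=config.channels,
                                   embed_dim=config.embed_dim, rng=rng)
        self.m_head = ProjectionHead(config.embed_dim, config.proj_dim, rng)
        # momentum branch starts as an exact copy of the online branch
        self.m_backbone.load_state_dict(self.backbone.state_dict())
        self.m_head.load_state_dict(self.head.state_dict())
        self.queue = MemoryQueue.warm(config.queue_size, config.proj_dim, rng)
        self.config = config
        self.step = 0
        self.history: list = []

    def parameters(self):
        # only the online branch receives gradients
        return self.backbone.parameters() + self.head.parameters()

    def momentum_parameters(self):
        return self.m_backbone.parameters() + self.m_head.parameters()

    def project(self, x: Tensor) -> Tensor:
        return self.head(self.backbone(x)).l2_normalize(axis=1)

    def project_momentum(self, x: np.ndarray) -> np.ndarray:
        z = self.m_head(self.m_backbone(Tensor(x)))
        zd = z.data
        return zd / np.linalg.norm(zd, axis=1, keepdims=True)


def momentum_update(state: EncoderState, m: float, keys: np.ndarray | None = None):
    """EMA update of the momentum branch; optionally enqueue new keys.

    momentum_params <- m * momentum_params + (1 - m) * online_params
    """
    if not 0 <= m < 1:
        raise ValueError("momentum coefficient must satisfy 0 <= m < 1")
    for p_m, p in zip(state.momentum_parameters(), state.parameters()):
        p_m.data *= m
        p_m.data += (1.0 - m) * p.data
    if keys is not None:
        state.queue.enqueue(keys)
    return state


def _resize_tiles(tiles: np.ndarray, out_px: int) -> np.ndarray:
    """Deterministic area-average resize of (N, tp, tp, 3) uint8 tiles to the
    encoder input, as (N, 3, out_px, out_px) float in [-0.5, 0.5]."""
    n, tp = tiles.shape[0], tiles.shape[1]
    x = tiles.astype(np.float64) / 255.0
    if tp % out_px == 0:
        f = tp // out_px
        x = x.reshape(n, out_px, f, out_px, f, 3).mean(axis=(2, 4))
    else:
        x = np.stack([resize(t, (out_px, out_px), order=1, anti_aliasing=True)
                      for t in x])
    return np.ascontiguousarray((x - 0.5).transpose(0, 3, 1, 2))


def subsample_bags(bags, fraction: float, max_slides: int | None,
                   seed: int) -> list:
    """Seeded per-slide uniform tile subsampling (and a cap on the number of
    contributing slides) for fine-tuning-scale pretraining sets."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AB5]))
    bags = list(bags)
    if max_slides is not None and max_slides < len(bags):
        pick = rng.choice(len(bags), size=max_slides, replace=False)
        bags = [bags[i] for i in sorted(pick)]
    out = []
    for bag in bags:
        n = len(bag)
        keep = max(1, int(round(fraction * n)))
        if keep < n:
            idx = np.sort(rng.choice(n, size=keep, replace=False))
        else:
            idx = np.arange(n)
        out.append((bag.pixels[idx], bag.slide_id))
    return out


def prepare_tiles(bags, config: PretrainConfig) -> np.ndarray:
    """Pool (optionally subsampled) tiles from all bags into one array."""
    sampled = subsample_bags(bags, config.sample_fraction, config.max_slides,
                             config.seed)
    tiles = np.concatenate([p for p, _ in sampled], axis=0)
    return tiles


def pretrain(bags, config: PretrainConfig | None = None,
             log_path: str | Path | None = None) -> EncoderState:
    """Momentum-contrast pretraining over the tiles of all bags."""
    config = config or PretrainConfig()
    tiles = prepare_tiles(bags, config)
    if len(tiles) < 2:
        raise ValueError("pretraining needs at least 2 tiles")
    state = EncoderState(config)
    policy = AugmentationPolicy()
    opt = SGD(state.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A11]))
    # warm the queue with momentum-encoded real tiles so negatives are hard
    # from the first step (a random-vector queue makes epoch 1 trivially easy)
    warm_idx = rng.choice(len(tiles), size=config.queue_size, replace=True)
    for start in range(0, config.queue_size, 128):
        chunk = warm_idx[start:start + 128]
        xw = np.stack([policy(tiles[i], config.in_px, rng) for i in chunk])
        state.queue.enqueue(state.project_momentum(xw))
    n = len(tiles)
    bs = min(config.batch_size, n)
    log_rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            xq = np.stack([policy(tiles[i], config.in_px, rng) for i in idx])
            xk = np.stack([policy(tiles[i], config.in_px, rng) for i in idx])
            q = state.project(Tensor(xq))
            k = state.project_momentum(xk)                 # no gradient
            l_pos = (q * Tensor(k)).sum(axis=1, keepdims=True)
            l_neg = q @ Tensor(state.queue.buffer.T)
            logits = cat([l_pos, l_neg], axis=1) * (1.0 / config.tau)
            if config.include_positive:
                per = logits.logsumexp(axis=1) - logits[:, 0]
            else:
                per = logits[:, 1:].logsumexp(axis=1) - logits[:, 0]
            loss = per.mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite contrastive loss at epoch {epoch}, "
                    f"step {state.step}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            momentum_update(state, config.ema, keys=k)
            state.step += 1
            losses.append(float(loss.data))
        state.history.append(float(np.mean(losses)))
        log_rows.append((epoch, state.history[-1], config.lr))
    if log_path is not None:
        import pandas as pd
        pd.DataFrame(log_rows, columns=["epoch", "loss", "lr"]).to_csv(
            log_path, index=False)
    return state


def embed(bag, state: EncoderState, batch_size: int = 256) -> np.ndarray:
    """Backbone embeddings h = f(x) for every tile of a bag (projection head
    discarded); rows follow bag order.  Returns an (N, d) matrix."""
    cfg = state.config
    n = len(bag)
    if n == 0:
        return np.empty((0, cfg.embed_dim))
    x = _resize_tiles(bag.pixels, cfg.in_px)
    outs = []
    for start in range(0, n, batch_size):
        h = state.backbone(Tensor(x[start:start + batch_size]))
        outs.append(h.data)
    return np.concatenate(outs, axis=0)


def save_checkpoint(state: EncoderState, path: str | Path):
    path = Path(path)
    arrays = state.backbone.state_dict("backbone.")
    arrays.update(state.head.state_dict("head."))
    arrays.update(state.m_backbone.state_dict("m_backbone."))
    arrays.update(state.m_head.state_dict("m_head."))
    arrays["queue.buffer"] = state.queue.buffer
    arrays["queue.head"] = np.array(state.queue.head)
    arrays["queue.inserted"] = np.array(state.queue.inserted)
    arrays["step"] = np.array(state.step)
    arrays["history"] = np.array(state.history)
    cfg = asdict(state.config)
    cfg["channels"] = list(cfg["channels"])
    np.savez(path, __config__=json.dumps(cfg), **arrays)


def load_checkpoint(path: str | Path) -> EncoderState:
    with np.load(Path(path), allow_pickle=False) as npz:
        cfg = json.loads(str(npz["__config__"]))
        cfg["channels"] = tuple(cfg["channels"])
        state = EncoderState(PretrainConfig(**cfg))
        arrays = {k: npz[k] for k in npz.files if k != "__config__"}
    state.backbone.load_state_dict(arrays, "backbone.")
    state.head.load_state_dict(arrays, "head.")
    state.m_backbone.load_state_dict(arrays, "m_backbone.")
    state.m_head.load_state_dict(arrays, "m_head.")
    state.queue.buffer = arrays["queue.buffer"].copy()
    state.queue.head = int(arrays["queue.head"])
    state.queue.inserted = int(arrays["queue.inserted"])
    state.step = int(arrays["step"])
    state.history = arrays["history"].tolist()
    return state
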