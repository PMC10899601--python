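"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as `Tensor`s with `requires_grad=True`;
`Module.parameters()` yields them for the optimizers.  State dicts are plain
``{name: ndarray}`` mappings so checkpoints serialize with ``np.savez``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d


class Module:
    def parameters(self):
        out = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_dict(self, prefix=""):
        state = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                state[prefix + name] = v.data.copy()
            elif isinstance(v, Module):
                state.update(v.state_dict(prefix + name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{prefix}{name}.{i}."))
        return state

    def load_state_dict(self, state, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[prefix + name], dtype=np.float64).copy()
            elif isinstance(v, Module):
                v.load_state_dict(state, prefix + name + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{prefix}{name}.{i}.")


class Dense(Module):
    """Fully connected layer y = xW^T + b with He-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.w = Tensor(rng.uniform(-bound, bound, (n_out, n_in)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w.T + self.b


class Conv(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        fan_in = c_in * k * k
        bound = np.sqrt(6.0 / fan_in)
        self.w = Tensor(rng.uniform(-bound, bound, (c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class SmallCNN(Module):
    """Compact convolutional tile encoder: strided 3x3 conv blocks with ReLU,
    global average pooling, and a linear map to the embedding dimension.

    The depth/width are configurable; defaults are sized so that contrastive
    pretraining and MIL fine-tuning run in minutes on one CPU core.
    """

    def __init__(self, in_channels: int = 3, channels=(16, 32), embed_dim: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.convs = []
        c_prev = in_channels
        for c in channels:
            self.convs.append(Conv(c_prev, c, k=3, stride=2, pad=1, rng=rng))
            c_prev = c
        self.fc = Dense(c_prev, embed_dim, rng)
        self.embed_dim = embed_dim
        self.channels = tuple(channels)
        self.in_channels = in_channels

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, C, H, W) -> embeddings h: (B, embed_dim)."""
        for conv in self.convs:
            x = conv(x).relu()
        pooled = x.mean(axis=3).mean(axis=2)      # global average pool -> (B, C)
        return self.fc(pooled)


class ProjectionHead(Module):
    """Two fully connected layers mapping the embedding h to the contrastive
    space z (ReLU in between, as in MoCo v2)."""

    def __init__(self, embed_dim: int, proj_dim: int, rng: np.random.Generator):
        self.fc1 = Dense(embed_dim, embed_dim, rng)
        self.fc2 = Dense(embed_dim, proj_dim, rng)
        self.proj_dim = proj_dim

    def __call__(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).relu())


class SGD:
    """SGD with Nesterov-free momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr=0.03, momentum=0.9, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad if p.grad is not None else 0.0
            g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
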