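"""Gated-attention pooling: aggregate tile embeddings into a slide feature.

For a bag of N tile embeddings h_i the attention logit of tile i is

    e_i = w^T ( tanh(V h_i) * sigm(U h_i) )        (elementwise product)

and the slide feature is the attention-weighted average S = sum_i a_i h_i
with a = softmax(e) (max-subtracted for numerical stability).  The pooled
feature therefore lies in the convex hull of the tile embeddings, and the
whole operation is permutation-invariant in S and permutation-equivariant
in a.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .autodiff import Tensor
from .nn import Module

__all__ = ["AttentionParams", "SlideFeature", "gated_attention",
           "attention_ranking", "GatedAttention"]


@dataclass
class AttentionParams:
    V: np.ndarray        # (L, d)
    U: np.ndarray        # (L, d)
    w: np.ndarray        # (L,)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.V.shape != self.U.shape or self.w.shape != (self.V.shape[0],):
            raise ValueError("inconsistent attention parameter shapes")


@dataclass
class SlideFeature:
    S: np.ndarray              # (d,) pooled slide feature
    attention: np.ndarray      # (N,) nonnegative, sums to 1
    coords: np.ndarray = None  # (N, 2) tile (x0, y0), row-major order
    slide_id: str = ""


def _softmax(e: np.ndarray) -> np.ndarray:
    z = np.exp(e - e.max())
    return z / z.sum()


def gated_attention(H: np.ndarray, params: AttentionParams,
                    coords: np.ndarray | None = None,
                    slide_id: str = "") -> SlideFeature:
    """Pool an (N, d) embedding matrix into a SlideFeature."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("empty bag: gated attention needs at least one tile")
    gate = np.tanh(H @ params.V.T) * expit(H @ params.U.T)
    e = gate @ params.w
    a = _softmax(e)
    return SlideFeature(S=a @ H, attention=a, coords=coords, slide_id=slide_id)


def attention_ranking(sf: SlideFeature, k: int):
    """Tiles with the k largest and k smallest attention scores.

    Ties are broken by row-major tile order (stable sort on bag position).
    Returns (top, bottom): lists of (index, (x0, y0) or None, score).
    """
    n = len(sf.attention)
    if k > n:
        raise ValueError(f"k={k} exceeds bag size {n}")
    order = np.argsort(-sf.attention, kind="stable")       # descending, stable
    order_asc = np.argsort(sf.attention, kind="stable")    # ascending, stable

    def _entry(i):
        xy = tuple(sf.coords[i]) if sf.coords is not None else None
        return (int(i), xy, float(sf.attention[i]))

    return [_entry(i) for i in order[:k]], [_entry(i) for i in order_asc[:k]]


class GatedAttention(Module):
    """Trainable gated-attention pooling layer (autodiff version)."""

    def __init__(self, embed_dim: int, hidden_dim: int = 128,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / embed_dim)
        self.V = Tensor(rng.uniform(-bound, bound, (hidden_dim, embed_dim)),
                        requires_grad=True)
        self.U = Tensor(rng.uniform(-bound, bound, (hidden_dim, embed_dim)),
                        requires_grad=True)
        self.w = Tensor(rng.uniform(-bound, bound, (hidden_dim, 1)),
                        requires_grad=True)

    def __call__(self, H: Tensor):
        """H: (N, d) -> (S: (1, d), a: (N, 1))."""
        gate = (H @ self.V.T).tanh() * (H @ self.U.T).sigmoid()
        e = gate @ self.w                       # (N, 1)
        a = e.softmax(axis=0)
        return a.T @ H, a

    def to_params(self) -> AttentionParams:
        return AttentionParams(V=self.V.data.copy(), U=self.U.data.copy(),
                               w=self.w.data[:, 0].copy())
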