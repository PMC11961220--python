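"""Unparameterized comparison poolers: average, max, K-max and softmax.

All four are permutation invariant and map an n x d token set to a length-d
vector, so each is a drop-in alternative to the SWE pooler with L = d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TokenEmbeddingSet

__all__ = ["PoolerSpec", "avg_pool", "max_pool", "kmax_pool", "softmax_pool",
           "default_kmax_k"]

_KINDS = ("average", "max", "kmax", "softmax")


@dataclass(frozen=True)
class PoolerSpec:
    kind: str
    K: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown pooler kind {self.kind!r}; choose from {_KINDS}")
        if self.kind == "kmax" and (self.K is None or self.K < 1):
            raise ValueError("kmax pooling needs a positive K")


def _as_matrix(X) -> np.ndarray:
    emb = X.embeddings if isinstance(X, TokenEmbeddingSet) else np.asarray(X, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[0] < 1:
        raise ValueError("pooling needs a non-empty n x d token matrix")
    return emb


def avg_pool(X) -> np.ndarray:
    """Coordinate-wise mean over tokens."""
    return _as_matrix(X).mean(axis=0)


def max_pool(X) -> np.ndarray:
    """Coordinate-wise maximum over tokens."""
    return _as_matrix(X).max(axis=0)


def default_kmax_k(n: int) -> int:
    """Default K for K-max pooling: 5% of the sequence length, at least 1."""
    return max(1, int(np.ceil(0.05 * n)))


def kmax_pool(X, K: int) -> np.ndarray:
    """Per dimension, mean of the K largest values (K clamped to n).

    K = 1 reduces to max pooling; K = n to average pooling.
    """
    emb = _as_matrix(X)
    if K < 1:
        raise ValueError("K must be positive")
    K = min(K, emb.shape[0])
    # partition then slice: top-K per column without a full sort
    top = np.partition(emb, emb.shape[0] - K, axis=0)[emb.shape[0] - K:]
    return top.mean(axis=0)


def softmax_pool(X) -> np.ndarray:
    """log of the mean of exponentials per dimension (max-shifted for overflow safety).

    Lies between the average and the maximum coordinate-wise.
    """
    emb = _as_matrix(X)
    shift = emb.max(axis=0)
    return shift + np.log(np.mean(np.exp(emb - shift), axis=0))


def pool_with_spec(X, spec: PoolerSpec) -> np.ndarray:
    emb = _as_matrix(X)
    if spec.kind == "average":
        return avg_pool(emb)
    if spec.kind == "max":
        return max_pool(emb)
    if spec.kind == "kmax":
        return kmax_pool(emb, spec.K if spec.K is not None else default_kmax_k(emb.shape[0]))
    return softmax_pool(emb)
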