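"""Downstream task heads and their losses.

Four heads sit on top of a pooled protein embedding:

* binary drug-target interaction (DTI): drug fingerprint and protein are
  projected into a shared non-negative co-embedding space (linear map +
  ReLU); the cosine similarity of the two projections is the interaction
  probability, trained with binary cross-entropy on the cosine;
* drug-target affinity: same projections, but the inner product predicts
  the real-valued affinity, trained with squared error;
* 10-class classification (subcellular localization): a single linear
  head with softmax cross-entropy;
* binary enzyme-activity classification: a two-layer perceptron with a
  d-dimensional hidden layer and LeakyReLU, softmax cross-entropy over
  two logits.

Each head exposes ``loss_and_grads`` returning the loss, analytic
gradients for its own parameters and the gradient w.r.t. the pooled
embedding, so the pooler can be trained end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DTIHeadParams", "MulticlassHeadParams", "ECHeadParams",
    "cos_bce_loss", "dti_predict", "affinity_loss", "multiclass_ce_loss",
    "ec_predict",
]

_NORM_EPS = 1e-8          # lower clamp on cosine denominators
_LOG_EPS = 1e-7           # log arguments clipped to [eps, 1 - eps]


# ---------------------------------------------------------------------------
# losses (pure functions, as used by the heads)

def cos_bce_loss(x1, x2, y) -> float:
    """Binary cross-entropy of the cosine similarity of two non-negative vectors.

    On the non-negative orthant the cosine lies in [0, 1], so it can act
    directly as a probability; denominators and log arguments are
    epsilon-guarded.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if np.any(x1 < 0) or np.any(x2 < 0):
        raise ValueError("cos_bce_loss expects non-negative vectors")
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    c = _cosine(x1, x2)
    c = np.clip(c, _LOG_EPS, 1.0 - _LOG_EPS)
    return float(-(y * np.log(c) + (1 - y) * np.log(1.0 - c)))


def affinity_loss(x1, x2, y) -> float:
    """Squared error between the label and the inner product of the embeddings."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return float((y - x1 @ x2) ** 2)


def multiclass_ce_loss(logits, y: int) -> float:
    """Negative log-softmax at the true class (1-based), max-shifted."""
    logits = np.asarray(logits, dtype=np.float64)
    k = logits.size
    if not (1 <= y <= k):
        raise ValueError(f"class label must be in 1..{k}, got {y}")
    shifted = logits - logits.max()
    return float(np.log(np.exp(shifted).sum()) - shifted[y - 1])


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = max(float(np.linalg.norm(a)), _NORM_EPS)
    nb = max(float(np.linalg.norm(b)), _NORM_EPS)
    return float(a @ b) / (na * nb)


# ---------------------------------------------------------------------------
# DTI / affinity co-embedding head

@dataclass
class DTIHeadParams:
    """Linear projections into the shared co-embedding space R^D.

    ``drug_proj`` (S) is D x c over the fingerprint, ``target_proj`` (V)
    is D x d over the pooled protein embedding; ReLU maps both into the
    non-negative orthant.
    """

    drug_proj: np.ndarray
    target_proj: np.ndarray

    def __post_init__(self):
        self.drug_proj = np.asarray(self.drug_proj, dtype=np.float64)
        self.target_proj = np.asarray(self.target_proj, dtype=np.float64)
        if self.drug_proj.shape[0] != self.target_proj.shape[0]:
            raise ValueError("drug and target projections must share the co-embedding dim")

    @property
    def D(self) -> int:
        return self.drug_proj.shape[0]

    @classmethod
    def init(cls, c: int, d: int, D: int = 1024, *, rng=None) -> "DTIHeadParams":
        rng = np.random.default_rng(rng)
        return cls(drug_proj=rng.normal(0, 1 / np.sqrt(c), (D, c)),
                   target_proj=rng.normal(0, 1 / np.sqrt(d), (D, d)))

    # -- forward -----------------------------------------------------------
    def embed(self, f, v):
        f = np.asarray(f, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        if f.size != self.drug_proj.shape[1]:
            raise ValueError(f"fingerprint length {f.size} != c={self.drug_proj.shape[1]}")
        if v.size != self.target_proj.shape[1]:
            raise ValueError(f"embedding length {v.size} != d={self.target_proj.shape[1]}")
        a_pre = self.drug_proj @ f
        b_pre = self.target_proj @ v
        return np.maximum(a_pre, 0.0), np.maximum(b_pre, 0.0), a_pre, b_pre

    def predict_interaction(self, f, v) -> float:
        a, b, _, _ = self.embed(f, v)
        return float(np.clip(_cosine(a, b), 0.0, 1.0))

    def predict_affinity(self, f, v) -> float:
        a, b, _, _ = self.embed(f, v)
        return float(a @ b)

    # -- backward ----------------------------------------------------------
    def loss_and_grads(self, v, f, y, *, mode: str = "interaction"):
        """Loss plus gradients w.r.t. (S, V) and the pooled embedding v."""
        f = np.asarray(f, dtype=np.float64)
        v = np.asarray(v, dtype=np.float64)
        a, b, a_pre, b_pre = self.embed(f, v)
        if mode == "interaction":
            na = max(float(np.linalg.norm(a)), _NORM_EPS)
            nb = max(float(np.linalg.norm(b)), _NORM_EPS)
            c_raw = float(a @ b) / (na * nb)
            c = float(np.clip(c_raw, _LOG_EPS, 1.0 - _LOG_EPS))
            loss = -(y * np.log(c) + (1 - y) * np.log(1.0 - c))
            if _LOG_EPS < c_raw < 1.0 - _LOG_EPS:
                dc = -(y / c - (1 - y) / (1.0 - c))
            else:
                dc = 0.0       # clipped region: flat
            da = dc * (b / (na * nb) - c_raw * a / (na * na))
            db = dc * (a / (na * nb) - c_raw * b / (nb * nb))
        elif mode == "affinity":
            pred = float(a @ b)
            loss = (y - pred) ** 2
            dpred = -2.0 * (y - pred)
            da = dpred * b
            db = dpred * a
        else:
            raise ValueError(f"unknown mode {mode!r}")
        da_pre = da * (a_pre > 0)
        db_pre = db * (b_pre > 0)
        grads = {"drug_proj": np.outer(da_pre, f),
                 "target_proj": np.outer(db_pre, v)}
        dv = self.target_proj.T @ db_pre
        return float(loss), grads, dv


# ---------------------------------------------------------------------------
# linear 10-class head

@dataclass
class MulticlassHeadParams:
    """Linear classification head over 10 classes (rows of ``class_matrix``)."""

    class_matrix: np.ndarray

    def __post_init__(self):
        self.class_matrix = np.asarray(self.class_matrix, dtype=np.float64)
        if self.class_matrix.shape[0] != 10:
            raise ValueError("10-class head requires a 10 x d class matrix")

    @classmethod
    def init(cls, d: int, *, rng=None) -> "MulticlassHeadParams":
        rng = np.random.default_rng(rng)
        return cls(class_matrix=rng.normal(0, 1 / np.sqrt(d), (10, d)))

    def logits(self, v) -> np.ndarray:
        return self.class_matrix @ np.asarray(v, dtype=np.float64)

    def loss_and_grads(self, v, y: int):
        v = np.asarray(v, dtype=np.float64)
        logits = self.class_matrix @ v
        loss = multiclass_ce_loss(logits, y)
        g = _softmax(logits)
        g[y - 1] -= 1.0
        grads = {"class_matrix": np.outer(g, v)}
        dv = self.class_matrix.T @ g
        return loss, grads, dv


# ---------------------------------------------------------------------------
# two-layer binary head

@dataclass
class ECHeadParams:
    """Two-layer perceptron for binary classification.

    Hidden width equals the embedding dimension d; LeakyReLU with a small
    negative slope keeps gradients alive on the negative side.
    """

    layer1: np.ndarray
    bias1: np.ndarray
    layer2: np.ndarray
    bias2: np.ndarray
    leaky_slope: float = 0.01

    def __post_init__(self):
        self.layer1 = np.asarray(self.layer1, dtype=np.float64)
        self.bias1 = np.asarray(self.bias1, dtype=np.float64)
        self.layer2 = np.asarray(self.layer2, dtype=np.float64)
        self.bias2 = np.asarray(self.bias2, dtype=np.float64)
        d = self.layer1.shape[1]
        if self.layer1.shape[0] != d:
            raise ValueError("hidden width must equal the embedding dimension")
        if self.layer2.shape != (2, d) or self.bias2.shape != (2,):
            raise ValueError("output layer must map d -> 2")

    @classmethod
    def init(cls, d: int, *, rng=None, leaky_slope: float = 0.01) -> "ECHeadParams":
        rng = np.random.default_rng(rng)
        return cls(layer1=rng.normal(0, 1 / np.sqrt(d), (d, d)),
                   bias1=np.zeros(d),
                   layer2=rng.normal(0, 1 / np.sqrt(d), (2, d)),
                   bias2=np.zeros(2),
                   leaky_slope=leaky_slope)

    def logits(self, v) -> np.ndarray:
        return ec_predict(v, self)

    def prob_positive(self, v) -> float:
        return float(_softmax(self.logits(v))[1])

    def loss_and_grads(self, v, y: int):
        """y is 0/1; internally class indices 1/2 of the two logits."""
        v = np.asarray(v, dtype=np.float64)
        h_pre = self.layer1 @ v + self.bias1
        h = np.where(h_pre > 0, h_pre, self.leaky_slope * h_pre)
        logits = self.layer2 @ h + self.bias2
        loss = multiclass_ce_loss(logits, y + 1)
        g = _softmax(logits)
        g[y] -= 1.0
        dh = self.layer2.T @ g
        dh_pre = dh * np.where(h_pre > 0, 1.0, self.leaky_slope)
        grads = {"layer2": np.outer(g, h), "bias2": g,
                 "layer1": np.outer(dh_pre, v), "bias1": dh_pre}
        dv = self.layer1.T @ dh_pre
        return loss, grads, dv


def dti_predict(f, protein_embedding, params: DTIHeadParams) -> float:
    """Interaction probability: cosine of the two ReLU co-embeddings, in [0, 1]."""
    return params.predict_interaction(f, protein_embedding)


def ec_predict(embedding, params: ECHeadParams) -> np.ndarray:
    """Two raw logits of the binary two-layer head."""
    v = np.asarray(embedding, dtype=np.float64)
    if v.size != params.layer1.shape[1]:
        raise ValueError(f"embedding length {v.size} != d={params.layer1.shape[1]}")
    h_pre = params.layer1 @ v + params.bias1
    h = np.where(h_pre > 0, h_pre, params.leaky_slope * h_pre)
    return params.layer2 @ h + params.bias2
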