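"""Sliced-Wasserstein embedding (SWE) pooling.

Turns a variable-size set of per-residue embeddings into a fixed-length,
permutation-invariant protein-level vector.  The token set and a trainable
reference set are projected onto ``L`` learnable directions ("slicers");
on each slice the 1-D Monge coupling between the projected input and the
reference values is computed in closed form by sorting (equal sizes) or by
inverting the interpolated empirical CDF (unequal sizes); the resulting
``L x m`` coupling matrix is collapsed to ``L`` numbers by a learned
combination ``w`` over the reference elements.

The map is piecewise linear in its parameters once the sort permutations
are fixed, so exact gradients are available in closed form; the backward
pass here treats the permutations as constants, which is the
almost-everywhere gradient of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TokenEmbeddingSet",
    "SWEPoolerParams",
    "MongeCouplingResult",
    "PooledEmbedding",
    "SWEGradients",
    "init_swe_params",
    "slice_tokens",
    "monge_coupling_1d",
    "swe_pool",
    "swe_pool_with_grad",
    "swe_pool_batch",
    "swe_param_count",
]

MATCH_D = "match-d"


@dataclass(frozen=True)
class TokenEmbeddingSet:
    """One protein's residue-level embedding matrix (n tokens x d dims)."""

    protein_id: str
    embeddings: np.ndarray

    def __post_init__(self):
        emb = np.asarray(self.embeddings, dtype=np.float64)
        if emb.ndim != 2:
            raise ValueError(f"embeddings must be 2-D, got shape {emb.shape}")
        if emb.shape[0] < 1:
            raise ValueError("token set must contain at least one token")
        if not np.all(np.isfinite(emb)):
            raise ValueError(f"non-finite embedding values for {self.protein_id!r}")
        object.__setattr__(self, "embeddings", emb)

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class SWEPoolerParams:
    """Trainable state of the SWE pooler.

    ``slicers`` is the L x d matrix of slicing directions, ``ref_slices``
    the m x L matrix of reference values expressed directly at the output
    of the slicers (the reference is learned in slice space, not as raw
    points in R^d), and ``combiner`` the length-m projection across
    reference elements.  With ``freeze_ref_and_slicers`` only the combiner
    is trainable (the "SWE_Simple" variant).
    """

    slicers: np.ndarray
    ref_slices: np.ndarray
    combiner: np.ndarray
    freeze_ref_and_slicers: bool = False
    seed: int = 0

    def __post_init__(self):
        self.slicers = np.asarray(self.slicers, dtype=np.float64)
        self.ref_slices = np.asarray(self.ref_slices, dtype=np.float64)
        self.combiner = np.asarray(self.combiner, dtype=np.float64)
        if self.slicers.ndim != 2 or self.ref_slices.ndim != 2 or self.combiner.ndim != 1:
            raise ValueError("slicers must be L x d, ref_slices m x L, combiner length m")
        L, _ = self.slicers.shape
        m, L2 = self.ref_slices.shape
        if L2 != L:
            raise ValueError(f"ref_slices has {L2} slices but there are {L} slicers")
        if self.combiner.shape[0] != m:
            raise ValueError(f"combiner length {self.combiner.shape[0]} != m={m}")
        for name, arr in (("slicers", self.slicers), ("ref_slices", self.ref_slices),
                          ("combiner", self.combiner)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def L(self) -> int:
        return self.slicers.shape[0]

    @property
    def d(self) -> int:
        return self.slicers.shape[1]

    @property
    def m(self) -> int:
        return self.ref_slices.shape[0]

    @property
    def n_trainable(self) -> int:
        return swe_param_count(self.m, self.d, self.L,
                               simple=self.freeze_ref_and_slicers)


@dataclass(frozen=True)
class MongeCouplingResult:
    """Closed-form 1-D Monge coupling of an input slice against a reference slice.

    ``z[i]`` is the signed displacement that moves reference element ``i``
    onto its rank-matched input value (equal sizes) or onto the input
    quantile at its rank (unequal sizes).  ``input_sort_perm`` is the
    stable argsort of the input values; ``ref_rank_inverse[i]`` is the
    rank of reference element ``i`` within its slice.
    """

    z: np.ndarray
    input_sort_perm: np.ndarray
    ref_rank_inverse: np.ndarray


@dataclass(frozen=True)
class PooledEmbedding:
    """Fixed-length protein-level embedding; length L regardless of input size."""

    vector: np.ndarray
    protein_id: str


@dataclass
class SWEGradients:
    """Analytic gradients of a scalar loss w.r.t. the pooler parameters.

    ``slicers``/``ref_slices`` are ``None`` when the pooler is frozen.
    """

    combiner: np.ndarray
    slicers: np.ndarray | None = None
    ref_slices: np.ndarray | None = None


def swe_param_count(m: int, d: int, L: int, *, simple: bool = False) -> int:
    """Number of trainable pooler parameters: m*L + d*L + m, or m for SWE_Simple."""
    if m < 1 or d < 1 or L < 1:
        raise ValueError("m, d and L must be positive")
    if simple:
        return m
    return m * L + d * L + m


def init_swe_params(d: int, m: int, L: int | str = MATCH_D, *,
                    freeze: bool = False, seed: int = 0) -> SWEPoolerParams:
    """Draw fresh pooler parameters.

    Slicer rows are i.i.d. normal with standard deviation ``1/sqrt(d)`` so
    that projections of unit-scale tokens stay O(1); reference slice values
    are standard normal; the combiner starts at the constant ``1/m`` so the
    initial output is a mean over reference-aligned couplings.  ``L``
    defaults to ``d`` so the pooler is a drop-in replacement for average
    pooling.
    """
    if L == MATCH_D:
        L = d
    d, m, L = int(d), int(m), int(L)
    if d < 1 or m < 1 or L < 1:
        raise ValueError(f"dimensions must be positive, got d={d}, m={m}, L={L}")
    rng = np.random.default_rng(seed)
    slicers = rng.normal(0.0, 1.0 / np.sqrt(d), size=(L, d))
    ref_slices = rng.normal(0.0, 1.0, size=(m, L))
    combiner = np.full(m, 1.0 / m)
    return SWEPoolerParams(slicers=slicers, ref_slices=ref_slices,
                           combiner=combiner, freeze_ref_and_slicers=bool(freeze),
                           seed=int(seed))


def slice_tokens(X: TokenEmbeddingSet | np.ndarray, slicers: np.ndarray) -> np.ndarray:
    """Project every token onto every slicing direction: entry (i, l) = <x_i, w_l>."""
    emb = X.embeddings if isinstance(X, TokenEmbeddingSet) else np.asarray(X, dtype=np.float64)
    slicers = np.asarray(slicers, dtype=np.float64)
    if emb.ndim != 2 or slicers.ndim != 2:
        raise ValueError("expected 2-D token matrix and 2-D slicer matrix")
    if emb.shape[1] != slicers.shape[1]:
        raise ValueError(
            f"token dimension {emb.shape[1]} != slicer dimension {slicers.shape[1]}")
    return emb @ slicers.T


def _ref_ranks(U0: np.ndarray) -> np.ndarray:
    """Per-column rank of each reference element (stable; ties by original index)."""
    order = np.argsort(U0, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(U0.shape[0])[:, None], axis=0)
    return ranks


def _coupling_forward(U: np.ndarray, U0: np.ndarray, *,
                      force_interpolation: bool = False):
    """Vectorized per-slice Monge couplings.

    U is n x L (projected input), U0 is m x L (reference slice values).
    Returns (Z, cache) with Z of shape m x L: Z[i, l] is the coupling value
    for reference element i on slice l.  ``force_interpolation`` evaluates
    the general inverse-CDF path even at n == m (the two paths agree there;
    useful for verifying the reduction).
    """
    n, L = U.shape
    m = U0.shape[0]
    perm = np.argsort(U, axis=0, kind="stable")          # rho per slice
    S = np.take_along_axis(U, perm, axis=0)              # sorted input values
    ranks = _ref_ranks(U0)                               # rho0^{-1} per slice

    if n == m and not force_interpolation:
        vals = np.take_along_axis(S, ranks, axis=0)
        cache = {"case": 1, "perm": perm, "ranks": ranks, "n": n, "m": m}
    else:
        # F^{-1} piecewise linear through (k/n -> k-th smallest), k = 1..n,
        # F^{-1}(p) = min value for p <= 1/n; evaluated at q_i = rank_i / m
        # (1-based).  Exact-integer numerator keeps n == m reduction exact.
        t = (n * (ranks + 1)) / m          # = q * n, in (0, n]
        k_float = np.clip(t - 1.0, 0.0, n - 1.0)
        k0 = np.floor(k_float).astype(np.intp)
        frac = k_float - k0
        k1 = np.minimum(k0 + 1, n - 1)
        s0 = np.take_along_axis(S, k0, axis=0)
        s1 = np.take_along_axis(S, k1, axis=0)
        vals = s0 * (1.0 - frac) + s1 * frac
        cache = {"case": 2, "perm": perm, "ranks": ranks, "n": n, "m": m,
                 "k0": k0, "k1": k1, "frac": frac}
    Z = vals - U0
    return Z, cache


def _coupling_backward(dZ: np.ndarray, cache: dict, n: int) -> np.ndarray:
    """Route dL/dZ back to dL/dU (the projected input values)."""
    dS = np.zeros((n, dZ.shape[1]))
    cols = np.broadcast_to(np.arange(dZ.shape[1]), dZ.shape)
    if cache["case"] == 1:
        np.add.at(dS, (cache["ranks"], cols), dZ)
    else:
        frac = cache["frac"]
        np.add.at(dS, (cache["k0"], cols), dZ * (1.0 - frac))
        np.add.at(dS, (cache["k1"], cols), dZ * frac)
    dU = np.empty_like(dS)
    np.put_along_axis(dU, cache["perm"], dS, axis=0)
    return dU


def monge_coupling_1d(u_in, u_ref, *, force_interpolation: bool = False) -> MongeCouplingResult:
    """Closed-form optimal (Monge) coupling between two 1-D empirical distributions.

    With equal sizes the coupling is the difference of rank-matched sorted
    values; otherwise reference element i receives the input quantile at
    position (rank_i + 1)/m under the piecewise-linear interpolated inverse
    CDF of the input values.  Ties are broken by a stable sort on the
    original index, which makes both permutations deterministic.
    """
    u_in = np.asarray(u_in, dtype=np.float64).ravel()
    u_ref = np.asarray(u_ref, dtype=np.float64).ravel()
    if u_in.size == 0 or u_ref.size == 0:
        raise ValueError("input and reference slices must be non-empty")
    if not (np.all(np.isfinite(u_in)) and np.all(np.isfinite(u_ref))):
        raise ValueError("non-finite values in slice")
    Z, cache = _coupling_forward(u_in[:, None], u_ref[:, None],
                                 force_interpolation=force_interpolation)
    return MongeCouplingResult(
        z=Z[:, 0],
        input_sort_perm=cache["perm"][:, 0],
        ref_rank_inverse=cache["ranks"][:, 0],
    )


def _check_dims(X: TokenEmbeddingSet, params: SWEPoolerParams) -> None:
    if X.d != params.d:
        raise ValueError(f"token dimension {X.d} != pooler dimension {params.d}")


def swe_pool(X: TokenEmbeddingSet, params: SWEPoolerParams, *,
             return_coupling: bool = False):
    """Pool one token set into a length-L embedding: pi(X) = Z w.

    Row l of the L x m matrix Z holds the Monge coupling of slice l of the
    input against reference slice l.  The output does not depend on the
    order of the rows of X, and its length is L for every input size.
    With ``return_coupling`` the stacked coupling matrix Z (L x m) is
    returned alongside the embedding.
    """
    _check_dims(X, params)
    U = X.embeddings @ params.slicers.T
    Z, _ = _coupling_forward(U, params.ref_slices)       # m x L
    vec = Z.T @ params.combiner                          # length L
    pooled = PooledEmbedding(vector=vec, protein_id=X.protein_id)
    if return_coupling:
        return pooled, Z.T
    return pooled


def swe_pool_with_grad(X: TokenEmbeddingSet, params: SWEPoolerParams):
    """Forward pass returning the embedding and a closure for the backward pass.

    The returned ``backward(grad_vector)`` maps dL/d(embedding) to
    ``SWEGradients``; slicer and reference gradients are omitted (None)
    when the pooler is frozen, so gradient flow matches the trainable
    parameter count exactly.
    """
    _check_dims(X, params)
    emb = X.embeddings
    U = emb @ params.slicers.T
    Z, cache = _coupling_forward(U, params.ref_slices)
    vec = Z.T @ params.combiner

    def backward(grad_vector: np.ndarray) -> SWEGradients:
        g = np.asarray(grad_vector, dtype=np.float64)
        d_comb = Z @ g                                   # m
        if params.freeze_ref_and_slicers:
            return SWEGradients(combiner=d_comb)
        dZ = np.outer(params.combiner, g)                # m x L
        d_ref = -dZ
        dU = _coupling_backward(dZ, cache, emb.shape[0])
        d_slicers = dU.T @ emb                           # L x d
        return SWEGradients(combiner=d_comb, slicers=d_slicers, ref_slices=d_ref)

    return PooledEmbedding(vector=vec, protein_id=X.protein_id), backward


def swe_pool_batch(padded: np.ndarray, lengths, params: SWEPoolerParams,
                   ids=None) -> np.ndarray:
    """Pool a padded batch (B x n_max x d); rows beyond each length are ignored.

    Padding positions never enter the sorting or CDF construction, so the
    result is identical to pooling each un-padded set on its own.
    """
    padded = np.asarray(padded, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.intp)
    if padded.ndim != 3:
        raise ValueError("padded batch must be B x n_max x d")
    if np.any(lengths < 1) or np.any(lengths > padded.shape[1]):
        raise ValueError("lengths must be in [1, n_max]")
    out = np.empty((padded.shape[0], params.L))
    for b in range(padded.shape[0]):
        X = TokenEmbeddingSet(
            protein_id=str(ids[b]) if ids is not None else str(b),
            embeddings=padded[b, : lengths[b]],
        )
        out[b] = swe_pool(X, params).vector
    return out
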