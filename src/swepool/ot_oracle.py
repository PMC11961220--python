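"""Independent exact 1-D optimal-transport references.

These routines deliberately share no code with the pooler: the equal-size
cost is a direct sorted-matching sum, the general case goes through the
transportation linear program (HiGHS) or scipy's closed-form 1-D
Wasserstein distance, so they can serve as oracles for the coupling
computed by sorting/quantile interpolation in :mod:`swepool.core`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import wasserstein_distance

__all__ = ["TransportPlan", "exact_w1_sorted", "exact_ot_lp",
           "exact_w1_quantile", "w1_from_coupling"]

_LP_SIZE_GUARD = 10_000


@dataclass(frozen=True)
class TransportPlan:
    """Optimal plan between two uniform empirical measures plus its W1 cost."""

    plan: np.ndarray
    cost: float

    def check_feasible(self, atol: float = 1e-9) -> None:
        n, m = self.plan.shape
        if np.any(self.plan < -atol):
            raise AssertionError("negative mass in transport plan")
        if not np.allclose(self.plan.sum(axis=1), 1.0 / n, atol=atol):
            raise AssertionError("row marginals != 1/n")
        if not np.allclose(self.plan.sum(axis=0), 1.0 / m, atol=atol):
            raise AssertionError("column marginals != 1/m")


def _vec(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64).ravel()
    if a.size == 0:
        raise ValueError("empty point set")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite values")
    return a


def exact_w1_sorted(a, b) -> float:
    """W1 between equal-size uniform empirical measures: mean |sorted(a) - sorted(b)|."""
    a, b = _vec(a), _vec(b)
    if a.size != b.size:
        raise ValueError(f"size mismatch: {a.size} vs {b.size}")
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


def exact_w1_quantile(a, b) -> float:
    """Exact 1-D W1 for arbitrary sizes (area between the empirical CDFs)."""
    return float(wasserstein_distance(_vec(a), _vec(b)))


def exact_ot_lp(a, b) -> TransportPlan:
    """Solve the uniform-weight transportation LP with cost |a_i - b_j|.

    Intended as a small-instance oracle; guards n*m <= 10000.
    """
    a, b = _vec(a), _vec(b)
    n, m = a.size, b.size
    if n * m > _LP_SIZE_GUARD:
        raise ValueError(f"LP oracle limited to n*m <= {_LP_SIZE_GUARD}, got {n * m}")
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    # marginal constraints; one row is redundant but HiGHS copes
    rows, cols, vals = [], [], []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
        vals.extend([1.0] * m)
    for j in range(m):
        rows.extend([n + j] * n)
        cols.extend(range(j, n * m, m))
        vals.extend([1.0] * n)
    A_eq = sparse.coo_matrix((vals, (rows, cols)), shape=(n + m, n * m))
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transportation LP failed: {res.message}")
    plan = res.x.reshape(n, m)
    return TransportPlan(plan=plan, cost=float(res.fun))


def w1_from_coupling(z) -> float:
    """W1 implied by a Monge coupling vector: mean absolute displacement."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.size == 0:
        return 0.0
    return float(np.mean(np.abs(z)))
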