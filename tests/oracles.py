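"""Independent reference implementations used as test oracles.

These deliberately avoid the code paths they validate: the weighted
minimum-norm solve is checked against a direct KKT linear system, the full
solver against a generic nonlinear equality-constrained optimizer, and the
hypergeometric tail against exact rational enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy.optimize import LinearConstraint, minimize


def qp_minnorm_kkt(B: np.ndarray, q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve min Tr(U^T Q U) s.t. BU = X by the KKT system.

    Stationarity 2QU = B^T L and feasibility BU = X are stacked into one
    indefinite linear system and solved directly — no min-norm formula.
    """
    n, b = B.shape
    kkt = np.block([[2.0 * np.diag(q), B.T], [B, np.zeros((n, n))]])
    rhs = np.vstack([np.zeros((b, X.shape[1])), X])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:b]


def smoothed_l21_constrained(
    B: np.ndarray,
    X: np.ndarray,
    epsilon: float,
    U0: np.ndarray | None = None,
) -> np.ndarray:
    """Generic convex solve of min sum_i sqrt(||u_i||^2 + eps) s.t. BU = X.

    Uses scipy's trust-constr on the column-major flattening of U with an
    analytic gradient; intended for tiny instances only.
    """
    n, b = B.shape
    c = X.shape[1]

    def objective(u: np.ndarray) -> float:
        U = u.reshape((b, c), order="F")
        return float(np.sqrt((U * U).sum(axis=1) + epsilon).sum())

    def gradient(u: np.ndarray) -> np.ndarray:
        U = u.reshape((b, c), order="F")
        denom = np.sqrt((U * U).sum(axis=1) + epsilon)
        return (U / denom[:, None]).flatten(order="F")

    constraint_matrix = np.kron(np.eye(c), B)
    target = X.flatten(order="F")
    if U0 is None:
        U0 = np.linalg.pinv(B) @ X
    res = minimize(
        objective,
        U0.flatten(order="F"),
        jac=gradient,
        constraints=[LinearConstraint(constraint_matrix, target, target)],
        method="trust-constr",
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
    )
    return res.x.reshape((b, c), order="F")


def hypergeom_sf_enumerate(k: int, n_query: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability by rational enumeration."""
    if k == 0:
        return 1.0
    total = comb(N, n_query)
    acc = Fraction(0)
    for j in range(k, min(n_query, K) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n_query - j), total)
    return float(acc)
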