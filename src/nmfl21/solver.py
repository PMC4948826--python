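"""Robust L2,1-norm nonnegative factorization solved by iterative reweighting.

The model approximates a nonnegative expression matrix ``X`` (genes x samples)
as ``A @ Y`` with a fixed nonnegative basis ``A`` while a scaled sparse
component ``E`` absorbs gene rows the low-rank background cannot explain:

    minimize  ||E||_{2,1} + ||Y||_{2,1}   subject to   A Y + lam * E = X.

Stacking ``U = [Y; E]`` and ``B = [A  lam*I]`` turns this into a row-sparse
min-norm problem ``min ||U||_{2,1} s.t. B U = X`` which is solved by
iteratively reweighted least squares: each sweep solves a weighted minimum
norm problem in closed form and then refreshes the row weights from the
current iterate.  Rows of ``E`` with large Euclidean norm flag characteristic
genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SolverConfig",
    "FactorizationResult",
    "l21_norm",
    "smoothed_l21",
    "build_reweighting",
    "weighted_minnorm_solve",
    "woodbury_minnorm_solve",
    "init_basis",
    "nmf_l21_fit",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative genes-by-samples matrix with identifier metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_genes, n_samples)``; every entry must be finite
        and nonnegative.
    gene_ids
        Unique row labels, one per gene.
    sample_ids
        Unique column labels, one per sample.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expression matrix must be 2-D, got ndim={values.ndim}")
        n, c = values.shape
        if n < 1 or c < 1:
            raise ValueError(f"expression matrix must be non-empty, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(f"non-finite expression value at row {bad[0]}, column {bad[1]}")
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {bad[0]!r} "
                f"(row {bad[0]}), sample column {bad[1]}"
            )
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(gene_ids) != n:
            raise ValueError(f"{len(gene_ids)} gene ids for {n} rows")
        if len(sample_ids) != c:
            raise ValueError(f"{len(sample_ids)} sample ids for {c} columns")
        if len(set(gene_ids)) != n:
            seen: set[str] = set()
            dup = next(g for g in gene_ids if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(sample_ids)) != c:
            seen = set()
            dup = next(s for s in sample_ids if s in seen or seen.add(s))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sample id: {dup!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SolverConfig:
    """Hyper-parameters and numerical settings for the factorization.

    ``lam`` trades data fit against row sparsity of the coefficient matrix,
    ``d`` is the latent rank, ``epsilon`` smooths the row-norm weights so
    collapsed rows never divide by zero.
    """

    lam: float = 0.3
    d: int = 3
    epsilon: float = 1e-8
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    clamp: bool = True
    fast_path: bool = True

    def __post_init__(self) -> None:
        if not (self.lam > 0):
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if not (self.epsilon > 0):
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if not (self.tol > 0):
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.d < 1:
            raise ValueError(f"rank d must be >= 1, got {self.d}")

    def validate_rank(self, n: int, c: int) -> None:
        """Warn when the rank violates ``d < min(n, c)``."""
        if self.d >= min(n, c):
            warnings.warn(
                f"rank d={self.d} is not smaller than min(n, c)=min({n}, {c}); "
                "the model expects d < min(n, c)",
                UserWarning,
                stacklevel=3,
            )


@dataclass
class FactorizationResult:
    """Output of :func:`nmf_l21_fit`.

    Attributes
    ----------
    A
        Fixed nonnegative basis, shape ``(n, d)``.
    Y
        Coefficient matrix, shape ``(d, c)``.
    E
        Sparse component, shape ``(n, c)``; its row norms score genes.
    U
        Stacked iterate ``[Y; E]`` of shape ``(d + n, c)``.
    objective_trace
        Smoothed L2,1 norm of ``U`` after every sweep; non-increasing when
        clamping is off.
    model_objective
        Diagnostic value of the original objective
        ``||X - A Y||_{2,1} + lam * ||Y||_{2,1}`` at the final iterate.
    """

    A: np.ndarray
    Y: np.ndarray
    E: np.ndarray
    U: np.ndarray
    lam: float
    objective_trace: list[float] = field(default_factory=list)
    model_objective: float = float("nan")
    constraint_residual: float = float("nan")
    n_iter: int = 0
    converged: bool = False

    @property
    def b(self) -> int:
        """Number of stacked rows, ``d + n``."""
        return self.U.shape[0]


# ---------------------------------------------------------------------------
# norms and weights
# ---------------------------------------------------------------------------


def l21_norm(M: np.ndarray) -> float:
    """Sum of the Euclidean norms of the rows of ``M``.

    Zero exactly when ``M`` is the zero matrix; penalizing it drives whole
    rows to zero rather than scattered entries.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("l21_norm requires finite entries")
    if M.ndim != 2:
        raise ValueError(f"l21_norm expects a matrix, got ndim={M.ndim}")
    return float(np.linalg.norm(M, axis=1).sum())


def smoothed_l21(M: np.ndarray, epsilon: float) -> float:
    """Smoothed variant ``sum_i sqrt(||row_i||^2 + epsilon)``.

    This is the quantity the reweighting sweep provably decreases; it upper
    bounds :func:`l21_norm` and converges to it as ``epsilon -> 0``.
    """
    if not (epsilon > 0):
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    sq = np.einsum("ij,ij->i", M, M)
    return float(np.sqrt(sq + epsilon).sum())


def build_reweighting(U: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-row weights ``q_i = 1 / (2 * sqrt(||row_i(U)||^2 + epsilon))``.

    ``epsilon > 0`` keeps every weight finite when a row collapses to zero.
    """
    if not (epsilon > 0):
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    U = np.asarray(U, dtype=float)
    sq = np.einsum("ij,ij->i", U, U)
    return 1.0 / (2.0 * np.sqrt(sq + epsilon))


# ---------------------------------------------------------------------------
# closed-form weighted minimum-norm solves
# ---------------------------------------------------------------------------


def weighted_minnorm_solve(B: np.ndarray, q: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve ``min Tr(U^T Q U)  s.t.  B U = X`` with ``Q = diag(q)``.

    Returns the closed form ``Q^-1 B^T (B Q^-1 B^T)^-1 X`` without ever
    materializing ``Q`` or its inverse: columns of ``B`` are rescaled by
    ``1/q`` directly.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``B Q^-1 B^T`` is singular, i.e. ``B`` has lost row rank.
    """
    B = np.asarray(B, dtype=float)
    q = np.asarray(q, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.any(q <= 0) or not np.all(np.isfinite(q)):
        raise ValueError("weights q must be strictly positive and finite")
    if B.shape[1] != q.shape[0]:
        raise ValueError(f"B has {B.shape[1]} columns but q has {q.shape[0]} weights")
    if B.shape[0] != X.shape[0]:
        raise ValueError(f"B has {B.shape[0]} rows but X has {X.shape[0]}")
    C = B / q  # C = B Q^-1, columns rescaled
    gram = C @ B.T  # B Q^-1 B^T, symmetric PSD
    try:
        S = np.linalg.solve(gram, X)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "weighted min-norm system B Q^-1 B^T is singular or ill-conditioned; "
            "B has lost row rank"
        ) from exc
    return C.T @ S


def woodbury_minnorm_solve(
    A: np.ndarray,
    lam: float,
    qY: np.ndarray,
    qE: np.ndarray,
    X: np.ndarray,
) -> np.ndarray:
    """Fast path of :func:`weighted_minnorm_solve` for ``B = [A  lam*I]``.

    Exploits ``B Q^-1 B^T = A diag(1/qY) A^T + lam^2 diag(1/qE)`` — a
    diagonal-plus-rank-d matrix — and inverts it with the matrix-inversion
    lemma, so the cost is linear in the number of genes instead of cubic.
    Algebraically identical to forming ``B`` densely.
    """
    A = np.asarray(A, dtype=float)
    qY = np.asarray(qY, dtype=float)
    qE = np.asarray(qE, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (lam > 0):
        raise ValueError(f"lam must be > 0, got {lam}")
    if np.any(qY <= 0) or np.any(qE <= 0):
        raise ValueError("weights must be strictly positive")
    n, d = A.shape
    if qY.shape[0] != d or qE.shape[0] != n or X.shape[0] != n:
        raise ValueError(
            f"shape mismatch: A {A.shape}, qY {qY.shape}, qE {qE.shape}, X {X.shape}"
        )
    dinv = qE / (lam * lam)  # inverse of the diagonal block, length n
    Z = A * dinv[:, None]  # n x d
    core = np.diag(qY) + A.T @ Z  # d x d
    try:
        # S = (B Q^-1 B^T)^-1 X via the inversion lemma
        S = dinv[:, None] * X - Z @ np.linalg.solve(core, Z.T @ X)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "weighted min-norm system B Q^-1 B^T is singular or ill-conditioned"
        ) from exc
    Y = (A.T @ S) / qY[:, None]
    E = (lam / qE)[:, None] * S
    return np.vstack([Y, E])


# ---------------------------------------------------------------------------
# main iteration
# ---------------------------------------------------------------------------


def init_basis(n: int, d: int, seed: int) -> np.ndarray:
    """Seeded nonnegative basis draw, uniform on [0, 1)."""
    return np.random.default_rng(seed).uniform(0.0, 1.0, size=(n, d))


def nmf_l21_fit(X: ExpressionMatrix, config: SolverConfig) -> FactorizationResult:
    """Fit the robust factorization by iteratively reweighted least squares.

    The basis ``A`` is drawn once from the seeded generator and held fixed.
    Each sweep solves the weighted minimum-norm problem in closed form,
    optionally clamps negative entries of ``U`` to zero, and refreshes the
    row weights.  Iteration stops when the relative Frobenius change of
    ``U`` drops below ``config.tol`` or after ``config.max_iter`` sweeps.
    """
    if not isinstance(X, ExpressionMatrix):
        X = ExpressionMatrix(
            np.asarray(X, dtype=float),
            tuple(f"g{i}" for i in range(np.asarray(X).shape[0])),
            tuple(f"s{j}" for j in range(np.asarray(X).shape[1])),
        )
    n, c = X.n_genes, X.n_samples
    config.validate_rank(n, c)
    d = config.d
    lam = config.lam

    A = init_basis(n, d, config.seed)
    q = np.ones(d + n)  # Q starts as the identity
    B = None if config.fast_path else np.hstack([A, lam * np.eye(n)])

    U_prev = np.zeros((d + n, c))
    trace: list[float] = []
    converged = False
    n_iter = 0
    for t in range(config.max_iter):
        if config.fast_path:
            U = woodbury_minnorm_solve(A, lam, q[:d], q[d:], X.values)
        else:
            U = weighted_minnorm_solve(B, q, X.values)
        if config.clamp:
            np.maximum(U, 0.0, out=U)
        q = build_reweighting(U, config.epsilon)
        obj = smoothed_l21(U, config.epsilon)
        trace.append(obj)
        n_iter = t + 1
        delta = np.linalg.norm(U - U_prev) / max(1.0, np.linalg.norm(U_prev))
        if logger.isEnabledFor(logging.DEBUG):
            resid = np.linalg.norm(A @ U[:d] + lam * U[d:] - X.values)
            logger.debug(
                "iter %d: objective=%.6g, delta=%.3g, residual=%.3g", n_iter, obj, delta, resid
            )
        U_prev = U
        if delta < config.tol:
            converged = True
            break

    Y, E = U_prev[:d], U_prev[d:]
    residual = X.values - A @ Y
    result = FactorizationResult(
        A=A,
        Y=Y,
        E=E,
        U=U_prev,
        lam=lam,
        objective_trace=trace,
        model_objective=l21_norm(residual) + lam * l21_norm(Y),
        constraint_residual=float(np.linalg.norm(residual - lam * E)),
        n_iter=n_iter,
        converged=converged,
    )
    return result
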