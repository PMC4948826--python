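"""Gene scoring, ranking, top-k selection and the lambda grid search."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .solver import ExpressionMatrix, FactorizationResult, SolverConfig, nmf_l21_fit

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGenes",
    "score_genes",
    "select_top_k",
    "tune_lambda",
    "default_lambda_grid",
    "LAMBDA_FLOOR",
    "PLANT_SELECTION_SIZE",
    "TUMOR_SELECTION_SIZE",
]

#: Selection size used in the plant stress protocol.
PLANT_SELECTION_SIZE = 500
#: Selection size used in the tumor protocol.
TUMOR_SELECTION_SIZE = 100

#: Replacement for the degenerate 0 point of the tuning grid (lam must be > 0).
LAMBDA_FLOOR = 1e-3

SCORING_SOURCES = ("sparse_component_rows", "basis_rows")


@dataclass(frozen=True)
class RankedGenes:
    """Genes ordered by non-increasing score.

    ``entries`` holds ``(gene_id, score, rank)`` triples with ranks 1..n;
    ties are broken deterministically by gene-id order.
    """

    entries: tuple[tuple[str, float, int], ...]
    scoring_source: str

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("entries must be sorted by non-increasing score")
        if [r for _, _, r in self.entries] != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be 1..n in order")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    @property
    def scores(self) -> list[float]:
        return [s for _, s, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_id", "score", "rank"])


def score_genes(
    result: FactorizationResult,
    gene_ids: Sequence[str],
    source: str = "sparse_component_rows",
) -> RankedGenes:
    """Score each gene by the Euclidean norm of its row in E (default) or A.

    Rows of the sparse component that the low-rank background cannot explain
    get large norms; those genes rank first.  ``basis_rows`` scores by rows
    of the fixed basis instead and exists only for fidelity experiments.
    """
    if source not in SCORING_SOURCES:
        raise ValueError(f"unknown scoring source {source!r}; expected one of {SCORING_SOURCES}")
    M = result.E if source == "sparse_component_rows" else result.A
    if M.shape[0] != len(gene_ids):
        raise ValueError(f"{len(gene_ids)} gene ids for a {M.shape[0]}-row score matrix")
    scores = np.linalg.norm(M, axis=1)
    # sort by descending score, ties by gene id
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], str(gene_ids[i])))
    entries = tuple(
        (str(gene_ids[i]), float(scores[i]), rank) for rank, i in enumerate(order, start=1)
    )
    return RankedGenes(entries=entries, scoring_source=source)


def select_top_k(ranked: RankedGenes, k: int) -> list[str]:
    """First ``k`` gene ids in rank order."""
    n = len(ranked.entries)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return ranked.gene_ids[:k]


def default_lambda_grid() -> list[float]:
    """The 11-point tuning grid 0, 0.1, ..., 1.0 with the 0 point floored.

    The factorization is undefined at lam = 0 (the constraint block loses
    row rank), so the grid's zero is replaced by ``LAMBDA_FLOOR``.
    """
    return [LAMBDA_FLOOR] + [round(0.1 * i, 1) for i in range(1, 11)]


def tune_lambda(
    X: ExpressionMatrix,
    grid: Sequence[float] | None,
    k: int,
    criterion: Callable[[list[str]], float],
    config: SolverConfig,
) -> tuple[float, pd.DataFrame]:
    """Grid search over lambda, judged by a user-supplied gene-list criterion.

    Fits once per grid value with a shared seed, selects the top-``k`` genes
    each time and evaluates ``criterion`` (larger is better, e.g. an
    enrichment ``-log10 p``).  Returns the best lambda (ties go to the
    smallest) and a per-lambda score table.
    """
    if grid is None:
        grid = default_lambda_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    floored = [LAMBDA_FLOOR if g == 0 else g for g in grid]
    if floored != grid:
        logger.info("lambda grid point 0 floored to %g", LAMBDA_FLOOR)

    rows = []
    for lam in floored:
        cfg = SolverConfig(
            lam=lam,
            d=config.d,
            epsilon=config.epsilon,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=config.seed,
            clamp=config.clamp,
            fast_path=config.fast_path,
        )
        result = nmf_l21_fit(X, cfg)
        ranked = score_genes(result, X.gene_ids)
        selected = select_top_k(ranked, k)
        score = float(criterion(selected))
        if not np.isfinite(score):
            raise ValueError(f"criterion returned non-finite score {score} at lambda={lam}")
        rows.append({"lam": lam, "score": score, "n_iter": result.n_iter})
    table = pd.DataFrame(rows)
    # max score; ties resolved toward the smallest lambda (table is in grid order)
    best_score = table["score"].max()
    best_lambda = float(table.loc[table["score"] == best_score, "lam"].min())
    return best_lambda, table
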