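"""Synthetic expression data with planted characteristic genes.

Generates a nonnegative low-rank background plus a small set of
high-residual outlier rows plus truncated Gaussian noise, so the solver and
selection modules can be validated against known ground truth without any
external dataset.  The basis used for the background is drawn exactly like
the solver's seeded basis, so a fit with the same seed sees a background it
can represent perfectly ("matched A").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import AnnotationCollection
from .solver import ExpressionMatrix, init_basis

__all__ = ["SyntheticTruth", "generate_synthetic", "make_toy_annotations"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic instance."""

    outlier_rows: frozenset[int]
    A_true: np.ndarray
    Y_true: np.ndarray
    noise_sd: float
    outlier_magnitude: float

    def outlier_gene_ids(self, gene_ids: tuple[str, ...]) -> set[str]:
        return {gene_ids[i] for i in self.outlier_rows}


def generate_synthetic(
    n: int = 200,
    c: int = 8,
    d: int = 3,
    k_outliers: int = 10,
    outlier_magnitude: float = 5.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Build ``X = A_true @ Y_true + outliers + noise`` clipped at zero.

    Exactly ``k_outliers`` rows get an additive nonnegative bump whose row
    norm is ``outlier_magnitude`` times the median background row norm;
    Gaussian noise has sd ``noise_sd`` times the median background entry.
    Everything is reproducible from ``seed``, and ``A_true`` equals the
    solver basis drawn with the same seed.
    """
    if n < 1 or c < 1:
        raise ValueError(f"need n >= 1 and c >= 1, got n={n}, c={c}")
    if not (0 <= k_outliers < n):
        raise ValueError(f"need 0 <= k_outliers < n, got k_outliers={k_outliers}, n={n}")
    if not (d < min(n, c)):
        raise ValueError(f"need d < min(n, c), got d={d}, n={n}, c={c}")

    rng = np.random.default_rng(seed)
    # first draw matches init_basis(n, d, seed) so the solver's A is A_true
    A_true = rng.uniform(0.0, 1.0, size=(n, d))
    assert np.array_equal(A_true, init_basis(n, d, seed))
    Y_true = rng.uniform(0.0, 1.0, size=(d, c))
    background = A_true @ Y_true

    X = background.copy()
    outlier_rows = frozenset(int(i) for i in rng.choice(n, size=k_outliers, replace=False))
    if k_outliers:
        median_row_norm = float(np.median(np.linalg.norm(background, axis=1)))
        for i in sorted(outlier_rows):
            bump = rng.uniform(0.0, 1.0, size=c)
            bump *= outlier_magnitude * median_row_norm / np.linalg.norm(bump)
            X[i] += bump
    if noise_sd > 0:
        scale = noise_sd * float(np.median(background))
        X += rng.normal(0.0, scale, size=(n, c))
    np.clip(X, 0.0, None, out=X)

    matrix = ExpressionMatrix(
        values=X,
        gene_ids=tuple(f"gene{i:05d}" for i in range(n)),
        sample_ids=tuple(f"sample{j}" for j in range(c)),
    )
    truth = SyntheticTruth(
        outlier_rows=outlier_rows,
        A_true=A_true,
        Y_true=Y_true,
        noise_sd=noise_sd,
        outlier_magnitude=outlier_magnitude,
    )
    return matrix, truth


def make_toy_annotations(
    matrix: ExpressionMatrix,
    truth: SyntheticTruth,
    n_terms: int = 5,
    term_size: int = 20,
    seed: int = 0,
) -> AnnotationCollection:
    """Toy gene-set collection for enrichment tests.

    The first term contains every planted outlier gene padded with random
    background genes (strongly enriched in any selection that recovers the
    planted rows); the remaining terms are random draws from the background.
    """
    rng = np.random.default_rng(seed)
    gene_ids = matrix.gene_ids
    outliers = sorted(truth.outlier_gene_ids(gene_ids))
    non_outliers = [g for g in gene_ids if g not in set(outliers)]
    gene_sets: dict[str, set[str]] = {}
    pad = max(0, term_size - len(outliers))
    gene_sets["TERM_PLANTED"] = set(outliers) | set(
        rng.choice(non_outliers, size=min(pad, len(non_outliers)), replace=False)
    )
    for t in range(1, n_terms):
        size = min(term_size, len(non_outliers))
        gene_sets[f"TERM_RANDOM_{t}"] = set(rng.choice(non_outliers, size=size, replace=False))
    return AnnotationCollection.from_gene_sets(gene_sets, background=set(gene_ids))
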