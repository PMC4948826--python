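"""Readers, writers, configuration files and run manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import AnnotationCollection, EnrichmentResult
from .selection import RankedGenes
from .solver import ExpressionMatrix, SolverConfig

__all__ = [
    "read_expression",
    "write_expression",
    "write_ranking",
    "read_ranking",
    "read_gmt",
    "write_gmt",
    "write_enrichment",
    "load_config",
    "RunManifest",
]

RANKING_COLUMNS = ["gene_id", "score", "rank"]
ENRICHMENT_COLUMNS = ["term_id", "term_name", "k", "n_query", "K", "N", "p", "p_bonferroni", "genes"]


def _resolve_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    clamp_negative: bool = False,
) -> ExpressionMatrix:
    """Read a labelled expression table (TSV by default, CSV by extension).

    First column holds gene ids, first row holds sample ids.  Negative cells
    raise an error naming the gene and sample unless ``clamp_negative`` is
    set, in which case they are clipped to zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    sep = _resolve_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found (delimiter {sep!r}?)")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}")
    if (values < 0).any():
        if clamp_negative:
            values = np.clip(values, 0.0, None)
        else:
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"{path}: negative value at gene {df.index[i]!r}, sample {df.columns[j]!r} "
                "(pass clamp_negative to clip to zero)"
            )
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _resolve_delimiter(path, delimiter)
    df = pd.DataFrame(matrix.values, index=list(matrix.gene_ids), columns=list(matrix.sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def write_ranking(ranked: RankedGenes, path: str | Path, k: int | None = None) -> None:
    """Write the (optionally truncated) ranking as TSV with fixed columns."""
    df = ranked.to_frame()
    if k is not None:
        df = df.head(k)
    df.to_csv(path, sep="\t", index=False, columns=RANKING_COLUMNS)


def read_ranking(path: str | Path) -> RankedGenes:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RANKING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ranking columns {missing}")
    entries = tuple(
        (str(r.gene_id), float(r.score), int(r.rank)) for r in df.itertuples(index=False)
    )
    return RankedGenes(entries=entries, scoring_source="sparse_component_rows")


def read_gmt(path: str | Path, background: set[str] | None = None) -> AnnotationCollection:
    """Read a GMT file: one term per line, ``term<TAB>description<TAB>genes...``.

    The background defaults to the union of all annotated genes.
    """
    path = Path(path)
    terms: list[tuple[str, str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields "
                    f"(term, description, genes), got {len(fields)}"
                )
            term_id, description, *genes = fields
            genes = [g for g in genes if g]
            terms.append((term_id, description, frozenset(genes)))
    if background is None:
        background = set()
        for _, _, genes in terms:
            background |= genes
    return AnnotationCollection(terms=tuple(terms), background=frozenset(background))


def write_gmt(annotations: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, term_name, genes in annotations.terms:
            fh.write("\t".join([term_id, term_name, *sorted(genes)]) + "\n")


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV with a stable column order."""
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "n_query": r.n_query,
            "K": r.K,
            "N": r.N,
            "p": r.p_value,
            "p_bonferroni": r.p_bonferroni,
            "genes": ",".join(r.overlapping_gene_ids),
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS).to_csv(path, sep="\t", index=False)


_CONFIG_KEYS = {"lam", "d", "epsilon", "max_iter", "tol", "seed", "clamp", "fast_path"}


def load_config(path: str | Path, **overrides) -> SolverConfig:
    """Load a YAML/flat key-value solver configuration; overrides win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return SolverConfig(**data)


def _tool_version() -> str:
    try:
        return version("nmfl21")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    k: int | None = None
    seed: int | None = None
    tool_version: str = field(default_factory=_tool_version)
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    @classmethod
    def for_run(
        cls,
        command: str,
        inputs: dict,
        outputs: dict,
        config: SolverConfig | None = None,
        k: int | None = None,
        seed: int | None = None,
    ) -> "RunManifest":
        return cls(
            command=command,
            inputs={k_: str(v) for k_, v in inputs.items()},
            outputs={k_: str(v) for k_, v in outputs.items()},
            config=asdict(config) if config is not None else {},
            k=k,
            seed=seed,
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
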