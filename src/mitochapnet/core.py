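"""Shared data containers and plain-text I/O.

All on-disk formats are TSV or JSON.  Floating point values are written with
17 significant digits so round-trips are bit-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"


class MitochapnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MitochapnetError):
    """An invalid configuration value or violated config invariant."""


class DataError(MitochapnetError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """One cohort's genes x samples non-negative expression values."""

    cohort_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise DataError("expression values must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise DataError(f"gene {gene_id!r} not present in cohort {self.cohort_id}") from None

    def subset(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Rows for the requested genes, in the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"genes missing from cohort {self.cohort_id}: {missing[:5]}")
        return self.values[[index[g] for g in gene_ids]]


@dataclass
class WeightMatrix:
    """A chaperone x client matrix of non-negative interaction weights."""

    chaperone_ids: list[str]
    client_ids: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.chaperone_ids), len(self.client_ids)):
            raise DataError(
                f"weight matrix shape {self.w.shape} does not match panels "
                f"({len(self.chaperone_ids)}, {len(self.client_ids)})"
            )


def read_expression_tsv(path: str | Path, cohort_id: str | None = None,
                        dedupe_first: bool = False) -> ExpressionMatrix:
    """Read an expression TSV: first column gene ID, remaining columns samples.

    Duplicate gene IDs are a hard error unless ``dedupe_first`` keeps the
    first occurrence of each.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        if not dedupe_first:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene IDs in {path.name}: {dups[:5]} "
                            "(pass dedupe_first to keep first occurrence)")
        df = df[~df.index.duplicated(keep="first")]
    return ExpressionMatrix(
        cohort_id=cohort_id or path.stem,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_panel(path: str | Path) -> list[str]:
    """Read a one-gene-per-line panel file; blank lines and '#' comments skipped."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if len(set(genes)) != len(genes):
        raise DataError(f"duplicate genes in panel file {path}")
    return genes


def write_panel(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_matrix_wide(matrix: np.ndarray, row_ids: Sequence[str],
                      col_ids: Sequence[str], path: str | Path,
                      index_name: str = "gene") -> None:
    df = pd.DataFrame(matrix, index=list(row_ids), columns=list(col_ids))
    df.index.name = index_name
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix_wide(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def fmt17(x: float) -> str:
    return FLOAT_FMT % x
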