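"""Per-cohort Spearman screening between a chaperone panel and a client panel.

Spearman r is the Pearson correlation of average ranks; two-sided p-values
come from the large-sample t approximation with n - 2 degrees of freedom.
Pairs failing the Bonferroni-corrected significance gate, or with negative r,
are zeroed: the surviving weights form a non-negative chaperone x client
matrix ready for pan-cancer aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import FLOAT_FMT, ConfigurationError, DataError, ExpressionMatrix


@dataclass
class CorrelationResult:
    cohort_id: str
    chaperone_ids: list[str]
    client_ids: list[str]
    r: np.ndarray  # chaperone x client Spearman coefficients
    p: np.ndarray  # two-sided p-values
    n_samples: int
    self_pair: np.ndarray = field(default=None)  # bool mask: gene paired with itself
    constant_flags: np.ndarray = field(default=None)  # bool mask: zero rank variance

    def __post_init__(self) -> None:
        if self.r.shape != self.p.shape:
            raise DataError("r and p must have identical shape")
        if self.self_pair is None:
            self.self_pair = np.zeros_like(self.r, dtype=bool)
        if self.constant_flags is None:
            self.constant_flags = np.zeros_like(self.r, dtype=bool)


@dataclass
class FilteredCorrelationMatrix:
    cohort_id: str
    chaperone_ids: list[str]
    client_ids: list[str]
    w: np.ndarray  # weights in [0, 1]; zero where filtered out
    alpha_corrected: float


def spearman_panel(expr: ExpressionMatrix, chaperones: list[str],
                   clients: list[str], permissive: bool = False,
                   ) -> CorrelationResult:
    """All chaperone x client Spearman correlations in one cohort.

    Missing panel genes are a hard error unless ``permissive`` drops them
    with a warning.  Constant genes (zero rank variance) get r = 0, p = 1 and
    are flagged; self-pairs (a gene appearing in both panels, paired with
    itself) get r = 1, p = 0 and are flagged for downstream exclusion.
    """
    if expr.n_samples < 3:
        raise DataError(f"cohort {expr.cohort_id} has {expr.n_samples} samples; "
                        ">= 3 required for correlation")
    present = set(expr.gene_ids)
    if permissive:
        missing = [g for g in list(chaperones) + list(clients) if g not in present]
        if missing:
            warnings.warn(f"dropping {len(missing)} panel genes absent from "
                          f"cohort {expr.cohort_id}: {missing[:5]}", stacklevel=2)
        chaperones = [g for g in chaperones if g in present]
        clients = [g for g in clients if g in present]
    chap_vals = expr.subset(chaperones)
    cli_vals = expr.subset(clients)
    n = expr.n_samples

    chap_ranks = stats.rankdata(chap_vals, axis=1)
    cli_ranks = stats.rankdata(cli_vals, axis=1)

    def standardize(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered ** 2).sum(axis=1))
        constant = norm == 0
        norm[constant] = 1.0
        return centered / norm[:, None], constant

    zc, chap_const = standardize(chap_ranks)
    zl, cli_const = standardize(cli_ranks)
    r = np.clip(zc @ zl.T, -1.0, 1.0)

    constant = chap_const[:, None] | cli_const[None, :]
    r[constant] = 0.0

    # t approximation with n-2 df; |r| = 1 maps to p = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p[constant] = 1.0

    self_pair = np.array([[c == l for l in clients] for c in chaperones], dtype=bool)
    r[self_pair] = 1.0
    p[self_pair] = 0.0

    return CorrelationResult(cohort_id=expr.cohort_id, chaperone_ids=list(chaperones),
                             client_ids=list(clients), r=r, p=p, n_samples=n,
                             self_pair=self_pair, constant_flags=constant)


def bonferroni_alpha(alpha: float, n_chaperones: int, n_clients: int) -> float:
    """Per-test threshold alpha / (n_chaperones * n_clients)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n_chaperones < 1 or n_clients < 1:
        raise ConfigurationError("panel sizes must be >= 1")
    return alpha / (n_chaperones * n_clients)


def filter_correlations(res: CorrelationResult, alpha_corrected: float,
                        ) -> FilteredCorrelationMatrix:
    """Keep r where p < alpha_corrected and r > 0; zero everything else.

    Self-pairs are always zeroed: a gene's correlation with itself carries no
    interaction information and is excluded from downstream networks.
    """
    if not 0.0 < alpha_corrected < 1.0:
        raise ConfigurationError(f"alpha_corrected must be in (0, 1), got {alpha_corrected}")
    keep = (res.p < alpha_corrected) & (res.r > 0) & ~res.self_pair
    w = np.where(keep, res.r, 0.0)
    return FilteredCorrelationMatrix(cohort_id=res.cohort_id,
                                     chaperone_ids=list(res.chaperone_ids),
                                     client_ids=list(res.client_ids),
                                     w=w, alpha_corrected=alpha_corrected)


def write_correlation_long(res: CorrelationResult,
                           filtered: FilteredCorrelationMatrix | None,
                           path: str | Path) -> None:
    """Long-format TSV: cohort, chaperone, client, r, p[, w]."""
    rows = []
    for i, c in enumerate(res.chaperone_ids):
        for j, l in enumerate(res.client_ids):
            row = {"cohort": res.cohort_id, "chaperone": c, "client": l,
                   "r": res.r[i, j], "p": res.p[i, j]}
            if filtered is not None:
                row["w"] = filtered.w[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
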