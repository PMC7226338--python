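"""Median aggregation of per-cohort filtered correlation matrices.

Zeros (non-significant or negative cells) participate in the median, so with
an odd cohort count a pan-cancer weight is positive exactly when the pair is
significantly positively correlated in a strict majority of cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FLOAT_FMT, DataError, write_json
from .coexpression import FilteredCorrelationMatrix


@dataclass
class PanCancerMatrix:
    chaperone_ids: list[str]
    client_ids: list[str]
    w_med: np.ndarray  # chaperone x client median weights in [0, 1]
    n_cohorts: int
    cohort_ids: list[str]

    @property
    def w(self) -> np.ndarray:  # generic weight-matrix access
        return self.w_med


@dataclass
class DegreeSummary:
    per_client_chaperone_count: dict[str, int]
    per_chaperone_client_count: dict[str, int]
    median_chaperones_per_client: float
    n_interacting_proteins: int
    n_interactions: int


def aggregate_median(filtered: list[FilteredCorrelationMatrix]) -> PanCancerMatrix:
    """Cellwise median of per-cohort weights, zeros included."""
    if not filtered:
        raise DataError("aggregate_median requires at least one cohort")
    ref = filtered[0]
    for f in filtered[1:]:
        for axis, ids, ref_ids in (("chaperone", f.chaperone_ids, ref.chaperone_ids),
                                   ("client", f.client_ids, ref.client_ids)):
            if ids != ref_ids:
                bad = next((a, b) for a, b in zip(ids + ["<short>"], ref_ids + ["<short>"])
                           if a != b)
                raise DataError(
                    f"{axis} ordering mismatch between cohorts {f.cohort_id} and "
                    f"{ref.cohort_id}: first discordant gene {bad[0]!r} vs {bad[1]!r}")
    stack = np.stack([f.w for f in filtered], axis=0)
    return PanCancerMatrix(chaperone_ids=list(ref.chaperone_ids),
                           client_ids=list(ref.client_ids),
                           w_med=np.median(stack, axis=0),
                           n_cohorts=len(filtered),
                           cohort_ids=[f.cohort_id for f in filtered])


def degree_summary(pc: PanCancerMatrix) -> DegreeSummary:
    """Counts of strictly positive cells per chaperone and per client."""
    positive = pc.w_med > 0
    per_chap = positive.sum(axis=1)
    per_client = positive.sum(axis=0)
    interacting = per_client[per_client >= 1]
    return DegreeSummary(
        per_client_chaperone_count={g: int(c) for g, c in zip(pc.client_ids, per_client)},
        per_chaperone_client_count={g: int(c) for g, c in zip(pc.chaperone_ids, per_chap)},
        median_chaperones_per_client=float(np.median(interacting)) if interacting.size else 0.0,
        n_interacting_proteins=int((per_client >= 1).sum()),
        n_interactions=int(positive.sum()),
    )


def write_pancancer(pc: PanCancerMatrix, wide_path: str | Path,
                    long_path: str | Path | None = None) -> None:
    df = pd.DataFrame(pc.w_med, index=pc.chaperone_ids, columns=pc.client_ids)
    df.index.name = "chaperone"
    df.to_csv(wide_path, sep="\t", float_format=FLOAT_FMT)
    if long_path is not None:
        long = df.stack().rename_axis(["chaperone", "client"]).reset_index(name="w_med")
        long.to_csv(long_path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_degree_summary(summary: DegreeSummary, path: str | Path) -> None:
    write_json({
        "per_client_chaperone_count": summary.per_client_chaperone_count,
        "per_chaperone_client_count": summary.per_chaperone_client_count,
        "median_chaperones_per_client": summary.median_chaperones_per_client,
        "n_interacting_proteins": summary.n_interacting_proteins,
        "n_interactions": summary.n_interactions,
    }, path)
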