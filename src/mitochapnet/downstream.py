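"""Hierarchical clustering of interaction profiles and pairwise client-set
partitions (shared / exclusive / absent clients for a chaperone pair)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import DataError, write_json
from .pancancer import PanCancerMatrix

AXES = ("chaperone_by_chaperone", "chaperone_by_client")
LINKAGES = ("average", "single", "complete")


@dataclass
class Dendrogram:
    items: list[str]  # leaf labels in input (sorted) order
    linkage: np.ndarray  # scipy linkage matrix, heights in distance units
    leaf_order: list[str]
    constant_items: list[str]  # zero-variance profiles (distance 1 to all)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ClientSetPartition:
    chap_a: str
    chap_b: str
    both: set[str]
    only_a: set[str]
    only_b: set[str]
    neither: set[str]


def cluster_profiles(matrix: np.ndarray, item_ids: list[str],
                     axis: str = "chaperone_by_chaperone",
                     linkage_method: str = "average",
                     metric: str = "one_minus_r") -> Dendrogram:
    """Average-linkage (by default) agglomeration of interaction profiles.

    For ``chaperone_by_chaperone``, ``matrix`` is the square chaperone x
    chaperone weight matrix and distance is 1 - w.  For
    ``chaperone_by_client`` the rows are chaperone-by-client weight profiles
    and distance is 1 - Pearson r between rows (or Euclidean with
    ``metric='euclidean'``).  Items are sorted by label before clustering so
    the result is invariant under input reordering; constant (zero-variance)
    profiles get distance 1 to every other item and are flagged.
    """
    if axis not in AXES:
        raise DataError(f"axis must be one of {AXES}")
    if linkage_method not in LINKAGES:
        raise DataError(f"linkage must be one of {LINKAGES}")
    matrix = np.asarray(matrix, dtype=float)
    if len(item_ids) < 2:
        raise DataError("need >= 2 items to cluster")
    order = np.argsort(item_ids)
    items = [item_ids[i] for i in order]
    constant: list[str] = []

    if axis == "chaperone_by_chaperone":
        if matrix.shape[0] != matrix.shape[1] or matrix.shape[0] != len(item_ids):
            raise DataError("chaperone_by_chaperone requires a square matrix "
                            "matching item_ids")
        m = matrix[np.ix_(order, order)]
        d = 1.0 - m
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0  # guard symmetry against serialization round-off
    else:
        rows = matrix[order]
        if metric == "euclidean":
            diff = rows[:, None, :] - rows[None, :, :]
            d = np.sqrt((diff ** 2).sum(axis=2))
        else:
            sd = rows.std(axis=1)
            const_mask = sd == 0
            constant = [items[i] for i in np.nonzero(const_mask)[0]]
            if constant:
                warnings.warn(f"constant profiles (distance set to 1): {constant}",
                              stacklevel=2)
            safe = rows.copy()
            safe[const_mask] = np.arange(rows.shape[1])  # placeholder, overwritten
            r = np.corrcoef(safe)
            d = 1.0 - r
            d[const_mask, :] = 1.0
            d[:, const_mask] = 1.0
        np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    leaves = hierarchy.leaves_list(link)
    return Dendrogram(items=items, linkage=link,
                      leaf_order=[items[i] for i in leaves],
                      constant_items=constant)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths derived from merge heights."""
    n = len(dend.items)
    heights = {i: 0.0 for i in range(n)}

    def render(idx: int) -> str:
        if idx < n:
            return dend.items[idx]
        a, b, h, _ = dend.linkage[idx - n]
        a, b = int(a), int(b)
        return (f"({render(a)}:{h - heights[a]:.17g},"
                f"{render(b)}:{h - heights[b]:.17g})")

    for k, row in enumerate(dend.linkage):
        heights[n + k] = float(row[2])
    return render(n + len(dend.linkage) - 1) + ";"


def write_dendrogram(dend: Dendrogram, newick_path: str | Path,
                     merges_path: str | Path | None = None) -> None:
    Path(newick_path).write_text(dendrogram_to_newick(dend) + "\n")
    if merges_path is not None:
        with open(merges_path, "w") as fh:
            fh.write("left\tright\theight\tn_items\n")
            for a, b, h, c in dend.linkage:
                fh.write(f"{int(a)}\t{int(b)}\t{h:.17g}\t{int(c)}\n")


def client_set_partition(pc: PanCancerMatrix, chap_a: str, chap_b: str,
                         ) -> ClientSetPartition:
    """Split the client panel by strictly positive pan-cancer weight with each
    of two chaperones: both / only A / only B / neither.  Self-pairs (either
    chaperone appearing in the client panel) are removed from consideration."""
    for chap in (chap_a, chap_b):
        if chap not in pc.chaperone_ids:
            raise DataError(f"unknown chaperone {chap!r}")
    ia, ib = pc.chaperone_ids.index(chap_a), pc.chaperone_ids.index(chap_b)
    with_a = pc.w_med[ia] > 0
    with_b = pc.w_med[ib] > 0
    both, only_a, only_b, neither = set(), set(), set(), set()
    for j, client in enumerate(pc.client_ids):
        if client in (chap_a, chap_b):
            continue
        if with_a[j] and with_b[j]:
            both.add(client)
        elif with_a[j]:
            only_a.add(client)
        elif with_b[j]:
            only_b.add(client)
        else:
            neither.add(client)
    return ClientSetPartition(chap_a=chap_a, chap_b=chap_b, both=both,
                              only_a=only_a, only_b=only_b, neither=neither)


def write_client_set_partition(part: ClientSetPartition, json_path: str | Path,
                               tsv_path: str | Path | None = None) -> None:
    sets = {"both": part.both, "only_a": part.only_a,
            "only_b": part.only_b, "neither": part.neither}
    write_json({
        "chap_a": part.chap_a,
        "chap_b": part.chap_b,
        "counts": {k: len(v) for k, v in sets.items()},
        "sets": {k: sorted(v) for k, v in sets.items()},
    }, json_path)
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("set\tcount\n")
            for k, v in sets.items():
                fh.write(f"{k}\t{len(v)}\n")
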