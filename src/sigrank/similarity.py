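"""Signature comparison: RMSD between interaction signatures and ranked
neighbour lists.

Two compounds with similar compound-proteome interaction signatures are
inferred to behave similarly; the similarity metric is the root mean
squared deviation over the full protein panel, with no per-protein
weighting and no special-casing of protein classes.  Smaller RMSD means
more similar.  Ties are broken by case-folded identifier order so that
rankings are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, squareform, pdist

from .data_model import InteractionMatrix, ValidationError, normalize_id

__all__ = ["NeighborList", "rmsd", "rank_neighbors", "neighbor_order_matrix"]


@dataclass(frozen=True)
class NeighborList:
    """All other compounds ranked by ascending RMSD to a query compound."""

    query_id: str
    #: sequence of (compound_id, rmsd, rank); rank is 1-based.
    neighbors: tuple[tuple[str, float, int], ...]

    def top(self, x: int) -> tuple[tuple[str, float, int], ...]:
        return self.neighbors[:x]

    def ids(self, x: int | None = None) -> list[str]:
        sel = self.neighbors if x is None else self.neighbors[:x]
        return [n[0] for n in sel]


def rmsd(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """Root mean squared deviation between two equal-length signatures."""
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValidationError("signatures must be 1-D vectors")
    if a.shape != b.shape:
        raise ValidationError(
            f"signature length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 1:
        raise ValidationError("signatures must have length >= 1")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("signatures contain non-finite values")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _rmsd_matrix(matrix: InteractionMatrix) -> np.ndarray:
    """All-pairs RMSD (euclidean distance scaled by 1/sqrt(n_proteins))."""
    d = squareform(pdist(matrix.scores, metric="euclidean"))
    return d / np.sqrt(matrix.n_proteins)


def neighbor_order_matrix(matrix: InteractionMatrix) -> np.ndarray:
    """Row i holds the indices of all other compounds sorted by ascending
    RMSD to compound i, ties broken by identifier order.

    Shape (n, n-1).  This is the shared work behind every TopX list; it is
    computed once per matrix and reused by the consensus stage.
    """
    n = matrix.n_compounds
    dist = _rmsd_matrix(matrix)
    # Identifier tie-break: position of each compound in sorted-id order.
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(np.asarray(matrix.compound_ids))] = np.arange(n)
    order = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        row = dist[i]
        full = np.lexsort((id_rank, row))
        order[i] = full[full != i]
    return order


def rank_neighbors(query_id: str, matrix: InteractionMatrix) -> NeighborList:
    """Rank every other compound by ascending RMSD to the query.

    The query compound itself is excluded (its distance-0 self-match is
    uninformative).
    """
    qi = matrix.row_index(query_id)
    dist = (
        cdist(matrix.scores[qi : qi + 1], matrix.scores, metric="euclidean")[0]
        / np.sqrt(matrix.n_proteins)
    )
    n = matrix.n_compounds
    id_rank = np.empty(n, dtype=int)
    id_rank[np.argsort(np.asarray(matrix.compound_ids))] = np.arange(n)
    full = np.lexsort((id_rank, dist))
    others = full[full != qi]
    neighbors = tuple(
        (matrix.compound_ids[j], float(dist[j]), r + 1)
        for r, j in enumerate(others)
    )
    return NeighborList(query_id=normalize_id(query_id), neighbors=neighbors)
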