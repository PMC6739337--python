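"""Per-indication TopX prediction lists and consensus-count statistics.

For an indication with k approved drugs, every approved drug contributes
its TopX most signature-similar compounds.  A candidate's *consensus
count* is the number of approved drugs whose TopX list contains it (at
most k), and its *percent occurrence* is the consensus count over k,
times 100.  Candidates that are themselves approved for the indication
are retained but flagged, preserving the "a compound may be predicted at
most k times" accounting used in benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AnalysisConfig,
    IndicationRecord,
    InteractionMatrix,
    ValidationError,
)
from .similarity import neighbor_order_matrix

__all__ = [
    "PredictionEntry",
    "ConsensusTable",
    "predict_indication",
    "build_consensus_table",
]

logger = logging.getLogger(__name__)

ENTRY_COLUMNS = (
    "indication_id",
    "compound_id",
    "topx",
    "consensus_count",
    "percent_occurrence",
    "already_approved",
)


@dataclass(frozen=True)
class PredictionEntry:
    indication_id: str
    compound_id: str
    topx: int
    consensus_count: int
    percent_occurrence: float
    already_approved: bool


@dataclass
class ConsensusTable:
    """Collection of prediction entries keyed by (indication, compound, topx)."""

    entries: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ENTRY_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValidationError(f"consensus table missing columns: {missing}")
        dup = self.entries.duplicated(
            subset=["indication_id", "compound_id", "topx"]
        )
        if dup.any():
            row = self.entries[dup].iloc[0]
            raise ValidationError(
                "duplicate consensus entry for "
                f"({row.indication_id}, {row.compound_id}, Top{row.topx})"
            )
        self.entries = self.entries.reset_index(drop=True)

    @classmethod
    def from_entries(
        cls, entries: Iterable[PredictionEntry], provenance: dict | None = None
    ) -> "ConsensusTable":
        frame = pd.DataFrame(
            [
                {
                    "indication_id": e.indication_id,
                    "compound_id": e.compound_id,
                    "topx": e.topx,
                    "consensus_count": e.consensus_count,
                    "percent_occurrence": e.percent_occurrence,
                    "already_approved": e.already_approved,
                }
                for e in entries
            ],
            columns=list(ENTRY_COLUMNS),
        )
        return cls(frame, provenance or {})

    @property
    def topx_levels(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries["topx"].unique()))

    def at_topx(self, topx: int) -> pd.DataFrame:
        sub = self.entries[self.entries["topx"] == topx]
        if sub.empty:
            raise ValidationError(f"consensus table has no entries at Top{topx}")
        return sub

    def mass_matrix(self, topx: int) -> pd.DataFrame:
        """Compound x indication consensus-count pivot at one TopX level."""
        sub = self.at_topx(topx)
        return sub.pivot_table(
            index="compound_id",
            columns="indication_id",
            values="consensus_count",
            aggfunc="sum",
            fill_value=0,
        )

    def save(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ConsensusTable":
        frame = pd.read_csv(path, sep="\t")
        frame["already_approved"] = frame["already_approved"].astype(bool)
        return cls(frame)


def _entries_for_indication(
    indication: IndicationRecord,
    matrix: InteractionMatrix,
    topx: int,
    order: np.ndarray,
) -> list[PredictionEntry]:
    approved = sorted(indication.approved_compound_ids)
    if not approved:
        raise ValidationError(
            f"indication {indication.mesh_id!r} unusable for prediction "
            "(no approved compounds)"
        )
    k = len(approved)
    counts = np.zeros(matrix.n_compounds, dtype=int)
    for drug in approved:
        top = order[matrix.row_index(drug), :topx]
        counts[top] += 1
    approved_idx = {matrix.row_index(d) for d in approved}
    entries = []
    for j in np.flatnonzero(counts):
        entries.append(
            PredictionEntry(
                indication_id=indication.mesh_id,
                compound_id=matrix.compound_ids[j],
                topx=topx,
                consensus_count=int(counts[j]),
                percent_occurrence=100.0 * counts[j] / k,
                already_approved=j in approved_idx,
            )
        )
    return entries


def predict_indication(
    indication: IndicationRecord,
    matrix: InteractionMatrix,
    topx: int,
    order: np.ndarray | None = None,
) -> list[PredictionEntry]:
    """TopX candidates for one indication with consensus counts.

    ``order`` is the precomputed neighbour-order matrix; it is derived
    from the matrix when not supplied.
    """
    if topx < 1:
        raise ValidationError("topx must be >= 1")
    if order is None:
        order = neighbor_order_matrix(matrix)
    return _entries_for_indication(indication, matrix, topx, order)


def build_consensus_table(
    indications: Sequence[IndicationRecord],
    matrix: InteractionMatrix,
    config: AnalysisConfig,
) -> ConsensusTable:
    """Consensus table over every usable indication and every TopX level.

    Indications without usable approved drugs are skipped with a logged
    warning; iteration order of the input does not affect the result
    (entries are sorted canonically).
    """
    usable = []
    for ind in sorted(indications, key=lambda r: r.mesh_id):
        if not ind.usable:
            logger.warning(
                "skipping indication %s: no approved compounds", ind.mesh_id
            )
            continue
        missing = [c for c in sorted(ind.approved_compound_ids) if c not in matrix]
        if missing:
            logger.warning(
                "skipping indication %s: approved compounds absent from "
                "matrix: %s",
                ind.mesh_id,
                missing,
            )
            continue
        usable.append(ind)
    if not usable:
        raise ValidationError("no usable indications for prediction")
    order = neighbor_order_matrix(matrix)
    entries: list[PredictionEntry] = []
    for topx in config.topx_values:
        for ind in usable:
            entries.extend(_entries_for_indication(ind, matrix, topx, order))
    table = ConsensusTable.from_entries(
        entries,
        provenance={
            "topx_values": list(config.topx_values),
            "similarity_metric": config.similarity_metric,
            "seed": config.seed,
            "n_indications_used": len(usable),
            "n_indications_skipped": len(indications) - len(usable),
        },
    )
    return table
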