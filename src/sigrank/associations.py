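"""Indication-indication association networks from shared psychoactives.

Two indications are associated when at least two *different* psychoactive
compounds are predicted for both, each clearing a per-TopX minimum
consensus count in BOTH indications (defaults: >=2 at Top10, >=3 at
Top25, >=4 at Top40, >=6 at Top100).  The association count is the number
of distinct qualifying shared psychoactives; pairs sharing fewer than two
are never emitted.  Non-psychoactive compounds never contribute, however
often they are shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .consensus import ConsensusTable
from .data_model import (
    AnalysisConfig,
    CompoundRecord,
    IndicationRecord,
    ValidationError,
)

__all__ = ["AssociationEdge", "build_associations", "edges_to_frame"]


@dataclass(frozen=True)
class AssociationEdge:
    """An unordered indication pair (stored with sorted ids) and the
    psychoactives shared above threshold."""

    indication_a: str
    indication_b: str
    topx: int
    threshold: int
    association_count: int
    #: (compound_id, consensus in a, consensus in b), sorted by compound.
    shared_compounds: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.indication_a >= self.indication_b:
            raise ValidationError("edge endpoints must be sorted and distinct")
        if self.association_count != len(self.shared_compounds):
            raise ValidationError("association_count mismatch")
        if self.association_count < 2:
            raise ValidationError("edges require at least two shared compounds")


def build_associations(
    table: ConsensusTable,
    compounds: Sequence[CompoundRecord],
    topx: int,
    thresholds: AnalysisConfig | Mapping[int, int],
    indications: Sequence[IndicationRecord] | None = None,
    mental_health_only: bool = True,
) -> list[AssociationEdge]:
    """Thresholded association edges at one TopX level.

    The threshold is applied per indication: a shared psychoactive must
    clear it in both endpoints independently.  By default only pairs of
    mental-health indications are considered (pass
    ``mental_health_only=False`` to include all); ``indications`` is
    required for the mental-health restriction.
    """
    if isinstance(thresholds, AnalysisConfig):
        thresholds = thresholds.association_thresholds
    if topx not in thresholds:
        raise ValidationError(f"no association threshold defined for Top{topx}")
    tau = int(thresholds[topx])

    sub = table.at_topx(topx)
    psy = {c.compound_id for c in compounds if c.is_psychoactive}
    qualifying = sub[
        sub["compound_id"].isin(psy) & (sub["consensus_count"] >= tau)
    ]

    if mental_health_only:
        if indications is None:
            raise ValidationError(
                "indication records required for the mental-health restriction"
            )
        mh = {i.mesh_id for i in indications if i.is_mental_health}
        qualifying = qualifying[qualifying["indication_id"].isin(mh)]

    by_ind: dict[str, dict[str, int]] = {}
    for row in qualifying.itertuples(index=False):
        by_ind.setdefault(row.indication_id, {})[row.compound_id] = int(
            row.consensus_count
        )

    edges: list[AssociationEdge] = []
    ind_ids = sorted(by_ind)
    for i, a in enumerate(ind_ids):
        for b in ind_ids[i + 1 :]:
            shared = sorted(set(by_ind[a]) & set(by_ind[b]))
            if len(shared) < 2:
                continue
            edges.append(
                AssociationEdge(
                    indication_a=a,
                    indication_b=b,
                    topx=topx,
                    threshold=tau,
                    association_count=len(shared),
                    shared_compounds=tuple(
                        (c, by_ind[a][c], by_ind[b][c]) for c in shared
                    ),
                )
            )
    return edges


def edges_to_frame(edges: Iterable[AssociationEdge]) -> pd.DataFrame:
    """Edge-list table (the plain export replacing chord diagrams)."""
    return pd.DataFrame(
        [
            {
                "indication_a": e.indication_a,
                "indication_b": e.indication_b,
                "topx": e.topx,
                "threshold": e.threshold,
                "association_count": e.association_count,
                "shared_compounds": ";".join(
                    f"{c}:{ca}:{cb}" for c, ca, cb in e.shared_compounds
                ),
            }
            for e in edges
        ],
        columns=[
            "indication_a",
            "indication_b",
            "topx",
            "threshold",
            "association_count",
            "shared_compounds",
        ],
    )


def to_networkx(edges: Iterable[AssociationEdge]):
    """Association edges as a weighted undirected networkx graph."""
    import networkx as nx

    graph = nx.Graph()
    for e in edges:
        graph.add_edge(
            e.indication_a,
            e.indication_b,
            weight=e.association_count,
            topx=e.topx,
            threshold=e.threshold,
        )
    return graph


def plot_associations(edges: Sequence[AssociationEdge], path) -> None:
    """Minimal circular-layout rendering; widths scale with counts."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = sorted({e.indication_a for e in edges} | {e.indication_b for e in edges})
    if not nodes:
        raise ValidationError("no edges to plot")
    angle = {
        n: 2 * math.pi * i / len(nodes) for i, n in enumerate(nodes)
    }
    pos = {n: (math.cos(a), math.sin(a)) for n, a in angle.items()}
    fig, ax = plt.subplots(figsize=(6, 6))
    for e in edges:
        (x0, y0), (x1, y1) = pos[e.indication_a], pos[e.indication_b]
        ax.plot([x0, x1], [y0, y1], lw=0.5 * e.association_count, alpha=0.6)
    for n, (x, y) in pos.items():
        ax.annotate(n, (x, y), fontsize=7, ha="center")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
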