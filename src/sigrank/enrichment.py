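"""Normalized indication ranks and normalized compound ranks.

The two headline enrichment statistics:

* *normalized indication rank* — for one indication, the percentage of
  its total consensus mass contributed by psychoactive candidates:
  100 * sum(consensus over psychoactives) / sum(consensus over all).
* *normalized compound rank* — for one compound, the percentage of its
  total consensus mass that falls on mental-health indications:
  100 * sum(consensus over mental-health indications) / sum(over all).

Both are consensus-weighted sums, not counts of distinct compounds; the
worked two-indication example (ergoline 7/3, aspirin 4/6 giving 70/40 and
64/33 percent) forces this reading.  Values are carried at full precision
and rounded half-up to integer percent only for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .consensus import ConsensusTable
from .data_model import (
    CHEM_CLASSES,
    CompoundRecord,
    IndicationRecord,
    ValidationError,
)

__all__ = ["RankDistribution", "indication_rank", "compound_rank", "class_breakdown"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankDistribution:
    """Entity-keyed percentages in [0, 100].

    Entities with zero total consensus mass are absent, not zero: an
    indication never predicted for, or a compound never predicted, has no
    defined rank value.
    """

    kind: str  # "indication_rank" | "compound_rank"
    topx: int
    values: Mapping[str, float]
    class_filter: str | None = None

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.values.items() if not 0 <= v <= 100}
        if bad:
            raise ValidationError(f"rank values outside [0, 100]: {bad}")

    def series(self) -> pd.Series:
        return pd.Series(dict(self.values), dtype=float).sort_index()

    def mean(self) -> float:
        s = self.series()
        if s.empty:
            raise ValidationError("empty rank distribution has no mean")
        return float(s.mean())

    def restricted(self, entity_ids: Iterable[str]) -> "RankDistribution":
        keep = set(entity_ids)
        return RankDistribution(
            kind=self.kind,
            topx=self.topx,
            values={k: v for k, v in self.values.items() if k in keep},
            class_filter=self.class_filter,
        )


def _psychoactive_ids(
    compounds: Iterable[CompoundRecord], class_filter: str | None
) -> set[str]:
    if class_filter is not None and class_filter not in CHEM_CLASSES:
        raise ValidationError(f"unknown chem_class filter {class_filter!r}")
    return {
        c.compound_id
        for c in compounds
        if c.is_psychoactive
        and (class_filter is None or c.chem_class == class_filter)
    }


def indication_rank(
    table: ConsensusTable,
    compounds: Iterable[CompoundRecord],
    topx: int,
    class_filter: str | None = None,
) -> RankDistribution:
    """Psychoactive share of each indication's consensus mass, percent.

    With ``class_filter`` the numerator is restricted to psychoactives of
    that chemical class.  Indications with zero total consensus are
    omitted with a warning.
    """
    sub = table.at_topx(topx)
    psy = _psychoactive_ids(compounds, class_filter)
    grouped = sub.groupby("indication_id")["consensus_count"].sum()
    psy_mass = (
        sub[sub["compound_id"].isin(psy)]
        .groupby("indication_id")["consensus_count"]
        .sum()
        .reindex(grouped.index, fill_value=0)
    )
    zero = grouped[grouped == 0]
    for iid in zero.index:
        logger.warning("indication %s has zero total consensus; omitted", iid)
    nonzero = grouped[grouped > 0]
    values = (100.0 * psy_mass[nonzero.index] / nonzero).to_dict()
    return RankDistribution(
        kind="indication_rank", topx=topx, values=values, class_filter=class_filter
    )


def compound_rank(
    table: ConsensusTable,
    indications: Iterable[IndicationRecord],
    topx: int,
) -> RankDistribution:
    """Mental-health share of each compound's consensus mass, percent.

    Computed for every compound appearing in the table at this TopX;
    compounds never predicted are absent.  Mental-health status comes
    from the indication records (epilepsy-tree indications are typically
    flagged mental-health there, pooling them with the psychiatric tree).
    """
    sub = table.at_topx(topx)
    mh = {i.mesh_id for i in indications if i.is_mental_health}
    total = sub.groupby("compound_id")["consensus_count"].sum()
    mh_mass = (
        sub[sub["indication_id"].isin(mh)]
        .groupby("compound_id")["consensus_count"]
        .sum()
        .reindex(total.index, fill_value=0)
    )
    values = (100.0 * mh_mass / total).to_dict()
    return RankDistribution(kind="compound_rank", topx=topx, values=values)


def class_breakdown(
    table: ConsensusTable,
    compounds: Iterable[CompoundRecord],
    indications: Iterable[IndicationRecord],
    topx: int,
) -> dict[str, RankDistribution]:
    """Compound-rank distributions restricted to each psychoactive class.

    The six class distributions partition the psychoactive compound-rank
    distribution: classes with no predicted members yield empty
    distributions.
    """
    compounds = list(compounds)
    full = compound_rank(table, indications, topx)
    out: dict[str, RankDistribution] = {}
    for cls in CHEM_CLASSES:
        if cls == "none":
            continue
        members = {
            c.compound_id
            for c in compounds
            if c.is_psychoactive and c.chem_class == cls
        }
        out[cls] = RankDistribution(
            kind="compound_rank",
            topx=topx,
            values={k: v for k, v in full.values.items() if k in members},
            class_filter=cls,
        )
    return out
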