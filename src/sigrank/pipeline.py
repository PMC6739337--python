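"""End-to-end orchestration: predict -> rank -> nulls -> tests -> associate.

Also provides the two tiny worked-example fixtures (a two-compound /
two-indication consensus table and a two-psychoactive association table)
that exercise the rank and association arithmetic without any matrix.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .associations import build_associations, edges_to_frame
from .consensus import ConsensusTable, PredictionEntry, build_consensus_table
from .data_model import (
    AnalysisConfig,
    CompoundRecord,
    IndicationRecord,
    InteractionMatrix,
    display_percent,
)
from .enrichment import compound_rank, indication_rank
from .nulls import shuffle_compounds, shuffle_indications
from .stats import ks_one_tailed, paired_t_one_tailed

__all__ = [
    "RunSummary",
    "run_pipeline",
    "worked_example_ranks",
    "worked_example_associations",
    "run_worked_example",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Worked-example fixtures (no matrix required)


def worked_example_ranks() -> tuple[
    ConsensusTable, list[CompoundRecord], list[IndicationRecord]
]:
    """The two-compound / two-indication rank example.

    A psychoactive (ergoline) predicted 7 times for Pica (mental health)
    and 3 times for stomach pain, and a non-psychoactive (aspirin)
    predicted 4 and 6 times respectively.  Percent occurrences assume ten
    approved drugs per indication (the example fixes only the consensus
    counts, which is all the rank statistics consume).
    """
    entries = [
        PredictionEntry("pica", "ergoline", 10, 7, 70.0, False),
        PredictionEntry("stomach_pain", "ergoline", 10, 3, 30.0, False),
        PredictionEntry("pica", "aspirin", 10, 4, 40.0, False),
        PredictionEntry("stomach_pain", "aspirin", 10, 6, 60.0, False),
    ]
    table = ConsensusTable.from_entries(entries, {"fixture": "worked-example"})
    compounds = [
        CompoundRecord("ergoline", "ergoline", None, True, "other"),
        CompoundRecord("aspirin", "aspirin", None, False, "none"),
    ]
    indications = [
        IndicationRecord("pica", "Pica", True),
        IndicationRecord("stomach_pain", "Stomach pain", False),
    ]
    return table, compounds, indications


def worked_example_associations() -> tuple[
    ConsensusTable, list[CompoundRecord], list[IndicationRecord]
]:
    """The seizures / sleep-disorder association example.

    One psychoactive predicted 10 times for seizures and 8 for sleep
    initiation and maintenance disorders (SIMD), another predicted 3 and
    2 times; at the Top10 threshold (consensus >= 2 in both indications)
    the pair's association count is 2.
    """
    entries = [
        PredictionEntry("seizures", "psy_naphthoylindole", 10, 10, 100.0, False),
        PredictionEntry("simd", "psy_naphthoylindole", 10, 8, 80.0, False),
        PredictionEntry("seizures", "psy_methoxytryptamine", 10, 3, 30.0, False),
        PredictionEntry("simd", "psy_methoxytryptamine", 10, 2, 20.0, False),
    ]
    table = ConsensusTable.from_entries(entries, {"fixture": "worked-example"})
    compounds = [
        CompoundRecord(
            "psy_naphthoylindole",
            "1-naphthyl(1-pentyl-1H-indol-3-yl)methanone",
            None,
            True,
            "other",
        ),
        CompoundRecord(
            "psy_methoxytryptamine",
            "2-(5-methoxy-2-methyl-1H-indol-3-yl)-N,N-dimethylethanamine",
            None,
            True,
            "tryptamine",
        ),
    ]
    indications = [
        IndicationRecord("seizures", "Seizures", True),
        IndicationRecord("simd", "Sleep Initiation and Maintenance Disorders", True),
    ]
    return table, compounds, indications


def run_worked_example() -> dict:
    """Rank and association arithmetic on the worked-example fixtures.

    Returns the compound ranks (percent), the indication ranks (percent,
    with display rounding), and the seizures/SIMD association count.
    """
    table, compounds, indications = worked_example_ranks()
    cranks = compound_rank(table, indications, 10)
    iranks = indication_rank(table, compounds, 10)
    atable, acompounds, aindications = worked_example_associations()
    edges = build_associations(
        atable, acompounds, 10, {10: 2}, indications=aindications
    )
    assoc = {
        f"{e.indication_a}--{e.indication_b}": e.association_count for e in edges
    }
    return {
        "compound_rank_percent": dict(cranks.values),
        "indication_rank_percent": dict(iranks.values),
        "indication_rank_display": {
            k: display_percent(v) for k, v in iranks.values.items()
        },
        "association_counts": assoc,
    }


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class TopxReport:
    topx: int
    observed_mean_indication_rank_mh: float
    observed_mean_compound_rank_psychoactive: float
    null_compound_shuffle_mean_indication_rank_mh: float
    null_compound_shuffle_mean_compound_rank_psychoactive: float
    null_indication_shuffle_mean_compound_rank_psychoactive: float
    ks_indication_rank_vs_compound_shuffle: dict
    ks_compound_rank_vs_indication_shuffle: dict
    t_indication_rank_vs_compound_shuffle: dict
    t_nulls_compound_vs_indication_shuffle: dict
    association_edge_count: int


@dataclass
class RunSummary:
    config: dict
    seed: int
    version: str
    n_compounds: int
    n_indications_used: int
    per_topx: dict[int, TopxReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "n_compounds": self.n_compounds,
            "n_indications_used": self.n_indications_used,
            "per_topx": {
                str(x): dataclasses.asdict(r) for x, r in self.per_topx.items()
            },
        }

    def to_json(self, path: str | pathlib.Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _child_seed(seed: int, label: str) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    matrix: InteractionMatrix,
    compounds: Sequence[CompoundRecord],
    indications: Sequence[IndicationRecord],
    config: AnalysisConfig,
    out_dir: str | pathlib.Path | None = None,
) -> RunSummary:
    """Execute predict -> rank -> nulls -> tests -> associate.

    Identical inputs and seed give identical summaries.  When ``out_dir``
    is set, every stage writes its TSV so any stage can be re-run from
    its persisted inputs.
    """
    out = pathlib.Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("predict: %d indications, %d compounds",
                len(indications), matrix.n_compounds)
    table = build_consensus_table(indications, matrix, config)
    if out is not None:
        table.save(out / "consensus.tsv")

    psy_ids = {c.compound_id for c in compounds if c.is_psychoactive}
    mh_ids = {i.mesh_id for i in indications if i.is_mental_health}
    summary = RunSummary(
        config=dataclasses.asdict(config)
        | {"topx_values": list(config.topx_values)},
        seed=config.seed,
        version=__version__,
        n_compounds=matrix.n_compounds,
        n_indications_used=int(table.provenance.get("n_indications_used", 0)),
    )

    for topx in config.topx_values:
        iranks = indication_rank(table, compounds, topx)
        cranks = compound_rank(table, indications, topx)
        obs_irank_mh = iranks.restricted(mh_ids).series()
        obs_crank_psy = cranks.restricted(psy_ids).series()

        cshuf = shuffle_compounds(
            table, compounds, indications, topx,
            config.n_randomizations, _child_seed(config.seed, f"cshuf{topx}"),
        )
        ishuf = shuffle_indications(
            indications, table, topx,
            config.n_randomizations, _child_seed(config.seed, f"ishuf{topx}"),
        )

        null_irank_mh = cshuf.mean_values("indication_rank").reindex(
            obs_irank_mh.index
        ).dropna()
        null_crank_psy_c = cshuf.mean_values("compound_rank").reindex(
            sorted(psy_ids)
        ).dropna()
        null_crank_psy_i = ishuf.mean_values("compound_rank").reindex(
            sorted(psy_ids)
        ).dropna()

        ks_ind = ks_one_tailed(obs_irank_mh, null_irank_mh)
        ks_comp = ks_one_tailed(obs_crank_psy, null_crank_psy_i)
        aligned = obs_irank_mh.index.intersection(null_irank_mh.index)
        t_ind = paired_t_one_tailed(
            obs_irank_mh[aligned], null_irank_mh[aligned]
        )
        both = null_crank_psy_c.index.intersection(null_crank_psy_i.index)
        t_nulls = paired_t_one_tailed(
            null_crank_psy_c[both], null_crank_psy_i[both]
        )

        edges = (
            build_associations(
                table, compounds, topx, config, indications=indications
            )
            if topx in config.association_thresholds
            else []
        )
        if out is not None:
            iranks.series().rename("value_percent").to_csv(
                out / f"indication_rank_top{topx}.tsv", sep="\t"
            )
            cranks.series().rename("value_percent").to_csv(
                out / f"compound_rank_top{topx}.tsv", sep="\t"
            )
            cshuf.mean_values("indication_rank").rename("mean_null").to_csv(
                out / f"null_compound_shuffle_indication_rank_top{topx}.tsv",
                sep="\t",
            )
            ishuf.mean_values("compound_rank").rename("mean_null").to_csv(
                out / f"null_indication_shuffle_compound_rank_top{topx}.tsv",
                sep="\t",
            )
            edges_to_frame(edges).to_csv(
                out / f"associations_top{topx}.tsv", sep="\t", index=False
            )

        summary.per_topx[topx] = TopxReport(
            topx=topx,
            observed_mean_indication_rank_mh=float(obs_irank_mh.mean()),
            observed_mean_compound_rank_psychoactive=float(obs_crank_psy.mean()),
            null_compound_shuffle_mean_indication_rank_mh=float(
                null_irank_mh.mean()
            ),
            null_compound_shuffle_mean_compound_rank_psychoactive=float(
                null_crank_psy_c.mean()
            ),
            null_indication_shuffle_mean_compound_rank_psychoactive=float(
                null_crank_psy_i.mean()
            ),
            ks_indication_rank_vs_compound_shuffle=ks_ind.summary,
            ks_compound_rank_vs_indication_shuffle=ks_comp.summary,
            t_indication_rank_vs_compound_shuffle=t_ind.summary,
            t_nulls_compound_vs_indication_shuffle=t_nulls.summary,
            association_edge_count=len(edges),
        )
        logger.info(
            "Top%d: observed MH indication rank %.2f%% vs null %.2f%% "
            "(KS p=%.3g); %d association edges",
            topx,
            summary.per_topx[topx].observed_mean_indication_rank_mh,
            summary.per_topx[topx].null_compound_shuffle_mean_indication_rank_mh,
            ks_ind.p_value,
            len(edges),
        )

    if out is not None:
        summary.to_json(out / "summary.json")
    return summary
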