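"""Permutation null controls for the enrichment statistics.

Two Monte-Carlo controls, repeated (by default) 1000 times and averaged:

* *compound shuffle* — per replicate and per indication, the distinct
  predicted compounds are relabelled by an injective uniform draw from
  the full compound library; a replacement inherits the original
  compound's entire consensus count ("consistent replacement").  Rank
  statistics are then recomputed on the relabelled table.
* *indication shuffle* — per replicate, the mental-health labels are
  permuted across indications (preserving their count) and the compound
  ranks recomputed.

Consensus counts ride along unchanged during relabelling: the controls
randomize identities in the already-computed prediction lists rather
than re-running prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusTable
from .data_model import (
    CompoundRecord,
    IndicationRecord,
    ValidationError,
)

__all__ = ["NullDistribution", "shuffle_compounds", "shuffle_indications"]


@dataclass
class NullDistribution:
    """Per-replicate and replicate-averaged null rank values.

    ``per_replicate[kind]`` is an entity x replicate frame (NaN where the
    entity does not appear in that replicate, which can happen for the
    compound kind under the compound shuffle).
    """

    control_kind: str  # "compound_shuffle" | "indication_shuffle"
    topx: int
    n_replicates: int
    seed: int
    per_replicate: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for kind, frame in self.per_replicate.items():
            if frame.shape[1] != self.n_replicates:
                raise ValidationError(
                    f"{kind}: replicate count {frame.shape[1]} != "
                    f"{self.n_replicates}"
                )

    def kinds(self) -> tuple[str, ...]:
        return tuple(self.per_replicate)

    def mean_values(self, kind: str) -> pd.Series:
        """Arithmetic mean per entity over the replicates where it appears."""
        frame = self.per_replicate[kind]
        return frame.mean(axis=1, skipna=True).dropna()

    def pooled(self, kind: str) -> np.ndarray:
        """All per-replicate values flattened (NaN dropped)."""
        vals = self.per_replicate[kind].to_numpy().ravel()
        return vals[~np.isnan(vals)]

    def mean(self, kind: str) -> float:
        return float(self.mean_values(kind).mean())


def _flags(
    compounds: Iterable[CompoundRecord],
) -> tuple[list[str], np.ndarray]:
    recs = sorted(compounds, key=lambda c: c.compound_id)
    ids = [c.compound_id for c in recs]
    psy = np.array([c.is_psychoactive for c in recs], dtype=bool)
    return ids, psy


def shuffle_compounds(
    table: ConsensusTable,
    compounds: Sequence[CompoundRecord],
    indications: Sequence[IndicationRecord],
    topx: int,
    n_reps: int,
    seed: int,
) -> NullDistribution:
    """Compound-randomization control.

    Per replicate and indication, draws an injective uniform mapping from
    the indication's distinct predicted compounds into the library, moves
    each consensus count to the replacement, and recomputes both the
    indication-rank and compound-rank statistics.  Deterministic given
    the seed.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    sub = table.at_topx(topx)
    lib_ids, psy = _flags(compounds)
    lib_index = {c: i for i, c in enumerate(lib_ids)}
    missing = set(sub["compound_id"]) - set(lib_ids)
    if missing:
        raise ValidationError(
            f"library does not span predicted compounds: {sorted(missing)[:5]}"
        )
    mh_by_id = {i.mesh_id: i.is_mental_health for i in indications}

    ind_ids = sorted(sub["indication_id"].unique())
    ind_row = {iid: r for r, iid in enumerate(ind_ids)}
    n_ind, n_lib = len(ind_ids), len(lib_ids)

    # Entry arrays: which indication row, which slot in that indication's
    # distinct-candidate list, the consensus count, the indication's MH flag.
    rows = sub["indication_id"].map(ind_row).to_numpy()
    counts = sub["consensus_count"].to_numpy(dtype=float)
    slot = np.zeros(len(sub), dtype=int)
    k_per_ind = np.zeros(n_ind, dtype=int)
    order_of_entry = np.argsort(rows, kind="stable")
    for e in order_of_entry:
        r = rows[e]
        slot[e] = k_per_ind[r]
        k_per_ind[r] += 1
    if k_per_ind.max(initial=0) > n_lib:
        raise ValidationError(
            "library smaller than an indication's distinct-prediction count; "
            "injective replacement impossible"
        )
    try:
        mh_flag = np.array([mh_by_id[iid] for iid in ind_ids], dtype=bool)
    except KeyError as exc:
        raise ValidationError(f"indication missing from records: {exc}") from exc
    total_per_ind = np.bincount(rows, weights=counts, minlength=n_ind)

    rng = np.random.default_rng(seed)
    ind_vals = np.empty((n_ind, n_reps))
    comp_vals = np.full((n_lib, n_reps), np.nan)
    kmax = int(k_per_ind.max(initial=1))
    for rep in range(n_reps):
        # Uniform injective draw per indication: the kmax smallest of a row
        # of iid uniform keys form a uniform random subset, and ordering
        # them by key value gives a uniform random ordering of it.
        keys = rng.random((n_ind, n_lib))
        part = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
        part_keys = np.take_along_axis(keys, part, axis=1)
        order = np.argsort(part_keys, axis=1)
        perm = np.take_along_axis(part, order, axis=1)
        new_idx = perm[rows, slot]

        psy_mass = np.bincount(
            rows, weights=counts * psy[new_idx], minlength=n_ind
        )
        ind_vals[:, rep] = 100.0 * psy_mass / total_per_ind

        tot_mass = np.zeros(n_lib)
        mh_mass = np.zeros(n_lib)
        np.add.at(tot_mass, new_idx, counts)
        np.add.at(mh_mass, new_idx, counts * mh_flag[rows])
        present = tot_mass > 0
        comp_vals[present, rep] = (
            100.0 * mh_mass[present] / tot_mass[present]
        )

    return NullDistribution(
        control_kind="compound_shuffle",
        topx=topx,
        n_replicates=n_reps,
        seed=seed,
        per_replicate={
            "indication_rank": pd.DataFrame(ind_vals, index=ind_ids),
            "compound_rank": pd.DataFrame(comp_vals, index=lib_ids),
        },
    )


def shuffle_indications(
    indications: Sequence[IndicationRecord],
    table: ConsensusTable,
    topx: int,
    n_reps: int,
    seed: int,
) -> NullDistribution:
    """Indication-label randomization control.

    Per replicate, permutes the mental-health labels across the table's
    indications (preserving the number of mental-health labels) and
    recomputes the compound ranks.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    mass = table.mass_matrix(topx)  # compounds x indications
    mh_by_id = {i.mesh_id: i.is_mental_health for i in indications}
    try:
        labels = np.array(
            [mh_by_id[iid] for iid in mass.columns], dtype=float
        )
    except KeyError as exc:
        raise ValidationError(f"indication missing from records: {exc}") from exc
    if labels.all() or not labels.any():
        raise ValidationError(
            "indication labels all identical; permutation control is vacuous"
        )
    M = mass.to_numpy(dtype=float)
    row_tot = M.sum(axis=1)

    rng = np.random.default_rng(seed)
    perms = np.empty((len(labels), n_reps))
    for rep in range(n_reps):
        perms[:, rep] = rng.permutation(labels)
    vals = 100.0 * (M @ perms) / row_tot[:, None]

    return NullDistribution(
        control_kind="indication_shuffle",
        topx=topx,
        n_replicates=n_reps,
        seed=seed,
        per_replicate={
            "compound_rank": pd.DataFrame(vals, index=list(mass.index))
        },
    )
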