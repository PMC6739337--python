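"""Synthetic cohorts with planted enrichment structure.

The generator emulates the statistical structure the analysis exploits,
not the marginal distribution of any real docking score.  Compounds fall
into latent signature clusters ("groups"): each compound's interaction
signature is its group centroid plus independent Gaussian noise, and
centroids are placed on an orthogonal block grid scaled so that the
minimal between-centroid RMSD is at least ten times the noise scale.
"Similar signature implies same group" therefore holds by construction,
mirroring the platform's core hypothesis.

Psychoactive structure is planted at the group level: a subset of groups
is designated psychoactive-bearing, and within each bearing group a small
number of members (default one) carries the psychoactive flag.  The
remaining members of a bearing group are ordinary compounds that can act
as approved drugs — exactly the prediction direction of the analysis,
where a psychoactive is only ever predicted through its signature
similarity to an approved non-psychoactive drug sharing its cluster.

Indications are group-coherent: each indication draws all of its approved
drugs from a single group (drugs approved for one indication are assumed
to share a mechanism, hence a signature cluster).  A mental-health
indication picks a psychoactive-bearing group with probability
``enrichment`` and a non-bearing group otherwise; non-mental-health
indications pick uniformly among all groups.  Setting ``enrichment`` to
the base rate (the bearing fraction of groups) therefore reproduces the
uniform assignment exactly, which makes mental-health labels exchangeable
— the no-planted-effect calibration point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import (
    CompoundRecord,
    IndicationRecord,
    InteractionMatrix,
    ValidationError,
)

__all__ = ["SyntheticSpec", "CohortTruth", "generate_cohort", "planted_truth"]

_CLASS_CYCLE = (
    "amphetamine",
    "cathinone",
    "phenethylamine",
    "tryptamine",
    "cannabinoid",
    "other",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale cohort: 720 compounds in 60 signature
    clusters of 12 over 120 proteins, 480 indications (25% mental-health)
    with 3 approved drugs each, and 18 psychoactives occupying one slot in
    each of 18 bearing clusters (base rate 0.3).  The cluster count and
    bearing coverage are chosen so that the psychoactives' prediction
    profiles are nearly independent, which keeps the label-permutation
    control calibrated at its nominal level.
    """

    n_compounds: int = 720
    n_proteins: int = 120
    n_groups: int = 60
    noise_sd: float = 0.05
    psychoactive_fraction: float = 18 / 720
    n_indications: int = 480
    mental_health_fraction: float = 0.25
    drugs_per_indication: int = 3
    enrichment: float = 0.9
    seed: int = 0
    #: psychoactive members per bearing group.
    psychoactives_per_group: int = 1
    #: approved drugs for mental-health indications; None means same as
    #: drugs_per_indication.  Larger values give mental-health indications
    #: more consensus mass, as in real drug-indication maps.
    mh_drugs_per_indication: int | None = None

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_proteins < 1 or self.n_groups < 1:
            raise ValidationError("cohort dimensions must be positive")
        if self.n_groups > self.n_compounds:
            raise ValidationError("n_groups must not exceed n_compounds")
        if self.n_groups > self.n_proteins:
            raise ValidationError(
                "n_proteins must be >= n_groups for separated centroids"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not 0 <= self.psychoactive_fraction <= 1:
            raise ValidationError("psychoactive_fraction must be in [0, 1]")
        if not 0 <= self.mental_health_fraction <= 1:
            raise ValidationError("mental_health_fraction must be in [0, 1]")
        if not 0 <= self.enrichment <= 1:
            raise ValidationError("enrichment must be in [0, 1]")
        if self.drugs_per_indication < 2:
            raise ValidationError("drugs_per_indication must be >= 2")
        if self.drugs_per_indication > self.n_compounds:
            raise ValidationError("drugs_per_indication exceeds n_compounds")
        if self.psychoactives_per_group < 1:
            raise ValidationError("psychoactives_per_group must be >= 1")

    @property
    def n_psychoactives(self) -> int:
        return round(self.psychoactive_fraction * self.n_compounds)

    @property
    def n_bearing_groups(self) -> int:
        return math.ceil(self.n_psychoactives / self.psychoactives_per_group)

    @property
    def base_rate(self) -> float:
        """Bearing fraction of groups — the no-effect enrichment value."""
        return self.n_bearing_groups / self.n_groups


@dataclass(frozen=True)
class CohortTruth:
    """Latent structure behind a generated cohort (ground truth)."""

    group_of: dict[str, int]
    group_members: tuple[tuple[str, ...], ...]
    bearing_groups: tuple[int, ...]
    psychoactive_ids: frozenset[str]
    indication_group: dict[str, int]
    mental_health_ids: frozenset[str]
    base_rate: float


def _structure(spec: SyntheticSpec, rng: np.random.Generator):
    """Latent assignments: groups, flags, indication draws.

    Separated from matrix noise so that planted_truth reproduces the
    bookkeeping without regenerating signatures.
    """
    n, g = spec.n_compounds, spec.n_groups
    compound_ids = tuple(f"c{i:04d}" for i in range(n))
    group_of = {cid: i % g for i, cid in enumerate(compound_ids)}
    members: list[list[str]] = [[] for _ in range(g)]
    for cid, grp in group_of.items():
        members[grp].append(cid)

    n_psy = spec.n_psychoactives
    n_bearing = spec.n_bearing_groups
    if n_bearing > g:
        raise ValidationError(
            "infeasible spec: more psychoactive-bearing groups than groups"
        )
    bearing = (
        tuple(sorted(rng.choice(g, size=n_bearing, replace=False)))
        if n_bearing
        else ()
    )

    psychoactive: list[str] = []
    class_of: dict[str, str] = {}
    remaining = n_psy
    for k, grp in enumerate(bearing):
        take = min(spec.psychoactives_per_group, remaining, len(members[grp]))
        chosen = rng.choice(members[grp], size=take, replace=False)
        for cid in chosen:
            psychoactive.append(cid)
            class_of[cid] = _CLASS_CYCLE[k % len(_CLASS_CYCLE)]
        remaining -= take
    if remaining > 0:
        raise ValidationError("infeasible spec: cannot place all psychoactives")
    psy_set = frozenset(psychoactive)

    eligible = [
        [cid for cid in members[grp] if cid not in psy_set] for grp in range(g)
    ]

    n_ind = spec.n_indications
    n_mh = round(spec.mental_health_fraction * n_ind)
    indication_ids = tuple(f"d{j:04d}" for j in range(n_ind))
    mh_ids = (
        frozenset(
            indication_ids[j]
            for j in rng.choice(n_ind, size=n_mh, replace=False)
        )
        if n_mh
        else frozenset()
    )

    non_bearing = tuple(grp for grp in range(g) if grp not in bearing)
    d_mh = spec.mh_drugs_per_indication or spec.drugs_per_indication

    # Feasibility before emitting any output.
    if n_mh and spec.enrichment > 0:
        if not bearing:
            raise ValidationError(
                "infeasible spec: enrichment > 0 but no psychoactive-bearing groups"
            )
        if min(len(eligible[grp]) for grp in bearing) < d_mh:
            raise ValidationError(
                "infeasible spec: bearing groups lack enough non-psychoactive "
                "members to serve as approved drugs"
            )
    if n_mh and spec.enrichment < 1:
        if not non_bearing:
            raise ValidationError(
                "infeasible spec: enrichment < 1 requires at least one "
                "non-bearing group"
            )
        if min(len(eligible[grp]) for grp in non_bearing) < d_mh:
            raise ValidationError(
                "infeasible spec: non-bearing groups lack enough members "
                "to serve as approved drugs for mental-health indications"
            )
    pool_all = [grp for grp in range(g) if len(eligible[grp]) >= 1]
    if n_ind and (
        not pool_all
        or min(len(e) for e in eligible) < spec.drugs_per_indication
    ):
        raise ValidationError(
            "infeasible spec: some group cannot supply "
            f"{spec.drugs_per_indication} non-psychoactive approved drugs"
        )

    indication_group: dict[str, int] = {}
    approved: dict[str, frozenset[str]] = {}
    for iid in indication_ids:
        if iid in mh_ids:
            if rng.random() < spec.enrichment:
                grp = int(rng.choice(bearing))
            else:
                grp = int(rng.choice(non_bearing))
            d = d_mh
        else:
            grp = int(rng.integers(g))
            d = spec.drugs_per_indication
        indication_group[iid] = grp
        approved[iid] = frozenset(rng.choice(eligible[grp], size=d, replace=False))

    return (
        compound_ids,
        group_of,
        tuple(tuple(m) for m in members),
        bearing,
        psy_set,
        class_of,
        indication_ids,
        mh_ids,
        indication_group,
        approved,
    )


def _rngs(spec: SyntheticSpec) -> tuple[np.random.Generator, np.random.Generator]:
    ss_struct, ss_noise = np.random.SeedSequence(spec.seed).spawn(2)
    return np.random.default_rng(ss_struct), np.random.default_rng(ss_noise)


def _centroids(spec: SyntheticSpec) -> np.ndarray:
    """Orthogonal block centroids with guaranteed minimal separation.

    Group k is offset by delta on its own block of protein coordinates;
    delta is scaled so the pairwise centroid RMSD equals
    max(10 * noise_sd, 1), keeping between-group distance an order of
    magnitude above within-group noise.
    """
    width = spec.n_proteins // spec.n_groups
    separation = max(10.0 * spec.noise_sd, 1.0)
    delta = separation / math.sqrt(2.0 * width / spec.n_proteins)
    cent = np.zeros((spec.n_groups, spec.n_proteins))
    for k in range(spec.n_groups):
        cent[k, k * width : (k + 1) * width] = delta
    return cent


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[InteractionMatrix, list[CompoundRecord], list[IndicationRecord]]:
    """Generate a matrix plus metadata with planted enrichment structure.

    Deterministic: the same spec (including seed) yields bit-identical
    output.  All randomness flows from the spec seed through named
    generators; no global random state is touched.
    """
    rng_struct, rng_noise = _rngs(spec)
    (
        compound_ids,
        group_of,
        _members,
        _bearing,
        psy_set,
        class_of,
        indication_ids,
        mh_ids,
        _ind_group,
        approved,
    ) = _structure(spec, rng_struct)

    cent = _centroids(spec)
    rows = cent[[group_of[cid] for cid in compound_ids]]
    if spec.noise_sd > 0:
        rows = rows + rng_noise.normal(
            0.0, spec.noise_sd, size=(spec.n_compounds, spec.n_proteins)
        )
    protein_ids = tuple(f"p{j:04d}" for j in range(spec.n_proteins))
    matrix = InteractionMatrix(compound_ids, protein_ids, rows)

    compounds = [
        CompoundRecord(
            compound_id=cid,
            name=cid,
            smiles=None,
            is_psychoactive=cid in psy_set,
            chem_class=class_of.get(cid, "none"),
        )
        for cid in compound_ids
    ]
    indications = [
        IndicationRecord(
            mesh_id=iid,
            name=iid,
            is_mental_health=iid in mh_ids,
            approved_compound_ids=approved[iid],
        )
        for iid in indication_ids
    ]
    return matrix, compounds, indications


def planted_truth(spec: SyntheticSpec) -> CohortTruth:
    """Ground-truth latent structure for the cohort generate_cohort(spec)
    produces — the reference for recovery tests."""
    rng_struct, _ = _rngs(spec)
    (
        _compound_ids,
        group_of,
        members,
        bearing,
        psy_set,
        _class_of,
        _indication_ids,
        mh_ids,
        indication_group,
        _approved,
    ) = _structure(spec, rng_struct)
    return CohortTruth(
        group_of=group_of,
        group_members=members,
        bearing_groups=bearing,
        psychoactive_ids=psy_set,
        indication_group=indication_group,
        mental_health_ids=mh_ids,
        base_rate=spec.base_rate,
    )
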