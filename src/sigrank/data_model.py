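"""Core domain types and tabular IO.

The analysis operates on three inputs: a dense compound x protein
interaction-score matrix (one real-valued "interaction signature" per
compound), a compound metadata table carrying psychoactive flags and
chemical classes, and an indication table mapping each indication to its
approved (non-psychoactive) drugs.  All identifiers are normalized on
ingest — whitespace-trimmed and case-folded — and every join downstream
uses the normalized form.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "InteractionMatrix",
    "CompoundRecord",
    "IndicationRecord",
    "AnalysisConfig",
    "CHEM_CLASSES",
    "normalize_id",
    "load_matrix",
    "save_matrix",
    "load_compounds",
    "load_indications",
    "load_metadata",
    "save_compounds",
    "save_indications",
    "display_percent",
]

#: Chemical classes used for psychoactives; "none" marks non-psychoactives.
CHEM_CLASSES = (
    "amphetamine",
    "cathinone",
    "phenethylamine",
    "tryptamine",
    "cannabinoid",
    "other",
    "none",
)


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


def normalize_id(identifier: str) -> str:
    """Whitespace-trim and case-fold an identifier."""
    return str(identifier).strip().casefold()


def display_percent(value: float) -> int:
    """Round a percentage half-up to integer, the convention used in reports.

    63.636... -> 64;  33.333... -> 33;  0.5 -> 1.
    """
    return int(np.floor(value + 0.5))


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class InteractionMatrix:
    """Dense compound x protein interaction scores (the signature universe).

    Rows are compounds, columns proteins.  Scores are unitless reals; no
    missing entries are permitted (the deposited matrices are dense, and
    silent imputation would corrupt RMSD-based ranks).
    """

    compound_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        comp = tuple(normalize_id(c) for c in self.compound_ids)
        prot = tuple(normalize_id(p) for p in self.protein_ids)
        object.__setattr__(self, "compound_ids", comp)
        object.__setattr__(self, "protein_ids", prot)
        _check_unique(comp, "compound")
        _check_unique(prot, "protein")
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2:
            raise ValidationError("scores must be a 2-D array")
        if scores.shape != (len(comp), len(prot)):
            raise ValidationError(
                f"scores shape {scores.shape} does not match "
                f"{len(comp)} compounds x {len(prot)} proteins"
            )
        bad = np.argwhere(~np.isfinite(scores))
        if bad.size:
            r, c = bad[0]
            raise ValidationError(
                f"missing/non-finite score at compound {comp[r]!r}, "
                f"protein {prot[c]!r}"
            )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(comp)}
        )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def row_index(self, compound_id: str) -> int:
        key = normalize_id(compound_id)
        try:
            return self._index[key]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"unknown compound: {compound_id!r}") from None

    def __contains__(self, compound_id: str) -> bool:
        return normalize_id(compound_id) in self._index  # type: ignore[attr-defined]

    def signature(self, compound_id: str) -> np.ndarray:
        """Interaction signature of one compound (read-only view)."""
        return self.scores[self.row_index(compound_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=list(self.compound_ids),
            columns=list(self.protein_ids),
        )


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str = ""
    smiles: str | None = None
    is_psychoactive: bool = False
    chem_class: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_id", normalize_id(self.compound_id))
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"unknown chem_class {self.chem_class!r} for {self.compound_id}"
            )
        if self.chem_class != "none" and not self.is_psychoactive:
            raise ValidationError(
                f"compound {self.compound_id}: chem_class "
                f"{self.chem_class!r} requires is_psychoactive"
            )


@dataclass(frozen=True)
class IndicationRecord:
    mesh_id: str
    name: str = ""
    is_mental_health: bool = False
    approved_compound_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "mesh_id", normalize_id(self.mesh_id))
        object.__setattr__(
            self,
            "approved_compound_ids",
            frozenset(normalize_id(c) for c in self.approved_compound_ids),
        )

    @property
    def usable(self) -> bool:
        """Whether the indication can drive predictions (has approved drugs)."""
        return len(self.approved_compound_ids) > 0


@dataclass
class AnalysisConfig:
    """Run-level knobs: TopX cut-offs, association thresholds, replicates."""

    topx_values: tuple[int, ...] = (10, 25, 40, 100)
    association_thresholds: dict[int, int] = field(
        default_factory=lambda: {10: 2, 25: 3, 40: 4, 100: 6}
    )
    n_randomizations: int = 1000
    seed: int = 0
    similarity_metric: str = "rmsd"

    def __post_init__(self) -> None:
        self.topx_values = tuple(int(x) for x in self.topx_values)
        if not self.topx_values or any(x < 1 for x in self.topx_values):
            raise ValidationError("topx_values must be positive integers")
        self.association_thresholds = {
            int(k): int(v) for k, v in self.association_thresholds.items()
        }
        for x, tau in self.association_thresholds.items():
            if x not in self.topx_values:
                raise ValidationError(
                    f"association threshold for Top{x} but {x} not in topx_values"
                )
            if tau < 1:
                raise ValidationError(f"threshold for Top{x} must be >= 1")
        if self.n_randomizations < 1:
            raise ValidationError("n_randomizations must be positive")
        if self.similarity_metric != "rmsd":
            raise ValidationError(
                f"unsupported similarity metric {self.similarity_metric!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | pathlib.Path) -> None:
        data = dataclasses.asdict(self)
        data["topx_values"] = list(self.topx_values)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Matrix IO


def load_matrix(path: str | pathlib.Path, dialect: str = "tsv") -> InteractionMatrix:
    """Read an interaction matrix.

    ``tsv``: first column holds compound ids, header row protein ids.
    ``matrix-market``: a coordinate/array .mtx file with sidecar label
    files ``<path>.rows`` and ``<path>.cols`` (one id per line).
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise ValidationError(f"matrix file not found: {path}")
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=None)
        scores = frame.to_numpy(dtype=float, na_value=np.nan)
        return InteractionMatrix(
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
            scores,
        )
    if dialect == "matrix-market":
        from scipy import io as sio
        from scipy import sparse

        mat = sio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        rows = pathlib.Path(str(path) + ".rows").read_text().split()
        cols = pathlib.Path(str(path) + ".cols").read_text().split()
        return InteractionMatrix(tuple(rows), tuple(cols), np.asarray(mat, float))
    raise ValidationError(f"unknown matrix dialect {dialect!r}")


def save_matrix(
    matrix: InteractionMatrix, path: str | pathlib.Path, dialect: str = "tsv"
) -> None:
    path = pathlib.Path(path)
    if dialect == "tsv":
        frame = matrix.to_frame()
        frame.index.name = "compound_id"
        frame.to_csv(path, sep="\t")
        return
    if dialect == "matrix-market":
        from scipy import io as sio

        sio.mmwrite(path, matrix.scores)
        pathlib.Path(str(path) + ".rows").write_text(
            "\n".join(matrix.compound_ids) + "\n"
        )
        pathlib.Path(str(path) + ".cols").write_text(
            "\n".join(matrix.protein_ids) + "\n"
        )
        return
    raise ValidationError(f"unknown matrix dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Metadata IO

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value: object, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().casefold()
    if text in _TRUE:
        return True
    if text in _FALSE or text == "nan":
        return False
    raise ValidationError(f"cannot parse boolean {value!r} in {where}")


def load_compounds(path: str | pathlib.Path) -> list[CompoundRecord]:
    """Read the compound table (TSV: compound_id, name, smiles,
    is_psychoactive, chem_class)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"compound_id", "is_psychoactive"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"compound table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        smiles = getattr(row, "smiles", "") or None
        records.append(
            CompoundRecord(
                compound_id=row.compound_id,
                name=getattr(row, "name", ""),
                smiles=smiles,
                is_psychoactive=_parse_bool(row.is_psychoactive, "compounds"),
                chem_class=getattr(row, "chem_class", "") or "none",
            )
        )
    _check_unique([r.compound_id for r in records], "compound")
    return sorted(records, key=lambda r: r.compound_id)


def load_indications(path: str | pathlib.Path) -> list[IndicationRecord]:
    """Read the indication table (TSV: mesh_id, name, is_mental_health,
    approved_compound_ids semicolon-joined)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"mesh_id", "is_mental_health", "approved_compound_ids"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"indication table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        approved = [
            c for c in str(row.approved_compound_ids).split(";") if c.strip()
        ]
        records.append(
            IndicationRecord(
                mesh_id=row.mesh_id,
                name=getattr(row, "name", ""),
                is_mental_health=_parse_bool(row.is_mental_health, "indications"),
                approved_compound_ids=frozenset(approved),
            )
        )
    _check_unique([r.mesh_id for r in records], "indication")
    return sorted(records, key=lambda r: r.mesh_id)


def validate_metadata(
    compounds: Iterable[CompoundRecord],
    indications: Iterable[IndicationRecord],
    matrix: InteractionMatrix,
) -> None:
    """Cross-reference checks between metadata and the matrix.

    Approved drugs must exist in the matrix and must not be psychoactive
    (the analysis direction is "psychoactive predicted from approved
    non-psychoactive drug", never the reverse).
    """
    psychoactive = {c.compound_id for c in compounds if c.is_psychoactive}
    for ind in indications:
        for cid in sorted(ind.approved_compound_ids):
            if cid in psychoactive:
                raise ValidationError(
                    f"psychoactive compound {cid!r} listed as approved for "
                    f"indication {ind.mesh_id!r}"
                )
            if cid not in matrix:
                raise ValidationError(
                    f"approved compound {cid!r} for indication "
                    f"{ind.mesh_id!r} is absent from the matrix"
                )


def load_metadata(
    compounds_path: str | pathlib.Path,
    indications_path: str | pathlib.Path,
    matrix: InteractionMatrix,
) -> tuple[list[CompoundRecord], list[IndicationRecord]]:
    """Load and cross-validate both metadata tables against a matrix."""
    compounds = load_compounds(compounds_path)
    indications = load_indications(indications_path)
    validate_metadata(compounds, indications, matrix)
    return compounds, indications


def save_compounds(
    records: Iterable[CompoundRecord], path: str | pathlib.Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "smiles": r.smiles or "",
                "is_psychoactive": str(r.is_psychoactive).lower(),
                "chem_class": r.chem_class,
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def save_indications(
    records: Iterable[IndicationRecord], path: str | pathlib.Path
) -> None:
    frame = pd.DataFrame(
        [
            {
                "mesh_id": r.mesh_id,
                "name": r.name,
                "is_mental_health": str(r.is_mental_health).lower(),
                "approved_compound_ids": ";".join(sorted(r.approved_compound_ids)),
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
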