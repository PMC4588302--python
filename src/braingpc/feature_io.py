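"""Subject metadata and regional feature tables.

Feature tables are subjects × named-features matrices carrying one imaging
modality each (cortical thickness in mm, cortical surface area in mm²,
subcortical volumes in mm³, or mean-scaled regional cerebral blood flow).
Metadata rows carry group membership, demographics and the covariates used
downstream: estimated total intracranial volume (eTIV), antipsychotic dose
in chlorpromazine equivalents, and a general-psychopathology symptom score.

Head-size correction divides area and volume features by each subject's
eTIV; thickness and perfusion are deliberately left untouched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "Modality",
    "SubjectRecord",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "read_subject_metadata",
    "write_subject_metadata",
    "normalize_by_icv",
    "build_consensus_mask",
    "scale_rows_by_mean",
]


class Group(str, enum.Enum):
    """Cohort groups: healthy controls, schizophrenia patients, bipolar
    patients, and family members without / with the t(1;11) translocation."""

    HC = "HC"
    SCZ = "SCZ"
    BP = "BP"
    T_MINUS = "T_MINUS"
    T_PLUS = "T_PLUS"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Modality(str, enum.Enum):
    THICKNESS = "thickness"
    SURFACE_AREA = "surface_area"
    SUBCORTICAL_VOLUME = "subcortical_volume"
    RCBF = "rcbf"


#: Modalities whose features are divided by eTIV for head-size correction.
ICV_NORMALIZED_MODALITIES = frozenset(
    {Modality.SURFACE_AREA, Modality.SUBCORTICAL_VOLUME}
)

_MODALITY_UNITS = {
    Modality.THICKNESS: "mm",
    Modality.SURFACE_AREA: "mm^2",
    Modality.SUBCORTICAL_VOLUME: "mm^3",
    Modality.RCBF: "a.u.",
}


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics, group label and optional covariates."""

    subject_id: str
    group: Group
    age: float
    sex: Sex
    diagnosis: str | None = None
    etiv: float | None = None
    cpz_equiv: float | None = None
    panss_general: int | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be a non-empty string")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        if self.etiv is not None and self.etiv <= 0:
            raise ValueError(f"etiv must be positive, got {self.etiv!r}")
        if self.cpz_equiv is not None and self.cpz_equiv < 0:
            raise ValueError("cpz_equiv must be nonnegative")
        if self.panss_general is not None and self.panss_general < 0:
            raise ValueError("panss_general must be nonnegative")


@dataclass(frozen=True)
class FeatureTable:
    """Subjects × features matrix for a single modality.

    ``values[i, j]`` is feature ``feature_names[j]`` of subject
    ``subject_ids[i]``; rows follow ``subject_ids`` order exactly.
    """

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    modality: Modality
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "modality", Modality(self.modality))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.subject_ids)} subjects × {len(self.feature_names)} features"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in feature table")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value for subject {self.subject_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if not self.units:
            object.__setattr__(self, "units", _MODALITY_UNITS[self.modality])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.subject_ids, name="subject_id"),
            columns=list(self.feature_names),
        )

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the named features, in the given order."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        cols = [index[n] for n in names]
        return replace(
            self, feature_names=tuple(names), values=self.values[:, cols]
        )

    def reindex_subjects(self, ids: Sequence[str]) -> "FeatureTable":
        """Reorder / subset rows to the given subject ids."""
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in table: {missing}")
        rows = [index[s] for s in ids]
        return replace(self, subject_ids=tuple(ids), values=self.values[rows])


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_feature_table(path: str | Path, modality: Modality | str) -> FeatureTable:
    """Read a delimited feature table (header = feature names, first column
    = subject ids). Comma/tab separation is inferred from the extension.

    Raises ``ValueError`` on missing or non-numeric cells, duplicate subject
    ids, or ragged rows — tables must be complete-case.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise ValueError(f"missing value at subject {row!r}, feature {col!r}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for r in df.index:
            for c in df.columns:
                try:
                    float(df.at[r, c])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {df.at[r, c]!r} at subject {r!r}, "
                        f"feature {c!r}"
                    ) from None
        raise
    return FeatureTable(
        subject_ids=tuple(str(s) for s in df.index),
        feature_names=tuple(str(c) for c in df.columns),
        values=values,
        modality=Modality(modality),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path))


_REQUIRED_META = ("subject_id", "group", "age", "sex")
_OPTIONAL_META = ("diagnosis", "etiv", "cpz_equiv", "panss_general", "family_id")


def read_subject_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read a delimited subject metadata table.

    Required columns: subject_id, group, age, sex. Optional columns
    (diagnosis, etiv, cpz_equiv, panss_general, family_id) may be absent or
    blank per subject. Group and sex labels are validated against the enums.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    missing_cols = [c for c in _REQUIRED_META if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        try:
            group = Group(str(row["group"]))
        except ValueError:
            raise ValueError(
                f"unknown group label {row['group']!r} for subject {sid!r}"
            ) from None
        try:
            sex = Sex(str(row["sex"]))
        except ValueError:
            raise ValueError(
                f"unknown sex label {row['sex']!r} for subject {sid!r}"
            ) from None

        def _opt(col: str, cast):
            if col not in df.columns or pd.isna(row[col]) or str(row[col]) == "":
                return None
            return cast(row[col])

        records.append(
            SubjectRecord(
                subject_id=sid,
                group=group,
                age=float(row["age"]),
                sex=sex,
                diagnosis=_opt("diagnosis", str),
                etiv=_opt("etiv", float),
                cpz_equiv=_opt("cpz_equiv", float),
                panss_general=_opt("panss_general", lambda v: int(float(v))),
                family_id=_opt("family_id", str),
            )
        )
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in metadata")
    return records


def write_subject_metadata(records: Sequence[SubjectRecord], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group.value,
                "age": r.age,
                "sex": r.sex.value,
                "diagnosis": r.diagnosis,
                "etiv": r.etiv,
                "cpz_equiv": r.cpz_equiv,
                "panss_general": r.panss_general,
                "family_id": r.family_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def normalize_by_icv(
    table: FeatureTable, records: Sequence[SubjectRecord]
) -> FeatureTable:
    """Divide each subject's features by that subject's eTIV.

    Only surface-area and subcortical-volume tables are eligible; thickness
    and perfusion are not head-size corrected, and passing them is an error.
    Output units are dimensionless ratios.
    """
    if table.modality not in ICV_NORMALIZED_MODALITIES:
        raise ValueError(
            f"modality {table.modality.value!r} is not ICV-normalized; "
            "only surface_area and subcortical_volume are"
        )
    etiv_by_id = {r.subject_id: r.etiv for r in records}
    etivs = np.empty(table.n_subjects)
    for i, sid in enumerate(table.subject_ids):
        if sid not in etiv_by_id:
            raise ValueError(f"no metadata record for subject {sid!r}")
        etiv = etiv_by_id[sid]
        if etiv is None:
            raise ValueError(f"subject {sid!r} has no etiv")
        etivs[i] = etiv
    return replace(
        table, values=table.values / etivs[:, None], units="ratio"
    )


def build_consensus_mask(
    per_subject_masks: Iterable[Iterable[int] | frozenset[int]],
) -> frozenset[int]:
    """Intersect per-subject feature-index masks into a consensus mask.

    Guarantees the same feature set is used for every subject downstream.
    """
    masks = [frozenset(m) for m in per_subject_masks]
    if not masks:
        raise ValueError("at least one mask is required")
    consensus = frozenset.intersection(*masks)
    if not consensus:
        raise ValueError("consensus mask is empty: masks have no common features")
    return consensus


def scale_rows_by_mean(table: FeatureTable) -> FeatureTable:
    """Divide each subject's row by its own mean, the global-scaling step
    applied to perfusion images; every output row then has mean 1."""
    means = table.values.mean(axis=1)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"row mean must be strictly positive; subject "
            f"{table.subject_ids[bad[0]]!r} has mean {means[bad[0]]:g}"
        )
    return replace(table, values=table.values / means[:, None], units="a.u.")
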