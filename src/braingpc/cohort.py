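"""Synthetic case-control cohorts with the covariate structure the
analysis assumes.

The generative model is additive Gaussian per region:

    value(s, r) = baseline_r
                  + age_slope * (age_s - mean age)
                  + sex_effect * 1[sex_s = F]
                  + group effect (cases: effect_r;
                                  carriers: carrier_effect_scale * effect_r)
                  + family intercept ~ N(0, family_sd^2)   (family groups)
                  + N(0, noise_sd_r^2)

with ages uniform over an age range and sexes balanced within each group.
Residuals are independent across regions; an optional shared latent factor
adds uniform spatial covariance. Cases and carriers receive a negative
(thinning) effect vector, mimicking widespread cortical-thickness reduction
with stronger involvement of temporal and precentral regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .feature_io import FeatureTable, Group, Modality, Sex, SubjectRecord

__all__ = [
    "CohortSpec",
    "GeneratedCohort",
    "default_thinning_pattern",
    "default_region_names",
    "generate_cohort",
]

#: Indices (per hemisphere block of 34 Desikan-Killiany-style regions) that
#: receive the boosted effect: temporal-lobe regions and precentral gyrus.
_BOOSTED_WITHIN_HEMI = (5, 6, 8, 14, 23, 29, 32, 33)

_DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal",
    "lingual", "medialorbitofrontal", "middletemporal", "parahippocampal",
    "paracentral", "parsopercularis", "parsorbitalis", "parstriangularis",
    "pericalcarine", "postcentral", "posteriorcingulate", "precentral",
    "precuneus", "rostralanteriorcingulate", "rostralmiddlefrontal",
    "superiorfrontal", "superiorparietal", "superiortemporal",
    "supramarginal", "frontalpole", "temporalpole", "transversetemporal",
    "insula",
)
_TEMPORAL_PRECENTRAL = {
    "bankssts", "entorhinal", "fusiform", "inferiortemporal",
    "middletemporal", "parahippocampal", "superiortemporal",
    "temporalpole", "transversetemporal", "precentral",
}


def default_region_names(n_features: int) -> tuple[str, ...]:
    """Region names for a thickness table: lh/rh Desikan-Killiany names for
    n = 68, generic ``region_###`` otherwise."""
    if n_features == 68:
        return tuple(f"{h}_{r}" for h in ("lh", "rh") for r in _DK_REGIONS)
    return tuple(f"region_{i:03d}" for i in range(n_features))


def boosted_region_indices(n_features: int) -> tuple[int, ...]:
    """Indices of the strongly affected (temporal lobe + precentral) regions."""
    names = default_region_names(n_features)
    if n_features == 68:
        return tuple(
            i for i, n in enumerate(names) if n.split("_", 1)[1] in _TEMPORAL_PRECENTRAL
        )
    # generic fallback: first eighth of regions, at least one
    k = max(1, n_features // 8)
    return tuple(range(k))


def default_thinning_pattern(
    n_features: int,
    magnitude: float,
    boosted: Sequence[int] | None = None,
) -> np.ndarray:
    """Negative (thinning) effect vector: ``-magnitude`` everywhere, with a
    designated temporal/precentral subset boosted to ``-1.5 * magnitude``.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if boosted is None:
        boosted = boosted_region_indices(n_features)
    effect = np.full(n_features, -float(magnitude))
    idx = np.asarray(list(boosted), dtype=int)
    if idx.size:
        if idx.min() < 0 or idx.max() >= n_features:
            raise ValueError("boosted index out of range")
        effect[idx] = -1.5 * magnitude
    return effect


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a four-group study with healthy controls, patients and
    translocation carrier/noncarrier family members; regional scales follow
    typical cortical-thickness values (baseline ~2.5 mm, residual SD
    ~0.12 mm, thinning of age ~0.005 mm/year).
    """

    group_sizes: Mapping[Group, int] = field(
        default_factory=lambda: {
            Group.HC: 24,
            Group.SCZ: 24,
            Group.T_MINUS: 18,
            Group.T_PLUS: 12,
        }
    )
    n_features: int = 68
    baseline: float | np.ndarray = 2.5
    noise_sd: float | np.ndarray = 0.12
    effect: np.ndarray | None = None
    carrier_effect_scale: float = 1.0
    bp_effect_scale: float = 0.0
    age_range: tuple[float, float] = (20.0, 60.0)
    age_slope: float = -0.005
    sex_effect: float = -0.02
    family_sd: float = 0.0
    shared_factor_sd: float = 0.0
    modality: Modality = Modality.THICKNESS
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {Group(g): int(n) for g, n in self.group_sizes.items()}
        if any(n < 0 for n in sizes.values()):
            raise ValueError("group sizes must be nonnegative")
        if sum(sizes.values()) == 0:
            raise ValueError("cohort must contain at least one subject")
        object.__setattr__(self, "group_sizes", sizes)
        lo, hi = self.age_range
        if not lo < hi or lo <= 0:
            raise ValueError(f"invalid age_range {self.age_range}")
        noise = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_features,)
        )
        if np.any(noise <= 0):
            raise ValueError("noise_sd must be strictly positive")
        if self.effect is not None:
            eff = np.asarray(self.effect, dtype=float)
            if eff.shape != (self.n_features,):
                raise ValueError(
                    f"effect must have length n_features={self.n_features}"
                )
            object.__setattr__(self, "effect", eff)
        if self.family_sd < 0 or self.shared_factor_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class GeneratedCohort:
    table: FeatureTable
    records: tuple[SubjectRecord, ...]
    true_effect: np.ndarray

    def __post_init__(self) -> None:
        if len(self.records) != self.table.n_subjects:
            raise ValueError("record count must equal table row count")


_GROUP_EFFECT_SCALE = {
    Group.HC: 0.0,
    Group.T_MINUS: 0.0,
    Group.SCZ: 1.0,
}
_FAMILY_GROUPS = frozenset({Group.T_MINUS, Group.T_PLUS})


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Draw a cohort from the additive Gaussian model.

    Deterministic given the spec (including its seed): the same spec always
    yields a bit-identical table. Ages are uniform over ``age_range``; sexes
    alternate M/F within each group so group sex ratios are balanced.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = np.broadcast_to(
        np.asarray(spec.baseline, dtype=float), (spec.n_features,)
    )
    noise_sd = np.broadcast_to(
        np.asarray(spec.noise_sd, dtype=float), (spec.n_features,)
    )
    effect = (
        np.zeros(spec.n_features) if spec.effect is None else spec.effect
    )

    scale_by_group = dict(_GROUP_EFFECT_SCALE)
    scale_by_group[Group.T_PLUS] = spec.carrier_effect_scale
    scale_by_group[Group.BP] = spec.bp_effect_scale

    records: list[SubjectRecord] = []
    rows: list[np.ndarray] = []
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    family_intercepts: dict[str, float] = {}
    counter = 0
    for group in Group:  # fixed enum order keeps generation deterministic
        n = spec.group_sizes.get(group, 0)
        for k in range(n):
            counter += 1
            sid = f"s{counter:04d}"
            age = float(rng.uniform(*spec.age_range))
            sex = Sex.M if k % 2 == 0 else Sex.F
            family_id = None
            family_term = 0.0
            if group in _FAMILY_GROUPS:
                # default: one nuclear family per pair of consecutive subjects
                family_id = f"fam{counter // 2:03d}"
                if spec.family_sd > 0:
                    if family_id not in family_intercepts:
                        family_intercepts[family_id] = float(
                            rng.normal(0.0, spec.family_sd)
                        )
                    family_term = family_intercepts[family_id]
            row = (
                baseline
                + spec.age_slope * (age - mid_age)
                + (spec.sex_effect if sex is Sex.F else 0.0)
                + scale_by_group.get(group, 0.0) * effect
                + family_term
                + rng.normal(0.0, noise_sd)
            )
            if spec.shared_factor_sd > 0:
                row = row + rng.normal(0.0, spec.shared_factor_sd)
            rows.append(row)
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    age=age,
                    sex=sex,
                    etiv=float(rng.normal(1.5e6, 1.2e5)),
                    cpz_equiv=(
                        float(np.round(rng.uniform(0, 600)))
                        if group is Group.SCZ
                        else None
                    ),
                    panss_general=(
                        int(rng.integers(16, 41))
                        if group in (Group.SCZ, Group.T_PLUS, Group.T_MINUS)
                        else None
                    ),
                    family_id=family_id,
                )
            )

    table = FeatureTable(
        subject_ids=tuple(r.subject_id for r in records),
        feature_names=default_region_names(spec.n_features),
        values=np.vstack(rows),
        modality=spec.modality,
    )
    return GeneratedCohort(
        table=table, records=tuple(records), true_effect=np.array(effect)
    )
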