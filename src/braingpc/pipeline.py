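"""End-to-end study orchestration.

Runs the two machine-learning schemes on a set of modality feature tables:

* **Scheme A** — train case vs control (pLOOCV on age/sex-matched pairs),
  assess the cross-validated accuracy by training-label permutation, and —
  only when significant — refit on the full contrast and transfer the model
  to the family carrier/noncarrier groups (contingency table + Fisher exact
  test) and to the specificity cohort (bipolar patients).  Predictive
  probabilities are correlated with covariates (mean feature level, symptom
  score, medication dose, age, head size) with Cook-distance screening.
* **Scheme B** — downsample the noncarrier group to age/sex-match the
  carriers, then discriminate carriers from matched noncarriers directly
  with LOOCV and permutation inference.

Everything is driven by a single seed; rerunning the same configuration
reproduces the report byte for byte.  Every stochastic step and every
subject exclusion is appended to a provenance log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, default_thinning_pattern, generate_cohort
from .feature_io import (
    FeatureTable,
    Group,
    SubjectRecord,
    read_feature_table,
    read_subject_metadata,
)
from .gpc import extract_weights
from .stats import ContingencyTable, ScreenedCorrelation, cooks_screen, fisher_exact_2x2
from .validation import (
    PredictionResult,
    accuracy,
    auc,
    downsample_to_match,
    loocv,
    match_pairs,
    permutation_test,
    ploocv,
    transfer_predict,
)

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "CovariateReport",
    "contingency_from_predictions",
    "probability_covariate_report",
    "run_pipeline",
]


@dataclass(frozen=True)
class CovariateReport:
    """Screened correlation between P(positive class) and one covariate."""

    covariate: str
    corr: ScreenedCorrelation
    dropped_ids: tuple[str, ...]


def contingency_from_predictions(
    result: PredictionResult,
    true_groups: Sequence[str],
    row_order: tuple[str, str],
    col_labels: tuple[str, str] = ("HC", "SCZ"),
) -> ContingencyTable:
    """Cross-tabulate true group membership (rows) against the predicted
    class (columns, negative class first)."""
    if len(true_groups) == 0:
        raise ValueError("no predictions to tabulate")
    if len(true_groups) != len(result.subject_ids):
        raise ValueError("true_groups length must match predictions")
    unknown = set(true_groups) - set(row_order)
    if unknown:
        raise ValueError(f"unknown group tags: {sorted(unknown)}")
    pred = result.predicted_label
    counts = np.zeros((2, 2), dtype=int)
    for g, lab in zip(true_groups, pred):
        counts[row_order.index(g), 0 if lab < 0 else 1] += 1
    return ContingencyTable(counts=counts, row_labels=row_order, col_labels=col_labels)


def probability_covariate_report(
    result: PredictionResult,
    records: Sequence[SubjectRecord],
    covariate: str,
    cook_threshold: float = 0.5,
) -> CovariateReport:
    """Correlate per-subject P(positive) with a metadata covariate.

    Subjects lacking the covariate are dropped (and reported); at least 4
    usable subjects are required for the Cook-screened correlation.
    """
    by_id = {r.subject_id: r for r in records}
    xs, ps, dropped = [], [], []
    for sid, p in zip(result.subject_ids, result.p_positive):
        rec = by_id.get(sid)
        val = getattr(rec, covariate, None) if rec is not None else None
        if val is None:
            dropped.append(sid)
        else:
            xs.append(float(val))
            ps.append(float(p))
    if len(xs) < 4:
        raise ValueError(
            f"covariate {covariate!r}: only {len(xs)} usable subjects (need >= 4)"
        )
    try:
        corr = cooks_screen(np.array(xs), np.array(ps), threshold=cook_threshold)
    except ValueError as exc:
        raise ValueError(f"covariate {covariate!r}: {exc}") from exc
    return CovariateReport(
        covariate=covariate, corr=corr, dropped_ids=tuple(dropped)
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Declarative description of a full study run.

    Either ``simulate`` (per-modality synthetic cohort settings) or ``data``
    (per-modality feature-table paths plus a metadata path) must be given.
    """

    seed: int = 0
    n_perm: int = 1000
    alpha: float = 0.05
    optimize_hyperparameters: bool = False
    train_groups: tuple[str, str] = ("HC", "SCZ")  # (negative, positive)
    family_groups: tuple[str, str] = ("T_MINUS", "T_PLUS")
    specificity_group: str | None = "BP"
    scheme_b_n_keep: int | None = None
    covariates: tuple[str, ...] = ("age", "etiv", "panss_general", "cpz_equiv")
    simulate: dict | None = None
    data: dict | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("train_groups", "family_groups", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_groups(self, records: Sequence[SubjectRecord]) -> None:
        present = {r.group.value for r in records}
        needed = set(self.train_groups)
        for g in (*self.train_groups, *self.family_groups):
            Group(g)  # raises on undefined group names
        missing = needed - present
        if missing:
            raise ValueError(f"groups absent from cohort: {sorted(missing)}")


def _load_inputs(
    config: PipelineConfig, log: list[str]
) -> tuple[dict[str, FeatureTable], list[SubjectRecord]]:
    if (config.simulate is None) == (config.data is None):
        raise ValueError("config must set exactly one of 'simulate' or 'data'")
    if config.data is not None:
        meta = read_subject_metadata(config.data["metadata"])
        tables = {
            name: read_feature_table(path, modality=name)
            for name, path in config.data["tables"].items()
        }
        log.append(f"loaded {len(tables)} feature table(s) and metadata")
        return tables, meta
    sim = dict(config.simulate)
    modality = sim.pop("modality", "thickness")
    effect_magnitude = sim.pop("effect_magnitude", None)
    sim.setdefault("seed", config.seed)
    if "group_sizes" in sim:
        sim["group_sizes"] = {Group(g): n for g, n in sim["group_sizes"].items()}
    spec_kwargs = dict(sim)
    if effect_magnitude is not None:
        n_features = spec_kwargs.get("n_features", 68)
        spec_kwargs["effect"] = default_thinning_pattern(
            n_features, effect_magnitude
        )
    spec = CohortSpec(modality=modality, **spec_kwargs)
    cohort = generate_cohort(spec)
    log.append(
        f"simulated cohort: seed={spec.seed}, groups="
        + ", ".join(f"{g.value}:{n}" for g, n in spec.group_sizes.items())
    )
    return {modality: cohort.table}, list(cohort.records)


# ---------------------------------------------------------------------------
# report


@dataclass
class StudyReport:
    """All numbers the pipeline produces, JSON-serialisable."""

    config: dict
    modalities: dict = field(default_factory=dict)
    scheme_b: dict = field(default_factory=dict)
    log: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _screened_dict(rep: CovariateReport) -> dict:
    c = rep.corr
    return {
        "covariate": rep.covariate,
        "rho_all": c.rho_all,
        "p_all": c.p_all,
        "rho_screened": c.rho_screened,
        "p_screened": c.p_screened,
        "n_excluded": len(c.excluded_indices),
        "n_dropped_missing": len(rep.dropped_ids),
    }


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute scheme A and scheme B on every configured modality.

    Returns the report; when ``config.output_dir`` is set, also writes
    ``report.json``, per-subject probability CSVs, weight-table CSVs and a
    provenance log.  Deterministic given the configuration.
    """
    log: list[str] = []
    tables, records = _load_inputs(config, log)
    config.validate_groups(records)
    by_id = {r.subject_id: r for r in records}
    neg_name, pos_name = config.train_groups
    fam_neg, fam_pos = config.family_groups
    gpc_options = {"optimize_hyperparameters": config.optimize_hyperparameters}

    outputs: dict[str, pd.DataFrame] = {}
    report = StudyReport(
        config={
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "train_groups": list(config.train_groups),
            "family_groups": list(config.family_groups),
        },
        log=log,
    )

    for modality, table in tables.items():
        stage = f"scheme A [{modality}]"
        try:
            entry = _run_scheme_a(
                table, records, by_id, config, gpc_options, log, outputs, modality
            )
        except Exception as exc:
            raise RuntimeError(f"{stage} failed: {exc}") from exc
        report.modalities[modality] = entry

        stage = f"scheme B [{modality}]"
        try:
            report.scheme_b[modality] = _run_scheme_b(
                table, records, config, gpc_options, log, outputs, modality
            )
        except Exception as exc:
            raise RuntimeError(f"{stage} failed: {exc}") from exc

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        for name, df in outputs.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "provenance.log").write_text("\n".join(log) + "\n")
    return report


def _rows_for(table: FeatureTable, ids: Sequence[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(table.subject_ids)}
    return table.values[[index[s] for s in ids]]


def _run_scheme_a(
    table, records, by_id, config, gpc_options, log, outputs, modality
) -> dict:
    neg_name, pos_name = config.train_groups
    neg = [r for r in records if r.group.value == neg_name]
    pos = [r for r in records if r.group.value == pos_name]
    pairs = match_pairs(neg, pos)
    log.append(
        f"[{modality}] matched {len(pairs.pairs)} {neg_name}/{pos_name} pairs, "
        f"mean |age gap| {pairs.mean_abs_age_gap:.2f} y"
    )
    # combined design: matched controls first, then cases
    neg_ids = [neg[i].subject_id for i, _ in pairs.pairs]
    pos_ids = [pos[j].subject_id for _, j in pairs.pairs]
    ids = neg_ids + pos_ids
    X = _rows_for(table, ids)
    y = np.array([-1.0] * len(neg_ids) + [1.0] * len(pos_ids))
    n_pairs = len(pairs.pairs)
    pair_idx = [(k, n_pairs + k) for k in range(n_pairs)]

    def procedure(rng):
        res = ploocv(X, y, pair_idx, gpc_options, subject_ids=ids, shuffle_train=rng)
        return accuracy(res)

    cv = ploocv(X, y, pair_idx, gpc_options, subject_ids=ids)
    perm = permutation_test(procedure, n_perm=config.n_perm, seed=config.seed)
    log.append(
        f"[{modality}] pLOOCV acc {perm.observed_accuracy:.1f}%, "
        f"perm p = {perm.p_value:.4g} ({config.n_perm} rounds, seed {config.seed})"
    )
    entry: dict = {
        "cv": {
            "accuracy": accuracy(cv),
            "auc": auc(cv),
            "permutation_p": perm.p_value,
            "null_accuracy_mean": float(np.mean(perm.null_accuracies)),
            "n_perm": perm.n_perm,
        },
        "n_pairs": n_pairs,
    }
    outputs[f"probabilities_cv_{modality}"] = pd.DataFrame(
        {"subject_id": cv.subject_ids, "p_positive": cv.p_positive,
         "true_label": cv.true_label}
    )

    # medication correlation uses the patients' cross-validated probabilities
    cpz_ids = [s for s in pos_ids if by_id[s].cpz_equiv is not None]
    if len(cpz_ids) >= 4:
        sub = PredictionResult(
            subject_ids=tuple(pos_ids),
            p_positive=cv.p_positive[len(neg_ids):],
        )
        try:
            entry["cpz_correlation"] = _screened_dict(
                probability_covariate_report(sub, records, "cpz_equiv")
            )
        except ValueError as exc:
            log.append(f"[{modality}] cpz correlation skipped: {exc}")

    significant = perm.p_value < config.alpha
    entry["transfer_performed"] = bool(significant)
    if not significant:
        log.append(
            f"[{modality}] permutation p >= {config.alpha}: transfer withheld"
        )
        return entry

    # refit on the full training contrast, transfer to family groups
    fam_neg, fam_pos = config.family_groups
    fam_records = [r for r in records if r.group.value in (fam_neg, fam_pos)]
    if fam_records:
        fam_ids = [r.subject_id for r in fam_records]
        res, model, scaler = transfer_predict(
            X, y, _rows_for(table, fam_ids), gpc_options,
            subject_ids=fam_ids, return_model=True,
        )
        groups = [by_id[s].group.value for s in fam_ids]
        ct = contingency_from_predictions(
            res, groups, row_order=(fam_neg, fam_pos),
            col_labels=(neg_name, pos_name),
        )
        fisher_p = fisher_exact_2x2(ct)
        entry["family_transfer"] = {
            "counts": ct.counts,
            "row_labels": list(ct.row_labels),
            "col_labels": list(ct.col_labels),
            "row_percentages": ct.row_percentages,
            "fisher_p": fisher_p,
        }
        log.append(
            f"[{modality}] family transfer: counts {ct.counts.tolist()}, "
            f"Fisher p = {fisher_p:.4g}"
        )
        outputs[f"probabilities_family_{modality}"] = pd.DataFrame(
            {"subject_id": res.subject_ids, "group": groups,
             "p_positive": res.p_positive}
        )
        # covariate correlations on the family cohort
        mean_feature = _rows_for(table, fam_ids).mean(axis=1)
        corr = cooks_screen(mean_feature, res.p_positive)
        entry["mean_feature_correlation"] = {
            "rho_all": corr.rho_all, "p_all": corr.p_all,
            "rho_screened": corr.rho_screened, "p_screened": corr.p_screened,
            "n_excluded": len(corr.excluded_indices),
        }
        entry["covariate_correlations"] = {}
        for cov in config.covariates:
            if cov == "cpz_equiv":
                continue  # handled on the patient group above
            try:
                rep = probability_covariate_report(res, records, cov)
            except ValueError as exc:
                log.append(f"[{modality}] covariate {cov}: skipped ({exc})")
                continue
            entry["covariate_correlations"][cov] = _screened_dict(rep)
            if rep.corr.excluded_indices:
                excl = [fam_ids[i] for i in rep.corr.excluded_indices]
                log.append(
                    f"[{modality}] covariate {cov}: Cook-excluded {excl}"
                )

        # weight map of the full-contrast model
        wm = extract_weights(model, feature_names=table.feature_names)
        outputs[f"weights_{modality}"] = pd.DataFrame(
            {"feature": wm.feature_names, "weight": wm.weights}
        )
        entry["weights_negative_fraction"] = float(np.mean(wm.weights < 0))

    # specificity cohort
    if config.specificity_group:
        spec_ids = [
            r.subject_id for r in records
            if r.group.value == config.specificity_group
        ]
        if spec_ids:
            res_bp = transfer_predict(
                X, y, _rows_for(table, spec_ids), gpc_options,
                subject_ids=spec_ids,
            )
            frac_pos = float(np.mean(res_bp.predicted_label > 0) * 100)
            entry["specificity"] = {
                "group": config.specificity_group,
                "n": len(spec_ids),
                "percent_assigned_positive": frac_pos,
            }
            log.append(
                f"[{modality}] specificity ({config.specificity_group}): "
                f"{frac_pos:.1f}% assigned {pos_name}"
            )
            outputs[f"probabilities_{config.specificity_group}_{modality}"] = (
                pd.DataFrame({"subject_id": res_bp.subject_ids,
                              "p_positive": res_bp.p_positive})
            )
    return entry


def _run_scheme_b(
    table, records, config, gpc_options, log, outputs, modality
) -> dict:
    fam_neg, fam_pos = config.family_groups
    tm = [r for r in records if r.group.value == fam_neg]
    tp = [r for r in records if r.group.value == fam_pos]
    if not tm or not tp:
        log.append(f"[{modality}] scheme B skipped: family groups absent")
        return {"skipped": True}
    n_keep = config.scheme_b_n_keep
    if n_keep is None:
        n_keep = min(len(tm), len(tp) + 2)
    keep = downsample_to_match(tm, tp, n_keep)
    kept_ids = [tm[i].subject_id for i in keep]
    log.append(
        f"[{modality}] scheme B: downsampled {fam_neg} {len(tm)} -> "
        f"{len(keep)} matched to {fam_pos} (n={len(tp)})"
    )
    ids = kept_ids + [r.subject_id for r in tp]
    X = _rows_for(table, ids)
    y = np.array([-1.0] * len(kept_ids) + [1.0] * len(tp))

    def procedure(rng):
        return accuracy(
            loocv(X, y, gpc_options, subject_ids=ids, shuffle_train=rng)
        )

    cv = loocv(X, y, gpc_options, subject_ids=ids)
    perm = permutation_test(procedure, n_perm=config.n_perm, seed=config.seed + 1)
    log.append(
        f"[{modality}] scheme B LOOCV acc {perm.observed_accuracy:.1f}%, "
        f"perm p = {perm.p_value:.4g}"
    )
    outputs[f"probabilities_schemeB_{modality}"] = pd.DataFrame(
        {"subject_id": cv.subject_ids, "p_positive": cv.p_positive,
         "true_label": cv.true_label}
    )
    return {
        "n_neg": len(kept_ids),
        "n_pos": len(tp),
        "accuracy": accuracy(cv),
        "auc": auc(cv),
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
    }
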