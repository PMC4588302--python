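"""Matching, cross-validation, transfer prediction and permutation inference.

Design of the two evaluation schemes:

* **Paired leave-one-out CV (pLOOCV)** — cases and controls are first
  matched into age/sex pairs; each fold holds out one whole pair and trains
  on the rest, so the folds stay class-balanced and the held-out pair never
  touches its fold's feature standardization.
* **LOOCV** — ordinary one-subject folds, used when the two groups are not
  equally sized and pairing is not meaningful.
* **Transfer prediction** — a model trained on one contrast is applied
  unchanged (including its standardization statistics) to an independent
  cohort, yielding one class probability per test subject.

Significance of a cross-validated accuracy is assessed by permutation:
training labels are shuffled, the whole train→test procedure is re-run, and
the observed accuracy is compared with the null distribution.  The p-value
is the fraction of null accuracies at least as large as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .feature_io import Sex, SubjectRecord
from .gpc import GPCModel, fit_gpc, predict_proba

__all__ = [
    "MatchedPairs",
    "PredictionResult",
    "PermutationResult",
    "FoldScaler",
    "match_pairs",
    "downsample_to_match",
    "ploocv",
    "loocv",
    "transfer_predict",
    "accuracy",
    "auc",
    "permutation_test",
]


@dataclass(frozen=True)
class MatchedPairs:
    """Index pairs (into group A and group B) of same-sex, age-matched
    subjects, plus the achieved mean absolute age gap in years."""

    pairs: tuple[tuple[int, int], ...]
    mean_abs_age_gap: float


@dataclass(frozen=True)
class PredictionResult:
    """Per-subject probabilistic predictions.

    ``p_positive`` is P(class = +1) — in the case-control contrast this is
    the probability of belonging to the patient class, P(SCZ).  Predicted
    labels threshold the probability at 0.5 (the symmetric point of the ±1
    coding).  ``true_label`` may be None for transfer runs onto cohorts
    outside the training contrast.
    """

    subject_ids: tuple[str, ...]
    p_positive: np.ndarray
    true_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p_positive, dtype=float)
        object.__setattr__(self, "p_positive", p)
        if len(self.subject_ids) != p.size:
            raise ValueError("subject_ids and p_positive lengths differ")
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("probabilities must lie strictly in (0, 1)")
        if self.true_label is not None:
            t = np.asarray(self.true_label, dtype=float)
            if t.size != p.size:
                raise ValueError("true_label length mismatch")
            object.__setattr__(self, "true_label", t)

    @property
    def predicted_label(self) -> np.ndarray:
        return np.where(self.p_positive >= 0.5, 1.0, -1.0)


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        null = np.asarray(self.null_accuracies, dtype=float)
        object.__setattr__(self, "null_accuracies", null)
        if null.size != self.n_perm:
            raise ValueError("null_accuracies length must equal n_perm")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value out of [0, 1]")


# ---------------------------------------------------------------------------
# matching


def _sex_of(r: SubjectRecord) -> Sex:
    return r.sex


def match_pairs(
    group_a: Sequence[SubjectRecord], group_b: Sequence[SubjectRecord]
) -> MatchedPairs:
    """Pair every subject of group B with a same-sex group-A subject of
    nearest age (greedy, B visited in age order, age ties broken by
    subject_id for determinism). Requires group A to have at least as many
    subjects of each sex as group B."""
    used_a: set[int] = set()
    pairs: list[tuple[int, int]] = []
    gaps: list[float] = []
    for sex in (Sex.M, Sex.F):
        b_idx = [i for i, r in enumerate(group_b) if r.sex is sex]
        a_idx = [i for i, r in enumerate(group_a) if r.sex is sex]
        if len(a_idx) < len(b_idx):
            raise ValueError(
                f"cannot match: group A has {len(a_idx)} subjects of sex "
                f"{sex.value}, group B needs {len(b_idx)}"
            )
        b_idx.sort(key=lambda i: (group_b[i].age, group_b[i].subject_id))
        for bi in b_idx:
            best = min(
                (ai for ai in a_idx if ai not in used_a),
                key=lambda ai: (
                    abs(group_a[ai].age - group_b[bi].age),
                    group_a[ai].subject_id,
                ),
            )
            used_a.add(best)
            pairs.append((best, bi))
            gaps.append(abs(group_a[best].age - group_b[bi].age))
    pairs.sort(key=lambda p: p[1])
    return MatchedPairs(
        pairs=tuple(pairs),
        mean_abs_age_gap=float(np.mean(gaps)) if gaps else 0.0,
    )


def downsample_to_match(
    group: Sequence[SubjectRecord],
    reference: Sequence[SubjectRecord],
    n_keep: int,
) -> tuple[int, ...]:
    """Pick the ``n_keep`` group members best matching the reference cohort
    for age and sex (greedy nearest-age within sex).

    Sex slots are allocated proportionally to the reference sex mix (largest
    remainder), capped by availability; within each sex, candidates closest
    in age to any reference subject of that sex are kept first.
    """
    if n_keep > len(group):
        raise ValueError(f"n_keep={n_keep} exceeds group size {len(group)}")
    if n_keep == len(group):
        return tuple(range(len(group)))
    avail = {s: [i for i, r in enumerate(group) if r.sex is s] for s in Sex}
    ref_n = {s: sum(1 for r in reference if r.sex is s) for s in Sex}
    total_ref = sum(ref_n.values())
    if total_ref == 0:
        raise ValueError("reference cohort is empty")
    # proportional allocation, capped by availability
    quota = {s: n_keep * ref_n[s] / total_ref for s in Sex}
    keep_n = {s: min(int(np.floor(quota[s])), len(avail[s])) for s in Sex}
    order = sorted(Sex, key=lambda s: quota[s] - np.floor(quota[s]), reverse=True)
    while sum(keep_n.values()) < n_keep:
        for s in order:
            if keep_n[s] < len(avail[s]) and sum(keep_n.values()) < n_keep:
                keep_n[s] += 1
        if all(keep_n[s] >= len(avail[s]) for s in Sex):
            break
    if sum(keep_n.values()) < n_keep:
        raise ValueError("not enough subjects to downsample to n_keep")

    kept: list[int] = []
    for s in Sex:
        ref_ages = sorted(r.age for r in reference if r.sex is s)
        if not ref_ages:
            ref_ages = sorted(r.age for r in reference)
        chosen: list[int] = []
        pool = list(avail[s])
        # cycle through the reference ages, each claiming its nearest unused
        # candidate, until the sex quota is filled
        while len(chosen) < keep_n[s]:
            for a in ref_ages:
                if len(chosen) >= keep_n[s] or not pool:
                    break
                best = min(
                    pool,
                    key=lambda i: (abs(group[i].age - a), group[i].subject_id),
                )
                pool.remove(best)
                chosen.append(best)
        kept.extend(chosen)
    return tuple(sorted(kept))


# ---------------------------------------------------------------------------
# fold-safe standardization


class FoldScaler:
    """Per-feature z-scoring with statistics from training rows only.

    Centering doubles as the model's offset handling (the kernel has no
    bias term), and using training statistics alone keeps held-out subjects
    out of their own fold's preprocessing.  Zero-variance features are
    centered but not scaled.
    """

    def __init__(self, X_train: np.ndarray):
        X_train = np.asarray(X_train, dtype=float)
        self.mean_ = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


# ---------------------------------------------------------------------------
# cross-validation


def _fit_fold(X_train, y_train, X_test, gpc_options) -> np.ndarray:
    scaler = FoldScaler(X_train)
    model = fit_gpc(scaler.transform(X_train), y_train, **gpc_options)
    return predict_proba(model, scaler.transform(X_test))


def _as_ids(subject_ids, n):
    if subject_ids is None:
        return tuple(f"row{i}" for i in range(n))
    if len(subject_ids) != n:
        raise ValueError("subject_ids length mismatch")
    return tuple(subject_ids)


def ploocv(
    X: np.ndarray,
    y: np.ndarray,
    pairs: MatchedPairs | Sequence[tuple[int, int]],
    gpc_options: dict | None = None,
    subject_ids: Sequence[str] | None = None,
    shuffle_train: np.random.Generator | None = None,
) -> PredictionResult:
    """Paired leave-one-out cross-validation.

    ``pairs`` holds (row index, row index) tuples covering every row of X
    exactly once; one fold is run per pair.  With ``shuffle_train`` set,
    the training labels of every fold are freshly permuted (the permutation
    null); test labels are never touched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pair_list = list(pairs.pairs if isinstance(pairs, MatchedPairs) else pairs)
    covered = [i for p in pair_list for i in p]
    if sorted(covered) != list(range(X.shape[0])):
        uncovered = set(range(X.shape[0])) - set(covered)
        raise ValueError(
            f"pairs must cover every subject exactly once; "
            f"problem rows: {sorted(uncovered) or sorted(covered)}"
        )
    gpc_options = gpc_options or {}
    ids = _as_ids(subject_ids, X.shape[0])
    p = np.empty(X.shape[0])
    for i, j in pair_list:
        test_idx = [i, j]
        train_idx = [k for k in range(X.shape[0]) if k not in (i, j)]
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            raise ValueError("a training fold contains a single class")
        if shuffle_train is not None:
            y_train = shuffle_train.permutation(y_train)
        p[test_idx] = _fit_fold(X[train_idx], y_train, X[test_idx], gpc_options)
    return PredictionResult(subject_ids=ids, p_positive=p, true_label=y)


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    gpc_options: dict | None = None,
    subject_ids: Sequence[str] | None = None,
    shuffle_train: np.random.Generator | None = None,
) -> PredictionResult:
    """Leave-one-out cross-validation with single-subject folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gpc_options = gpc_options or {}
    ids = _as_ids(subject_ids, X.shape[0])
    p = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        train_idx = [k for k in range(X.shape[0]) if k != i]
        y_train = y[train_idx]
        if np.unique(y_train).size < 2:
            raise ValueError("a training fold contains a single class")
        if shuffle_train is not None:
            y_train = shuffle_train.permutation(y_train)
        p[i] = _fit_fold(X[train_idx], y_train, X[[i]], gpc_options)[0]
    return PredictionResult(subject_ids=ids, p_positive=p, true_label=y)


def transfer_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    gpc_options: dict | None = None,
    subject_ids: Sequence[str] | None = None,
    true_label: np.ndarray | None = None,
    shuffle_train: np.random.Generator | None = None,
    return_model: bool = False,
):
    """Train on one full contrast, predict an independent cohort.

    The training-set standardization statistics are applied unchanged to
    the test rows; the test cohort has no influence on the fit.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[1] != X_train.shape[1]:
        raise ValueError(
            f"feature mismatch: train has {X_train.shape[1]}, "
            f"test has {X_test.shape[1]}"
        )
    y_train = np.asarray(y_train, dtype=float)
    if shuffle_train is not None:
        y_train = shuffle_train.permutation(y_train)
    scaler = FoldScaler(X_train)
    model = fit_gpc(scaler.transform(X_train), y_train, **(gpc_options or {}))
    p = predict_proba(model, scaler.transform(X_test))
    result = PredictionResult(
        subject_ids=_as_ids(subject_ids, X_test.shape[0]),
        p_positive=p,
        true_label=true_label,
    )
    return (result, model, scaler) if return_model else result


# ---------------------------------------------------------------------------
# metrics


def accuracy(result: PredictionResult) -> float:
    """Percent of subjects whose thresholded prediction matches the truth."""
    if result.true_label is None:
        raise ValueError("true labels required for accuracy")
    return float(np.mean(result.predicted_label == result.true_label) * 100.0)


def auc(result: PredictionResult) -> float:
    """Area under the ROC curve of p_positive against the ±1 truth — the
    Mann–Whitney probability that a random positive outranks a random
    negative, with ties counted one half."""
    if result.true_label is None:
        raise ValueError("true labels required for AUC")
    truth = result.true_label
    if np.unique(truth).size < 2:
        raise ValueError("AUC undefined for single-class truth")
    return float(roc_auc_score((truth > 0).astype(int), result.p_positive))


# ---------------------------------------------------------------------------
# permutation inference


def permutation_test(
    procedure: Callable[[np.random.Generator | None], float],
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation significance of a train→test accuracy.

    ``procedure(rng)`` must run the full pipeline and return an accuracy in
    percent; with ``rng=None`` it uses the true training labels (the
    observed statistic), otherwise it must use ``rng`` to shuffle its
    training labels.  Each permutation round receives an independent
    counter-derived stream of the top-level seed, so rounds are reproducible
    regardless of execution order.

    The p-value is the plain fraction of null accuracies ≥ observed
    (``count / n_perm``, which can reach exactly 0); ``add_one`` switches to
    the (count+1)/(n_perm+1) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(procedure(None))
    if not np.isfinite(observed):
        raise ValueError("procedure returned non-finite observed accuracy")
    null = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        null[b] = procedure(rng)
    if not np.all(np.isfinite(null)):
        raise ValueError("procedure returned non-finite null accuracy")
    count = int(np.sum(null >= observed))
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )
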