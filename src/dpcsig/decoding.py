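"""Bootstrap out-of-sample decoding of imagined support vs. self-feel.

Every resample refits dPCA, feature standardization, and the logistic model on
the training portion only, so no test-set information leaks into the decoder.
Class imbalance (56/44 by design) is handled with a uniform prior
(inverse-frequency class weights), and the reported accuracy is balanced
accuracy so chance is 0.5 regardless of prevalence.  Significance comes from a
label-permutation null run through the identical resampling procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import fbeta_score, roc_auc_score

from .dpca import (DpcaModel, _fit_signature_arrays, _project_arrays, _stack,
                   project_trials)
from .synthetic import CONDITION_SUPPORT, TrialRecord

__all__ = [
    "DecodingError",
    "DecodingResult",
    "AccuracyComparison",
    "trial_features",
    "bootstrap_decode",
    "compare_accuracies",
]

METRICS = ("accuracy", "sensitivity", "specificity", "auc", "f2")


class DecodingError(ValueError):
    pass


@dataclass
class DecodingResult:
    """Per-replicate out-of-sample metrics plus the null-calibrated p-value."""

    replicates: pd.DataFrame
    mean_accuracy: float
    p_value: Optional[float]
    B: int
    mode: str
    scheme: str
    seed: int
    train_frac: float
    n_permutations: int = 0
    null_mean_accuracies: Optional[np.ndarray] = None


@dataclass
class AccuracyComparison:
    delta: float
    p_value: float
    B: int


def trial_features(trials: Sequence[TrialRecord], mode: str = "dpc",
                   model: Optional[DpcaModel] = None) -> pd.DataFrame:
    """Per-trial feature table (unstandardized).

    ``dpc`` mode yields the n_timepoints-long dPC expression time course;
    ``mean_activity`` yields the per-parcel time mean (n_parcels features).
    Standardization is left to the caller so it can use training statistics
    only.
    """
    if mode == "dpc":
        if model is None:
            raise DecodingError("dpc mode requires a fitted DpcaModel")
        features = project_trials(model, trials)
    elif mode == "mean_activity":
        features = np.stack([t.data.mean(axis=1) for t in trials])
    else:
        raise DecodingError(f"mode must be 'dpc' or 'mean_activity', got {mode!r}")
    table = pd.DataFrame(features, columns=[f"f{j}" for j in range(features.shape[1])])
    table.insert(0, "participant_id", [t.participant_id for t in trials])
    table.insert(1, "condition", [t.condition for t in trials])
    return table


def _labels(trials: Sequence[TrialRecord]) -> np.ndarray:
    return np.array([1 if t.condition == CONDITION_SUPPORT else 0 for t in trials])


def _draw_splits(trials: Sequence[TrialRecord], y: np.ndarray, B: int,
                 train_frac: float, group_by_participant: bool,
                 rng: np.random.Generator,
                 max_redraw: int = 200) -> List[Tuple[np.ndarray, np.ndarray]]:
    n = len(trials)
    idx = np.arange(n)
    participants = np.array([t.participant_id for t in trials])
    groups = np.unique(participants)
    splits: List[Tuple[np.ndarray, np.ndarray]] = []
    redraws = 0
    while len(splits) < B:
        if group_by_participant:
            n_train = max(1, min(len(groups) - 1, int(round(train_frac * len(groups)))))
            perm = rng.permutation(groups)
            train_mask = np.isin(participants, perm[:n_train])
        else:
            n_train = max(1, min(n - 1, int(round(train_frac * n))))
            perm = rng.permutation(idx)
            train_mask = np.zeros(n, dtype=bool)
            train_mask[perm[:n_train]] = True
        train_idx, test_idx = idx[train_mask], idx[~train_mask]
        if (len(np.unique(y[train_idx])) < 2) or (len(np.unique(y[test_idx])) < 2):
            redraws += 1
            if redraws > max_redraw:
                raise DecodingError(
                    "could not draw a split with both classes on both sides "
                    f"after {max_redraw} redraws")
            continue
        splits.append((train_idx, test_idx))
    if redraws:
        warnings.warn(f"redrew {redraws} split(s) with a single-class side",
                      RuntimeWarning, stacklevel=3)
    return splits


def _replicate_metrics(data: np.ndarray, mean_activity: np.ndarray, y: np.ndarray,
                       train_idx: np.ndarray, test_idx: np.ndarray, mode: str,
                       lam: Optional[float], C: float,
                       full_metrics: bool = True) -> Optional[Dict[str, float]]:
    y_train, y_test = y[train_idx], y[test_idx]
    if len(np.unique(y_train)) < 2:
        return None
    if mode == "dpc":
        train_mask = np.zeros(len(y), dtype=bool)
        train_mask[train_idx] = True
        model = _fit_signature_arrays(data, y == 1, lam=lam,
                                      weights=train_mask.astype(float))
        z_all = _project_arrays(model, data)
        x_train, x_test = z_all[train_idx], z_all[test_idx]
    else:
        x_train = mean_activity[train_idx]
        x_test = mean_activity[test_idx]
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    if not np.all(np.isfinite(x_train)) or float(np.abs(x_train).max(initial=0.0)) == 0.0:
        raise DecodingError("degenerate features: training features are all zero")
    x_train = (x_train - mean) / sd
    x_test = (x_test - mean) / sd
    clf = LogisticRegression(class_weight="balanced", C=C, solver="lbfgs",
                             max_iter=1000)
    with config_context(assume_finite=True):
        clf.fit(x_train, y_train)
    scores = x_test @ clf.coef_[0] + clf.intercept_[0]
    pred = (scores > 0).astype(int)
    pos, neg = y_test == 1, y_test == 0
    sensitivity = float((pred[pos] == 1).mean()) if pos.any() else np.nan
    specificity = float((pred[neg] == 0).mean()) if neg.any() else np.nan
    accuracy = float(np.nanmean([sensitivity, specificity]))
    if not full_metrics:
        return {"accuracy": accuracy}
    auc = float(roc_auc_score(y_test, scores)) if pos.any() and neg.any() else np.nan
    f2 = float(fbeta_score(y_test, pred, beta=2.0, pos_label=1, zero_division=0))
    return {"accuracy": accuracy, "sensitivity": sensitivity,
            "specificity": specificity, "auc": auc, "f2": f2}


def _kfold_splits(trials: Sequence[TrialRecord], y: np.ndarray, k: int,
                  group_by_participant: bool,
                  rng: np.random.Generator) -> List[Tuple[np.ndarray, np.ndarray]]:
    n = len(trials)
    idx = np.arange(n)
    if group_by_participant:
        participants = np.array([t.participant_id for t in trials])
        units = rng.permutation(np.unique(participants))
        folds = [np.flatnonzero(np.isin(participants, part))
                 for part in np.array_split(units, k)]
    else:
        folds = np.array_split(rng.permutation(idx), k)
    splits = []
    for fold in folds:
        test_idx = np.sort(fold)
        train_idx = np.setdiff1d(idx, test_idx)
        if (len(np.unique(y[train_idx])) < 2) or (len(np.unique(y[test_idx])) < 2):
            raise DecodingError(
                "a cross-validation fold has a single-class side; "
                "use fewer folds or more trials")
        splits.append((train_idx, test_idx))
    return splits


def bootstrap_decode(trials: Sequence[TrialRecord], mode: str = "dpc",
                     B: int = 1000, train_frac: float = 0.9,
                     group_by_participant: bool = True, seed: int = 0,
                     n_permutations: int = 0, lam: Optional[float] = None,
                     C: float = 1.0,
                     splits: Optional[Sequence[Tuple[np.ndarray, np.ndarray]]] = None,
                     kfold: Optional[int] = None) -> DecodingResult:
    """Bootstrap out-of-sample decoding with leakage-free per-replicate refits.

    Each of ``B`` replicates draws a fresh train/test split (by participant by
    default, trial-wise otherwise), refits the dPC signature on the training
    side only, and scores held-out trials with a balanced logistic model.  With
    ``n_permutations > 0`` the mean accuracy is referred to a label-permutation
    null built with the identical splits, giving
    p = (1 + #{null >= observed}) / (n_permutations + 1).  Deterministic given
    ``seed``.

    ``kfold=k`` switches the resampling engine to one pass of k-fold
    cross-validation (disjoint test folds, B := k); the bootstrap remains the
    primary engine for significance testing.
    """
    if mode not in ("dpc", "mean_activity"):
        raise DecodingError(f"mode must be 'dpc' or 'mean_activity', got {mode!r}")
    if B < 1:
        raise DecodingError(f"B must be >= 1, got {B!r}")
    if not (0.0 < train_frac < 1.0):
        raise DecodingError(f"train_frac must be in (0, 1), got {train_frac!r}")
    y = _labels(trials)
    if len(np.unique(y)) < 2:
        raise DecodingError("both conditions must be present in the trials")

    rng = np.random.default_rng(seed)
    grouping = "participant" if group_by_participant else "trial"
    if splits is None and kfold is not None:
        if kfold < 2:
            raise DecodingError(f"kfold must be >= 2, got {kfold!r}")
        splits = _kfold_splits(trials, y, kfold, group_by_participant, rng)
        B = kfold
        scheme = f"kfold(k={kfold},grouping={grouping})"
    elif splits is None:
        splits = _draw_splits(trials, y, B, train_frac, group_by_participant, rng)
        scheme = f"bootstrap(train_frac={train_frac},grouping={grouping})"
    else:
        splits = [(np.asarray(a), np.asarray(b)) for a, b in splits]
        if len(splits) != B:
            raise DecodingError(f"{len(splits)} fixed splits provided for B={B}")
        scheme = "fixed-splits"

    data, _ = _stack(trials)
    mean_activity = data.mean(axis=2)

    rows = []
    for train_idx, test_idx in splits:
        metrics = _replicate_metrics(data, mean_activity, y, train_idx, test_idx,
                                     mode, lam, C)
        if metrics is None:
            raise DecodingError("a provided split has a single-class training set")
        rows.append(metrics)
    replicates = pd.DataFrame(rows, columns=list(METRICS))
    mean_accuracy = float(replicates["accuracy"].mean())

    p_value = None
    null_means = None
    if n_permutations > 0:
        null_means = np.empty(n_permutations)
        for k in range(n_permutations):
            y_perm = rng.permutation(y)
            accs = []
            for train_idx, test_idx in splits:
                metrics = _replicate_metrics(data, mean_activity, y_perm, train_idx,
                                             test_idx, mode, lam, C,
                                             full_metrics=False)
                accs.append(np.nan if metrics is None else metrics["accuracy"])
            null_means[k] = np.nanmean(accs)
        p_value = float((1 + np.sum(null_means >= mean_accuracy)) / (n_permutations + 1))

    return DecodingResult(replicates=replicates, mean_accuracy=mean_accuracy,
                          p_value=p_value, B=B, mode=mode, scheme=scheme,
                          seed=seed, train_frac=train_frac,
                          n_permutations=n_permutations,
                          null_mean_accuracies=null_means)


def compare_accuracies(result_a: DecodingResult, result_b: DecodingResult,
                       n_resamples: int = 2000, seed: int = 0) -> AccuracyComparison:
    """Paired comparison of per-replicate accuracies via a sign-flip test.

    Requires matched replicate counts and split schemes; when the two results
    were produced with the same seed and scheme, replicates are paired by the
    shared resample indices.  Self-comparison yields delta = 0, p = 1.
    """
    if result_a.B != result_b.B:
        raise DecodingError(f"replicate counts differ: {result_a.B} vs {result_b.B}")
    if result_a.scheme != result_b.scheme:
        raise DecodingError(
            f"split schemes differ: {result_a.scheme!r} vs {result_b.scheme!r}")
    diffs = (result_a.replicates["accuracy"].to_numpy()
             - result_b.replicates["accuracy"].to_numpy())
    delta = float(diffs.mean())
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_resamples, len(diffs)))
    null = (flips * diffs).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(delta))) / (n_resamples + 1))
    return AccuracyComparison(delta=delta, p_value=p, B=result_a.B)
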