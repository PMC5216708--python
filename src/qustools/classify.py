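"""KNN response classification: LOOCV, class re-balancing, exhaustive subset search.

The response classifier is a k-nearest-neighbor vote (default k=2, Euclidean
distance) evaluated with leave-one-PATIENT-out cross-validation.  Class
imbalance (typically ~42 responders vs 16 non-responders) is compensated by
sampling responders with replacement down to the non-responder count; the
whole evaluation is repeated (default 10 resamples) and performance reported
as mean +- SD of sensitivity, specificity and accuracy.  Feature selection is
an exhaustive search over all subsets of sizes 2..7 of the seven QUS features
(C(7,2)+...+C(7,7) = 120 subsets).

Numerical conventions (the study description leaves these open; they are fixed
here and documented):

* features are z-scored per LOOCV training fold before distances are taken
  (Euclidean distance across dBr / mm / dB-cm-MHz units is meaningless
  unscaled);
* a k=2 split vote falls back to the class of the single nearest neighbor;
  exact distance ties break toward the lower training index;
* when a patient drawn multiple times by the resampling is held out, *all*
  copies leave the training fold (leave-one-patient-out, leakage-free).  The
  optimistic alternative (copies stay) is available via
  ``remove_duplicates=False`` for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .clinical import NON_RESPONDER, RESPONDER

__all__ = [
    "KNNConfig",
    "PerformanceSummary",
    "knn_predict",
    "loocv",
    "balance_and_evaluate",
    "exhaustive_feature_search",
]


@dataclass(frozen=True)
class KNNConfig:
    """k (default 2), Euclidean metric, nearest-neighbor tie rule."""

    k: int = 2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class PerformanceSummary:
    """Mean +- SD (over resampling repeats) of sensitivity/specificity/accuracy, %."""

    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_sd: float = 0.0
    specificity_sd: float = 0.0
    accuracy_sd: float = 0.0
    n_repeats: int = 1

    def __str__(self) -> str:  # e.g. "Sen 79 ± 10  Spe 76 ± 11  Acc 77 ± 8"
        return (
            f"Sen {self.sensitivity:.0f} ± {self.sensitivity_sd:.0f}  "
            f"Spe {self.specificity:.0f} ± {self.specificity_sd:.0f}  "
            f"Acc {self.accuracy:.0f} ± {self.accuracy_sd:.0f}"
        )


def knn_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    query: np.ndarray,
    config: KNNConfig = KNNConfig(),
) -> object:
    """Majority label among the k nearest training points (Euclidean).

    Features are assumed already standardized.  Split votes (including the
    common k=2 one-per-class case) resolve to the class of the single nearest
    neighbor; exact distance ties resolve to the lower training index.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    k = min(config.k, X.shape[0])
    d = np.sqrt(np.sum((X - np.asarray(query, dtype=float)) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[:k]
    neighbor_labels = y[order]
    classes, counts = np.unique(neighbor_labels, return_counts=True)
    top = counts.max()
    winners = classes[counts == top]
    if winners.size == 1:
        return winners[0]
    return neighbor_labels[0]  # tie -> nearest neighbor's class


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def loocv(
    features: np.ndarray,
    labels: np.ndarray,
    config: KNNConfig = KNNConfig(),
    patient_ids: np.ndarray | None = None,
    standardize: bool = True,
    remove_duplicates: bool = True,
) -> np.ndarray:
    """Leave-one-patient-out predictions for every row.

    ``patient_ids`` groups rows belonging to the same patient (duplicates from
    resampling); when a patient is held out, all of their rows leave the
    training fold.  Deterministic given the table.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if patient_ids is None:
        patient_ids = np.arange(X.shape[0])
    pids = np.asarray(patient_ids)
    preds = np.empty(X.shape[0], dtype=y.dtype)
    for pid in np.unique(pids):
        held = pids == pid
        if not remove_duplicates:
            # optimistic variant: only one copy leaves at a time
            for i in np.flatnonzero(held):
                mask = np.ones(X.shape[0], dtype=bool)
                mask[i] = False
                Xt, Xq = _standardize(X[mask], X[i]) if standardize else (X[mask], X[i])
                preds[i] = knn_predict(Xt, y[mask], Xq, config)
            continue
        train_mask = ~held
        Xt, Xq = X[train_mask], X[held]
        if Xt.shape[0] == 0:
            raise ValueError("training fold is empty")
        if standardize:
            Xt, Xq = _standardize(Xt, Xq)
        pred = knn_predict(Xt, y[train_mask], Xq[0], config)
        preds[held] = pred  # identical copies share one prediction
    return preds


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    resp = y_true == RESPONDER
    non = y_true == NON_RESPONDER
    sens = 100.0 * np.mean(y_pred[resp] == RESPONDER) if resp.any() else np.nan
    spec = 100.0 * np.mean(y_pred[non] == NON_RESPONDER) if non.any() else np.nan
    acc = 100.0 * np.mean(y_pred == y_true)
    return sens, spec, acc


def balance_and_evaluate(
    table: pd.DataFrame,
    config: KNNConfig = KNNConfig(),
    n_repeats: int = 10,
    seed: int = 0,
    feature_columns: list[str] | None = None,
    n_per_class: int | None = None,
    remove_duplicates: bool = True,
) -> PerformanceSummary:
    """Repeat-averaged, class-balanced LOOCV performance.

    ``table`` must have a ``label`` column and feature columns, indexed by
    patient id.  Per repeat, the majority class is resampled with replacement
    down to the minority-class count (``n_per_class`` if given; the 58-patient
    study configuration corresponds to N=16), all minority patients are kept,
    and leave-one-patient-out KNN predictions are scored.  Seed-deterministic:
    per-repeat RNG streams derive from one master seed.
    """
    cols = feature_columns or [c for c in table.columns if c != "label"]
    data = table[["label", *cols]].dropna()
    if len(data) < len(table):
        dropped = set(table.index) - set(data.index)
        logging.getLogger(__name__).info(
            "dropping %d patients with missing features: %s", len(dropped), sorted(dropped)
        )
    y = data["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("need both classes present")
    minority = counts.idxmin()
    majority = counts.idxmax()
    n_min = int(counts.min())
    if n_per_class is not None:
        if n_min < n_per_class:
            raise ValueError(
                f"minority class has {n_min} patients, fewer than requested {n_per_class}"
            )
        n_bal = n_per_class
    else:
        n_bal = n_min

    X = data[cols].to_numpy(dtype=float)
    pid = data.index.to_numpy()
    min_rows = np.flatnonzero(y == minority)
    maj_rows = np.flatnonzero(y == majority)

    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    sens_list, spec_list, acc_list = [], [], []
    for ss_ in streams:
        rng = np.random.default_rng(ss_)
        maj_sample = rng.choice(maj_rows, size=n_bal, replace=True)
        if n_bal < min_rows.size:
            min_sample = rng.choice(min_rows, size=n_bal, replace=False)
        else:
            min_sample = min_rows
        rows = np.concatenate([min_sample, maj_sample])
        preds = loocv(
            X[rows], y[rows], config, patient_ids=pid[rows], remove_duplicates=remove_duplicates
        )
        s, p, a = _metrics(y[rows], preds)
        sens_list.append(s)
        spec_list.append(p)
        acc_list.append(a)

    return PerformanceSummary(
        sensitivity=float(np.mean(sens_list)),
        specificity=float(np.mean(spec_list)),
        accuracy=float(np.mean(acc_list)),
        sensitivity_sd=float(np.std(sens_list)),
        specificity_sd=float(np.std(spec_list)),
        accuracy_sd=float(np.std(acc_list)),
        n_repeats=n_repeats,
    )


def enumerate_subsets(n_features: int, sizes: tuple[int, ...]) -> list[tuple[int, ...]]:
    """All index subsets of the given sizes, in size-then-lexicographic order."""
    subsets: list[tuple[int, ...]] = []
    for size in sizes:
        subsets.extend(combinations(range(n_features), size))
    return subsets


def exhaustive_feature_search(
    table: pd.DataFrame,
    config: KNNConfig = KNNConfig(),
    subset_sizes: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
    n_repeats: int = 10,
    seed: int = 0,
    paired_baseline: bool = False,
    n_per_class: int | None = None,
) -> tuple[tuple[str, ...], PerformanceSummary, pd.DataFrame]:
    """Evaluate every feature subset and return the best by mean accuracy.

    With the seven QUS features and sizes 2-7 this enumerates exactly 120
    subsets.  ``paired_baseline=True`` treats each (``<f>_wk0``, ``d<f>``)
    column pair as one selectable unit, so including baselines doubles the
    columns without changing the enumeration.  Ties resolve to the smaller
    subset, then lexicographically.  Returns (best subset column names, its
    summary, a leaderboard DataFrame).
    """
    feat_cols = [c for c in table.columns if c != "label"]
    if paired_baseline:
        units = sorted({c[1:] if c.startswith("d") else c.rsplit("_wk0", 1)[0] for c in feat_cols})
        unit_cols = {u: [f"{u}_wk0", f"d{u}"] for u in units}
    else:
        units = feat_cols
        unit_cols = {u: [u] for u in units}

    rows = []
    best: tuple | None = None
    for subset in enumerate_subsets(len(units), subset_sizes):
        names = tuple(units[i] for i in subset)
        cols = [c for u in names for c in unit_cols[u]]
        summary = balance_and_evaluate(
            table, config, n_repeats=n_repeats, seed=seed, feature_columns=cols,
            n_per_class=n_per_class,
        )
        rows.append({"subset": names, "size": len(names), "accuracy": summary.accuracy,
                     "sensitivity": summary.sensitivity, "specificity": summary.specificity})
        key = (-summary.accuracy, len(names), names)
        if best is None or key < best[0]:
            best = (key, names, summary)

    leaderboard = pd.DataFrame(rows).sort_values(
        ["accuracy", "size", "subset"], ascending=[False, True, True]
    ).reset_index(drop=True)
    assert best is not None
    _, best_names, best_summary = best
    best_cols = tuple(c for u in best_names for c in unit_cols[u])
    return best_cols, best_summary, leaderboard
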