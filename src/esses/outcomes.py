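"""Surgical-outcome classification from model-derived biomarkers.

Three per-patient biomarkers summarize the virtual-resection analyses: the
size of the optimal resection S(R_op), its overlap with the planned
resection area Ov(R_op, RA), and the simulated effect of the planned
resection deltaIR(RA). Non-seizure-free (NSF) is the positive class, with
fixed, data-independent score orientations: larger S(R_op), smaller Ov and
smaller deltaIR(RA) all point toward NSF.

The layer provides ROC/Youden analysis, an exact two-sided Wilcoxon
rank-sum test (midrank ties), leave-one-out threshold-based prediction, a
2-of-3 majority vote, and adaptive boosting of decision stumps with random
undersampling of the majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SF",
    "NSF",
    "BIOMARKER_DIRECTIONS",
    "CohortTable",
    "ROCResult",
    "PredictionResult",
    "roc_analysis",
    "ranksum_exact",
    "loocv_predict",
    "combined_vote",
    "rusboost_predict",
    "metrics_from_confusion",
]

SF, NSF = "SF", "NSF"

# score orientation toward the positive (NSF) class; fixed a priori
BIOMARKER_DIRECTIONS = {"s_rop": "higher", "ov": "lower", "dir_ra": "lower"}


@dataclass
class CohortTable:
    """Per-patient biomarkers and outcome labels.

    ``table`` columns: patient_id, s_rop, ov, dir_ra, outcome (SF/NSF).
    """

    table: pd.DataFrame
    label: str = "cohort"

    def __post_init__(self):
        required = {"patient_id", "s_rop", "ov", "dir_ra", "outcome"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.table[["s_rop", "ov", "dir_ra"]].isna().any().any():
            raise ValueError("cohort table contains missing biomarkers")
        bad = set(self.table["outcome"]) - {SF, NSF}
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> np.ndarray:
        return self.table["outcome"].to_numpy()

    @classmethod
    def from_csv(cls, path, label: str = "cohort") -> "CohortTable":
        return cls(pd.read_csv(path), label=label)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    youden_threshold: float
    confusion: dict  # tp, fp, fn, tn at the Youden point
    metrics: dict

    @property
    def youden_index(self) -> float:
        return self.metrics["sensitivity"] + self.metrics["specificity"] - 1.0


@dataclass
class PredictionResult:
    calls: pd.DataFrame  # patient_id, predicted, outcome
    confusion: dict
    metrics: dict
    excluded: list = field(default_factory=list)
    feature_importance: dict | None = None


def metrics_from_confusion(tp: float, fp: float, fn: float, tn: float) -> dict:
    """Accuracy, precision, sensitivity, specificity, F1 from confusion counts."""
    total = tp + fp + fn + tn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan"),
    }


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "higher":
        return scores
    if direction == "lower":
        return -scores
    raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[str],
    direction: str = "higher",
) -> ROCResult:
    """ROC threshold sweep with AUC (trapezoid) and the Youden operating point.

    ``direction`` states which end of the score points to NSF; the Youden
    point maximizes TPR - FPR, ties resolved toward lower FPR. The confusion
    and derived metrics are evaluated at that threshold (predict NSF when
    the oriented score is >= threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == NSF
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    s = _oriented(scores, direction)
    fpr, tpr, thresholds = roc_curve(y, s)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best = best[np.argmin(fpr[best])]
    thr = float(thresholds[best])
    # place the cut midway between adjacent observed scores so that unseen
    # cases falling inside the separating gap are classified with it
    if np.isfinite(thr):
        below = s[s < thr]
        if below.size:
            thr = (thr + below.max()) / 2.0
    pred = s >= thr
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc_value,
        youden_threshold=thr,
        confusion=confusion,
        metrics=metrics_from_confusion(tp, fp, fn, tn),
    )


def ranksum_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value with midrank ties.

    The null distribution of the rank sum of ``x`` is enumerated by a
    counting recursion over all C(n_x + n_y, n_x) group assignments (exact
    even with ties). For pooled n > 40 a normal approximation with tie
    correction is used and a warning issued.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    if nx + ny > 40:
        warnings.warn("pooled n > 40: using normal approximation", stacklevel=2)
        return _ranksum_normal(ranks, nx, ny)
    # doubled midranks are integers; DP over (count, doubled rank sum)
    r2 = np.rint(2 * ranks).astype(int)
    obs = int(r2[:nx].sum())
    max_sum = int(r2.sum())
    counts = np.zeros((nx + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:
        # iterate k downward so each item is used at most once
        for k in range(nx - 1, -1, -1):
            row = counts[k]
            nz = np.flatnonzero(row)
            if nz.size:
                counts[k + 1, nz + r] += row[nz]
    total = comb(nx + ny, nx)
    dist = counts[nx]
    p_low = dist[: obs + 1].sum() / total
    p_high = dist[obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _ranksum_normal(ranks: np.ndarray, nx: int, ny: int) -> float:
    n = nx + ny
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def loocv_predict(
    cohort: CohortTable,
    biomarker: str,
    direction: str | None = None,
) -> PredictionResult:
    """Leave-one-out threshold prediction for a single biomarker.

    Each fold fits the ROC and Youden threshold on the remaining patients
    only (the held-out label is never seen) and classifies the held-out
    case. Folds whose training set lacks a class are flagged and excluded.
    """
    if direction is None:
        direction = BIOMARKER_DIRECTIONS[biomarker]
    df = cohort.table
    if cohort.n < 3:
        raise ValueError("need at least 3 patients for leave-one-out prediction")
    scores = df[biomarker].to_numpy(dtype=float)
    labels = cohort.labels
    calls, excluded = [], []
    for i in range(cohort.n):
        mask = np.ones(cohort.n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        if (train_labels == NSF).all() or (train_labels == SF).all():
            excluded.append(df.loc[i, "patient_id"])
            warnings.warn(
                f"fold for patient {df.loc[i, 'patient_id']} has one class; excluded",
                stacklevel=2,
            )
            continue
        roc = roc_analysis(scores[mask], train_labels, direction)
        s_i = _oriented(np.array([scores[i]]), direction)[0]
        pred = NSF if s_i >= roc.youden_threshold else SF
        calls.append({"patient_id": df.loc[i, "patient_id"], "predicted": pred, "outcome": labels[i]})
    calls_df = pd.DataFrame(calls)
    tp = int(((calls_df["predicted"] == NSF) & (calls_df["outcome"] == NSF)).sum())
    fp = int(((calls_df["predicted"] == NSF) & (calls_df["outcome"] == SF)).sum())
    fn = int(((calls_df["predicted"] == SF) & (calls_df["outcome"] == NSF)).sum())
    tn = int(((calls_df["predicted"] == SF) & (calls_df["outcome"] == SF)).sum())
    confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return PredictionResult(calls_df, confusion, metrics_from_confusion(tp, fp, fn, tn), excluded)


def combined_vote(predictions: Sequence[str]) -> str:
    """Majority vote over the three per-biomarker calls: NSF iff >= 2 NSF."""
    preds = list(predictions)
    if len(preds) != 3:
        raise ValueError("combined vote requires exactly 3 predictions")
    bad = set(preds) - {SF, NSF}
    if bad:
        raise ValueError(f"unknown predictions: {sorted(bad)}")
    return NSF if preds.count(NSF) >= 2 else SF


def loocv_combined(cohort: CohortTable) -> PredictionResult:
    """Compound 2-of-3 vote over the three per-biomarker LOOCV predictions."""
    per_marker = {b: loocv_predict(cohort, b) for b in BIOMARKER_DIRECTIONS}
    merged = None
    for b, res in per_marker.items():
        cols = res.calls.rename(columns={"predicted": f"pred_{b}"})
        merged = cols if merged is None else merged.merge(
            cols[["patient_id", f"pred_{b}"]], on="patient_id"
        )
    votes = [
        combined_vote([row[f"pred_{b}"] for b in BIOMARKER_DIRECTIONS])
        for _, row in merged.iterrows()
    ]
    calls_df = pd.DataFrame(
        {"patient_id": merged["patient_id"], "predicted": votes, "outcome": merged["outcome"]}
    )
    tp = int(((calls_df["predicted"] == NSF) & (calls_df["outcome"] == NSF)).sum())
    fp = int(((calls_df["predicted"] == NSF) & (calls_df["outcome"] == SF)).sum())
    fn = int(((calls_df["predicted"] == SF) & (calls_df["outcome"] == NSF)).sum())
    tn = int(((calls_df["predicted"] == SF) & (calls_df["outcome"] == SF)).sum())
    confusion = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return PredictionResult(calls_df, confusion, metrics_from_confusion(tp, fp, fn, tn))


def rusboost_predict(
    cohort: CohortTable,
    rng: np.random.Generator | int | None = None,
    n_repetitions: int = 10,
) -> PredictionResult:
    """Boosted-stump outcome prediction with random undersampling.

    Leave-one-out outer loop; in each fold the majority (SF) class is
    undersampled to the minority size, an adaptive-boosting ensemble of
    depth-1 stumps is fitted on the three biomarkers (number of learners =
    balanced training-set size - 1, learning rate 1.0), and the held-out
    patient is classified. Everything is averaged over ``n_repetitions``
    undersampling/boosting repetitions; feature importances are the
    normalized mean stump usage.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    df = cohort.table
    labels = cohort.labels
    n = cohort.n
    if n < 6:
        raise ValueError("need at least 6 patients")
    for cls in (SF, NSF):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls} must have at least 2 members")
    features = df[["s_rop", "ov", "dir_ra"]].to_numpy(dtype=float)
    votes = np.zeros((n, n_repetitions), dtype=object)
    importances = np.zeros(3)
    n_models = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        idx = np.flatnonzero(mask)
        lab = labels[idx]
        minority = NSF if np.sum(lab == NSF) <= np.sum(lab == SF) else SF
        majority = SF if minority == NSF else NSF
        min_idx = idx[lab == minority]
        maj_idx = idx[lab == majority]
        for rep in range(n_repetitions):
            chosen_maj = rng.choice(maj_idx, size=min_idx.size, replace=False)
            train = np.concatenate([min_idx, chosen_maj])
            n_learners = max(1, train.size - 1)
            clf = AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=n_learners,
                learning_rate=1.0,
                random_state=int(rng.integers(2**31 - 1)),
            )
            clf.fit(features[train], labels[train])
            votes[i, rep] = clf.predict(features[[i]])[0]
            importances += clf.feature_importances_
            n_models += 1
    # mean confusion fractions over repetitions
    conf = np.zeros(4)  # tp, fp, fn, tn
    for rep in range(n_repetitions):
        pred = votes[:, rep]
        conf[0] += np.sum((pred == NSF) & (labels == NSF))
        conf[1] += np.sum((pred == NSF) & (labels == SF))
        conf[2] += np.sum((pred == SF) & (labels == NSF))
        conf[3] += np.sum((pred == SF) & (labels == SF))
    conf /= n_repetitions
    tp, fp, fn, tn = conf
    final_calls = [
        NSF if np.mean(votes[i] == NSF) >= 0.5 else SF for i in range(n)
    ]
    calls_df = pd.DataFrame(
        {"patient_id": df["patient_id"], "predicted": final_calls, "outcome": labels}
    )
    imp = importances / importances.sum() if importances.sum() else importances
    return PredictionResult(
        calls_df,
        {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        metrics_from_confusion(tp, fp, fn, tn),
        feature_importance=dict(zip(["s_rop", "ov", "dir_ra"], imp.tolist())),
    )
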