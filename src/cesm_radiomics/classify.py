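"""Binary classification of histological outcomes with pooled-covariance LDA.

Six tasks are defined on the histology table: ER+/ER- (1% cutoff),
PR+/PR- (20%), Ki67+/Ki67- (20%), HER2+/HER2-, high grade (G3) vs low
(G1/G2), and triple-negative (ER-, PR- and HER2-) vs non-triple-negative.
Cutoffs are inclusive (>= cutoff -> positive), matching the clinical
ER >= 1% convention.

The classifier is Gaussian linear discriminant analysis written in closed
form: class means mu_k, a pooled covariance Sigma (unbiased, n-2
denominator, plus a ridge on the diagonal for numerical stability with 14
features and folds in the tens of lesions), and empirical priors pi_k.  A
lesion's score is the positive-minus-negative discriminant

    delta_k(x) = x' Sigma^-1 mu_k - mu_k' Sigma^-1 mu_k / 2 + ln pi_k,

which is monotone in the positive-class posterior.  Performance is
summarized by the ROC and its trapezoidal area over scores pooled across
all leave-one-out folds; with the threshold sweep used here the
trapezoidal area equals the Mann-Whitney pairwise statistic
(#(pos > neg) + #(pos = neg)/2) / (n_pos * n_neg) exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.linalg

from .cohort_io import LesionRecord
from .features import FEATURE_NAMES

__all__ = [
    "TaskDefinition",
    "TASKS",
    "LDAModel",
    "TaskResult",
    "binarize_labels",
    "fit_lda",
    "lda_score",
    "loo_cv",
    "roc_auc",
    "run_all_tasks",
    "task_summary_frame",
    "plot_roc_overlay",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskDefinition:
    """One binary labeling of the cohort."""

    name: str
    labeler: Callable[[LesionRecord], bool]
    description: str


TASKS: tuple[TaskDefinition, ...] = (
    TaskDefinition("ER", lambda r: r.er_pct >= 1.0, "ER+ (>= 1%) vs ER-"),
    TaskDefinition("PR", lambda r: r.pr_pct >= 20.0, "PR+ (>= 20%) vs PR-"),
    TaskDefinition("Ki67", lambda r: r.ki67_pct >= 20.0, "Ki67+ (>= 20%) vs Ki67-"),
    TaskDefinition("Grade", lambda r: r.grade == "G3", "high grade (G3) vs low (G1/G2)"),
    TaskDefinition(
        "TN",
        lambda r: (r.er_pct < 1.0) and (r.pr_pct < 20.0) and (r.her2 == "-"),
        "triple-negative (ER-, PR-, HER2-) vs non-triple-negative",
    ),
    TaskDefinition("HER2", lambda r: r.her2 == "+", "HER2+ vs HER2-"),
)


def binarize_labels(records: list[LesionRecord], task: TaskDefinition):
    """Apply a task's labeling rule; returns (y, n_pos, n_neg) with y in {0,1}."""
    y = np.array([1 if task.labeler(r) else 0 for r in records], dtype=int)
    n_pos = int(y.sum())
    return y, n_pos, len(y) - n_pos


@dataclass
class LDAModel:
    """Two-class Gaussian LDA with pooled covariance."""

    class_means: np.ndarray        # (2, p): row 0 = negative, row 1 = positive
    pooled_covariance: np.ndarray  # (p, p), ridge already added
    priors: np.ndarray             # (2,)
    feature_names: tuple[str, ...]
    regularization: float
    _chol: tuple = field(default=None, repr=False)

    def _solve(self, b: np.ndarray) -> np.ndarray:
        if self._chol is None:
            object.__setattr__(self, "_chol",
                               scipy.linalg.cho_factor(self.pooled_covariance, lower=True))
        return scipy.linalg.cho_solve(self._chol, b)


def default_ridge(X: np.ndarray) -> float:
    """1e-6 x mean feature variance scale: keeps Sigma invertible, changes nothing else."""
    p = X.shape[1]
    total_var = float(X.var(axis=0, ddof=1).sum()) if X.shape[0] > 1 else 1.0
    return 1e-6 * total_var / p


def fit_lda(X, y, ridge: float | None = None,
            feature_names: tuple[str, ...] | None = None) -> LDAModel:
    """Fit the closed-form pooled-covariance LDA.

    ``pooled_covariance = sum_k sum_{i in k} (x_i - mu_k)(x_i - mu_k)' / (n - 2)
    + ridge * I``; priors are the empirical class proportions.  Rows
    containing NaN are dropped with a logged count.  Raises on a one-class
    input or, at ``ridge = 0``, on a singular covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) aligned with y")
    keep = ~np.isnan(X).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_lda: dropping %d rows with missing features", n_dropped)
        X, y = X[keep], y[keep]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    n, p = X.shape
    counts = np.array([(y == 0).sum(), (y == 1).sum()])
    if counts.min() < 2:
        raise ValueError(f"each class needs >= 2 members, got sizes {counts.tolist()}")

    means = np.vstack([X[y == k].mean(axis=0) for k in (0, 1)])
    scatter = np.zeros((p, p))
    for k in (0, 1):
        d = X[y == k] - means[k]
        scatter += d.T @ d
    cov = scatter / (n - 2)
    if ridge is None:
        ridge = default_ridge(X)
    cov_r = cov + ridge * np.eye(p)
    try:
        scipy.linalg.cho_factor(cov_r, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise ValueError(
            "pooled covariance is singular; rerun with a positive ridge "
            f"(ridge={ridge})"
        ) from err

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(p)
    )
    return LDAModel(class_means=means, pooled_covariance=cov_r,
                    priors=counts / n, feature_names=names, regularization=float(ridge))


def lda_score(model: LDAModel, x) -> float | np.ndarray:
    """Positive-minus-negative discriminant; accepts a vector or (n, p) matrix.

    Equals ``x' Sigma^-1 (mu1 - mu0) - (mu1 + mu0)' Sigma^-1 (mu1 - mu0)/2
    + ln(pi1/pi0)`` and is an affine function of x along the discriminant
    direction.  The positive-class posterior is ``1/(1 + exp(-score))``.
    """
    x = np.asarray(x, dtype=float)
    mu0, mu1 = model.class_means
    w = model._solve(mu1 - mu0)
    bias = -0.5 * float((mu1 + mu0) @ w) + float(np.log(model.priors[1] / model.priors[0]))
    out = x @ w + bias
    return float(out) if out.ndim == 0 else out


def loo_cv(X, y, ridge: float | None = None, standardize: bool = False) -> np.ndarray:
    """Leave-one-out scores: fold i is scored by the model fit without row i.

    Output order matches input order.  ``standardize`` z-scores the
    features inside each training fold (the held-out row is transformed
    with the training fold's statistics, never its own).  A fold whose
    training set loses a class raises, because the task is infeasible at
    this sample size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 samples")
    if np.isnan(X).any():
        raise ValueError("loo_cv requires a complete feature matrix (drop NaN rows first)")
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"removing sample {i} empties a class; task infeasible")
        X_tr, x_te = X[tr], X[i]
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            x_te = (x_te - mu) / sd
        model = fit_lda(X_tr, y_tr, ridge=ridge)
        scores[i] = lda_score(model, x_te)
    return scores


def roc_auc(scores, y) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and its trapezoidal area.

    Thresholds run over the unique scores (descending), predicting
    positive at ``score >= threshold``; the curve starts at (0, 0) and ends
    at (1, 1).  The trapezoidal area equals the tie-aware Mann-Whitney
    probability ``(#(pos > neg) + #(pos = neg)/2) / (n_pos * n_neg)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr = float((pred & (y == 1)).sum()) / n_pos
        fpr = float((pred & (y == 0)).sum()) / n_neg
        points.append((fpr, tpr))
    pts = np.asarray(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


@dataclass
class TaskResult:
    """Outcome of one classification task on one cohort."""

    task: TaskDefinition
    n_pos: int
    n_neg: int
    feasible: bool
    reason: str = ""
    lesion_ids: list[str] = field(default_factory=list)
    y: np.ndarray | None = None
    loo_scores: np.ndarray | None = None
    roc_points: np.ndarray | None = None
    auc: float | None = None


def run_all_tasks(features: pd.DataFrame, records: list[LesionRecord],
                  ridge: float | None = None, standardize: bool = False,
                  tasks: tuple[TaskDefinition, ...] = TASKS) -> list[TaskResult]:
    """Run every task: binarize, LOO-validate the LDA, pool scores into a ROC.

    Lesions with any missing feature are excluded (logged).  A task whose
    smaller class cannot sustain leave-one-out refits (fewer than 3
    members) is reported infeasible; the others are unaffected.
    """
    ids = [r.lesion_id for r in records]
    if list(features.index) != ids:
        raise ValueError("features and records are not aligned by lesion_id")
    X_all = features.to_numpy(dtype=float)
    complete = ~np.isnan(X_all).any(axis=1)
    if not complete.all():
        logger.info("run_all_tasks: excluding %d lesions with missing features",
                    int((~complete).sum()))
    results = []
    for task in tasks:
        y_all, _, _ = binarize_labels(records, task)
        y = y_all[complete]
        X = X_all[complete]
        kept_ids = [i for i, c in zip(ids, complete) if c]
        n_pos, n_neg = int(y.sum()), int((y == 0).sum())
        if min(n_pos, n_neg) < 3:
            results.append(TaskResult(task=task, n_pos=n_pos, n_neg=n_neg, feasible=False,
                                      reason=f"class sizes {n_pos}/{n_neg} too small for LOO"))
            logger.warning("task %s infeasible: class sizes %d/%d", task.name, n_pos, n_neg)
            continue
        scores = loo_cv(X, y, ridge=ridge, standardize=standardize)
        pts, auc = roc_auc(scores, y)
        results.append(TaskResult(task=task, n_pos=n_pos, n_neg=n_neg, feasible=True,
                                  lesion_ids=kept_ids, y=y, loo_scores=scores,
                                  roc_points=pts, auc=auc))
    return results


def task_summary_frame(results: list[TaskResult]) -> pd.DataFrame:
    """Summary table: task, class sizes, AUC as a percentage."""
    rows = []
    for res in results:
        rows.append({
            "task": res.task.name,
            "pos": res.n_pos,
            "neg": res.n_neg,
            "auc_pct": round(100.0 * res.auc, 2) if res.feasible else "",
            "feasible": res.feasible,
        })
    return pd.DataFrame(rows, columns=["task", "pos", "neg", "auc_pct", "feasible"])


def plot_roc_overlay(results: list[TaskResult], path) -> None:
    """One figure overlaying the pooled-LOO ROC of every feasible task."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for res in results:
        if not res.feasible:
            continue
        ax.plot(res.roc_points[:, 0], res.roc_points[:, 1],
                label=f"{res.task.name} (AUC {100 * res.auc:.1f}%)")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Leave-one-out ROC per classification task")
    ax.legend(loc="lower right", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
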