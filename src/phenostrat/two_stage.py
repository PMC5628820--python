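"""Separating pure-class ("extreme") individuals from mixtures.

A trained three-class model assigns every sample a class-probability vector;
pure-class individuals concentrate mass on one class while mixtures spread
it, so the *probability maximum* (the largest of the K probabilities, in
[1/K, 1]) is an informative scalar.  A binary logistic regression of
extreme-vs-mixture status on that scalar, with 10-fold cross validation and
ROC/AUC evaluation, forms the second stage.  One such model is built per
base method (lasso / elastic net / random forest); candidate models differ
by their CV seed and the best per method is kept by mean CV accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .matrix import PhenotypeMatrix

__all__ = [
    "MaximaScores",
    "BinaryModel",
    "probability_maxima",
    "fit_binary",
    "roc_auc",
    "evaluate_binary",
    "select_best_two_stage",
    "two_stage_analysis",
]


@dataclass
class MaximaScores:
    sample_ids: list
    score: np.ndarray  # in [1/K, 1]
    source_method: str
    is_extreme: np.ndarray | None = None  # boolean truth, optional

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"score": self.score}, index=self.sample_ids)
        df["method"] = self.source_method
        if self.is_extreme is not None:
            df["is_extreme"] = self.is_extreme
        return df


def probability_maxima(model, m: PhenotypeMatrix, is_extreme=None,
                       source_method: str | None = None) -> MaximaScores:
    """Max class-membership probability per sample under a K-class model."""
    proba = model.predict_proba(m)
    method = source_method or getattr(model, "method", type(model).__name__)
    return MaximaScores(
        sample_ids=list(proba.index),
        score=proba.to_numpy().max(axis=1),
        source_method=method,
        is_extreme=None if is_extreme is None else np.asarray(is_extreme, dtype=bool),
    )


# ---------------------------------------------------------------------------
# scalar logistic regression


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _newton_logistic(x, y, ridge: float = 0.0, tol: float = 1e-8,
                     max_iter: int = 100):
    """MLE of logit P(y=1) = b0 + b1*x by Newton-Raphson; optional L2 ridge."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        p = _sigmoid(X @ beta)
        w = p * (1.0 - p)
        grad = X.T @ (y - p) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
        if np.max(np.abs(beta)) > 1e6:
            return beta, False
    return beta, False


def _perfectly_separated(x, y) -> bool:
    if y.all() or not y.any():
        return True
    return x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min()


@dataclass
class BinaryModel:
    intercept: float
    slope: float
    threshold: float
    cv_accuracies: list
    auc: float
    separated: bool = False
    source_method: str = ""
    cv_seed: int = 0

    def predict_proba(self, score: np.ndarray) -> np.ndarray:
        return _sigmoid(self.intercept + self.slope * np.asarray(score, dtype=float))

    def predict(self, score: np.ndarray) -> np.ndarray:
        return self.predict_proba(score) >= self.threshold

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracies))


def _fit_scalar_logistic(x, y):
    """Fit, falling back to a tiny ridge when the classes are separable."""
    separated = _perfectly_separated(x, y)
    if not separated:
        beta, ok = _newton_logistic(x, y)
        if ok:
            return beta, False
    beta, _ = _newton_logistic(x, y, ridge=1e-6, max_iter=500)
    return beta, True


def fit_binary(scores: MaximaScores, threshold: float = 0.5, n_folds: int = 10,
               seed: int = 0) -> BinaryModel:
    """Logistic regression of extreme status on the probability maximum.

    Stratified 10-fold CV accuracies are recorded at the given posterior
    threshold; perfect separation triggers a 1e-6 ridge and a flag.
    """
    if scores.is_extreme is None:
        raise ValueError("scores must carry extreme/non-extreme truth")
    x = np.asarray(scores.score, dtype=float)
    y = scores.is_extreme.astype(float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    beta, separated = _fit_scalar_logistic(x, y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(x[:, None], y):
        b, _ = _fit_scalar_logistic(x[tr], y[tr])
        pred = _sigmoid(b[0] + b[1] * x[va]) >= threshold
        accs.append(float(np.mean(pred == (y[va] == 1))))
    auc = roc_auc(x, y == 1)
    return BinaryModel(intercept=float(beta[0]), slope=float(beta[1]),
                       threshold=threshold, cv_accuracies=accs, auc=auc,
                       separated=separated, source_method=scores.source_method,
                       cv_seed=seed)


def roc_auc(scores, truth) -> float:
    """P(score_pos > score_neg) + P(equal)/2, the Mann-Whitney AUC.

    Computed from average ranks, which equals the all-pairs count with ties
    contributing one half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_binary(model: BinaryModel, scores: MaximaScores) -> dict:
    """Sensitivity/specificity/accuracy of the thresholded model."""
    if scores.is_extreme is None:
        raise ValueError("scores must carry truth")
    pred = model.predict(scores.score)
    y = scores.is_extreme
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / len(y),
        "auc": model.auc,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


def select_best_two_stage(candidates: dict) -> dict:
    """Per method, keep the candidate with highest mean CV accuracy.

    Ties resolve to the higher AUC.
    """
    best = {}
    for method, models in candidates.items():
        if not models:
            raise ValueError(f"no candidates for method {method!r}")
        best[method] = max(models, key=lambda mdl: (mdl.mean_cv_accuracy, mdl.auc))
    return best


def two_stage_analysis(models: dict, extreme: PhenotypeMatrix,
                       nonextreme: PhenotypeMatrix, n_candidates: int = 10,
                       threshold: float = 0.5, seed: int = 0) -> dict:
    """Full second stage for each base method.

    Scores the pooled extreme + mixture cohort under each trained K-class
    model, builds ``n_candidates`` logistic candidates (distinct CV seeds),
    keeps the best per method, and reports its held-in sensitivity,
    specificity, accuracy and AUC at the threshold.
    """
    shared = [f for f in extreme.feature_ids if f in set(nonextreme.feature_ids)]
    if not shared:
        raise ValueError("extreme and non-extreme cohorts share no features")
    pooled = extreme.select_features(shared).concat(nonextreme.select_features(shared))
    truth = np.r_[np.ones(extreme.n_samples, dtype=bool),
                  np.zeros(nonextreme.n_samples, dtype=bool)]
    out = {}
    candidates = {}
    all_scores = {}
    for method, model in models.items():
        scores = probability_maxima(model, pooled, is_extreme=truth,
                                    source_method=method)
        all_scores[method] = scores
        candidates[method] = [
            fit_binary(scores, threshold=threshold, seed=seed + j)
            for j in range(n_candidates)
        ]
    best = select_best_two_stage(candidates)
    for method, model in best.items():
        report = evaluate_binary(model, all_scores[method])
        report["mean_cv_accuracy"] = model.mean_cv_accuracy
        report["intercept"], report["slope"] = model.intercept, model.slope
        report["separated"] = model.separated
        out[method] = {"model": model, "scores": all_scores[method], "report": report}
    return out
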