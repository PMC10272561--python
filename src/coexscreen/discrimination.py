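"""Case/control discrimination of module hub genes.

Modules are ranked by how well a logistic regression on their hub-gene
expression separates cases from controls, summarized as the median area
under the precision–recall curve (AUPRC) over three replicates of
stratified five-fold cross-validation. The AUPRC uses the step-wise
average-precision rule (no interpolation), with tied scores grouped at a
single threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler


def logistic_fit(features, labels, ridge: float = 1e-6) -> Pipeline:
    """Standardize-then-logistic model returning class-1 probabilities.

    A small ridge penalty keeps the fit defined under complete separation.
    Features are standardized inside the pipeline, so cross-validation uses
    train-fold statistics only.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0 / max(ridge, 1e-12),
                           solver="lbfgs", max_iter=5000))
    model.fit(np.asarray(features, dtype=float), y)
    lr = model.named_steps["logisticregression"]
    if lr.n_iter_[0] >= 5000:
        raise RuntimeError(f"logistic fit did not converge ({lr.n_iter_[0]} iters)")
    return model


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    area: float


def auprc(scores, labels) -> PRCurve:
    """Precision–recall curve and its step-wise (average precision) area.

    Thresholds are placed at every distinct score, descending; area is
    sum over points of (R_i - R_{i-1}) * P_i.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels.sum()
    if pos == 0:
        raise ValueError("no positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices of the last element of each tied-score group
    last = np.r_[np.where(np.diff(s) != 0)[0], s.size - 1]
    tp = np.cumsum(y)[last]
    n_pred = last + 1
    precision = tp / n_pred
    recall = tp / pos
    area = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return PRCurve(recall=recall, precision=precision, area=area)


@dataclass
class CVResult:
    replicate_auprc: list[float]
    median_auprc: float
    fold_table: pd.DataFrame


def repeated_cv_auprc(features, labels, k: int = 5, replicates: int = 3,
                      stratified: bool = True, seed: int = 0,
                      ridge: float = 1e-6) -> CVResult:
    """Median AUPRC over repeated k-fold CV of a logistic model.

    Out-of-fold class-1 probabilities are pooled within each replicate to
    give one PR curve per replicate; the summary is the median over
    replicates. Fold assignment is stratified (both classes in every fold)
    with a replicate-specific sub-seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    rows, rep_scores = [], []
    for rep in range(replicates):
        sub_seed = (seed * 1009 + rep) % (2**31)
        oof = np.full(y.size, np.nan)
        for attempt in range(10):
            splitter = (StratifiedKFold(k, shuffle=True, random_state=sub_seed)
                        if stratified else
                        KFold(k, shuffle=True, random_state=sub_seed))
            folds = list(splitter.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                break
            sub_seed += 1
        else:
            raise RuntimeError("could not build folds containing both classes")
        for fold_i, (tr, te) in enumerate(folds):
            model = logistic_fit(X[tr], y[tr], ridge=ridge)
            prob = model.predict_proba(X[te])[:, 1]
            oof[te] = prob
            rows.append({"replicate": rep, "fold": fold_i,
                         "fold_auprc": auprc(prob, y[te]).area
                         if y[te].sum() else np.nan})
        rep_scores.append(auprc(oof, y).area)
    return CVResult(replicate_auprc=rep_scores,
                    median_auprc=float(np.median(rep_scores)),
                    fold_table=pd.DataFrame(rows))


class ModuleDiscriminator(BaseEstimator, ClassifierMixin):
    """Logistic hub-gene classifier with a repeated-CV AUPRC summary.

    ``fit(X, y)`` fits the standardize+logistic model on samples x hub-gene
    features and records ``cv_result_`` (median AUPRC over ``replicates``
    replicates of ``k``-fold CV).
    """

    def __init__(self, k: int = 5, replicates: int = 3, stratified: bool = True,
                 seed: int = 0, ridge: float = 1e-6):
        self.k = k
        self.replicates = replicates
        self.stratified = stratified
        self.seed = seed
        self.ridge = ridge

    def fit(self, X, y):
        self.cv_result_ = repeated_cv_auprc(
            X, y, k=self.k, replicates=self.replicates,
            stratified=self.stratified, seed=self.seed, ridge=self.ridge)
        self.model_ = logistic_fit(X, y, ridge=self.ridge)
        self.classes_ = np.unique(np.asarray(y))
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))
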