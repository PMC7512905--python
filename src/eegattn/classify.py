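"""LDA- and SVM-based 3-class attention classifiers under LOOCV.

Two classifiers mirror the study design: a Gaussian linear discriminant
with pooled within-class covariance and equal priors, and a soft-margin
RBF support vector machine with one-vs-one voting (scikit-learn's SVC,
built on libsvm, with the libsvm defaults C = 1 and gamma = 1/d, plus
class-weight balancing to compensate the one-sample class imbalance that
leave-one-out folds create).  Features are z-scored per training fold by
default; evaluation is leave-one-out cross-validation with a chi-squared
test of the per-class correct counts against the 33.3% chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from eegattn.entropy import FeatureTable
from eegattn.simulate import CONDITIONS
from eegattn.stats import chi2_vs_chance

CLASSIFIER_KINDS = ("lda", "svm")


class PooledCovarianceLDA(BaseEstimator, ClassifierMixin):
    """Gaussian LDA: pooled within-class covariance, equal priors.

    The discriminant score of class k is
    ``x @ inv(S) @ mu_k - 0.5 * mu_k @ inv(S) @ mu_k``; prediction is the
    argmax, with ties broken by class order.  When the pooled covariance
    is numerically singular a ridge ``lam * trace(S)/d * I`` is added and
    the model is flagged via ``regularized_``.
    """

    def __init__(self, ridge: float = 1e-6):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if any(np.sum(y == c) < 2 for c in self.classes_):
            raise ValueError("each class needs at least 2 training samples")
        d = X.shape[1]
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        scatter = np.zeros((d, d))
        for c, mu in zip(self.classes_, self.means_):
            resid = X[y == c] - mu
            scatter += resid.T @ resid
        cov = scatter / (X.shape[0] - len(self.classes_))
        self.regularized_ = False
        try:
            self._solve = np.linalg.cholesky(cov)
            self.covariance_ = cov
        except np.linalg.LinAlgError:
            # trace can itself be zero (all-constant within-class data)
            scale = np.trace(cov) / d or 1.0
            cov = cov + self.ridge * scale * np.eye(d)
            self._solve = np.linalg.cholesky(cov)
            self.covariance_ = cov
            self.regularized_ = True
        # coef_k = inv(S) mu_k via the Cholesky factor
        self.coef_ = np.linalg.solve(
            self._solve.T, np.linalg.solve(self._solve, self.means_.T)
        ).T
        self.intercept_ = -0.5 * np.einsum("kd,kd->k", self.means_, self.coef_)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def build_classifier(
    kind: str,
    standardize: bool = True,
    C: float = 1.0,
    gamma="auto",
    class_weight="balanced",
    ridge: float = 1e-6,
):
    """Assemble the (optionally z-scoring) classifier pipeline.

    The SVM uses libsvm's RBF defaults (C = 1, gamma = 1/d) with
    per-class weight balancing.  Balancing matters under leave-one-out
    cross-validation: the held-out trial's class has one fewer training
    sample, and with heavily overlapping classes an unweighted one-vs-one
    vote then systematically excludes the true class (observed as 0%
    identification on null data).  Weighting by inverse class frequency
    removes that artifact; pass ``class_weight=None`` for raw libsvm
    behaviour.
    """
    if kind == "lda":
        model = PooledCovarianceLDA(ridge=ridge)
    elif kind == "svm":
        # gamma="auto" is 1/d, the libsvm default for the RBF kernel
        model = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", model)])
    return model


@dataclass
class ClassifierResult:
    """LOOCV summary: confusion counts, identification rates, chance test."""

    confusion: np.ndarray  # 3x3 ints, rows = true condition, cols = predicted
    per_class_rate: Dict[str, float]  # percent correct per condition
    average_rate: float  # mean of the three per-class rates, percent
    chi2: float
    chi2_p: float
    classifier_kind: str
    feature_spec: str = ""

    @property
    def n_per_class(self) -> int:
        return int(self.confusion.sum(axis=1)[0])

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier_kind,
            "features": self.feature_spec,
            "confusion": self.confusion.tolist(),
            "per_class_rate_pct": dict(self.per_class_rate),
            "average_rate_pct": self.average_rate,
            "chi2": self.chi2,
            "chi2_p": self.chi2_p,
        }


def loocv(
    table: FeatureTable,
    classifier_kind: str,
    standardize: bool = True,
    C: float = 1.0,
    gamma="auto",
    class_weight="balanced",
    feature_spec: str = "",
) -> ClassifierResult:
    """Leave-one-out cross-validation over all trials in the table.

    Requires balanced labels (equal trials per condition), since the
    chance level is defined as 33.3%; non-finite feature rows are refused.
    """
    X = table.values
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite rows; cannot classify")
    labels = np.asarray(table.labels)
    counts = {cond: int(np.sum(labels == cond)) for cond in CONDITIONS}
    if len(set(counts.values())) != 1 or min(counts.values()) < 2:
        raise ValueError(f"labels must be balanced across {CONDITIONS}, got {counts}")
    n_per_class = counts[CONDITIONS[0]]

    # integer codes fix the class order Rest < AOA1 < AOA2 for tie-breaking
    y = np.array([CONDITIONS.index(lab) for lab in labels])
    template = build_classifier(
        classifier_kind, standardize=standardize, C=C, gamma=gamma, class_weight=class_weight
    )

    n = X.shape[0]
    confusion = np.zeros((3, 3), dtype=int)
    for held_out in range(n):
        mask = np.ones(n, dtype=bool)
        mask[held_out] = False
        model = clone(template)
        model.fit(X[mask], y[mask])
        pred = int(model.predict(X[held_out : held_out + 1])[0])
        confusion[y[held_out], pred] += 1

    per_class_rate = {
        cond: float(100.0 * confusion[i, i] / n_per_class)
        for i, cond in enumerate(CONDITIONS)
    }
    chi2, p = chi2_vs_chance(np.diag(confusion), n_per_class)
    return ClassifierResult(
        confusion=confusion,
        per_class_rate=per_class_rate,
        average_rate=float(np.mean(list(per_class_rate.values()))),
        chi2=chi2,
        chi2_p=p,
        classifier_kind=classifier_kind,
        feature_spec=feature_spec,
    )


def sweep(
    features_by_setting: Mapping[str, FeatureTable] | Sequence[Tuple[str, FeatureTable]],
    classifier_kind: str,
    **loocv_kwargs,
) -> List[ClassifierResult]:
    """LOOCV over a family of feature settings (per channel, per tau, per r)."""
    if isinstance(features_by_setting, Mapping):
        items = list(features_by_setting.items())
    else:
        items = list(features_by_setting)
    if not items:
        raise ValueError("empty sweep: no feature settings given")
    return [
        loocv(table, classifier_kind, feature_spec=name, **loocv_kwargs)
        for name, table in items
    ]


def results_table(results: Sequence[ClassifierResult]) -> pd.DataFrame:
    """Render a list of LOOCV results as one row per (classifier, features)."""
    records = []
    for res in results:
        rec = {"classifier": res.classifier_kind, "features": res.feature_spec}
        for cond in CONDITIONS:
            rec[f"{cond}_pct"] = res.per_class_rate[cond]
        rec["average_idr_pct"] = res.average_rate
        rec["chi2_p"] = res.chi2_p
        records.append(rec)
    return pd.DataFrame.from_records(records)
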