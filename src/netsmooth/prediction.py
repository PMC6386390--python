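"""Cross-validated classification and classifier blending.

The classifier roster covers L1- and L2-regularized logistic regression,
random forests, and RBF support-vector machines with probability
calibration. Evaluation is leave-one-out cross-validation scored by the
rank-based (Mann-Whitney) ROC AUC with tied scores contributing 1/2.
A cell-line-derived classifier can be blended with the patient classifier
through a convex weight gamma tuned by grid search on a stratified holdout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import CombinationWeight, CvResult, FeatureTable, LabelVector
from .errors import ValidationError

#: fixed classifier hyperparameters (reported alongside every result)
MODEL_SPECS = ("logistic_l1", "logistic_l2", "random_forest", "svm")
GAMMA_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def make_classifier(model_spec: str, seed: int = 0):
    """Instantiate one of the supported classifier families with the
    package's fixed hyperparameters (forest: 500 trees; logistic: C=1;
    SVM: RBF kernel with probability calibration)."""
    if model_spec == "logistic_l1":
        clf = LogisticRegression(C=1.0, solver="liblinear", l1_ratio=1.0, max_iter=5000, random_state=seed)
    elif model_spec == "logistic_l2":
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000, random_state=seed)
    elif model_spec == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif model_spec == "svm":
        # probabilistic SVM: RBF kernel with sigmoid (Platt) calibration
        clf = CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed), cv=3, ensemble=False)
    else:
        raise ValidationError(f"unknown model_spec {model_spec!r}; choose from {MODEL_SPECS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _aligned_arrays(features: FeatureTable, labels: LabelVector) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if set(features.sample_ids) != set(labels.sample_ids):
        raise ValidationError("feature table and label vector cover different samples")
    index = labels.data.index
    x = features.data.reindex(index).to_numpy(dtype=float)
    y = labels.labels.to_numpy(dtype=int)
    if not np.all(np.isfinite(x)):
        raise ValidationError("features contain NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present for cross-validation")
    return x, y, index


def _fold_importances(model, n_features: int) -> np.ndarray | None:
    if isinstance(model, RandomForestClassifier):
        return model.feature_importances_
    if isinstance(model, Pipeline):
        clf = model.named_steps["clf"]
        if isinstance(clf, LogisticRegression):
            return np.abs(clf.coef_).ravel()
    return None


def loo_cross_validate(
    features: FeatureTable, labels: LabelVector, model_spec: str = "random_forest", seed: int = 0
) -> CvResult:
    """Leave-one-out cross-validation: each sample is scored with the
    non-response probability from a model trained on all other samples.
    Deterministic given the seed. Importances (forest impurity importances
    or mean |logistic coefficient|) are averaged across folds."""
    x, y, index = _aligned_arrays(features, labels)
    n = len(y)
    scores = np.empty(n)
    importance_sum: np.ndarray | None = None
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            raise ValidationError(f"training fold for sample {index[i]!r} contains a single class")
        model = make_classifier(model_spec, seed=seed)
        model.fit(x[mask], y_train)
        scores[i] = model.predict_proba(x[i : i + 1])[0, 1]
        imp = _fold_importances(model, x.shape[1])
        if imp is not None:
            importance_sum = imp if importance_sum is None else importance_sum + imp
    score_series = pd.Series(scores, index=index)
    importances = None
    if importance_sum is not None:
        importances = pd.Series(importance_sum / n, index=features.data.reindex(index).columns)
    return CvResult(
        scores=score_series,
        fold_assignment=pd.Series(np.arange(n), index=index),
        auc=roc_auc(scores, y),
        importances=importances,
        model_spec=model_spec,
    )


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC (Mann-Whitney statistic); tied scores contribute
    1/2 per discordant-pair comparison. Requires both classes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both a positive and a negative class")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def univariate_feature_auc(
    features: FeatureTable, labels: LabelVector, orient: bool = True
) -> list[tuple[str, float]]:
    """Score each feature column as a standalone predictor by its ROC AUC,
    optionally orientation-corrected to max(AUC, 1-AUC); returns features
    sorted by AUC, descending. Constant features score 0.5 with a warning."""
    x, y, index = _aligned_arrays(features, labels)
    results = []
    for j, name in enumerate(features.data.reindex(index).columns):
        column = x[:, j]
        if np.ptp(column) == 0.0:
            warnings.warn(f"feature {name!r} is constant; univariate AUC is 0.5", stacklevel=2)
            auc = 0.5
        else:
            auc = roc_auc(column, y)
            if orient:
                auc = max(auc, 1.0 - auc)
        results.append((name, auc))
    return sorted(results, key=lambda item: -item[1])


def tune_gamma(cell_scores, patient_scores, holdout_labels) -> CombinationWeight:
    """Grid-search the convex blending weight gamma over {0, 0.01, ..., 1},
    maximizing holdout AUC of gamma*p_c + (1-gamma)*p_p; ties resolve to the
    smallest gamma."""
    p_c = np.asarray(cell_scores, dtype=float)
    p_p = np.asarray(patient_scores, dtype=float)
    y = np.asarray(holdout_labels, dtype=int)
    if p_c.shape != p_p.shape or p_c.shape != y.shape:
        raise ValidationError("score vectors and holdout labels must align")
    if len(np.unique(y)) < 2:
        raise ValidationError("degenerate holdout: both classes required to tune gamma")
    aucs = np.array([roc_auc(g * p_c + (1.0 - g) * p_p, y) for g in GAMMA_GRID])
    best = int(np.argmax(aucs))  # first maximum -> smallest gamma on ties
    return CombinationWeight(gamma=float(GAMMA_GRID[best]), auc_trace=pd.Series(aucs, index=GAMMA_GRID))


def combine_predictions(cell_scores, patient_scores, gamma: float) -> np.ndarray:
    """Final blended prediction p = gamma*p_c + (1-gamma)*p_p, element-wise."""
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError("gamma must lie in [0,1]")
    p_c = np.asarray(cell_scores, dtype=float)
    p_p = np.asarray(patient_scores, dtype=float)
    if p_c.shape != p_p.shape:
        raise ValidationError("score vectors must align")
    return gamma * p_c + (1.0 - gamma) * p_p


def stratified_holdout(labels: LabelVector, fraction: float = 0.1, seed: int = 0) -> tuple[list[str], list[str]]:
    """Split sample IDs into a label-stratified (holdout, rest) pair; the
    holdout is used for tuning the blending weight gamma."""
    ids = np.array(labels.sample_ids)
    y = labels.labels.to_numpy()
    holdout, rest = train_test_split(ids, train_size=fraction, stratify=y, random_state=seed)
    return sorted(holdout.tolist()), sorted(rest.tolist())
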