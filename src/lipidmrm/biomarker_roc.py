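"""ROC analysis and multivariate biomarker panels.

Univariate discrimination is quantified by the area under the ROC curve,
computed from the Mann-Whitney rank statistic (exactly the trapezoidal ROC
integral) and oriented so AUC >= 0.5.  Panels are evaluated with PLS-DA
(partial least squares regression on a 0/1 class code, two latent
components by default) or optionally a random forest, trained strictly on
the testing split, cross-validated by repeated stratified Monte-Carlo
subsampling, and then applied blind to the validation split — the workflow
used to qualify the three-ceramide and three-FFA panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from .ingest import FeatureMatrix

__all__ = [
    "RocResult",
    "PanelModel",
    "CvConfig",
    "univariate_roc",
    "fit_panel",
    "predict_validation",
]

_POSITIVE_CLASS = "cpdm"


@dataclass
class CvConfig:
    """Repeated stratified Monte-Carlo cross-validation scheme."""

    train_fraction: float = 2 / 3
    repeats: int = 100
    seed: int = 0


@dataclass
class RocResult:
    """ROC metrics for a single feature or a fitted panel."""

    feature: str
    auc: float
    threshold: Optional[float] = None
    direction: Optional[str] = None  # 'greater' if cpdm values are higher
    probabilities: Optional[pd.Series] = None
    predicted: Optional[pd.Series] = None
    accuracy: Optional[float] = None
    cv_config: Optional[CvConfig] = None


@dataclass
class PanelModel:
    """A multivariate panel classifier trained on the testing split."""

    features: list
    algorithm: str
    scaler: StandardScaler
    estimator: object
    training_samples: list
    n_components: int = 2

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"matrix lacks panel features {missing}")
        Z = self.scaler.transform(X[self.features].to_numpy())
        if self.algorithm == "plsda":
            yhat = np.asarray(self.estimator.predict(Z)).ravel()
            prob = np.clip(yhat, 0.0, 1.0)
        else:
            prob = self.estimator.predict_proba(Z)[:, 1]
        return pd.Series(prob, index=X.index, name="p_cpdm")


def univariate_roc(values, labels) -> RocResult:
    """AUC and Youden-optimal threshold for one feature.

    The AUC is U / (n1 * n0) from the Mann-Whitney statistic (ties counted
    half), oriented so AUC >= 0.5.  The threshold maximizes sensitivity +
    specificity - 1 and is placed at the midpoint between the adjacent
    observed values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    name = getattr(values, "name", "feature")
    pos, neg = values[labels == _POSITIVE_CLASS], values[labels != _POSITIVE_CLASS]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for ROC analysis")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = u / (len(pos) * len(neg))
    direction = "greater"
    if auc < 0.5:
        auc, direction = 1.0 - auc, "less"

    signed = values if direction == "greater" else -values
    order = np.argsort(signed)
    sorted_vals = signed[order]
    cuts = np.concatenate(
        [[sorted_vals[0] - 1.0], (sorted_vals[1:] + sorted_vals[:-1]) / 2, [sorted_vals[-1] + 1.0]]
    )
    best_j, best = 0.0, -np.inf
    is_pos = labels == _POSITIVE_CLASS
    for cut in cuts:
        called = signed > cut
        sens = (called & is_pos).sum() / is_pos.sum()
        spec = (~called & ~is_pos).sum() / (~is_pos).sum()
        if sens + spec - 1 > best:
            best, best_j = sens + spec - 1, cut
    threshold = best_j if direction == "greater" else -best_j
    return RocResult(str(name), float(auc), float(threshold), direction)


def _make_estimator(algorithm: str, n_components: int, seed: int):
    if algorithm == "plsda":
        return PLSRegression(n_components=n_components, scale=False)
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    raise ValueError(f"unknown panel algorithm {algorithm!r}")


def fit_panel(
    matrix: FeatureMatrix,
    features: Sequence[str],
    algorithm: str = "plsda",
    n_components: int = 2,
    cv: Optional[CvConfig] = None,
) -> tuple:
    """Train a panel on the testing split and cross-validate it.

    Only testing-split samples are used.  Returns ``(model, cv_auc,
    cv_accuracy)`` where the CV metrics are means over repeated stratified
    Monte-Carlo splits (accuracy at probability 0.5).
    """
    cv = cv or CvConfig()
    features = list(features)
    missing = [f for f in features if f not in matrix.X.columns]
    if missing:
        raise KeyError(f"panel features missing from matrix: {missing}")
    train = matrix.subset("testing")
    y = (train.groups == _POSITIVE_CLASS).to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("testing split must contain both classes")
    X = train.X[features].to_numpy()

    n_components = min(n_components, len(features))
    aucs, accs = [], []
    splitter = StratifiedShuffleSplit(
        n_splits=cv.repeats, train_size=cv.train_fraction, random_state=cv.seed
    )
    for idx_train, idx_test in splitter.split(X, y):
        if len(np.unique(y[idx_test])) < 2:
            continue
        scaler = StandardScaler().fit(X[idx_train])
        est = _make_estimator(algorithm, n_components, cv.seed)
        est.fit(scaler.transform(X[idx_train]), y[idx_train])
        if algorithm == "plsda":
            prob = np.clip(np.asarray(est.predict(scaler.transform(X[idx_test]))).ravel(), 0, 1)
        else:
            prob = est.predict_proba(scaler.transform(X[idx_test]))[:, 1]
        fold_labels = np.where(y[idx_test] == 1, _POSITIVE_CLASS, "WT")
        aucs.append(univariate_roc(prob, fold_labels).auc)
        accs.append(((prob >= 0.5).astype(int) == y[idx_test]).mean())

    scaler = StandardScaler().fit(X)
    est = _make_estimator(algorithm, n_components, cv.seed)
    est.fit(scaler.transform(X), y)
    model = PanelModel(
        features, algorithm, scaler, est, list(train.X.index), n_components
    )
    return model, float(np.mean(aucs)), float(np.mean(accs))


def predict_validation(model: PanelModel, matrix: FeatureMatrix) -> RocResult:
    """Blind class prediction of the validation split.

    Refuses to score samples the model has already seen (split leakage).
    Accuracy and AUC are computed only when true labels are available.
    """
    valid = matrix.subset("validation")
    overlap = set(valid.X.index) & set(model.training_samples)
    if overlap:
        raise ValueError(f"validation samples seen in training: {sorted(overlap)}")
    if valid.X.empty:
        return RocResult("panel:" + "+".join(model.features), np.nan)
    prob = model.predict_proba(valid.X)
    predicted = pd.Series(
        np.where(prob >= 0.5, _POSITIVE_CLASS, "WT"), index=prob.index, name="predicted"
    )
    accuracy = auc = None
    labels = valid.groups
    if set(labels.unique()) >= {"WT", _POSITIVE_CLASS}:
        accuracy = float((predicted == labels).mean())
        auc = univariate_roc(prob.to_numpy(), labels.to_numpy()).auc
    return RocResult(
        "panel:" + "+".join(model.features),
        auc if auc is not None else np.nan,
        probabilities=prob,
        predicted=predicted,
        accuracy=accuracy,
    )
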