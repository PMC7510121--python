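"""Biological-status prediction from 46-metric profiles.

Covers the discrimination toolkit applied to the phenotypic profiles:
correlation-based PCA, four classifier families (subspace discriminant
ensemble, linear SVM, logistic regression, K-nearest neighbors) under
stratified 5-fold cross-validation with an optional held-out validation
set, ROC/AUC, and bidirectional stepwise logistic feature selection
minimizing AIC.

The subspace discriminant ensemble (SDE) is a probability-averaged vote
over B linear discriminant learners, each trained on a random feature
subspace of dimension d_sub (defaults: B = 30, d_sub = ceil(d/2), the
common "subspace discriminant" convention).  It is an sklearn-style
estimator and composes with sklearn pipelines and model selection.

Undefined (NaN-flagged) metrics from low-bead images are imputed with the
training-fold per-metric median; features are standardized on training
folds for every model family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.multiclass import check_classification_targets
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ParameterError

MODEL_NAMES = ("sde", "svm", "logistic", "knn")


class SubspaceDiscriminantEnsemble(ClassifierMixin, BaseEstimator):
    """Random-subspace ensemble of linear discriminants.

    Each of ``n_estimators`` learners sees a random subset of
    ``subspace_dim`` features (default ceil(d/2)) and is a linear
    discriminant; a learner whose within-class covariance is singular is
    refit with ridge (Ledoit-Wolf) shrinkage rather than dropped.
    Learner votes are aggregated by averaging posterior probabilities
    (a probability-weighted vote, the convention for discriminant
    ensembles); ``predict`` takes the class with the highest average
    posterior.
    """

    def __init__(self, n_estimators: int = 30, subspace_dim: int | None = None, random_state=None):
        self.n_estimators = n_estimators
        self.subspace_dim = subspace_dim
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        check_classification_targets(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ParameterError(
                "this classifier needs samples of at least 2 classes, got 1 class"
            )
        d = X.shape[1]
        d_sub = self.subspace_dim if self.subspace_dim is not None else math.ceil(d / 2)
        if not (1 <= d_sub <= d):
            raise ParameterError(f"subspace_dim must be in [1, {d}], got {d_sub}")
        rng = np.random.default_rng(self.random_state)
        self.estimators_: list[tuple[np.ndarray, LinearDiscriminantAnalysis]] = []
        for _ in range(self.n_estimators):
            idx = np.sort(rng.choice(d, size=d_sub, replace=False))
            lda = LinearDiscriminantAnalysis(solver="lsqr")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    lda.fit(X[:, idx], y_enc)
                except np.linalg.LinAlgError:
                    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                    lda.fit(X[:, idx], y_enc)
            self.estimators_.append((idx, lda))
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for idx, lda in self.estimators_:
            proba += lda.predict_proba(X[:, idx])
        return proba / len(self.estimators_)

    def decision_function(self, X):
        proba = self.predict_proba(X)
        if len(self.classes_) == 2:
            # zero-thresholded margin, sign-consistent with predict
            return proba[:, 1] - proba[:, 0]
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)  # performs the fitted/input checks
        return self.classes_[proba.argmax(axis=1)]


@dataclass
class PCASummary:
    component_loadings: np.ndarray  # (n_components, n_features_kept)
    variance_fractions: np.ndarray
    scores: np.ndarray  # (n_samples, n_components)
    kept_features: list[int] = field(default_factory=list)


def pca_summary(X: np.ndarray, standardize: bool = True) -> PCASummary:
    """Correlation-based PCA: features standardized to unit variance
    (zero-variance features dropped with a warning), variance fractions
    summing to one, and per-sample scores."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ParameterError("PCA needs at least 2 samples")
    X = SimpleImputer(strategy="median").fit_transform(X)
    sd = X.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - kept.size} zero-variance feature(s) before PCA")
    X = X[:, kept]
    if standardize:
        X = StandardScaler().fit_transform(X)
    pca = PCA()
    scores = pca.fit_transform(X)
    return PCASummary(
        component_loadings=pca.components_,
        variance_fractions=pca.explained_variance_ratio_,
        scores=scores,
        kept_features=[int(k) for k in kept],
    )


@dataclass
class ClassifierReport:
    model_name: str
    train_accuracy: float
    cv_accuracy: float
    validation_accuracy: float  # NaN when no validation set given
    per_fold: list[float]
    roc_points: list[tuple[float, float]]
    auc: float
    selected_features: list[int] = field(default_factory=list)
    seed: int = 0


def make_model(model_name: str, seed: int = 0) -> Pipeline:
    """Imputation + standardization + classifier pipeline for one family."""
    if model_name == "sde":
        clf = SubspaceDiscriminantEnsemble(random_state=seed)
    elif model_name == "svm":
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
    elif model_name == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif model_name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ParameterError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )


def fit_classifier(
    X: np.ndarray,
    y: np.ndarray,
    model_name: str = "sde",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> Pipeline:
    """Fit one model family on the full feature set; deterministic given
    ``seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ParameterError("need exactly two classes with >= 2 samples each")
    model = make_model(model_name, seed=seed)
    if hyperparams:
        model.set_params(**{f"clf__{k}": v for k, v in hyperparams.items()})
    return model.fit(X, y)


def _decision_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X), dtype=float)
        except AttributeError:
            pass
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def roc_auc(model: Pipeline, X_val: np.ndarray, y_val: np.ndarray):
    """ROC by threshold sweep over the model's continuous scores and AUC
    by the trapezoidal rule; undefined (NaN) for single-class sets."""
    scores = _decision_scores(model, np.asarray(X_val, dtype=float))
    return roc_from_scores(np.asarray(y_val), scores)


def roc_from_scores(y: np.ndarray, scores: np.ndarray):
    classes = np.unique(y)
    if len(classes) < 2:
        return [], float("nan")
    positive = classes[-1]
    fpr, tpr, _ = roc_curve(y, scores, pos_label=positive)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_name: str = "sde",
    k: int = 5,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    hyperparams: dict | None = None,
) -> ClassifierReport:
    """Stratified k-fold cross-validation of one model family.

    ``cv_accuracy`` is the mean per-fold accuracy.  ROC/AUC come from the
    held-out validation set when given, otherwise from pooled
    out-of-fold scores.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ParameterError("binary tasks only")
    if k > counts.min():
        raise ParameterError(
            f"k={k} exceeds the smallest class size {counts.min()}; a class would vanish from a fold"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    oof_scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = fit_classifier(X[train_idx], y[train_idx], model_name, hyperparams, seed=seed)
        pred = model.predict(X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        oof_scores[test_idx] = _decision_scores(model, X[test_idx])
    full_model = fit_classifier(X, y, model_name, hyperparams, seed=seed)
    train_acc = float(np.mean(full_model.predict(X) == y))
    if X_val is not None and y_val is not None:
        val_acc = float(np.mean(full_model.predict(np.asarray(X_val, dtype=float)) == np.asarray(y_val)))
        roc_points, auc = roc_auc(full_model, X_val, y_val)
    else:
        val_acc = float("nan")
        roc_points, auc = roc_from_scores(y, oof_scores)
    return ClassifierReport(
        model_name=model_name,
        train_accuracy=train_acc,
        cv_accuracy=float(np.mean(fold_acc)),
        validation_accuracy=val_acc,
        per_fold=fold_acc,
        roc_points=roc_points,
        auc=auc,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# stepwise logistic feature selection


def _logit_aic(X: np.ndarray, y01: np.ndarray, subset: tuple[int, ...]) -> float:
    design = sm.add_constant(X[:, list(subset)] if subset else np.empty((len(y01), 0)), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, design).fit(disp=0, method="lbfgs", maxiter=200)
        except Exception:
            return float("inf")
    if not np.isfinite(res.llf):
        return float("inf")
    return float(2 * design.shape[1] - 2 * res.llf)


def stepwise_logistic(
    X: np.ndarray,
    y: np.ndarray,
    criterion: str = "aic",
    max_steps: int = 60,
):
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the intercept-only model; at each step the best single
    addition and the best single removal are considered and the move that
    most lowers AIC is taken; stops when neither improves.  Returns the
    selected feature indices in order of entry plus the fitted statsmodels
    result (None for an empty selection).
    """
    if criterion != "aic":
        raise ParameterError("only the AIC criterion is implemented")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) <= 10:
        raise ParameterError("need more than 10 samples for stepwise selection")
    X = SimpleImputer(strategy="median").fit_transform(X)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ParameterError("binary tasks only")
    y01 = (y == classes[-1]).astype(int)
    selected: list[int] = []
    current_aic = _logit_aic(X, y01, ())
    for _ in range(max_steps):
        best_move: tuple[str, int] | None = None
        best_aic = current_aic
        for j in range(X.shape[1]):
            if j in selected:
                continue
            aic = _logit_aic(X, y01, tuple(selected + [j]))
            if aic < best_aic - 1e-9:
                best_aic, best_move = aic, ("add", j)
        for j in selected:
            subset = tuple(k for k in selected if k != j)
            aic = _logit_aic(X, y01, subset)
            if aic < best_aic - 1e-9:
                best_aic, best_move = aic, ("drop", j)
        if best_move is None:
            break
        op, j = best_move
        if op == "add":
            selected.append(j)
        else:
            selected.remove(j)
        current_aic = best_aic
    if not selected:
        return [], None
    design = sm.add_constant(X[:, selected], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.Logit(y01, design).fit(disp=0, method="lbfgs", maxiter=200)
    return selected, result


# ---------------------------------------------------------------------------
# task labels


def labels_for_task(table: pd.DataFrame, task: str) -> tuple[np.ndarray, np.ndarray]:
    """(row mask, binary labels) for one of the study's binary tasks.

    ``young_vs_aged``: adult age <= 4 days vs > 4 days;
    ``cold_vs_control``: cold-shocked vs control/young;
    ``cold_vs_aged``; ``anterior_vs_posterior``.
    """
    if task == "young_vs_aged":
        age = table["age_day"]
        mask = age.notna()
        labels = np.where(age[mask] <= 4, "young", "aged")
    elif task == "cold_vs_control":
        mask = table["condition"].isin(["cold_shock", "control", "young"])
        labels = np.where(table.loc[mask, "condition"] == "cold_shock", "cold_shock", "control")
    elif task == "cold_vs_aged":
        mask = table["condition"].isin(["cold_shock", "aged"])
        labels = table.loc[mask, "condition"].to_numpy()
    elif task == "anterior_vs_posterior":
        mask = table["region"].isin(["anterior", "posterior"])
        labels = table.loc[mask, "region"].to_numpy()
    else:
        raise ParameterError(f"unknown task {task!r}")
    return mask.to_numpy(), np.asarray(labels)
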