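"""Multivariate layer: PCA, cross-validated LDA, CVA, permutation MANOVA.

The classifiers are scikit-learn style estimators (fit / predict /
get_params, fitted attributes with trailing underscores) so they compose
with sklearn pipelines and model selection; the module-level functions
``pca``, ``lda_cv``, ``cva`` and ``manova_permutation`` are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_X_y


@dataclass
class PcaModel:
    loadings: np.ndarray  # components x variables
    explained_ratio: np.ndarray
    retained: int  # smallest k with cumulative ratio > retain threshold
    scores: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray | None
    columns: list = field(default_factory=list)


def pca(X, retain: float = 0.95, standardize: bool = True, columns=None) -> PcaModel:
    """Standardized PCA; retained = smallest k with cumulative ratio > retain.

    Missing cells are rejected (imputation is out of scope).
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("missing or non-finite cells in the PCA matrix")
    scaler = StandardScaler(with_std=standardize)
    Xs = scaler.fit_transform(X)
    model = PCA()
    scores = model.fit_transform(Xs)
    cum = np.cumsum(model.explained_variance_ratio_)
    retained = int(np.searchsorted(cum, retain) + 1)
    retained = min(retained, scores.shape[1])
    return PcaModel(
        loadings=model.components_,
        explained_ratio=model.explained_variance_ratio_,
        retained=retained,
        scores=scores,
        mean_=scaler.mean_,
        scale_=scaler.scale_ if standardize else None,
        columns=list(columns) if columns is not None else [],
    )


@dataclass
class ClassifierReport:
    confusion: pd.DataFrame
    accuracy: float
    ci_low: float
    ci_high: float
    nir: float
    accuracy_p_value: float
    kappa: float
    per_class: pd.DataFrame  # sensitivity, specificity, precision
    cv_accuracy_mean: float
    cv_accuracy_std: float
    n_train: int
    n_test: int
    seed: int


def _classification_report(y_true, y_pred, classes, cv_scores, n_train, seed) -> ClassifierReport:
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = len(y_true)
    correct = int(np.trace(cm))
    acc = correct / n
    ci = sps.binomtest(correct, n).proportion_ci(confidence_level=0.95, method="exact")
    counts = pd.Series(y_true).value_counts()
    nir = counts.max() / n
    p_vs_nir = sps.binomtest(correct, n, p=nir, alternative="greater").pvalue
    kappa = cohen_kappa_score(y_true, y_pred, labels=classes)
    rows = []
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = cm.sum() - tp - fn - fp
        rows.append(
            {
                "class": cls,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
            }
        )
    return ClassifierReport(
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
        accuracy=float(acc),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        nir=float(nir),
        accuracy_p_value=float(p_vs_nir),
        kappa=float(kappa),
        per_class=pd.DataFrame(rows).set_index("class"),
        cv_accuracy_mean=float(np.mean(cv_scores)) if len(cv_scores) else np.nan,
        cv_accuracy_std=float(np.std(cv_scores)) if len(cv_scores) else np.nan,
        n_train=n_train,
        n_test=n,
        seed=seed,
    )


class CrossValidatedLDA(BaseEstimator, ClassifierMixin):
    """LDA with a stratified train/test split and k-fold CV on the train set.

    ``fit`` performs the full evaluation protocol: stratified 80/20 split,
    k-fold (default 10) cross-validation of the LDA on the training
    portion, refit on the whole training portion and evaluation on the
    held-out test set. The resulting :class:`ClassifierReport` (confusion
    matrix, accuracy with exact Clopper-Pearson CI, no-information rate
    with a one-sided binomial test, Cohen's kappa, per-class sensitivity /
    specificity / precision) lands in ``report_``.
    """

    def __init__(self, k: int = 10, test_size: float = 0.2, seed: int = 0):
        self.k = k
        self.test_size = test_size
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, float), np.asarray(y))
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("LDA needs at least 2 classes")
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=self.test_size, stratify=y, random_state=self.seed
        )
        if np.unique(y_tr).size < classes.size:
            raise ValueError("a class is absent from the training split")
        k_eff = min(self.k, int(np.min(np.unique(y_tr, return_counts=True)[1])))
        if k_eff >= 2:
            cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=self.seed)
            cv_scores = cross_val_score(LinearDiscriminantAnalysis(), X_tr, y_tr, cv=cv)
        else:
            cv_scores = np.array([])
        self.lda_ = LinearDiscriminantAnalysis().fit(X_tr, y_tr)
        self.classes_ = classes
        y_pred = self.lda_.predict(X_te)
        self.report_ = _classification_report(
            y_te, y_pred, list(classes), cv_scores, len(y_tr), self.seed
        )
        return self

    def predict(self, X):
        return self.lda_.predict(np.asarray(X, float))

    def decision_function(self, X):
        return self.lda_.decision_function(np.asarray(X, float))


def lda_cv(scores, labels, k: int = 10, test_size: float = 0.2, seed: int = 0) -> ClassifierReport:
    return CrossValidatedLDA(k=k, test_size=test_size, seed=seed).fit(scores, labels).report_


class CanonicalVariates(BaseEstimator, TransformerMixin):
    """Canonical variate analysis: axes maximizing between/within scatter.

    ``transform`` projects onto the (g - 1 at most) canonical axes;
    ``loo_scores_`` holds jack-knifed (leave-one-out) scores computed
    during ``fit``. A singular within-class scatter is ridge-regularized
    (recorded in ``regularized_``).
    """

    def __init__(self, regularization: float = 1e-8):
        self.regularization = regularization

    def _axes(self, X, y):
        classes = np.unique(y)
        mean = X.mean(axis=0)
        p = X.shape[1]
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        for c in classes:
            Xi = X[y == c]
            mi = Xi.mean(axis=0)
            W += (Xi - mi).T @ (Xi - mi)
            B += Xi.shape[0] * np.outer(mi - mean, mi - mean)
        reg = False
        ridge = self.regularization * np.trace(W) / p if np.trace(W) > 0 else self.regularization
        try:
            sol = np.linalg.solve(W, B)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(W + ridge * np.eye(p), B)
            reg = True
        if not np.isfinite(sol).all() or np.linalg.cond(W) > 1e12:
            sol = np.linalg.solve(W + ridge * np.eye(p), B)
            reg = True
        evals, evecs = np.linalg.eig(sol)
        order = np.argsort(evals.real)[::-1]
        k = min(classes.size - 1, p)
        return evecs.real[:, order[:k]], evals.real[order[:k]], reg

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, float), np.asarray(y))
        self.axes_, self.eigenvalues_, self.regularized_ = self._axes(X, y)
        self.mean_ = X.mean(axis=0)
        self.classes_ = np.unique(y)
        loo = np.empty((X.shape[0], self.axes_.shape[1]))
        for i in range(X.shape[0]):
            keep = np.arange(X.shape[0]) != i
            axes, _, _ = self._axes(X[keep], y[keep])
            # align jack-knifed axis signs with the full-sample axes
            for j in range(axes.shape[1]):
                if np.dot(axes[:, j], self.axes_[:, min(j, self.axes_.shape[1] - 1)]) < 0:
                    axes[:, j] = -axes[:, j]
            loo[i] = (X[i] - X[keep].mean(axis=0)) @ axes[:, : self.axes_.shape[1]]
        self.loo_scores_ = loo
        return self

    def transform(self, X):
        return (np.asarray(X, float) - self.mean_) @ self.axes_


def cva(scores, labels) -> CanonicalVariates:
    return CanonicalVariates().fit(scores, labels)


@dataclass
class ManovaResult:
    wilks_lambda: float
    n_permutations: int
    p_value: float


def wilks_lambda(X, y) -> float:
    """Wilks Lambda = det(W) / det(T) over groups of rows of X."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    mean = X.mean(axis=0)
    T = (X - mean).T @ (X - mean)
    W = np.zeros_like(T)
    for c in np.unique(y):
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        W += (Xi - mi).T @ (Xi - mi)
    detT = np.linalg.det(T)
    if detT <= 0:
        raise ValueError("singular total scatter")
    return float(np.clip(np.linalg.det(W) / detT, 0.0, 1.0))


def manova_permutation(
    scores, labels, n_perm: int = 999, components: int = 2, seed: int = 0
) -> ManovaResult:
    """Permutation MANOVA on the first ``components`` score columns.

    Wilks Lambda is the test statistic; labels are permuted ``n_perm``
    times and p = (1 + #{Lambda_perm <= Lambda_obs}) / (n_perm + 1), so the
    smallest attainable p is 1/(n_perm + 1).
    """
    X = np.asarray(scores, float)[:, :components]
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 groups")
    lam_obs = wilks_lambda(X, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if wilks_lambda(X, rng.permutation(y)) <= lam_obs:
            count += 1
    return ManovaResult(lam_obs, n_perm, (1 + count) / (n_perm + 1))
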