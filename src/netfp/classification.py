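"""Classification and fingerprinting on network edge vectors.

Disease classification pipeline (binary one-vs-all and multiclass):

1. stratified 70/30 train/test split;
2. edgewise confound model fitted on the healthy controls of the training
   split only, then applied to every scan (leakage-safe residualization);
3. features z-scored with train-split statistics;
4. L1-regularized logistic regression, penalty strength selected by
   repeated stratified k-fold cross-validation maximizing mean average
   precision (fold count shrinks so each fold keeps >= 1 positive);
5. test-set average precision and ROC AUC with percentile bootstrap CIs.

Also here: covariate predictability probes (elastic-net LR / KNN / SVM),
per-region importance scores, coefficient-overlap correlations, and
nearest-neighbour diagnostic fingerprinting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, rankdata, spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    confusion_matrix,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .harmonization import fit_edgewise_model, residualize

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "MulticlassReport",
    "CovariateReport",
    "FingerprintReport",
    "classify_disease_binary",
    "classify_multiclass",
    "predict_covariate",
    "regional_importance",
    "coefficient_overlap",
    "patient_fingerprint",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the classification pipeline (defaults follow the method)."""

    test_size: float = 0.3
    #: L1 penalty strengths (lambda); C = 1/lambda. Exact CV-score ties
    #: resolve to the weakest penalty (see _select_lambda).
    l1_lambda_grid: tuple[float, ...] = tuple(np.logspace(-3, 2, 15))
    cv_folds: int = 10
    cv_repeats: int = 10
    n_bootstrap: int = 1000
    negative_label: str = "HC"
    covariate_names: tuple[str, ...] = ("batch", "sex", "genotype", "age", "dw")


@dataclass
class ClassifierReport:
    task: str
    ap: float
    ap_ci: tuple[float, float]
    ap_chance: float
    roc_auc: float
    roc_auc_ci: tuple[float, float]
    selected_lambda: float
    coefficients: pd.Series
    test_scan_ids: list[str]
    cv_mean_ap: float
    test_scores: np.ndarray | None = None


@dataclass
class MulticlassReport:
    task: str
    balanced_accuracy: float
    ci: tuple[float, float]
    confusion: pd.DataFrame
    selected_lambda: float
    coefficients: pd.DataFrame
    test_scan_ids: list[str]


@dataclass
class CovariateReport:
    target: str
    best_model: str
    balanced_accuracy: float
    ci: tuple[float, float]
    per_model: dict[str, float]


@dataclass
class FingerprintReport:
    correlation: pd.DataFrame
    confusion: pd.DataFrame
    balanced_accuracy: float
    recall: pd.Series
    assigned: pd.Series


# --------------------------------------------------------------------------
# helpers


def _split(
    edge_table: pd.DataFrame, y: np.ndarray, test_size: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(edge_table))
    train, test = train_test_split(
        idx, test_size=test_size, stratify=y, random_state=seed
    )
    for part, name in ((train, "train"), (test, "test")):
        if np.unique(y[part]).size < np.unique(y).size:
            raise ValueError(
                f"a class is absent from the {name} split; try a different seed"
            )
    return np.sort(train), np.sort(test)


def _harmonize(
    edge_table: pd.DataFrame,
    covariates: pd.DataFrame | None,
    hc_train_ids: list[str],
    covariate_names: Sequence[str],
) -> pd.DataFrame:
    """Fit confound model on training HCs only; residualize everything."""
    if covariates is None:
        return edge_table
    usable = [c for c in covariate_names if c in covariates.columns]
    model = fit_edgewise_model(
        edge_table, covariates, fit_subset=hc_train_ids, covariate_names=usable
    )
    return residualize(model, edge_table, covariates)


def _l1_logistic(lam: float, multiclass: bool) -> LogisticRegression:
    # liblinear has no multiclass support; saga handles multinomial L1
    if multiclass:
        return LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=5000, random_state=0
        )
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=2000, random_state=0
    )


def _select_lambda(
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: ClassifierConfig,
    seed: int,
    scoring: str = "ap",
) -> tuple[float, float]:
    """Repeated stratified k-fold CV over the lambda grid.

    Returns (best lambda, its mean CV score).  Exact ties go to the weakest
    penalty: ties only arise in (near-)separable regimes, where the denser
    solution keeps the per-edge coefficients usable for regional-importance
    interpretation instead of collapsing onto a minimal separating subset.
    """
    classes, counts = np.unique(y_train, return_counts=True)
    n_min = int(counts.min())
    folds = min(config.cv_folds, n_min)  # each fold keeps >= 1 of the rarest class
    if folds < 2:
        raise ValueError("rarest class has < 2 training members; cannot cross-validate")

    lambdas = sorted(config.l1_lambda_grid)
    scores = np.zeros(len(lambdas))
    counts_arr = np.zeros(len(lambdas))
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed * 1000 + rep)
        for tr, va in skf.split(x_train, y_train):
            if np.unique(y_train[va]).size < classes.size:
                continue
            scaler = StandardScaler().fit(x_train[tr])
            xt, xv = scaler.transform(x_train[tr]), scaler.transform(x_train[va])
            for li, lam in enumerate(lambdas):
                clf = _l1_logistic(lam, multiclass=classes.size > 2)
                clf.fit(xt, y_train[tr])
                if scoring == "ap":
                    s = clf.decision_function(xv)
                    scores[li] += average_precision_score(y_train[va], s)
                else:
                    scores[li] += balanced_accuracy_score(y_train[va], clf.predict(xv))
                counts_arr[li] += 1
    mean_scores = scores / np.maximum(counts_arr, 1)
    best = max(range(len(lambdas)), key=lambda i: (round(mean_scores[i], 12), -lambdas[i]))
    return lambdas[best], float(mean_scores[best])


def _bootstrap_ci(
    metric_fn, y_test: np.ndarray, scores: np.ndarray, n_boot: int, seed: int
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    vals = []
    n = len(y_test)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(y_test[idx]).size < 2:
            continue
        vals.append(metric_fn(y_test[idx], scores[idx]))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# disease classification


def classify_disease_binary(
    edge_table: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """One-vs-all disease classification (disease = positive class).

    ``labels`` holds diagnosis strings; rows equal to
    ``config.negative_label`` are the controls.  When ``covariates`` is
    given, the confound model is fitted on control training rows only.
    """
    config = config or ClassifierConfig()
    labels = labels.loc[edge_table.index]
    y = (labels != config.negative_label).to_numpy(dtype=int)
    if y.sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >= 2 scans per class")

    train, test = _split(edge_table, y, config.test_size, seed)
    train_ids = list(edge_table.index[train])
    test_ids = list(edge_table.index[test])
    hc_train = [s for s, yy in zip(train_ids, y[train]) if yy == 0]
    corrected = _harmonize(edge_table, covariates, hc_train, config.covariate_names)

    x = corrected.to_numpy(dtype=float)
    lam, cv_ap = _select_lambda(x[train], y[train], config, seed, scoring="ap")

    scaler = StandardScaler().fit(x[train])
    clf = _l1_logistic(lam, multiclass=False)
    clf.fit(scaler.transform(x[train]), y[train])
    scores = clf.decision_function(scaler.transform(x[test]))

    ap = float(average_precision_score(y[test], scores))
    auc = float(roc_auc_score(y[test], scores))
    ap_ci = _bootstrap_ci(average_precision_score, y[test], scores, config.n_bootstrap, seed)
    auc_ci = _bootstrap_ci(roc_auc_score, y[test], scores, config.n_bootstrap, seed + 1)

    disease = sorted(set(labels) - {config.negative_label})
    return ClassifierReport(
        task="+".join(disease) + f"_vs_{config.negative_label}",
        ap=ap,
        ap_ci=ap_ci,
        ap_chance=float(y[test].mean()),
        roc_auc=auc,
        roc_auc_ci=auc_ci,
        selected_lambda=float(lam),
        coefficients=pd.Series(clf.coef_.ravel(), index=edge_table.columns),
        test_scan_ids=test_ids,
        cv_mean_ap=cv_ap,
        test_scores=scores,
    )


def classify_multiclass(
    edge_table: pd.DataFrame,
    group_labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    hc_labels: Sequence[str] | None = None,
) -> MulticlassReport:
    """Multiclass L1 logistic regression (one-vs-rest) over diagnostic groups.

    When covariates are supplied the confound model is fitted on the
    training rows whose label is in ``hc_labels`` (default: all training
    rows, since patient-only multiclass tables contain no controls).
    """
    config = config or ClassifierConfig()
    group_labels = group_labels.loc[edge_table.index]
    y = group_labels.to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 groups")

    train, test = _split(edge_table, y, config.test_size, seed)
    train_ids = list(edge_table.index[train])
    test_ids = list(edge_table.index[test])
    if hc_labels is not None:
        fit_ids = [s for s, g in zip(train_ids, y[train]) if g in set(hc_labels)]
    else:
        fit_ids = train_ids
    corrected = _harmonize(edge_table, covariates, fit_ids, config.covariate_names)

    x = corrected.to_numpy(dtype=float)
    lam, _ = _select_lambda(x[train], y[train], config, seed, scoring="balanced_accuracy")

    scaler = StandardScaler().fit(x[train])
    clf = _l1_logistic(lam, multiclass=np.unique(y).size > 2)
    clf.fit(scaler.transform(x[train]), y[train])
    pred = clf.predict(scaler.transform(x[test]))

    ba = float(balanced_accuracy_score(y[test], pred))
    rng = np.random.default_rng(seed)
    vals = []
    n = len(test)
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.unique(y[test][idx]).size < np.unique(y).size:
            continue
        vals.append(balanced_accuracy_score(y[test][idx], pred[idx]))
    lo, hi = (np.percentile(vals, [2.5, 97.5]) if vals else (ba, ba))

    groups = list(clf.classes_)
    cm = confusion_matrix(y[test], pred, labels=groups)
    return MulticlassReport(
        task="multiclass",
        balanced_accuracy=ba,
        ci=(float(lo), float(hi)),
        confusion=pd.DataFrame(cm, index=groups, columns=groups),
        selected_lambda=float(lam),
        coefficients=pd.DataFrame(clf.coef_, index=groups, columns=edge_table.columns),
        test_scan_ids=test_ids,
    )


# --------------------------------------------------------------------------
# covariate predictability


def _covariate_models(seed: int) -> dict[str, object]:
    return {
        "LR-elasticnet": LogisticRegression(
            solver="saga", l1_ratio=0.5, C=1.0,
            max_iter=5000, random_state=seed,
        ),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "SVM-linear": SVC(kernel="linear", C=1.0, random_state=seed),
        "SVM-poly": SVC(kernel="poly", degree=3, C=1.0, random_state=seed),
        "SVM-rbf": SVC(kernel="rbf", C=1.0, random_state=seed),
    }


_COVARIATE_GRIDS: dict[str, dict[str, list]] = {
    "LR-elasticnet": {"C": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "SVM-linear": {"C": [0.1, 1.0, 10.0]},
    "SVM-poly": {"C": [0.1, 1.0, 10.0]},
    "SVM-rbf": {"C": [0.1, 1.0, 10.0]},
}


def predict_covariate(
    edge_table: pd.DataFrame,
    covariates: pd.DataFrame,
    target: str,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    models: Sequence[str] | None = None,
) -> CovariateReport:
    """How well can a covariate (batch / sex / genotype) be predicted?

    The other covariates are regressed out first (confound model fitted on
    the training rows), then each classifier family is grid-searched with
    stratified k-fold CV on balanced accuracy; the best model's test
    balanced accuracy and bootstrap CI are reported.
    """
    from sklearn.model_selection import GridSearchCV

    config = config or ClassifierConfig()
    if target not in covariates.columns:
        raise ValueError(f"unknown target covariate {target!r}")
    y_raw = covariates.loc[edge_table.index, target].astype(str)
    if y_raw.nunique() < 2:
        raise ValueError(f"target {target!r} has a single class")
    y = y_raw.to_numpy()

    train, test = _split(edge_table, y, config.test_size, seed)
    train_ids = list(edge_table.index[train])

    others = [
        c for c in config.covariate_names
        if c != target and c in covariates.columns
        and covariates.loc[edge_table.index, c].nunique() > 1
    ]
    if others:
        model = fit_edgewise_model(
            edge_table, covariates, fit_subset=train_ids, covariate_names=others
        )
        corrected = residualize(model, edge_table, covariates)
    else:
        corrected = edge_table

    x = corrected.to_numpy(dtype=float)
    scaler = StandardScaler().fit(x[train])
    xt, xs = scaler.transform(x[train]), scaler.transform(x[test])

    classes, counts = np.unique(y[train], return_counts=True)
    folds = max(2, min(config.cv_folds, int(counts.min())))
    names = list(models) if models is not None else list(_covariate_models(seed))
    per_model: dict[str, float] = {}
    preds: dict[str, np.ndarray] = {}
    for name in names:
        est = _covariate_models(seed)[name]
        gs = GridSearchCV(
            est, _COVARIATE_GRIDS[name],
            scoring="balanced_accuracy",
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        gs.fit(xt, y[train])
        pred = gs.predict(xs)
        per_model[name] = float(balanced_accuracy_score(y[test], pred))
        preds[name] = pred

    best = max(per_model, key=lambda k: per_model[k])
    rng = np.random.default_rng(seed)
    vals = []
    n = len(test)
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.unique(y[test][idx]).size < 2:
            continue
        vals.append(balanced_accuracy_score(y[test][idx], preds[best][idx]))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return CovariateReport(
        target=target,
        best_model=best,
        balanced_accuracy=per_model[best],
        ci=(float(lo), float(hi)),
        per_model=per_model,
    )


# --------------------------------------------------------------------------
# interpretation


def regional_importance(
    per_edge_coefficients: pd.Series | np.ndarray, roi_names: Sequence[str]
) -> pd.Series:
    """score(ROI) = sum of |beta| over edges touching the ROI.

    Conservation: sum over ROIs = 2 * sum over edges of |beta|.
    """
    beta = np.abs(np.asarray(per_edge_coefficients, dtype=float))
    r = len(roi_names)
    if beta.size != r * (r - 1) // 2:
        raise ValueError(
            f"coefficient vector length {beta.size} does not match {r} ROIs"
        )
    iu, ju = np.triu_indices(r, k=1)
    score = np.zeros(r)
    np.add.at(score, iu, beta)
    np.add.at(score, ju, beta)
    return pd.Series(score, index=list(roi_names), name="importance")


def coefficient_overlap(
    beta_task1, beta_task2, method: str = "kendall"
) -> tuple[float, float]:
    """Rank correlation between two classifiers' coefficient vectors."""
    a = np.asarray(beta_task1, dtype=float)
    b = np.asarray(beta_task2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coefficient vectors must have equal length")
    if method == "kendall":
        res = kendalltau(a, b)
    elif method == "spearman":
        res = spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r} (use 'kendall' or 'spearman')")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# fingerprinting


def patient_fingerprint(
    edge_table_patients: pd.DataFrame,
    diagnoses: pd.Series,
    harmonization_model=None,
    covariates: pd.DataFrame | None = None,
) -> FingerprintReport:
    """Nearest-neighbour diagnostic assignment from edge-vector correlations.

    Each patient is assigned the diagnosis of the other patient with the
    highest Spearman correlation (self excluded).  Pass a fitted
    harmonization model (with its covariate table) for the corrected
    variant, or neither for the uncorrected sensitivity variant.
    """
    diagnoses = diagnoses.loc[edge_table_patients.index]
    if diagnoses.nunique() < 2:
        raise ValueError("fingerprinting needs >= 2 diagnostic groups")
    table = edge_table_patients
    if harmonization_model is not None:
        if covariates is None:
            raise ValueError("covariates are required to apply the harmonization model")
        table = residualize(harmonization_model, table, covariates)

    ranks = np.apply_along_axis(rankdata, 1, table.to_numpy(dtype=float))
    z = ranks - ranks.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    corr = z @ z.T
    np.fill_diagonal(corr, -np.inf)

    nearest = np.argmax(corr, axis=1)
    assigned = pd.Series(
        diagnoses.to_numpy()[nearest], index=table.index, name="assigned"
    )
    groups = sorted(diagnoses.unique())
    cm = confusion_matrix(diagnoses, assigned, labels=groups)
    confusion = pd.DataFrame(cm, index=groups, columns=groups)
    recall = pd.Series(
        np.diag(cm) / cm.sum(axis=1), index=groups, name="recall"
    )
    np.fill_diagonal(corr, 1.0)
    return FingerprintReport(
        correlation=pd.DataFrame(corr, index=table.index, columns=table.index),
        confusion=confusion,
        balanced_accuracy=float(recall.mean()),
        recall=recall,
        assigned=assigned,
    )
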