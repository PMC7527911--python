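"""Feature tables, cross-validation, classifiers/regressors, and evaluation.

Diagnosis is binary classification (PD vs non-PD) evaluated by
accuracy/precision/recall/F1 from a confusion matrix pooled over the folds
of a seeded 5-fold cross-validation; the positive class is PD, so recall
is PD sensitivity. Severity estimation is regression of the UPDRS score
(0-199) evaluated by MAE/MSE/RMSE on a held-out test split of a 4:1:1
train/validation/test partition, the validation part selecting the
regularization setting. Feature standardization always uses
training-portion statistics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

logger = logging.getLogger(__name__)

UPDRS_MAX = 199.0

CLASSIFIERS = ("svm", "logreg", "nn1", "nn2", "gnb")
REGRESSORS = ("svr", "linear", "lasso")


@dataclass
class FeatureTable:
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X columns and feature_names differ")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("feature table contains missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold: list[ConfusionMatrix]
    algo: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "algo": self.algo,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_fold": [
                {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn} for cm in self.per_fold
            ],
        }


@dataclass
class RegressionReport:
    mae: float
    mse: float
    rmse: float
    algo: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "algo": self.algo,
            "seed": self.seed,
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
        }


# ---------------------------------------------------------------------------
# table loading: the two public-repository CSV dialects


def _find_col(columns, name: str) -> str:
    for c in columns:
        if c.strip().lower() == name.lower():
            return c
    raise ValueError(f"missing expected column {name!r}")


def read_uci_table(path, dialect: str, target: str = "total_UPDRS") -> FeatureTable:
    """Load a CSV feature table in one of the two public-dataset dialects.

    ``parkinsons``: one name column, 22 voice features, binary ``status``.
    ``telemonitoring``: subject id, age, sex, test_time, motor_UPDRS,
    total_UPDRS and 16 voice features; ``target`` selects which UPDRS
    column becomes y (total by default). Column names match
    case-insensitively.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty feature table: {path}")
    if dialect == "parkinsons":
        name_col = _find_col(df.columns, "name")
        status_col = _find_col(df.columns, "status")
        feat_cols = [c for c in df.columns if c not in (name_col, status_col)]
        X = df[feat_cols].to_numpy(dtype=np.float64)
        y = df[status_col].to_numpy(dtype=np.float64)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("status column must be binary 0/1")
        return FeatureTable(feat_cols, X, y, groups=df[name_col].to_numpy())
    if dialect == "telemonitoring":
        subj = _find_col(df.columns, "subject#")
        meta_cols = [_find_col(df.columns, c) for c in ("age", "sex", "test_time")]
        motor = _find_col(df.columns, "motor_UPDRS")
        total = _find_col(df.columns, "total_UPDRS")
        tgt = _find_col(df.columns, target)
        drop = {subj, motor, total, *meta_cols}
        feat_cols = [c for c in df.columns if c not in drop]
        X = df[feat_cols].to_numpy(dtype=np.float64)
        y = df[tgt].to_numpy(dtype=np.float64)
        return FeatureTable(
            feat_cols, X, y, groups=df[subj].to_numpy(), meta=df[meta_cols].copy()
        )
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# splitting


def kfold_split(n: int, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random k-fold partition; fold sizes differ by at most one."""
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    return [
        (np.sort(np.concatenate(folds[:i] + folds[i + 1 :])), np.sort(folds[i]))
        for i in range(k)
    ]


def train_val_test_split(n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 4:1:1 partition into train/validation/test index arrays."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts = np.array_split(perm, 6)
    return (
        np.sort(np.concatenate(parts[:4])),
        np.sort(parts[4]),
        np.sort(parts[5]),
    )


# ---------------------------------------------------------------------------
# models


def make_classifier(algo: str, seed: int = 0):
    if algo == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if algo == "logreg":
        return LogisticRegression(C=1.0, max_iter=2000)
    mlp_kw = dict(
        max_iter=2000, early_stopping=True, n_iter_no_change=30,
        learning_rate_init=0.05, validation_fraction=0.15, random_state=seed,
    )
    if algo == "nn1":
        return MLPClassifier(hidden_layer_sizes=(16,), **mlp_kw)
    if algo == "nn2":
        return MLPClassifier(hidden_layer_sizes=(16, 8), **mlp_kw)
    if algo == "gnb":
        return GaussianNB()
    raise ValueError(f"unknown classifier {algo!r}; choose from {CLASSIFIERS}")


def make_regressor(algo: str, reg: float = 1.0):
    if algo == "svr":
        return SVR(kernel="rbf", C=reg, epsilon=0.1, gamma="scale")
    if algo == "linear":
        return LinearRegression()
    if algo == "lasso":
        return Lasso(alpha=reg, max_iter=50_000)
    raise ValueError(f"unknown regressor {algo!r}; choose from {REGRESSORS}")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = y_true.astype(int)
    y_pred = y_pred.astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def run_classification(
    table: FeatureTable, algo: str = "svm", k: int = 5, seed: int = 0,
    pooled: bool = True,
) -> ClassificationReport:
    """k-fold cross-validated classification with fold-local standardization.

    Metrics come from the confusion matrix pooled over folds (micro
    average) by default; ``pooled=False`` averages per-fold metrics instead.
    """
    classes = np.unique(table.y)
    if len(classes) < 2:
        raise ValueError("classification needs both classes present")
    per_fold: list[ConfusionMatrix] = []
    for tr, va in kfold_split(table.n, k, seed):
        scaler = StandardScaler().fit(table.X[tr])
        clf = make_classifier(algo, seed)
        clf.fit(scaler.transform(table.X[tr]), table.y[tr])
        pred = clf.predict(scaler.transform(table.X[va]))
        per_fold.append(_confusion(table.y[va], pred))
    if pooled:
        cm = per_fold[0]
        for f in per_fold[1:]:
            cm = cm + f
        acc, prec, rec, f1 = classification_metrics(cm)
    else:
        ms = np.array([classification_metrics(f) for f in per_fold])
        acc, prec, rec, f1 = ms.mean(axis=0)
    return ClassificationReport(acc, prec, rec, f1, per_fold, algo, seed)


_REG_GRIDS = {
    "svr": [0.1, 1.0, 10.0, 100.0],
    "lasso": list(np.geomspace(1e-4, 10.0, 20)),
    "linear": [1.0],
}


def run_regression(
    table: FeatureTable, algo: str = "svr", k: int = 5, seed: int = 0,
) -> RegressionReport:
    """4:1:1 train/validation/test regression with validation-selected regularization.

    Features are standardized with training statistics; for SVR the target
    is standardized too (and predictions mapped back) so the default kernel
    scale is meaningful regardless of the UPDRS range.
    """
    del k  # the fold count parameterizes the companion k-fold variant
    if table.n < 7:
        raise ValueError("too few records for a 4:1:1 split")
    tr, va, te = train_val_test_split(table.n, seed)
    if algo == "lasso" and np.ptp(table.y[tr]) == 0:
        logger.warning("constant target: lasso fit is uninformative")

    best_err, best_reg = np.inf, _REG_GRIDS[algo][0]
    for reg in _REG_GRIDS[algo]:
        pred = _fit_predict_regression(table, tr, va, algo, reg)
        err = float(np.mean(np.abs(table.y[va] - pred)))
        if err < best_err:
            best_err, best_reg = err, reg
    fit_idx = np.sort(np.concatenate([tr, va]))
    pred = _fit_predict_regression(table, fit_idx, te, algo, best_reg)
    mae, mse, rmse = regression_metrics(table.y[te], pred)
    return RegressionReport(mae, mse, rmse, algo, seed)


def _fit_predict_regression(table, fit_idx, eval_idx, algo, reg) -> np.ndarray:
    scaler = StandardScaler().fit(table.X[fit_idx])
    Xf = scaler.transform(table.X[fit_idx])
    Xe = scaler.transform(table.X[eval_idx])
    y = table.y[fit_idx]
    model = make_regressor(algo, reg)
    if algo == "svr":
        mu, sd = y.mean(), y.std()
        sd = sd if sd > 0 else 1.0
        model.fit(Xf, (y - mu) / sd)
        return model.predict(Xe) * sd + mu
    model.fit(Xf, y)
    return model.predict(Xe)


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1), all in percent."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        logger.warning("no positive predictions: precision set to 0 by convention")
        prec = 0.0
    else:
        prec = cm.tp / (cm.tp + cm.fp)
    if cm.tp + cm.fn == 0:
        logger.warning("no positive truths: recall set to 0 by convention")
        rec = 0.0
    else:
        rec = cm.tp / (cm.tp + cm.fn)
    if prec + rec == 0:
        logger.warning("precision + recall = 0: F1 set to 0 by convention")
        f1 = 0.0
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return (acc * 100.0, prec * 100.0, rec * 100.0, f1 * 100.0)


def regression_metrics(truth, pred) -> tuple[float, float, float]:
    """(MAE, MSE, RMSE)."""
    t = np.asarray(truth, dtype=np.float64)
    p = np.asarray(pred, dtype=np.float64)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("truth and prediction must be equal-length and non-empty")
    err = t - p
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    return (mae, mse, float(np.sqrt(mse)))


# ---------------------------------------------------------------------------
# feature relevance


def lasso_feature_ranking(
    table: FeatureTable, lambda_grid=None, seed: int = 0
) -> list[tuple[str, float]]:
    """Rank features by |LASSO weight| at the validation-selected penalty.

    Features and target are standardized; the penalty is chosen on a 4:1
    seeded hold-out by MAE; zero-weight features are excluded from the
    returned (name, signed weight) list.
    """
    grid = list(lambda_grid) if lambda_grid is not None else list(np.geomspace(1e-3, 1.0, 20))
    Xs = StandardScaler().fit_transform(table.X)
    y = table.y
    ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n)
    cut = int(0.8 * table.n)
    tr, va = perm[:cut], perm[cut:]

    best_err, best_alpha = np.inf, grid[0]
    for alpha in grid:
        model = Lasso(alpha=alpha, max_iter=50_000).fit(Xs[tr], ys[tr])
        err = float(np.mean(np.abs(ys[va] - model.predict(Xs[va]))))
        if err < best_err:
            best_err, best_alpha = err, alpha
    model = Lasso(alpha=best_alpha, max_iter=50_000).fit(Xs, ys)
    weights = model.coef_
    if np.all(weights == 0):
        raise ValueError("all LASSO weights zero at every penalty in the grid")
    order = np.argsort(-np.abs(weights))
    return [
        (table.feature_names[i], float(weights[i])) for i in order if weights[i] != 0.0
    ]


def feature_significance(
    table: FeatureTable, correct: bool = False
) -> list[tuple[str, float, float]]:
    """Per-feature two-sided Mann-Whitney U test between the two classes.

    Returns (feature, U, p) triples in table order. Constant features get
    p = 1 by convention. ``correct=True`` applies Benjamini-Hochberg to
    the p-values.
    """
    y = table.y
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("significance testing needs exactly two classes")
    a_idx, b_idx = y == classes[1], y == classes[0]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each class needs at least 2 members")
    out = []
    for j, name in enumerate(table.feature_names):
        a, b = table.X[a_idx, j], table.X[b_idx, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            out.append((name, a.size * b.size / 2.0, 1.0))
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out.append((name, float(u), float(p)))
    if correct:
        ps = stats.false_discovery_control([p for _, _, p in out])
        out = [(n, u, float(q)) for (n, u, _), q in zip(out, ps)]
    return out
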