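"""Per-site elastic-net classifiers under leave-one-patient-out CV.

Two region-level classification tasks are supported: treatment status
(untreated vs anti-CD40-treated tissue) and disease-free survival group
(long vs short, within the treated cohort, labels from a median split).
Each histopathologic site gets its own model; every cross-validation fold
holds out *all* regions of one patient so the model can never learn
patient-specific signal.

Inside each fold, in order: features are log10(x+1) transformed, min-max
scaled with the scaler fit on the training rows only (test values clipped
to [0, 1]), the training set is balanced by SMOTE, and a logistic model
with a mixed L1/L2 penalty (l1_ratio 0.5) is fit. Held-out predictions are
pooled across folds into a single confusion matrix, from which accuracy,
F1 (positive class) and AUC (midrank statistic on pooled probabilities)
are computed. Feature attribution uses the exact closed form for linear
models: shap_i(x) = w_i (x_i - mu_i) with mu the fold-train feature mean.

The regularization objective is normalized per training sample,
(1/n) sum loss + alpha * penalty, so duplicating every training row leaves
the fit unchanged; ``alpha`` is a fixed documented constant shared across
folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .constants import COHORT_ACD40, DFS_LONG, DFS_SHORT, SITES

logger = logging.getLogger(__name__)

TASKS = ("treatment", "dfs")


class ModelError(RuntimeError):
    pass


class ConvergenceError(ModelError):
    pass


@dataclass
class TaskSpec:
    task: str
    site: str
    positive_class: str = ""
    l1_ratio: float = 0.5
    alpha: float = 5e-2  # per-sample regularization strength
    seed: int = 0
    max_iter: int = 200_000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.task == "dfs" and self.site == "NAP":
            raise ValueError("the DFS task excludes NAP regions")
        if not self.positive_class:
            self.positive_class = COHORT_ACD40 if self.task == "treatment" else DFS_LONG


@dataclass
class FoldResult:
    held_out_patient: str
    test_region_ids: list[str]
    predictions: pd.DataFrame  # region_id, true, pred, prob(positive)
    coef: np.ndarray
    intercept: float
    base_value: float
    shap: pd.DataFrame  # test regions x features
    test_X: pd.DataFrame  # preprocessed test features


@dataclass
class ModelResult:
    spec: TaskSpec
    feature_names: list
    folds: list[FoldResult]
    pooled: pd.DataFrame
    confusion: dict  # TP/FP/FN/TN
    metrics: dict  # accuracy, f1, auc
    shap_values: pd.DataFrame
    importance: pd.Series
    direction: pd.Series

    def top_features(self, k: int = 15) -> pd.DataFrame:
        """Top-k features by mean |SHAP| with their driving direction."""
        top = self.importance.sort_values(ascending=False).head(k)
        return pd.DataFrame(
            {
                "importance": top,
                "direction": self.direction.reindex(top.index),
            }
        )

    def top_k_share(self, k: int = 30) -> float:
        total = float(self.importance.sum())
        if total == 0:
            return 0.0
        return float(self.importance.sort_values(ascending=False).head(k).sum()) / total


# ---------------------------------------------------------------------------
# Labels and folds
# ---------------------------------------------------------------------------

def derive_dfs_labels(patients: pd.DataFrame) -> pd.DataFrame:
    """Median-split DFS labels for treated patients (strictly above -> long).

    The median is computed over treated patients only; values at or below
    the median are labelled short.
    """
    out = patients.copy()
    treated = out["cohort"] == COHORT_ACD40
    dfs = out.loc[treated, "dfs_months"]
    if dfs.isna().any():
        missing = out.index[treated & out["dfs_months"].isna()].tolist()
        raise ValueError(f"treated patients missing dfs_months: {missing}")
    median = float(dfs.median())
    labels = np.where(dfs > median, DFS_LONG, DFS_SHORT)
    out["dfs_label"] = None
    out.loc[treated, "dfs_label"] = labels
    return out


def region_labels(task: str, regions: pd.DataFrame, patients: pd.DataFrame) -> pd.Series:
    """Per-region class labels for a task (DFS restricted to treated regions)."""
    if task == "treatment":
        return regions["cohort"].copy()
    if "dfs_label" not in patients.columns or patients["dfs_label"].isna().all():
        patients = derive_dfs_labels(patients)
    treated = regions[regions["cohort"] == COHORT_ACD40]
    return treated["patient_id"].map(patients["dfs_label"])


def make_folds_lopo(regions: pd.DataFrame, labels: pd.Series) -> list[tuple[str, list[str]]]:
    """One fold per patient: the fold's test set is that patient's regions."""
    if regions["patient_id"].nunique() < 2:
        raise ModelError("leave-one-patient-out needs at least 2 patients")
    observed = set(labels.dropna().unique())
    if len(observed) < 2:
        raise ModelError(f"unlearnable task: only one class present ({observed})")
    folds = []
    for pid in pd.unique(regions["patient_id"]):
        test_ids = regions.index[regions["patient_id"] == pid].tolist()
        folds.append((pid, test_ids))
    return folds


# ---------------------------------------------------------------------------
# Per-fold preprocessing, balancing, fitting
# ---------------------------------------------------------------------------

def preprocess_fold(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """log10(x+1) then per-column min-max fit on train; test clipped to [0,1].

    Columns constant on the training rows map to 0 everywhere (for both
    train and test) — a zero-range column carries no information and this
    avoids dividing by zero.
    """
    if not train.columns.equals(test.columns):
        raise ValueError("train and test matrices must share columns")
    if (train.to_numpy() < 0).any() or (test.to_numpy() < 0).any():
        raise ValueError("features must be non-negative")
    ltrain = np.log10(train.to_numpy(float) + 1.0)
    ltest = np.log10(test.to_numpy(float) + 1.0)
    lo = ltrain.min(axis=0)
    span = ltrain.max(axis=0) - lo
    nonconst = span > 0
    safe_span = np.where(nonconst, span, 1.0)
    strain = np.where(nonconst, (ltrain - lo) / safe_span, 0.0)
    stest = np.where(nonconst, (ltest - lo) / safe_span, 0.0)
    stest = np.clip(stest, 0.0, 1.0)
    return (
        pd.DataFrame(strain, index=train.index, columns=train.columns),
        pd.DataFrame(stest, index=test.index, columns=test.columns),
    )


def balance_train(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: up-sample the minority class to the majority count.

    Synthetic samples are convex combinations x_i + u (x_nn - x_i) of a
    minority point and one of its k = min(5, minority - 1) minority nearest
    neighbors. A single-point minority class is left unchanged with a
    warning; a one-class training set is an error.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("cannot balance a one-class training set")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X, y
    if n_min < 2:
        logger.warning("minority class has a single sample; skipping SMOTE")
        return X, y
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    k = min(5, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself
    n_new = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_new)
    neighbor = idx[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.random(n_new)[:, None]
    synthetic = Xmin[base] + u * (Xmin[neighbor] - Xmin[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def fit_en_model(
    X: np.ndarray, y: np.ndarray, spec: TaskSpec
) -> LogisticRegression:
    """Fit the elastic-net logistic model with per-sample-normalized penalty."""
    n = X.shape[0]
    C = 1.0 / (spec.alpha * n)
    y_bin = np.asarray(y == spec.positive_class)
    if np.all(X == X[0]):
        # Degenerate design (every row identical): the penalized optimum is
        # the intercept-only model, which saga does not reach reliably.
        prevalence = float(np.clip(y_bin.mean(), 1e-12, 1 - 1e-12))
        model = LogisticRegression()
        model.classes_ = np.array([False, True])
        model.coef_ = np.zeros((1, X.shape[1]))
        model.intercept_ = np.array([np.log(prevalence / (1 - prevalence))])
        model.n_iter_ = np.array([0])
        return model
    model = LogisticRegression(
        l1_ratio=spec.l1_ratio,
        C=C,
        solver="saga",
        tol=spec.tol,
        max_iter=spec.max_iter,
        random_state=spec.seed,
    )
    model.fit(X, y_bin)
    n_iter = int(np.max(model.n_iter_))
    if n_iter >= spec.max_iter:
        raise ConvergenceError(
            f"elastic-net solver hit max_iter={spec.max_iter} "
            f"(n={n}, p={X.shape[1]}, C={C:.3g})"
        )
    return model


# ---------------------------------------------------------------------------
# LOPO driver, scoring, attribution
# ---------------------------------------------------------------------------

def run_lopo(
    spec: TaskSpec,
    matrix: pd.DataFrame,
    regions: pd.DataFrame,
    labels: pd.Series,
) -> ModelResult:
    """Run the full leave-one-patient-out loop for one site model.

    *matrix* rows and *labels* must already be restricted to the site (and,
    for the DFS task, the treated cohort).
    """
    region_ids = matrix.index
    labels = labels.reindex(region_ids)
    if labels.isna().any():
        raise ModelError("labels missing for some regions in the matrix")
    folds_def = make_folds_lopo(regions.loc[region_ids], labels)

    folds: list[FoldResult] = []
    for pid, test_ids in folds_def:
        try:
            train_ids = [r for r in region_ids if r not in set(test_ids)]
            strain, stest = preprocess_fold(
                matrix.loc[train_ids], matrix.loc[test_ids]
            )
            y_train = labels.loc[train_ids].to_numpy()
            if len(np.unique(y_train)) < 2:
                raise ModelError("training fold lost one class entirely")
            Xb, yb = balance_train(strain.to_numpy(), y_train, spec.seed)
            model = fit_en_model(Xb, yb, spec)
            w = model.coef_.ravel()
            b = float(model.intercept_[0])
            prob = model.predict_proba(stest.to_numpy())[:, 1]
            pred = np.where(
                prob >= 0.5, spec.positive_class, _other_class(labels, spec)
            )
            mu = strain.mean(axis=0).to_numpy()
            shap = (stest.to_numpy() - mu) * w
            folds.append(
                FoldResult(
                    held_out_patient=pid,
                    test_region_ids=list(test_ids),
                    predictions=pd.DataFrame(
                        {
                            "region_id": test_ids,
                            "true": labels.loc[test_ids].to_numpy(),
                            "pred": pred,
                            "prob": prob,
                        }
                    ),
                    coef=w,
                    intercept=b,
                    base_value=float(w @ mu + b),
                    shap=pd.DataFrame(shap, index=test_ids, columns=matrix.columns),
                    test_X=stest,
                )
            )
        except Exception as exc:
            raise ModelError(f"fold for patient {pid!r} failed: {exc}") from exc

    pooled = pd.concat([f.predictions for f in folds], ignore_index=True)
    if set(pooled["region_id"]) != set(region_ids) or len(pooled) != len(region_ids):
        raise ModelError("pooled predictions do not cover every region exactly once")
    confusion, metrics = score_pooled(
        pooled["true"].to_numpy(),
        pooled["pred"].to_numpy(),
        pooled["prob"].to_numpy(),
        spec.positive_class,
    )
    shap_values, importance, direction = compute_shap(folds)
    return ModelResult(
        spec=spec,
        feature_names=list(matrix.columns),
        folds=folds,
        pooled=pooled,
        confusion=confusion,
        metrics=metrics,
        shap_values=shap_values,
        importance=importance,
        direction=direction,
    )


def _other_class(labels: pd.Series, spec: TaskSpec) -> str:
    others = [c for c in pd.unique(labels.dropna()) if c != spec.positive_class]
    if len(others) != 1:
        raise ModelError("expected a binary task")
    return others[0]


def score_pooled(
    y_true: np.ndarray, y_pred: np.ndarray, prob: np.ndarray, positive_class: str
) -> tuple[dict, dict]:
    """Pooled confusion matrix and accuracy / F1 / AUC.

    F1 is reported for the positive class; AUC is the rank statistic on the
    pooled positive-class probabilities with midrank tie handling.
    """
    t = y_true == positive_class
    p = y_pred == positive_class
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    if t.all() or (~t).all():
        raise ModelError("AUC undefined: pooled truth contains a single class")
    auc = float(roc_auc_score(t, prob))
    confusion = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return confusion, {"accuracy": accuracy, "f1": f1, "auc": auc}


def compute_shap(folds: list[FoldResult]) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Pool exact linear SHAP rows; mean |SHAP| importance and direction.

    Direction is the sign of the Pearson correlation between a feature's
    preprocessed value and its SHAP value over the pooled held-out rows
    (for a linear model this matches the coefficient's sign toward the
    positive class); zero-variance features get direction 0.
    """
    shap_values = pd.concat([f.shap for f in folds])
    X = pd.concat([f.test_X for f in folds])
    importance = shap_values.abs().mean(axis=0)
    xc = X - X.mean(axis=0)
    sc = shap_values - shap_values.mean(axis=0)
    cov = (xc * sc).sum(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (sc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    direction = np.sign(corr.fillna(0.0))
    return shap_values, importance, direction
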