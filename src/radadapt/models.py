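"""Model builds, seeded hyperparameter search and the metric battery.

Six canonical builds are evaluated: {penalized logistic regression,
gradient-boosted trees} x {all features, top-K consensus features,
L1-front-end-filtered features}.  Hyperparameters are tuned by a seeded
random search whose objective is the mean validation-fold AUC across the
CV folds; the best configuration is refit on the full train-CV set.  Test
rows are never touched during the search (hash-guarded).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

# this lightgbm/sklearn version pair raises the feature-names warning even
# on consistent pure-array fit/predict; it carries no signal here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from radadapt.ranking import ZScorer, _fit_sparse_logistic
from radadapt.splitting import SplitPlan
from radadapt.table import FeatureTable

BASES = ("LOGISTIC", "GBT")
FEATURE_SETS = ("ALL", "TOP_K", "L1_FILTERED")


@dataclass
class BuildSpec:
    """One of the six canonical model builds.

    ``n_trials`` defaults to a desk-scale 25; the study-scale 400 is a
    plain configuration change.  ``filter_fraction`` is the starting value
    for L1 builds and is itself part of the search space.
    """

    base: str = "GBT"
    feature_set: str = "TOP_K"
    k: int = 500
    filter_fraction: float = 0.8
    n_trials: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}, got {self.base!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(
                f"feature_set must be one of {FEATURE_SETS}, got {self.feature_set!r}"
            )
        if not 0.0 <= self.filter_fraction < 1.0:
            raise ValueError("filter_fraction must lie in [0, 1)")

    @property
    def name(self) -> str:
        return f"{self.base.lower()}-{self.feature_set.lower()}"


def canonical_builds(k: int = 500, n_trials: int = 25, seed: int = 0) -> list[BuildSpec]:
    """The six builds of the study design."""
    return [
        BuildSpec(base=b, feature_set=fs, k=k, n_trials=n_trials, seed=seed)
        for b in BASES
        for fs in FEATURE_SETS
    ]


def l1_front_filter(
    matrix: pd.DataFrame,
    labels,
    filter_fraction: float,
    C: float = 1.0,
    seed: int = 0,
) -> list[str]:
    """Drop the weakest ``filter_fraction`` of features by |L1 coefficient|.

    The L1 penalty drives already-small weights to exactly zero, so
    zero-coefficient features drop first; remaining ties break by feature
    name.  Keeps ``ceil((1 - fraction) * p)`` features.  ``matrix`` must be
    standardized.
    """
    if not 0.0 <= filter_fraction < 1.0:
        raise ValueError(f"filter_fraction must lie in [0, 1), got {filter_fraction}")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    model = _fit_sparse_logistic(matrix.to_numpy(), y, C=C, seed=seed)
    coefs = dict(zip(matrix.columns, np.abs(model.coef_[0])))
    ordered = sorted(matrix.columns, key=lambda f: (-coefs[f], f))
    # keep ceil((1 - fraction) * p), computed as p - floor(fraction * p) to
    # dodge float representation of the fraction
    p = len(ordered)
    n_keep = max(1, p - int(np.floor(filter_fraction * p + 1e-9)))
    return ordered[:n_keep]


def _sample_params(base: str, feature_set: str, rng: np.random.Generator) -> dict[str, Any]:
    """One random draw from the documented search space."""
    if base == "LOGISTIC":
        params: dict[str, Any] = {
            "C": float(10 ** rng.uniform(-3, 3)),
            # penalty type: pure L1 or pure L2
            "l1_ratio": float(rng.choice([1.0, 0.0])),
            "tol": float(10 ** rng.uniform(-6, -3)),
        }
    else:
        params = {
            "num_leaves": int(rng.integers(4, 64)),
            "max_depth": int(rng.integers(2, 9)),
            "learning_rate": float(10 ** rng.uniform(-2, np.log10(0.3))),
            "n_estimators": int(rng.integers(50, 301)),
            "reg_alpha": float(10 ** rng.uniform(-8, 1)),
            "reg_lambda": float(10 ** rng.uniform(-8, 1)),
            "min_child_samples": int(rng.integers(5, 31)),
        }
    if feature_set == "L1_FILTERED":
        params["filter_fraction"] = float(rng.uniform(0.0, 0.95))
    return params


def make_estimator(base: str, params: dict[str, Any], seed: int):
    """Construct the base classifier for a sampled configuration."""
    params = {k: v for k, v in params.items() if k != "filter_fraction"}
    if base == "LOGISTIC":
        return LogisticRegression(
            solver="liblinear", random_state=seed, max_iter=5000, **params
        )
    return LGBMClassifier(
        random_state=seed, n_jobs=1, verbose=-1, deterministic=True,
        force_row_wise=True, **params
    )


def _hash_rows(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes())
    h.update(",".join(map(str, df.index)).encode())
    return h.hexdigest()


def _drop_constant(train: pd.DataFrame) -> list[str]:
    sd = train.to_numpy().std(axis=0, ddof=0)
    return [c for c, s in zip(train.columns, sd) if s > 0]


@dataclass
class TrainedModel:
    """Refit best-trial model with its preprocessing, ready to score patients."""

    build: BuildSpec
    params: dict[str, Any]
    features: list[str]
    scaler: ZScorer
    estimator: Any
    trial_log: pd.DataFrame = field(repr=False, default=None)
    cv_fold_aucs: list[float] = field(default_factory=list)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Class-1 probability for each row of a wide feature table."""
        X = self.scaler.transform(features[self.features]).to_numpy()
        return self.estimator.predict_proba(X)[:, 1]

    @property
    def best_cv_auc(self) -> float:
        return float(np.mean(self.cv_fold_aucs))


def _fold_auc(
    base: str,
    params: dict[str, Any],
    matrix: pd.DataFrame,
    labels: pd.Series,
    tr_ids: list[str],
    val_ids: list[str],
    feature_set: str,
    seed: int,
) -> float:
    keep = _drop_constant(matrix.loc[tr_ids])
    scaler = ZScorer().fit(matrix.loc[tr_ids, keep])
    X_tr = scaler.transform(matrix.loc[tr_ids, keep])
    X_val = scaler.transform(matrix.loc[val_ids, keep])
    y_tr = labels.loc[tr_ids].to_numpy()
    y_val = labels.loc[val_ids].to_numpy()
    if feature_set == "L1_FILTERED":
        surv = l1_front_filter(X_tr, y_tr, params["filter_fraction"], seed=seed)
        X_tr, X_val = X_tr[surv], X_val[surv]
    est = make_estimator(base, params, seed)
    est.fit(X_tr.to_numpy(), y_tr)
    return float(roc_auc_score(y_val, est.predict_proba(X_val.to_numpy())[:, 1]))


def tune_and_train(
    build: BuildSpec,
    table: FeatureTable,
    plan: SplitPlan,
    top_k_features: list[str] | None = None,
) -> TrainedModel:
    """Random-search hyperparameters on the CV folds and refit the winner.

    The objective is the mean validation-fold AUC; each trial is scored on
    the same folds.  TOP_K builds consume exactly ``top_k_features`` (the
    ranking report's retained list).  A SHA-256 hash of the test rows is
    taken before the search and re-checked after, guarding against any
    mutation-based leakage; only train-CV rows are ever indexed.
    """
    if not plan.folds:
        raise ValueError("plan has no folds; call make_folds first")
    if build.feature_set == "TOP_K":
        if top_k_features is None:
            raise ValueError("TOP_K build requires the ranking report's top_k list")
        cols = list(top_k_features)
    else:
        cols = list(table.features.columns)
    test_hash = _hash_rows(table.features.loc[plan.test_ids]) if plan.test_ids else None

    matrix = table.features.loc[plan.train_ids, cols]
    labels = table.labels.loc[plan.train_ids]

    rng = np.random.default_rng(build.seed)
    records = []
    best: tuple[float, int, dict[str, Any]] | None = None
    best_fold_aucs: list[float] = []
    for t in range(build.n_trials):
        params = _sample_params(build.base, build.feature_set, rng)
        fold_aucs = []
        for val_ids in plan.folds:
            val_set = set(val_ids)
            tr_ids = [i for i in plan.train_ids if i not in val_set]
            fold_aucs.append(
                _fold_auc(build.base, params, matrix, labels, tr_ids, list(val_ids),
                          build.feature_set, build.seed)
            )
        mean_auc = float(np.mean(fold_aucs))
        records.append({"trial": t, "mean_cv_auc": mean_auc, **params})
        if best is None or mean_auc > best[0]:
            best = (mean_auc, t, params)
            best_fold_aucs = fold_aucs

    _, _, best_params = best
    keep = _drop_constant(matrix)
    scaler = ZScorer().fit(matrix[keep])
    X_full = scaler.transform(matrix[keep])
    y_full = labels.to_numpy()
    final_cols = keep
    if build.feature_set == "L1_FILTERED":
        final_cols = l1_front_filter(
            X_full, y_full, best_params["filter_fraction"], seed=build.seed
        )
        X_full = X_full[final_cols]
        scaler = ZScorer().fit(matrix[final_cols])
        X_full = scaler.transform(matrix[final_cols])
    est = make_estimator(build.base, best_params, build.seed)
    est.fit(X_full.to_numpy(), y_full)

    if test_hash is not None and _hash_rows(table.features.loc[plan.test_ids]) != test_hash:
        raise AssertionError("test rows changed during hyperparameter search")
    return TrainedModel(
        build=build,
        params=best_params,
        features=final_cols,
        scaler=scaler,
        estimator=est,
        trial_log=pd.DataFrame.from_records(records),
        cv_fold_aucs=best_fold_aucs,
    )


@dataclass
class MetricPanel:
    """Threshold-based classification metrics plus threshold-free AUC."""

    auc: float
    recall: float
    accuracy: float
    precision: float
    specificity: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    auc_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc, "recall": self.recall, "accuracy": self.accuracy,
            "precision": self.precision, "specificity": self.specificity,
            "f1": self.f1,
        }


def metrics_from_probs(labels, probs, threshold: float = 0.5) -> MetricPanel:
    """Compute the metric battery from probabilities at a decision threshold.

    Positive decision at p >= threshold.  Undefined ratios (empty
    denominators) are reported as 0.0; AUC on a single-class set is NaN
    with ``auc_defined=False``.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = len(y)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / n if n else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y)) < 2:
        auc, defined = float("nan"), False
    else:
        auc, defined = float(roc_auc_score(y, p)), True
    return MetricPanel(
        auc=auc, recall=recall, accuracy=accuracy, precision=precision,
        specificity=specificity, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn,
        auc_defined=defined,
    )


def evaluate(
    model: TrainedModel,
    table: FeatureTable,
    ids,
    threshold: float = 0.5,
) -> MetricPanel:
    """Score ``ids`` rows of ``table`` and compute the metric battery."""
    sub = table.features.loc[list(ids)]
    probs = model.predict_proba(sub)
    return metrics_from_probs(table.labels.loc[list(ids)], probs, threshold=threshold)


def oof_predictions(model: TrainedModel, table: FeatureTable, plan: SplitPlan) -> pd.Series:
    """Out-of-fold validation probabilities under the tuned configuration.

    The winning hyperparameters are refit on each fold's training rows and
    scored on its validation rows, so every train-CV patient is predicted
    exactly once by a model that never saw it.  These pooled scores are the
    input to Platt calibration and threshold selection.
    """
    if not plan.folds:
        raise ValueError("plan has no folds")
    cols = (
        model.features
        if model.build.feature_set != "L1_FILTERED"
        else list(table.features.columns)
    )
    if model.build.feature_set == "TOP_K":
        cols = model.features
    matrix = table.features.loc[plan.train_ids, [c for c in cols if c in table.features.columns]]
    labels = table.labels
    out = {}
    for val_ids in plan.folds:
        val_set = set(val_ids)
        tr_ids = [i for i in plan.train_ids if i not in val_set]
        keep = _drop_constant(matrix.loc[tr_ids])
        scaler = ZScorer().fit(matrix.loc[tr_ids, keep])
        X_tr = scaler.transform(matrix.loc[tr_ids, keep])
        X_val = scaler.transform(matrix.loc[list(val_ids), keep])
        y_tr = labels.loc[tr_ids].to_numpy()
        if model.build.feature_set == "L1_FILTERED":
            surv = l1_front_filter(
                X_tr, y_tr, model.params["filter_fraction"], seed=model.build.seed
            )
            X_tr, X_val = X_tr[surv], X_val[surv]
        est = make_estimator(model.build.base, model.params, model.build.seed)
        est.fit(X_tr.to_numpy(), y_tr)
        probs = est.predict_proba(X_val.to_numpy())[:, 1]
        for pid, pr in zip(val_ids, probs):
            out[pid] = float(pr)
    return pd.Series(out).loc[plan.train_ids]
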