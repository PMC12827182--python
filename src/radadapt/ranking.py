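"""Consensus feature-importance ranking with redundancy reduction.

Pipeline (train-CV rows only): a variance cutoff (< 1e-8) removes
near-constant features, a greedy Spearman filter (|rho| > 0.80) removes the
later member of every highly correlated pair, surviving features are
z-scored and ranked two ways — by the absolute coefficients of an
L1-penalized logistic regression fitted on the full train-CV set, and by
permutation importance measured as the mean increase in validation-fold
log-loss over 5 folds x 100 shuffles.  The consensus rank of a feature is
the sum of its two component ranks; the top-K (default 500) features by
ascending consensus are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from radadapt.features import parse_feature_name
from radadapt.splitting import SplitPlan

_EPS = 1e-15


def log_loss(labels, probs) -> float:
    """Negative mean Bernoulli log-likelihood of predicted probabilities.

    Probabilities are clipped to [1e-15, 1 - 1e-15] so the loss is defined
    at p in {0, 1}.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: labels {y.shape} vs probs {p.shape}")
    if y.size == 0:
        raise ValueError("log_loss requires at least one sample")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class FilterTrace:
    """Fate of every feature through the variance and Spearman filters."""

    dropped_by_variance: list[str] = field(default_factory=list)
    dropped_by_spearman: list[tuple[str, str, float]] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    @property
    def all_dropped(self) -> set[str]:
        return set(self.dropped_by_variance) | {d for _, d, _ in self.dropped_by_spearman}


def variance_filter(matrix: pd.DataFrame, threshold: float = 1e-8) -> FilterTrace:
    """Flag features whose population variance is strictly below ``threshold``.

    The input must be complete (imputation happens upstream).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("variance_filter requires a non-empty matrix")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute before filtering")
    var = matrix.to_numpy().var(axis=0, ddof=0)
    dropped = [c for c, v in zip(matrix.columns, var) if v < threshold]
    survivors = [c for c, v in zip(matrix.columns, var) if v >= threshold]
    return FilterTrace(dropped_by_variance=dropped, survivors=survivors)


def spearman_filter(
    matrix: pd.DataFrame,
    threshold: float = 0.80,
    trace: FilterTrace | None = None,
) -> FilterTrace:
    """Greedy redundancy filter: drop the later column of every pair with
    |Spearman rho| > ``threshold``.

    Columns are scanned in input order; a candidate is dropped the first
    time it exceeds the threshold against an already-kept feature, and the
    (kept, dropped, |rho|) triple is recorded.  The surviving set therefore
    has no offending pair.  Apply :func:`variance_filter` first; pass its
    trace to accumulate both fates in one report.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    if X.shape[1] == 0:
        raise ValueError("spearman_filter requires at least one feature")
    # Spearman = Pearson on ranks
    R = np.apply_along_axis(rankdata, 0, X)
    R = (R - R.mean(axis=0)) / np.where(R.std(axis=0) == 0, 1.0, R.std(axis=0))
    corr = np.abs(R.T @ R) / X.shape[0]

    cols = list(matrix.columns)
    kept_idx: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(len(cols)):
        offender = None
        for i in kept_idx:
            if corr[i, j] > threshold:
                offender = i
                break
        if offender is None:
            kept_idx.append(j)
        else:
            dropped.append((cols[offender], cols[j], float(corr[offender, j])))
    out = trace if trace is not None else FilterTrace()
    out.dropped_by_spearman = dropped
    out.survivors = [cols[i] for i in kept_idx]
    return out


class ZScorer:
    """Column standardization with train-set statistics (population SD)."""

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "ZScorer":
        self.mean_ = train.mean(axis=0)
        self.sd_ = pd.Series(train.to_numpy().std(axis=0, ddof=0), index=train.columns)
        if (self.sd_ <= 0).any():
            bad = list(self.sd_[self.sd_ <= 0].index[:5])
            raise ValueError(f"zero-variance columns cannot be z-scored: {bad}")
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("ZScorer not fitted")
        return (matrix[self.mean_.index] - self.mean_) / self.sd_


def zscore(train: pd.DataFrame, apply_to: pd.DataFrame | None = None) -> pd.DataFrame:
    """Standardize with train statistics; transform ``apply_to`` if given."""
    scaler = ZScorer().fit(train)
    return scaler.transform(train if apply_to is None else apply_to)


def _fit_sparse_logistic(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", random_state=seed,
        max_iter=5000, tol=1e-6,
    )
    model.fit(X, y)
    n_iter = int(np.max(model.n_iter_))
    if n_iter >= 5000:
        raise RuntimeError(
            f"sparse logistic regression did not converge (n_iter={n_iter}, C={C})"
        )
    return model


def _importance_ranks(values: dict[str, float]) -> dict[str, int]:
    """Integer ranks 1..p by descending value, ties broken by name."""
    ordered = sorted(values, key=lambda f: (-values[f], f))
    return {f: i + 1 for i, f in enumerate(ordered)}


def coef_importance(
    matrix: pd.DataFrame,
    labels,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, int], dict[str, float]]:
    """Rank features by |coefficient| of an L1 logistic fit on train-CV.

    ``matrix`` must already be z-scored so coefficients are comparable.
    Returns (rank map with 1 = largest |coefficient|, coefficient map).
    Ties — including the all-zero coefficients of a strong penalty — break
    by feature name, giving a deterministic total order.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    model = _fit_sparse_logistic(matrix.to_numpy(), y, C=C, seed=seed)
    coefs = {f: float(c) for f, c in zip(matrix.columns, model.coef_[0])}
    ranks = _importance_ranks({f: abs(c) for f, c in coefs.items()})
    return ranks, coefs


@dataclass
class PermutationImportance:
    """Per-feature mean increase in validation log-loss under shuffling."""

    baseline_auc: list[float]
    baseline_logloss: list[float]
    delta_logloss: dict[str, float]
    n_repeats: int
    seed: int
    # per-feature (n_folds, n_repeats) array of deltas, for SE estimates
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def standard_error(self, feature: str) -> float:
        """Monte-Carlo SE of the mean importance.

        Repeats within a fold share one fitted model and one baseline, so
        the draws are strongly correlated within folds; the sampling unit
        of the estimator is the fold.  The per-draw spread sets the scale
        of the baseline-vs-permutation fluctuation, divided by the number
        of independent folds.
        """
        d = self.draws[feature]
        n_folds = d.shape[0]
        return float(d.std(ddof=1) / np.sqrt(n_folds))


def permutation_importance(
    matrix: pd.DataFrame,
    labels,
    plan: SplitPlan,
    n_repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> PermutationImportance:
    """Permutation importance by log-loss destruction over CV folds.

    For each fold, a sparse logistic model (on z-scored features, statistics
    from the fold-training rows) provides baseline AUC and log-loss on the
    validation fold.  Each surviving feature's validation values are then
    shuffled ``n_repeats`` times; the importance is the mean over folds and
    repeats of (permuted log-loss - baseline log-loss).  Shuffling is
    confined to the validation fold, preserving the marginal distribution
    while severing the link to the label.  RNG streams derive from
    (seed, fold, feature) so results are reproducible and order-independent.
    """
    if not plan.folds:
        raise ValueError("plan has no folds; call make_folds first")
    labels = pd.Series(labels)
    cols = list(matrix.columns)
    baseline_auc: list[float] = []
    baseline_ll: list[float] = []
    per_draw = {f: [] for f in cols}

    for fold_idx, val_ids in enumerate(plan.folds):
        val_set = set(val_ids)
        tr_ids = [i for i in plan.train_ids if i not in val_set]
        y_tr = labels.loc[tr_ids].to_numpy()
        y_val = labels.loc[val_ids].to_numpy()
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_val)) < 2:
            raise ValueError(f"fold {fold_idx} has a single class")
        scaler = ZScorer().fit(matrix.loc[tr_ids])
        X_tr = scaler.transform(matrix.loc[tr_ids]).to_numpy()
        X_val = scaler.transform(matrix.loc[val_ids]).to_numpy()
        model = _fit_sparse_logistic(X_tr, y_tr, C=C, seed=seed)
        w = model.coef_[0]
        b = float(model.intercept_[0])
        logits = X_val @ w + b
        p_base = expit(logits)
        ll_base = log_loss(y_val, p_base)
        baseline_ll.append(ll_base)
        baseline_auc.append(float(roc_auc_score(y_val, p_base)))

        n_val = len(val_ids)
        for j, feat in enumerate(cols):
            if w[j] == 0.0:
                # model ignores the feature: shuffling cannot change predictions
                per_draw[feat].append(np.zeros(n_repeats))
                continue
            rng = np.random.default_rng([seed, fold_idx, j])
            x = X_val[:, j]
            deltas = np.empty(n_repeats)
            for r in range(n_repeats):
                xp = rng.permutation(x)
                p_perm = expit(logits + w[j] * (xp - x))
                deltas[r] = log_loss(y_val, p_perm) - ll_base
            per_draw[feat].append(deltas)

    draws = {f: np.stack(v) for f, v in per_draw.items()}
    delta = {f: float(d.mean()) for f, d in draws.items()}
    return PermutationImportance(
        baseline_auc=baseline_auc,
        baseline_logloss=baseline_ll,
        delta_logloss=delta,
        n_repeats=n_repeats,
        seed=seed,
        draws=draws,
    )


@dataclass
class RankingReport:
    """Component ranks, their consensus sum, and the retained top-K list."""

    coef_rank: dict[str, int]
    perm_rank: dict[str, int]
    consensus_rank: dict[str, int]
    top_k: list[str]

    def to_frame(self) -> pd.DataFrame:
        feats = sorted(self.consensus_rank, key=lambda f: self.consensus_rank[f])
        selected = set(self.top_k)
        return pd.DataFrame(
            {
                "feature": feats,
                "coef_rank": [self.coef_rank[f] for f in feats],
                "perm_rank": [self.perm_rank[f] for f in feats],
                "consensus": [self.consensus_rank[f] for f in feats],
                "selected": [f in selected for f in feats],
            }
        )


def consensus_rank(
    coef_rank: dict[str, int],
    perm_rank: dict[str, int],
    k: int = 500,
) -> RankingReport:
    """Sum the two component ranks and retain the top-k by ascending sum.

    Ties in the consensus sum break by (perm_rank, feature name).
    """
    if set(coef_rank) != set(perm_rank):
        raise ValueError("coef_rank and perm_rank must cover the same feature set")
    consensus = {f: coef_rank[f] + perm_rank[f] for f in coef_rank}
    ordered = sorted(consensus, key=lambda f: (consensus[f], perm_rank[f], f))
    if k > len(ordered):
        warnings.warn(
            f"k={k} exceeds survivor count {len(ordered)}; retaining all", stacklevel=2
        )
    return RankingReport(
        coef_rank=dict(coef_rank),
        perm_rank=dict(perm_rank),
        consensus_rank=consensus,
        top_k=ordered[:k],
    )


def perm_ranks(importance: PermutationImportance) -> dict[str, int]:
    """Rank map from permutation importance (1 = largest log-loss increase)."""
    return _importance_ranks(importance.delta_logloss)


@dataclass
class RedundancyDiagnostics:
    """Correlation-tail summaries before and after redundancy filtering."""

    p95_abs_corr_before: dict[str, float]
    p95_abs_corr_after: dict[str, float]
    frac_high_corr_before: dict[str, float]
    frac_high_corr_after: dict[str, float]


def _corr_tail_stats(matrix: pd.DataFrame, threshold: float) -> tuple[dict[str, float], dict[str, float]]:
    by_group: dict[str, list[str]] = {"all": list(matrix.columns)}
    for c in matrix.columns:
        fam = parse_feature_name(c).family
        by_group.setdefault(fam, []).append(c)
    p95: dict[str, float] = {}
    frac: dict[str, float] = {}
    for group, cols in by_group.items():
        if len(cols) < 2:
            continue
        corr = np.corrcoef(matrix[cols].to_numpy(), rowvar=False)
        iu = np.triu_indices(len(cols), k=1)
        vals = np.abs(corr[iu])
        p95[group] = float(np.percentile(vals, 95))
        frac[group] = float(np.mean(vals > threshold))
    return p95, frac


def redundancy_diagnostics(
    matrix_before: pd.DataFrame,
    matrix_after: pd.DataFrame,
    threshold: float = 0.8,
) -> RedundancyDiagnostics:
    """Pairwise |Pearson r| 95th percentile and high-correlation fraction,
    overall and per family, before vs after filtering."""
    if matrix_before.shape[1] < 2 or matrix_after.shape[1] < 2:
        raise ValueError("need at least 2 features on each side")
    p95_b, frac_b = _corr_tail_stats(matrix_before, threshold)
    p95_a, frac_a = _corr_tail_stats(matrix_after, threshold)
    return RedundancyDiagnostics(
        p95_abs_corr_before=p95_b,
        p95_abs_corr_after=p95_a,
        frac_high_corr_before=frac_b,
        frac_high_corr_after=frac_a,
    )


def rank_features(
    matrix: pd.DataFrame,
    labels,
    plan: SplitPlan,
    k: int = 500,
    n_repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
    variance_threshold: float = 1e-8,
    spearman_threshold: float = 0.80,
) -> tuple[RankingReport, FilterTrace, PermutationImportance]:
    """Full consensus-ranking pipeline on the train-CV rows of ``matrix``.

    Filters, z-scoring and both importance measures use only
    ``plan.train_ids``; the report's top-k list is what downstream model
    builds consume.
    """
    train = matrix.loc[plan.train_ids]
    trace = variance_filter(train, threshold=variance_threshold)
    trace = spearman_filter(train[trace.survivors], threshold=spearman_threshold, trace=trace)
    surv = trace.survivors
    train_z = zscore(train[surv])
    ranks_coef, _ = coef_importance(train_z, labels.loc[plan.train_ids], C=C, seed=seed)
    perm = permutation_importance(
        matrix[surv], labels, plan, n_repeats=n_repeats, seed=seed, C=C
    )
    report = consensus_rank(ranks_coef, perm_ranks(perm), k=k)
    return report, trace, perm
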