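"""Consensus ranking: filters, z-scoring, importances, log-loss, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from radadapt.ranking import (
    coef_importance,
    consensus_rank,
    log_loss,
    perm_ranks,
    permutation_importance,
    rank_features,
    redundancy_diagnostics,
    spearman_filter,
    variance_filter,
    zscore,
)
from radadapt.splitting import SplitPlan, make_folds, make_split


def _name(i):
    return f"T1_original_firstorder_Mean{i}"


def _frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[_name(i) for i in range(arr.shape[1])])


# ---------------------------------------------------------------- log-loss

def test_log_loss_closed_forms():
    assert log_loss([1], [1.0]) <= 1e-14  # perfect prediction, clipped
    assert log_loss([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)
    # clipping at eps=1e-15 makes the worst case -ln(1e-15)
    assert log_loss([1], [0.0]) == pytest.approx(-np.log(1e-15), rel=1e-9)


def test_log_loss_validation():
    with pytest.raises(ValueError):
        log_loss([1, 0], [0.5])
    with pytest.raises(ValueError):
        log_loss([1], [1.5])


# ----------------------------------------------------------------- filters

def test_variance_filter_strictness():
    n = 4
    col_var = np.array([0.0, 1.0, 1e-8, 1e-9])
    # construct columns with exact population variances
    base = np.array([-1.0, 1.0, -1.0, 1.0])
    X = np.stack([base * np.sqrt(v) for v in col_var], axis=1)
    X[:, 0] = 5.0  # constant column
    trace = variance_filter(_frame(X))
    assert _name(0) in trace.dropped_by_variance  # constant
    assert _name(1) in trace.survivors
    assert _name(2) in trace.survivors  # exactly 1e-8: strict "<" keeps it
    assert _name(3) in trace.dropped_by_variance


def test_variance_filter_rejects_missing():
    X = _frame(np.ones((3, 2)))
    X.iloc[0, 0] = np.nan
    with pytest.raises(ValueError):
        variance_filter(X)


def test_spearman_duplicate_column_dropped(rng):
    x = rng.normal(size=200)
    X = _frame(np.stack([x, x, rng.normal(size=200)], axis=1))
    trace = spearman_filter(X)
    assert trace.survivors == [_name(0), _name(2)]
    kept, dropped, rho = trace.dropped_by_spearman[0]
    assert (kept, dropped) == (_name(0), _name(1))
    assert rho == pytest.approx(1.0)


def test_spearman_greedy_order_three_duplicates(rng):
    x = rng.normal(size=100)
    X = _frame(np.stack([x, x, x], axis=1))
    trace = spearman_filter(X)
    # keep-first rule: first kept, the later two each dropped against it
    assert trace.survivors == [_name(0)]
    assert [(k, d) for k, d, _ in trace.dropped_by_spearman] == [
        (_name(0), _name(1)),
        (_name(0), _name(2)),
    ]


def test_spearman_independent_columns_kept(rng):
    # |rho| > 0.80 between independent N(0,1) columns at n=500 is a
    # large-deviation event; both columns survive
    X = _frame(rng.normal(size=(500, 2)))
    assert len(spearman_filter(X).survivors) == 2


def test_spearman_survivors_have_no_offending_pair(rng):
    base = rng.normal(size=(120, 4))
    # plant duplicates and near-duplicates
    X = np.concatenate([base, base[:, :2] + 0.01 * rng.normal(size=(120, 2))], axis=1)
    trace = spearman_filter(_frame(X))
    surv = _frame(X)[trace.survivors]
    rho = surv.corr(method="spearman").to_numpy()
    off = np.abs(rho[np.triu_indices(len(trace.survivors), 1)])
    assert (off <= 0.80).all()


# ---------------------------------------------------------------- z-score

def test_zscore_two_point_population_sd():
    train = _frame(np.array([[0.0], [2.0]]))
    z = zscore(train)
    np.testing.assert_allclose(z.to_numpy().ravel(), [-1.0, 1.0])


def test_zscore_train_stats_applied_to_test(rng):
    train = _frame(rng.normal(2.0, 3.0, size=(50, 3)))
    z_train = zscore(train)
    z_same = zscore(train, apply_to=train)
    pd.testing.assert_frame_equal(z_train, z_same)
    assert np.abs(z_train.mean(axis=0)).max() < 1e-12


# ------------------------------------------------------------- importances

def _planted(rng, n=300, p=10, delta=2.0):
    y = rng.binomial(1, 0.5, size=n)
    X = rng.normal(size=(n, p))
    X[:, 0] += delta * y
    return _frame(X), pd.Series(y, index=_frame(X).index)


def test_coef_importance_recovers_planted_signal(rng):
    X, y = _planted(rng)
    Xz = zscore(X)
    ranks, coefs = coef_importance(Xz, y, seed=0)
    assert ranks[_name(0)] == 1
    assert abs(coefs[_name(0)]) > max(abs(coefs[_name(j)]) for j in range(1, 10))


def test_coef_importance_all_zero_tie_rule(rng):
    X, y = _planted(rng, delta=0.0)
    Xz = zscore(X)
    # extreme penalty zeroes every coefficient; ranks fall back to name order
    ranks, coefs = coef_importance(Xz, y, C=1e-4, seed=0)
    assert all(c == 0.0 for c in coefs.values())
    ordered = sorted(ranks, key=ranks.get)
    assert ordered == sorted(ranks)


def test_coef_importance_permutation_equivariance(rng):
    X, y = _planted(rng)
    Xz = zscore(X)
    ranks_a, _ = coef_importance(Xz, y, seed=0)
    perm_cols = list(Xz.columns[::-1])
    ranks_b, _ = coef_importance(Xz[perm_cols], y, seed=0)
    assert ranks_a == ranks_b


def _plan_with_folds(y, seed=0, k=5):
    plan = SplitPlan(train_ids=list(y.index), test_ids=[], seed=seed)
    return make_folds(plan, y, k=k)


def test_permutation_importance_signal_and_null(rng):
    X, y = _planted(rng, n=400, delta=1.5)
    plan = _plan_with_folds(y)
    imp = permutation_importance(X, y, plan, n_repeats=30, seed=0)
    # sole informative feature: strictly positive log-loss destruction
    assert imp.delta_logloss[_name(0)] > 0
    assert imp.delta_logloss[_name(0)] == max(imp.delta_logloss.values())
    # label-independent features: mean delta within 3 Monte-Carlo SEs of 0
    for j in range(1, 10):
        f = _name(j)
        assert abs(imp.delta_logloss[f]) <= 3 * imp.standard_error(f) + 1e-12


def test_permutation_importance_reproducible(rng):
    X, y = _planted(rng, n=200)
    plan = _plan_with_folds(y)
    a = permutation_importance(X, y, plan, n_repeats=5, seed=3)
    b = permutation_importance(X, y, plan, n_repeats=5, seed=3)
    assert a.delta_logloss == b.delta_logloss
    assert a.baseline_logloss == b.baseline_logloss


def test_permutation_repeats_shrink_estimator_variance(rng):
    """Mean is unbiased either way; averaging 100 shuffles instead of 1
    shrinks the spread of the importance estimate."""
    X, y = _planted(rng, n=200, p=4, delta=1.0)
    plan = _plan_with_folds(y)
    f = _name(1)  # a null feature
    few = [
        permutation_importance(X, y, plan, n_repeats=1, seed=s).delta_logloss[f]
        for s in range(12)
    ]
    many = [
        permutation_importance(X, y, plan, n_repeats=100, seed=s).delta_logloss[f]
        for s in range(3)
    ]
    assert np.std(few) > np.std(many)


# ---------------------------------------------------------- consensus rank

def test_consensus_sum_and_tie_break():
    coef = {"A": 1, "B": 2, "C": 3}
    perm = {"A": 3, "B": 2, "C": 1}
    report = consensus_rank(coef, perm, k=3)
    assert report.consensus_rank == {"A": 4, "B": 4, "C": 4}
    # ties break by perm_rank then name
    assert report.top_k == ["C", "B", "A"]


def test_consensus_agreeing_ranks():
    coef = {"A": 1, "B": 2, "C": 3}
    report = consensus_rank(coef, dict(coef), k=2)
    assert report.top_k == ["A", "B"]


def test_consensus_k_clamped_with_warning():
    coef = {"A": 1, "B": 2}
    with pytest.warns(UserWarning, match="exceeds survivor count"):
        report = consensus_rank(coef, dict(coef), k=10)
    assert report.top_k == ["A", "B"]


def test_consensus_key_mismatch_rejected():
    with pytest.raises(ValueError):
        consensus_rank({"A": 1}, {"B": 1})


def test_consensus_identity_holds_everywhere(rng):
    X, y = _planted(rng, n=200)
    plan = _plan_with_folds(y)
    report, _, perm = rank_features(X, y, plan, k=5, n_repeats=5, seed=0)
    for f, c in report.consensus_rank.items():
        assert c == report.coef_rank[f] + report.perm_rank[f]


# ------------------------------------------------------------- diagnostics

def test_redundancy_diagnostics_planted_block(rng):
    base = rng.normal(size=(300, 6))
    dup = np.concatenate([base, base[:, :3] + 0.05 * rng.normal(size=(300, 3))], axis=1)
    before = _frame(dup)
    trace = spearman_filter(before)
    after = before[trace.survivors]
    diag = redundancy_diagnostics(before, after)
    assert diag.frac_high_corr_before["all"] > diag.frac_high_corr_after["all"]
    for d in (diag.p95_abs_corr_before, diag.p95_abs_corr_after,
              diag.frac_high_corr_before, diag.frac_high_corr_after):
        assert all(0.0 <= v <= 1.0 for v in d.values())


def test_rank_features_train_only_and_recomputable(small_cohort):
    """Filters and ranks depend only on train-CV rows and are reproducible
    from the persisted split."""
    from radadapt.imputation import apply_imputer, fit_imputer

    plan = make_split(small_cohort.labels, seed=4)
    make_folds(plan, small_cohort.labels, k=5)
    table = apply_imputer(fit_imputer(small_cohort.table, plan.train_ids), small_cohort.table)
    rep1, tr1, _ = rank_features(table.features, table.labels, plan, k=10, n_repeats=3, seed=4)
    rep2, tr2, _ = rank_features(table.features, table.labels, plan, k=10, n_repeats=3, seed=4)
    assert rep1.top_k == rep2.top_k
    assert tr1.survivors == tr2.survivors
    # perturb a test row: ranking unchanged
    mutated = table.features.copy()
    mutated.loc[plan.test_ids[0]] += 50.0
    rep3, _, _ = rank_features(mutated, table.labels, plan, k=10, n_repeats=3, seed=4)
    assert rep3.top_k == rep1.top_k
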