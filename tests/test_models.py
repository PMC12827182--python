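"""Model builds: L1 front filter, seeded search, metric battery."""

import numpy as np
import pandas as pd
import pytest

from radadapt.models import (
    BuildSpec,
    canonical_builds,
    evaluate,
    l1_front_filter,
    metrics_from_probs,
    oof_predictions,
    tune_and_train,
)
from radadapt.ranking import zscore
from radadapt.splitting import SplitPlan, make_folds, make_split
from radadapt.table import FeatureTable


def _name(i):
    return f"FLAIR_original_glcm_Contrast{i}"


def _planted_table(rng, n=200, p=12, n_info=3, delta=1.5):
    y = rng.binomial(1, 0.6, size=n)
    X = rng.normal(size=(n, p))
    X[:, :n_info] += delta * y[:, None]
    ids = [f"P{i:04d}" for i in range(n)]
    feats = pd.DataFrame(X, index=ids, columns=[_name(i) for i in range(p)])
    return FeatureTable(
        features=feats,
        labels=pd.Series(y, index=ids),
        cohort=pd.Series(["FULL"] * n, index=ids),
    )


def test_six_canonical_builds():
    builds = canonical_builds()
    assert len(builds) == 6
    assert len({b.name for b in builds}) == 6


@pytest.mark.parametrize("bad", [dict(base="SVM"), dict(feature_set="PCA"),
                                 dict(filter_fraction=1.0)])
def test_buildspec_validation(bad):
    with pytest.raises(ValueError):
        BuildSpec(**bad)


def test_l1_filter_fraction_zero_keeps_all(rng):
    t = _planted_table(rng)
    Xz = zscore(t.features)
    surv = l1_front_filter(Xz, t.labels, filter_fraction=0.0)
    assert set(surv) == set(t.features.columns)


def test_l1_filter_recovers_planted_features():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        t = _planted_table(rng, n=300, p=100, n_info=5, delta=1.5)
        Xz = zscore(t.features)
        surv = l1_front_filter(Xz, t.labels, filter_fraction=0.9, seed=seed)
        assert len(surv) == 10  # ceil(0.1 * 100)
        hits += len(set(surv) & {_name(i) for i in range(5)}) >= 4
    assert hits >= 8  # planted recovery across seeds


def test_l1_filter_degenerate_all_zero_count(rng):
    t = _planted_table(rng, n=60, p=10, n_info=0)
    Xz = zscore(t.features)
    # extreme penalty zeroes everything; count rule still holds
    surv = l1_front_filter(Xz, t.labels, filter_fraction=0.7, C=1e-5)
    assert len(surv) == int(np.ceil(0.3 * 10))
    assert surv == sorted(surv)  # name tie-break on all-zero coefficients


def test_l1_filter_fraction_one_rejected(rng):
    t = _planted_table(rng, n=50, p=4)
    with pytest.raises(ValueError):
        l1_front_filter(zscore(t.features), t.labels, filter_fraction=1.0)


def _plan(t, seed=0):
    plan = make_split(t.labels, test_fraction=0.2, seed=seed)
    return make_folds(plan, t.labels, k=5)


def test_single_trial_equals_plain_fit(rng):
    t = _planted_table(rng)
    plan = _plan(t)
    build = BuildSpec(base="LOGISTIC", feature_set="ALL", n_trials=1, seed=0)
    model = tune_and_train(build, t, plan)
    assert len(model.trial_log) == 1
    assert model.best_cv_auc == pytest.approx(model.trial_log.mean_cv_auc.iloc[0])


def test_best_trial_is_argmax(rng):
    t = _planted_table(rng)
    plan = _plan(t)
    model = tune_and_train(BuildSpec(base="LOGISTIC", feature_set="ALL", n_trials=8, seed=1), t, plan)
    assert model.best_cv_auc >= model.trial_log.mean_cv_auc.max() - 1e-12


def test_separable_data_high_cv_auc():
    rng = np.random.default_rng(0)
    t = _planted_table(rng, n=400, p=10, n_info=2, delta=2.0)
    plan = _plan(t)
    model = tune_and_train(BuildSpec(base="GBT", feature_set="ALL", n_trials=5, seed=0), t, plan)
    assert model.best_cv_auc > 0.9


def test_search_reproducible_same_seed(rng):
    t = _planted_table(rng)
    plan = _plan(t)
    build = BuildSpec(base="GBT", feature_set="ALL", n_trials=3, seed=5)
    a = tune_and_train(build, t, plan)
    b = tune_and_train(build, t, plan)
    pd.testing.assert_frame_equal(a.trial_log, b.trial_log)
    np.testing.assert_array_equal(
        a.predict_proba(t.features.loc[plan.test_ids]),
        b.predict_proba(t.features.loc[plan.test_ids]),
    )


def test_top_k_build_consumes_exact_list(rng):
    t = _planted_table(rng)
    plan = _plan(t)
    top = [_name(i) for i in (0, 1, 2, 5, 7)]
    model = tune_and_train(
        BuildSpec(base="LOGISTIC", feature_set="TOP_K", n_trials=2, seed=0),
        t, plan, top_k_features=top,
    )
    assert set(model.features) == set(top)
    with pytest.raises(ValueError):
        tune_and_train(BuildSpec(base="LOGISTIC", feature_set="TOP_K", n_trials=1), t, plan)


def test_l1_filtered_build_runs(rng):
    t = _planted_table(rng, n=150, p=20, n_info=3)
    plan = _plan(t)
    model = tune_and_train(
        BuildSpec(base="LOGISTIC", feature_set="L1_FILTERED", n_trials=4, seed=2), t, plan
    )
    assert 0 < len(model.features) <= 20
    assert "filter_fraction" in model.params


def test_oof_predictions_cover_train_exactly_once(rng):
    t = _planted_table(rng)
    plan = _plan(t)
    model = tune_and_train(BuildSpec(base="LOGISTIC", feature_set="ALL", n_trials=2, seed=0), t, plan)
    oof = oof_predictions(model, t, plan)
    assert list(oof.index) == plan.train_ids
    assert oof.notna().all()


# --------------------------------------------------------------- metrics

def test_metrics_perfect_and_inverted():
    y = [0, 0, 1, 1]
    perfect = metrics_from_probs(y, [0.1, 0.2, 0.8, 0.9], threshold=0.5)
    assert perfect.auc == 1.0
    for v in (perfect.recall, perfect.accuracy, perfect.precision,
              perfect.specificity, perfect.f1):
        assert v == 1.0
    inverted = metrics_from_probs(y, [0.9, 0.8, 0.2, 0.1], threshold=0.5)
    assert inverted.auc == 0.0


def test_metrics_fixed_confusion_table():
    """TP=9, FP=3, TN=3, FN=1 -> recall 0.9, specificity 0.5,
    accuracy 0.75, precision 0.75 (direct arithmetic)."""
    y = [1] * 10 + [0] * 6
    p = [0.9] * 9 + [0.1] + [0.9] * 3 + [0.1] * 3
    m = metrics_from_probs(y, p, threshold=0.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (9, 3, 3, 1)
    assert m.recall == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.5)
    assert m.accuracy == pytest.approx(0.75)
    assert m.precision == pytest.approx(0.75)
    # self-consistency identities
    assert m.accuracy == pytest.approx((m.tp + m.tn) / 16)
    assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))


def test_single_class_eval_flags_auc(rng):
    m = metrics_from_probs([1, 1, 1], [0.6, 0.7, 0.8], threshold=0.5)
    assert not m.auc_defined and np.isnan(m.auc)


def test_evaluate_on_held_out(rng):
    t = _planted_table(rng, n=300, delta=2.0)
    plan = _plan(t)
    model = tune_and_train(BuildSpec(base="LOGISTIC", feature_set="ALL", n_trials=2, seed=0), t, plan)
    panel = evaluate(model, t, plan.test_ids, threshold=0.5)
    assert panel.auc > 0.8  # strong planted signal generalizes
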