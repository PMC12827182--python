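"""Shapley attribution: additivity, closed forms, independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from lightgbm import LGBMClassifier
from scipy.special import expit

from radadapt.attribution import (
    class_attribution_report,
    exact_shapley,
    sampled_shapley,
    verify_additivity,
)


def _value_function(scorer, x, background):
    """v(S): mean model output with features outside S drawn from background."""
    def v(S):
        Z = background.copy()
        for j in S:
            Z[:, j] = x[j]
        return float(np.mean(scorer(Z)))
    return v


def brute_force_shapley(scorer, x, background):
    """Independent oracle: average marginal contribution over all Nf!
    feature orderings, computed directly from the definition."""
    nf = x.size
    v = _value_function(scorer, x, background)
    phi = np.zeros(nf)
    for order in itertools.permutations(range(nf)):
        S = []
        prev = v(S)
        for j in order:
            S.append(j)
            cur = v(S)
            phi[j] += cur - prev
            prev = cur
    return phi / math.factorial(nf)


def test_linear_model_closed_form(rng):
    w = rng.normal(size=6)
    f = lambda X: X @ w
    bg = rng.normal(size=(40, 6))
    x = rng.normal(size=6)
    res = exact_shapley(f, x, bg)
    expected = w * (x - bg.mean(axis=0))
    np.testing.assert_allclose(list(res.phi.values()), expected, atol=1e-9)
    assert res.phi0 == pytest.approx(float(bg.mean(axis=0) @ w), abs=1e-12)


def test_null_player_gets_zero(rng):
    f = lambda X: np.tanh(X[:, 0]) + X[:, 1] ** 2  # ignores feature 2
    bg = rng.normal(size=(25, 3))
    x = rng.normal(size=3)
    res = exact_shapley(f, x, bg)
    assert res.phi["f2"] == pytest.approx(0.0, abs=1e-12)


def test_constant_model():
    f = lambda X: np.full(X.shape[0], 0.37)
    res = exact_shapley(f, np.zeros(4), np.zeros((5, 4)))
    assert res.phi0 == pytest.approx(0.37)
    assert res.fx == pytest.approx(0.37)
    assert all(v == 0.0 for v in res.phi.values())
    ok, resid = verify_additivity(res)
    assert ok and resid == 0.0


def test_symmetry_of_interchangeable_features(rng):
    f = lambda X: np.sin(X[:, 0] + X[:, 1]) + 0.3 * X[:, 2]
    bg_half = rng.normal(size=(15, 3))
    # symmetric background: swapping columns 0/1 leaves it unchanged
    bg = np.concatenate([bg_half, bg_half[:, [1, 0, 2]]], axis=0)
    x = np.array([0.7, 0.7, -0.2])
    res = exact_shapley(f, x, bg)
    assert res.phi["f0"] == pytest.approx(res.phi["f1"], abs=1e-9)


def test_gbt_matches_brute_force_oracle(rng):
    X = rng.normal(size=(200, 3))
    y = (X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.normal(size=200) > 0).astype(int)
    gbt = LGBMClassifier(n_estimators=20, max_depth=3, random_state=0,
                         n_jobs=1, verbose=-1).fit(X, y)
    scorer = lambda Z: gbt.predict_proba(Z)[:, 1]
    bg = X[:12]
    x = X[50]
    res = exact_shapley(scorer, x, bg)
    oracle = brute_force_shapley(scorer, x, bg)
    np.testing.assert_allclose(list(res.phi.values()), oracle, atol=1e-12)
    ok, resid = verify_additivity(res)
    assert ok and resid <= 1e-9


def test_random_models_additive_and_match_oracle(rng):
    """Random nonlinear scorers at 2-5 features: enumeration equals the
    permutation-definition oracle and additivity is exact."""
    for trial in range(20):
        nf = int(rng.integers(2, 6))
        W = rng.normal(size=(nf, nf))
        w = rng.normal(size=nf)
        f = lambda X, W=W, w=w: expit(X @ w + 0.5 * np.sum((X @ W) ** 2, axis=1) / nf)
        bg = rng.normal(size=(8, nf))
        x = rng.normal(size=nf)
        res = exact_shapley(f, x, bg)
        ok, resid = verify_additivity(res)
        assert ok, f"residual {resid}"
        oracle = brute_force_shapley(f, x, bg)
        np.testing.assert_allclose(list(res.phi.values()), oracle, atol=1e-12)


def test_additivity_detects_corruption(rng):
    f = lambda X: X @ np.ones(3)
    res = exact_shapley(f, rng.normal(size=3), rng.normal(size=(10, 3)))
    biggest = max(res.phi, key=lambda k: abs(res.phi[k]))
    res.phi[biggest] = 0.0
    ok, resid = verify_additivity(res)
    assert not ok and resid > 0


def test_enumeration_budget_enforced(rng):
    f = lambda X: X.sum(axis=1)
    with pytest.raises(ValueError, match="sampled_shapley"):
        exact_shapley(f, np.zeros(13), np.zeros((4, 13)))


def test_sampled_backend_additive_and_consistent(rng):
    w = rng.normal(size=15)
    f = lambda X: expit(X @ w)
    bg = rng.normal(size=(20, 15))
    x = rng.normal(size=15)
    res = sampled_shapley(f, x, bg, n_permutations=100, seed=0)
    ok, resid = verify_additivity(res)
    assert ok and resid <= 1e-9  # telescoping makes sampling exactly additive
    # agrees with the linear-ish closed form within sampling error
    res2 = sampled_shapley(f, x, bg, n_permutations=100, seed=0)
    assert res.phi == res2.phi  # seeded determinism


def test_class_report_single_driver(rng):
    """One feature alone drives the score: it tops both class reports,
    negative for correctly classified class-0 samples."""
    cols = [
        "FLAIR_wavelet-LLL_firstorder_Minimum",
        "T1_original_glcm_Contrast",
        "T2_original_glszm_ZoneEntropy",
    ]
    X = pd.DataFrame(rng.normal(size=(80, 3)), columns=cols)
    y = (X[cols[0]] > 0).astype(int).to_numpy()
    f = lambda Z: expit(4.0 * Z[:, 0])
    report = class_attribution_report(f, X, y, background=X, k=3)
    top0 = report.per_class[0][0]
    assert top0.feature == cols[0]
    assert top0.mean_phi < 0
    assert report.per_class[1][0].feature == cols[0]
    assert report.per_class[1][0].mean_phi > 0
    assert top0.modality == "FLAIR" and top0.family == "firstorder"
    # tallies over the k entries conserve counts
    tally = report.tallies(0)
    assert tally.total == 3


def test_class_report_zero_model(rng):
    cols = ["T1_original_glcm_Contrast", "T2_original_glcm_Contrast"]
    X = pd.DataFrame(rng.normal(size=(30, 2)), columns=cols)
    y = rng.binomial(1, 0.5, size=30)
    f = lambda Z: np.full(Z.shape[0], 0.4)  # classifies everyone negative
    report = class_attribution_report(f, X, y, background=X, k=2)
    assert report.n_correct[1] == 0  # warning path: no correct class-1
    assert any("class-1" in w for w in report.warnings)
    for entry in report.per_class[0]:
        assert entry.mean_phi == 0.0
    assert report.phi0 == pytest.approx(0.4)
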