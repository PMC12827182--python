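"""Platt scaling, Brier score and FP+FN-minimizing operating threshold.

Platt scaling fits a one-dimensional logistic regression mapping raw
classifier scores s to calibrated probabilities sigmoid(a*s + b).  Being a
monotone map (for a > 0) it reorders nothing, so discrimination (AUC) is
unchanged; only the probability scale moves.  The operating threshold t*
is then the probability cut minimizing false positives + false negatives
on validation predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score


@dataclass
class PlattMap:
    """Fitted logistic recalibration p = sigmoid(a*s + b)."""

    a: float
    b: float
    fitted_on: set[str] = field(default_factory=set)

    def transform(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return expit(self.a * s + self.b)


def fit_platt(scores, labels, fitted_on=None) -> PlattMap:
    """Maximum-likelihood logistic fit of labels on raw scores.

    Requires both classes among the (validation) rows.  When the fitted
    slope is positive the map is strictly increasing, so the AUC of the
    calibrated probabilities equals that of the raw scores; this is
    asserted on every fit.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit Platt scaling")
    # near-unpenalized logistic fit; the tiny ridge only bounds the
    # separable case
    lr = LogisticRegression(C=1e8, solver="lbfgs", max_iter=10000, tol=1e-10)
    lr.fit(s.reshape(-1, 1), y)
    pmap = PlattMap(
        a=float(lr.coef_[0, 0]),
        b=float(lr.intercept_[0]),
        fitted_on=set(fitted_on) if fitted_on is not None else set(),
    )
    if pmap.a > 0:
        auc_raw = roc_auc_score(y, s)
        auc_cal = roc_auc_score(y, pmap.transform(s))
        assert abs(auc_raw - auc_cal) < 1e-12, "Platt map altered discrimination"
    return pmap


def brier(labels, probs) -> float:
    """Mean squared error between predicted probabilities and labels."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch between labels and probs")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


@dataclass
class OperatingPoint:
    """FP+FN-minimizing probability threshold on validation predictions."""

    t_star: float
    fp_plus_fn: int


def select_threshold(labels, probs) -> OperatingPoint:
    """Exhaustive scan for the threshold minimizing FP + FN.

    Candidates are the midpoints between consecutive distinct sorted
    probabilities plus boundary sentinels below the minimum (classify all
    positive) and above the maximum (classify all negative), clipped into
    (0, 1).  Decision rule: positive iff p >= t.  Ties resolve toward the
    larger threshold, i.e. fewer interventions.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(p)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    lo = uniq[0] / 2.0
    hi = (uniq[-1] + 1.0) / 2.0
    candidates = np.clip(np.concatenate([[lo], mids, [hi]]), 1e-9, 1.0 - 1e-9)
    best_t, best_obj = None, None
    for t in candidates:
        pred = p >= t
        obj = int(np.sum(pred & (y == 0)) + np.sum(~pred & (y == 1)))
        if best_obj is None or obj < best_obj or (obj == best_obj and t > best_t):
            best_t, best_obj = float(t), obj
    return OperatingPoint(t_star=best_t, fp_plus_fn=best_obj)
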