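"""Additive Shapley attribution of model probabilities.

The model output for a sample decomposes as f(x) = phi0 + sum_j phi_j,
where phi0 is the expected model output over a background (training)
matrix and phi_j the marginal contribution of feature j.  Positive values
push toward class 1 (methylated), negative toward class 0.  The value
function is interventional: v(S) is the mean model output with features
outside S replaced by background rows.  For up to 12 features the Shapley
values are computed exactly by coalition enumeration; beyond that a seeded
permutation-sampling estimator is provided, which remains exactly additive
because each sampled permutation's marginal contributions telescope from
v(empty) to f(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radadapt.features import FeatureNameError, parse_feature_name, tally_features

MAX_EXACT_FEATURES = 12


def _as_scorer(model):
    """Normalize a model to a callable X (2d array) -> class-1 probability."""
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1]
    raise TypeError("model must be callable or expose predict_proba")


@dataclass
class AttributionResult:
    """Baseline phi0 plus per-feature contributions, in model-output units."""

    phi0: float
    phi: dict[str, float]
    fx: float
    n_features: int
    method: str = "exact"

    @property
    def residual(self) -> float:
        return abs(self.phi0 + sum(self.phi.values()) - self.fx)


def _prepare(x, background, feature_names):
    if isinstance(x, pd.Series):
        feature_names = list(x.index) if feature_names is None else feature_names
        x = x.to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float).ravel()
    if isinstance(background, pd.DataFrame):
        if feature_names is None:
            feature_names = list(background.columns)
        background = background.to_numpy(dtype=float)
    else:
        background = np.asarray(background, dtype=float)
    if background.ndim != 2:
        raise ValueError("background must be 2-dimensional")
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if background.shape[1] != x.size:
        raise ValueError("background and sample disagree on feature count")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(x.size)]
    return x, background, list(feature_names)


def exact_shapley(model, x, background, feature_names=None) -> AttributionResult:
    """Exact interventional Shapley values by coalition enumeration.

    phi_j = sum over coalitions S not containing j of
    |S|! (Nf-|S|-1)! / Nf! * [v(S + {j}) - v(S)], with
    v(S) = mean_b f(x restricted to S, background row b elsewhere).
    Enumeration cost is 2^Nf model batches, so Nf <= 12 is enforced; use
    :func:`sampled_shapley` above that.
    """
    x, bg, names = _prepare(x, background, feature_names)
    nf = x.size
    if nf > MAX_EXACT_FEATURES:
        raise ValueError(
            f"exact enumeration limited to {MAX_EXACT_FEATURES} features "
            f"(got {nf}); use sampled_shapley"
        )
    scorer = _as_scorer(model)
    n_bg = bg.shape[0]
    n_sets = 1 << nf

    # one batched model call over every (coalition, background row) pair
    Z = np.repeat(bg[None, :, :], n_sets, axis=0)  # (2^nf, n_bg, nf)
    for j in range(nf):
        mask = (np.arange(n_sets) >> j) & 1 == 1
        Z[mask, :, j] = x[j]
    v = scorer(Z.reshape(n_sets * n_bg, nf)).reshape(n_sets, n_bg).mean(axis=1)

    fact = [math.factorial(i) for i in range(nf + 1)]
    denom = fact[nf]
    phi = np.zeros(nf)
    sizes = np.array([bin(s).count("1") for s in range(n_sets)])
    for j in range(nf):
        bit = 1 << j
        without = np.flatnonzero((np.arange(n_sets) & bit) == 0)
        s = sizes[without]
        weights = np.array([fact[k] * fact[nf - k - 1] for k in s]) / denom
        phi[j] = float(np.sum(weights * (v[without | bit] - v[without])))

    return AttributionResult(
        phi0=float(v[0]),
        phi={names[j]: float(phi[j]) for j in range(nf)},
        fx=float(v[n_sets - 1]),
        n_features=nf,
        method="exact",
    )


def sampled_shapley(
    model, x, background, feature_names=None, n_permutations: int = 200, seed: int = 0
) -> AttributionResult:
    """Permutation-sampling Shapley estimator for larger feature counts.

    For each sampled feature order, features are switched from background
    to the sample's values one at a time; each feature's contribution is
    its marginal change in v.  Per permutation the contributions telescope
    exactly from v(empty) = phi0 to v(full) = f(x), so the average is
    additive to floating-point precision regardless of n_permutations.
    """
    x, bg, names = _prepare(x, background, feature_names)
    nf = x.size
    scorer = _as_scorer(model)
    rng = np.random.default_rng(seed)
    n_bg = bg.shape[0]

    phi = np.zeros(nf)
    phi0 = float(np.mean(scorer(bg)))
    for _ in range(n_permutations):
        order = rng.permutation(nf)
        # batch the nf cumulative coalitions of this permutation
        Z = np.repeat(bg[None, :, :], nf, axis=0)
        for step in range(nf):
            Z[step:, :, order[step]] = x[order[step]]
        v = scorer(Z.reshape(nf * n_bg, nf)).reshape(nf, n_bg).mean(axis=1)
        prev = phi0
        for step in range(nf):
            phi[order[step]] += v[step] - prev
            prev = v[step]
    phi /= n_permutations
    fx = float(scorer(x[None, :])[0])
    return AttributionResult(
        phi0=phi0,
        phi={names[j]: float(phi[j]) for j in range(nf)},
        fx=fx,
        n_features=nf,
        method="sampled",
    )


def verify_additivity(result: AttributionResult, tol: float | None = None) -> tuple[bool, float]:
    """Check phi0 + sum(phi) == f(x) within tolerance; returns (pass, residual).

    Default tolerance: 1e-9 for the exact backend, 1e-3 otherwise.
    """
    if tol is None:
        tol = 1e-9 if result.method == "exact" else 1e-3
    residual = result.residual
    return residual <= tol, residual


@dataclass
class ClassAttributionEntry:
    feature: str
    mean_phi: float
    modality: str | None = None
    filter: str | None = None
    family: str | None = None


@dataclass
class ClassAttributionReport:
    """Per-class top-k mean attributions with feature-anatomy annotation."""

    per_class: dict[int, list[ClassAttributionEntry]] = field(default_factory=dict)
    phi0: float = 0.0
    n_correct: dict[int, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def tallies(self, cls: int):
        names = [e.feature for e in self.per_class.get(cls, []) if e.modality is not None]
        return tally_features(names) if names else None


def class_attribution_report(
    model,
    samples: pd.DataFrame,
    labels,
    background: pd.DataFrame,
    k: int = 20,
    threshold: float = 0.5,
    backend: str = "auto",
    seed: int = 0,
) -> ClassAttributionReport:
    """Average attributions over correctly classified samples, per class.

    For each class, Shapley values are averaged over all samples the model
    classifies correctly at ``threshold``; the top-k features by |mean phi|
    are reported, annotated with (modality, filter, family) when the name
    parses.  Negative mean phi points toward the unmethylated class.
    """
    scorer = _as_scorer(model)
    y = np.asarray(labels).astype(int)
    probs = scorer(samples.to_numpy(dtype=float))
    pred = (probs >= threshold).astype(int)
    nf = samples.shape[1]
    use_exact = backend == "exact" or (backend == "auto" and nf <= MAX_EXACT_FEATURES)

    report = ClassAttributionReport()
    names = list(samples.columns)
    for cls in (0, 1):
        idx = np.flatnonzero((y == cls) & (pred == cls))
        report.n_correct[cls] = len(idx)
        if len(idx) == 0:
            report.warnings.append(f"no correctly classified class-{cls} samples")
            report.per_class[cls] = []
            continue
        acc = np.zeros(nf)
        for i in idx:
            row = samples.iloc[i]
            if use_exact:
                res = exact_shapley(scorer, row, background, feature_names=names)
            else:
                res = sampled_shapley(
                    scorer, row, background, feature_names=names, seed=seed
                )
            ok, resid = verify_additivity(res)
            if not ok:
                raise AssertionError(
                    f"attribution additivity violated (residual {resid:.2e})"
                )
            acc += np.array([res.phi[n] for n in names])
            report.phi0 = res.phi0
        mean_phi = acc / len(idx)
        order = np.argsort(-np.abs(mean_phi))[:k]
        entries = []
        for j in order:
            try:
                parsed = parse_feature_name(names[j])
                entries.append(
                    ClassAttributionEntry(
                        feature=names[j], mean_phi=float(mean_phi[j]),
                        modality=parsed.modality, filter=parsed.filter,
                        family=parsed.family,
                    )
                )
            except FeatureNameError:
                entries.append(
                    ClassAttributionEntry(feature=names[j], mean_phi=float(mean_phi[j]))
                )
        report.per_class[cls] = entries
    return report
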