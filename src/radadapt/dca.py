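"""Decision Curve Analysis: Net Benefit, default strategies, and the Net
Reduction in unnecessary Interventions per 100 patients.

At a threshold probability pt, acting on a positive model call is worth

    NB = TP/N - FP/N * pt / (1 - pt)

true positives net of harm-weighted false positives.  The default
strategies are treat-all (every patient positive) and treat-none (NB = 0).
The model's advantage over treat-all converts into avoided unnecessary
interventions per 100 patients:

    NRI_100 = (NB_model - NB_treat-all) * (1 - pt) / pt * 100

A four-band interpreter maps calibrated probabilities onto clinical
read-outs with cut-points 0.300 / 0.575 / 0.800.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def net_benefit(TP: int, FP: int, N: int, pt: float) -> float:
    """TP/N - FP/N * pt/(1-pt); the harm weight is the odds of pt."""
    if not 0.0 < pt < 1.0:
        raise ValueError(f"pt must lie strictly inside (0,1), got {pt}")
    if N <= 0:
        raise ValueError("N must be positive")
    if TP + FP > N:
        raise ValueError("TP + FP cannot exceed N")
    return TP / N - FP / N * pt / (1.0 - pt)


def treat_all_nb(prevalence: float, pt: float) -> float:
    """Net benefit of treating every patient: prevalence - (1-prev)*odds(pt).

    Equals :func:`net_benefit` with TP = all class-1 and FP = all class-0;
    crosses zero exactly at pt = prevalence.
    """
    if not 0.0 < pt < 1.0:
        raise ValueError(f"pt must lie strictly inside (0,1), got {pt}")
    return prevalence - (1.0 - prevalence) * pt / (1.0 - pt)


def nri_per_100(nb_model: float, nb_all: float, pt: float) -> float:
    """Unnecessary interventions avoided per 100 patients vs treat-all."""
    if not 0.0 < pt < 1.0:
        raise ValueError(f"pt must lie strictly inside (0,1), got {pt}")
    return (nb_model - nb_all) * (1.0 - pt) / pt * 100.0


@dataclass
class DecisionCurvePoint:
    """Counts and benefit quantities at one threshold probability."""

    pt: float
    TP: int
    FP: int
    N: int
    nb_model: float
    nb_all: float
    nb_none: float
    nri_100: float


@dataclass
class DecisionCurve:
    """Decision curve over a pt grid plus the beneficial interval."""

    points: list[DecisionCurvePoint]
    # pt sub-grid where nb_model > max(nb_all, 0); None if empty
    beneficial_interval: tuple[float, float] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pt": [q.pt for q in self.points],
                "nb_model": [q.nb_model for q in self.points],
                "nb_all": [q.nb_all for q in self.points],
                "nb_none": [q.nb_none for q in self.points],
                "nri_100": [q.nri_100 for q in self.points],
                "TP": [q.TP for q in self.points],
                "FP": [q.FP for q in self.points],
            }
        )


def default_pt_grid() -> np.ndarray:
    """Dense default grid 0.01..0.99 step 0.005, covering the clinically
    relevant 0.35-0.65 window."""
    return np.round(np.arange(0.01, 0.99 + 1e-12, 0.005), 6)


def decision_curve(labels, probs, pt_grid=None) -> DecisionCurve:
    """Evaluate the decision curve of predicted probabilities.

    Positive call at p >= pt.  Also locates the pt interval (grid extremes)
    where the model beats both default strategies.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probs, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    grid = default_pt_grid() if pt_grid is None else np.asarray(pt_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty pt grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("pt grid must lie strictly inside (0,1)")
    N = y.size
    prevalence = float(y.mean())
    points: list[DecisionCurvePoint] = []
    beneficial: list[float] = []
    for pt in grid:
        pred = p >= pt
        TP = int(np.sum(pred & (y == 1)))
        FP = int(np.sum(pred & (y == 0)))
        nb = net_benefit(TP, FP, N, pt)
        nb_all = treat_all_nb(prevalence, pt)
        points.append(
            DecisionCurvePoint(
                pt=float(pt), TP=TP, FP=FP, N=N,
                nb_model=nb, nb_all=nb_all, nb_none=0.0,
                nri_100=nri_per_100(nb, nb_all, pt),
            )
        )
        if nb > max(nb_all, 0.0):
            beneficial.append(float(pt))
    interval = (min(beneficial), max(beneficial)) if beneficial else None
    return DecisionCurve(points=points, beneficial_interval=interval)


# four-band clinical interpreter of calibrated probabilities
BAND_CUTS = (0.300, 0.575, 0.800)
BAND_LABELS = (
    "ASSUME_UNMETHYLATED",
    "LOW_CONFIDENCE_CONFIRM",
    "ASSUME_METHYLATED",
    "ASSUME_METHYLATED_VERY_HIGH",
)


@dataclass(frozen=True)
class ProbabilityBand:
    """Half-open probability band with its clinical interpretation label."""

    lower: float
    upper: float
    interpretation: str


_BANDS = (
    ProbabilityBand(0.0, BAND_CUTS[0], BAND_LABELS[0]),
    ProbabilityBand(BAND_CUTS[0], BAND_CUTS[1], BAND_LABELS[1]),
    ProbabilityBand(BAND_CUTS[1], BAND_CUTS[2], BAND_LABELS[2]),
    ProbabilityBand(BAND_CUTS[2], 1.0, BAND_LABELS[3]),
)


def interpret_probability(p_cal: float) -> ProbabilityBand:
    """Map a calibrated probability onto its interpretation band.

    Bands are lower-closed / upper-open except the last, which is closed at
    1.0 — so the four bands partition [0, 1].
    """
    if not 0.0 <= p_cal <= 1.0:
        raise ValueError(f"probability must lie in [0,1], got {p_cal}")
    for band in _BANDS[:-1]:
        if band.lower <= p_cal < band.upper:
            return band
    return _BANDS[-1]
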