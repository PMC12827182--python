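"""Modality-adaptive constant imputation.

Features of absent modalities are filled with per-feature medians computed
during training from modality-complete patients.  The fill values are
constant across every affected patient, so a downstream model can learn to
recognize and ignore them — the imputed columns carry no discriminative
signal for those patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radadapt.table import FeatureTable


@dataclass
class ImputationModel:
    """Per-feature median fill constants with training provenance."""

    medians: dict[str, float]
    fitted_on: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"medians": self.medians, "fitted_on": sorted(self.fitted_on)},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ImputationModel":
        d = json.loads(Path(path).read_text())
        return cls(medians={k: float(v) for k, v in d["medians"].items()},
                   fitted_on=set(d["fitted_on"]))


def fit_imputer(
    table: FeatureTable,
    train_ids,
    *,
    test_ids=None,
) -> ImputationModel:
    """Compute per-feature medians over observed training values.

    Only ``train_ids`` rows are consulted.  The even-count median is the
    mean of the two middle values.  Passing ``test_ids`` enables the
    provenance guard: any overlap with ``train_ids`` is rejected.

    Raises
    ------
    ValueError
        if a feature has zero observed training values (named in the
        message), or if the provenance guard trips.
    """
    train_ids = list(train_ids)
    if test_ids is not None:
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(
                f"imputer fit would leak test patients into training medians: {sorted(overlap)[:5]}"
            )
    sub = table.features.loc[train_ids]
    medians: dict[str, float] = {}
    for col in sub.columns:
        vals = sub[col].dropna()
        if vals.empty:
            raise ValueError(f"feature {col!r} has no observed training values to impute from")
        medians[col] = float(vals.median())
    return ImputationModel(medians=medians, fitted_on=set(train_ids))


def apply_imputer(model: ImputationModel, table: FeatureTable) -> FeatureTable:
    """Replace every missing cell by its feature's training-median constant.

    Observed cells are untouched; a per-cell boolean imputation flag is
    recorded on the returned table (OR-ed with any existing flag, so the
    operation is idempotent).
    """
    missing_cols = [c for c in table.features.columns if c not in model.medians]
    if missing_cols:
        raise ValueError(f"features absent from imputation model: {missing_cols[:5]}")
    newly_imputed = table.features.isna()
    filled = table.features.fillna(pd.Series(model.medians))
    imputed = newly_imputed
    if table.imputed is not None:
        imputed = imputed | table.imputed
    return FeatureTable(
        features=filled,
        labels=table.labels,
        cohort=table.cohort,
        imputed=imputed,
    )
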