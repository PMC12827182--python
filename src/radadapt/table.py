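"""Patient-by-feature table container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radadapt.features import parse_feature_name

ADVANCED_MODALITIES = ("ADC", "ASL", "DWI")


@dataclass
class FeatureTable:
    """Wide radiomics table: rows = patients, columns = named features.

    ``features`` is indexed by patient id with grammar-compliant column
    names; missing modalities are explicit NaN cells, never sentinel
    numbers.  ``labels`` holds the binary MGMT status (methylated = 1) and
    ``cohort`` a categorical cohort id per patient (e.g. FULL / CONV).
    ``imputed`` is an optional boolean mask of cells filled by the
    modality-adaptive imputer.
    """

    features: pd.DataFrame
    labels: pd.Series
    cohort: pd.Series
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the same patient index")
        if not self.features.index.equals(self.cohort.index):
            raise ValueError("features and cohort must share the same patient index")
        bad = set(np.unique(self.labels.to_numpy())) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_patients(self) -> int:
        return len(self.features)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def availability_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is observed (not missing)."""
        return self.features.notna()

    def advanced_columns(self) -> list[str]:
        """Columns belonging to the advanced modalities (ADC/ASL/DWI)."""
        return [
            c
            for c in self.features.columns
            if parse_feature_name(c).modality in ADVANCED_MODALITIES
        ]

    def subset(self, ids) -> "FeatureTable":
        """Row-subset by patient ids, preserving order of ``ids``."""
        ids = list(ids)
        return FeatureTable(
            features=self.features.loc[ids],
            labels=self.labels.loc[ids],
            cohort=self.cohort.loc[ids],
            imputed=self.imputed.loc[ids] if self.imputed is not None else None,
        )
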