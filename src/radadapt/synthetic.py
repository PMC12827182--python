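"""Synthetic multimodal radiomics cohort generator with known ground truth.

Emulates the statistical structure of a two-cohort glioma radiomics study:
one cohort with all seven MRI modalities (ADC, ASL, DWI, FLAIR, T1, T1CE,
T2) and one with only the four conventional ones, class prevalence near
0.61 (methylated MGMT), blocks of strongly correlated features induced by a
single latent factor per block, a planted informative subset carrying a
class-dependent mean shift, and pure-noise features.  No images are
synthesized — the generator produces the wide feature table that a
radiomics extractor would emit, with grammar-compliant feature names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from radadapt.features import (
    FAMILIES,
    LOG_SIGMAS,
    MODALITIES,
    WAVELET_SUBBANDS,
    make_feature_name,
)
from radadapt.table import ADVANCED_MODALITIES, FeatureTable

_FILTERS = (
    ("original",)
    + tuple(f"wavelet-{b}" for b in WAVELET_SUBBANDS)
    + tuple(f"log-sigma-{s}-mm-3D" for s in LOG_SIGMAS)
)

# terminal descriptors per family, enough to keep generated names unique
_FAMILY_VOCAB = {
    "shape": ("Sphericity", "SurfaceArea", "VoxelVolume", "Compactness", "Elongation"),
    "firstorder": ("Mean", "Median", "Skewness", "Kurtosis", "Minimum", "Energy", "Entropy", "RootMeanSquared"),
    "glcm": ("Contrast", "Correlation", "ClusterShade", "InverseVariance", "MCC", "Imc1", "JointEnergy"),
    "glrlm": ("RunVariance", "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity", "RunEntropy"),
    "glszm": ("SmallAreaEmphasis", "ZoneEntropy", "ZoneVariance", "SmallAreaLowGrayLevelEmphasis", "LargeAreaEmphasis"),
    "gldm": ("DependenceVariance", "DependenceEntropy", "LargeDependenceHighGrayLevelEmphasis", "SmallDependenceEmphasis"),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
}


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults mirror the real two-cohort design: 399 patients with all seven
    modalities plus 262 with only the conventional four, prevalence 0.61
    methylated.  ``effect_size`` is the standardized mean difference (delta)
    planted in informative features; correlation blocks follow a
    single-factor model ``x = lam*f + sqrt(1-lam^2)*eps`` giving expected
    pairwise Pearson correlation ~ lam^2 within a block.
    """

    n_full_cohort: int = 399
    n_conv_cohort: int = 262
    prevalence: float = 0.61
    n_features_per_modality: int = 60
    n_informative: int = 40
    effect_size: float = 0.8
    n_corr_blocks: int = 10
    block_size: int = 5
    block_loading: float = 0.9
    noise_sd: float = 1.0
    seed: int = 0
    # optional override: exact total feature count, distributed round-robin
    # over the 7 modalities (for conditions stated as totals, e.g. 200)
    n_features_total: int | None = None

    @property
    def n_patients(self) -> int:
        return self.n_full_cohort + self.n_conv_cohort

    @property
    def total_features(self) -> int:
        if self.n_features_total is not None:
            return self.n_features_total
        return self.n_features_per_modality * len(MODALITIES)

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0,1), got {self.prevalence}")
        if not 0.0 <= self.block_loading < 1.0:
            raise ValueError(f"block_loading must lie in [0,1), got {self.block_loading}")
        for name in (
            "n_full_cohort",
            "n_conv_cohort",
            "n_features_per_modality",
            "n_informative",
            "n_corr_blocks",
            "block_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_patients < 1:
            raise ValueError("at least one patient required")
        total = self.total_features
        if self.n_informative > total:
            raise ValueError(
                f"n_informative={self.n_informative} exceeds feature budget {total}"
            )
        if self.n_informative + self.n_corr_blocks * self.block_size > total:
            raise ValueError("informative + block features exceed feature budget")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SyntheticCohort:
    """Generated cohort: feature table plus planted ground truth.

    ``truth`` is the set of informative feature names; ``block_map`` maps
    block-member feature names to their latent-factor index.
    """

    table: FeatureTable
    truth: set[str]
    block_map: dict[str, int]
    config: SyntheticConfig = field(repr=False, default=None)

    # convenience passthroughs used throughout the tests
    @property
    def features(self) -> pd.DataFrame:
        return self.table.features

    @property
    def labels(self) -> pd.Series:
        return self.table.labels

    @property
    def cohort_id(self) -> pd.Series:
        return self.table.cohort


def _feature_names(total: int) -> list[str]:
    """Unique grammar-compliant names; modality cycles fastest so any prefix
    of the list is spread round-robin across modalities and filter tokens."""
    names: list[str] = []
    i = 0
    seen: set[str] = set()
    n_mod, n_filt, n_fam = len(MODALITIES), len(_FILTERS), len(FAMILIES)
    while len(names) < total:
        modality = MODALITIES[i % n_mod]
        # filter and family co-cycle with coprime periods (13 and 7), so any
        # prefix of the list spreads over modalities, filters and families
        k = i // n_mod
        filt = _FILTERS[k % n_filt]
        family = FAMILIES[k % n_fam]
        vocab = _FAMILY_VOCAB[family]
        depth = i // (n_mod * n_filt * n_fam)
        feature = vocab[depth % len(vocab)]
        if depth >= len(vocab):
            feature = f"{feature}{depth // len(vocab)}"
        name = make_feature_name(modality, filt, family, feature)
        if name not in seen:
            seen.add(name)
            names.append(name)
        i += 1
    return names


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the configured generative model.

    Labels are i.i.d. Bernoulli(prevalence).  Informative features get a
    class-dependent mean shift of ``effect_size`` standard deviations;
    block features share a per-block latent factor with the stated loading;
    everything else is label-independent noise.  Advanced-modality columns
    (ADC/ASL/DWI) are set to NaN for every CONV-cohort patient.
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    p = config.total_features
    names = _feature_names(p)

    labels = rng.binomial(1, config.prevalence, size=n).astype(int)
    sd = config.noise_sd
    X = rng.normal(0.0, sd, size=(n, p))

    # planted signal: first n_informative columns (round-robin over modalities)
    informative = names[: config.n_informative]
    if config.n_informative:
        X[:, : config.n_informative] += config.effect_size * sd * labels[:, None]

    # correlation blocks drawn from the remaining (pure-noise) columns
    block_map: dict[str, int] = {}
    lam = config.block_loading
    resid = np.sqrt(1.0 - lam**2)
    col = config.n_informative
    for b in range(config.n_corr_blocks):
        factor = rng.normal(0.0, sd, size=n)
        for _ in range(config.block_size):
            X[:, col] = lam * factor + resid * X[:, col]
            block_map[names[col]] = b
            col += 1

    patient_ids = [f"P{i:04d}" for i in range(n)]
    cohort = np.array(
        ["FULL"] * config.n_full_cohort + ["CONV"] * config.n_conv_cohort
    )
    features = pd.DataFrame(X, index=patient_ids, columns=names)

    conv_rows = cohort == "CONV"
    advanced_cols = [
        c for c in names if c.split("_", 1)[0] in ADVANCED_MODALITIES
    ]
    if conv_rows.any() and advanced_cols:
        features.loc[conv_rows, advanced_cols] = np.nan

    table = FeatureTable(
        features=features,
        labels=pd.Series(labels, index=patient_ids, name="label"),
        cohort=pd.Series(cohort, index=patient_ids, name="cohort_id"),
    )
    return SyntheticCohort(table=table, truth=set(informative), block_map=block_map, config=config)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the cohort to ``<out_dir>/cohort.csv`` plus a sidecar JSON.

    The CSV has grammar-compliant feature columns plus ``patient_id``,
    ``cohort_id`` and ``label``; missing cells are empty.  The sidecar
    records the config, the truth set and the block map for audit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "cohort.csv"
    meta_path = out_dir / "cohort.meta.json"

    df = cohort.table.features.copy()
    df.insert(0, "patient_id", cohort.table.patient_ids)
    df.insert(1, "cohort_id", cohort.table.cohort.to_numpy())
    df.insert(2, "label", cohort.table.labels.to_numpy())
    df.to_csv(csv_path, index=False)

    meta = {
        "config": asdict(cohort.config) if cohort.config is not None else None,
        "truth": sorted(cohort.truth),
        "block_map": cohort.block_map,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return csv_path, meta_path


def read_cohort(csv_path: str | Path, meta_path: str | Path | None = None) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort`."""
    df = pd.read_csv(csv_path)
    df = df.set_index("patient_id")
    cohort_id = df.pop("cohort_id")
    labels = df.pop("label").astype(int)
    table = FeatureTable(features=df, labels=labels, cohort=cohort_id)
    truth: set[str] = set()
    block_map: dict[str, int] = {}
    config = None
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        truth = set(meta.get("truth", []))
        block_map = {k: int(v) for k, v in meta.get("block_map", {}).items()}
        if meta.get("config"):
            config = SyntheticConfig(**meta["config"])
    return SyntheticCohort(table=table, truth=truth, block_map=block_map, config=config)
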