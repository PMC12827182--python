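import numpy as np
import pandas as pd
import pytest

from radadapt.synthetic import SyntheticConfig, generate_cohort

# the 11 printed rows of the index->name map, in package grammar
INDEX_MAP_NAMES = [
    "T2_log-sigma-0.5-mm-3D_glszm_SmallAreaEmphasis",
    "ADC_wavelet-LLH_firstorder_Median",
    "T2_wavelet-HLH_glcm_InverseVariance",
    "DWI_wavelet-LHH_glrlm_RunVariance",
    "ADC_wavelet-HHH_firstorder_Skewness",
    "ASL_wavelet-LLL_gldm_LargeDependenceHighGrayLevelEmphasis",
    "FLAIR_wavelet-HLL_firstorder_Kurtosis",
    "ADC_wavelet-HLH_firstorder_Skewness",
    "ADC_wavelet-LLL_firstorder_RootMeanSquared",
    "FLAIR_wavelet-LLL_firstorder_Minimum",
    "T2_wavelet-LLL_glszm_ZoneVariance",
]


@pytest.fixture(scope="session")
def small_cohort():
    """Mixed two-cohort table with planted signal, blocks and missingness."""
    cfg = SyntheticConfig(
        n_full_cohort=120,
        n_conv_cohort=60,
        prevalence=0.61,
        n_features_total=60,
        n_informative=8,
        effect_size=1.2,
        n_corr_blocks=3,
        block_size=4,
        block_loading=0.9,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def logistic_scores(n, rng, beta=2.0):
    """Labels drawn from a known logistic model plus the true probabilities."""
    z = rng.normal(size=n)
    p = 1.0 / (1.0 + np.exp(-beta * z))
    y = rng.binomial(1, p)
    return y, p
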