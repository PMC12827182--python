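"""Parse radiomic feature names and tally their anatomy.

Feature names follow <modality>_<filter>_<family>_<descriptor>; the tally
breaks a feature list down by filter class (original / wavelet / LoG),
wavelet sub-band, modality and family — the bookkeeping used to describe
which parts of the imaging signal a selected feature set draws on.
"""

from radadapt.features import parse_feature_name, tally_features
from radadapt.synthetic import SyntheticConfig, generate_cohort

name = "ADC_wavelet-LLH_firstorder_Median"
p = parse_feature_name(name)
print(f"{name}\n  -> modality={p.modality} filter={p.filter} "
      f"family={p.family} descriptor={p.feature}")
print(f"  filter class: {p.filter_class}, sub-band: {p.subband}\n")

cohort = generate_cohort(SyntheticConfig(n_full_cohort=10, n_conv_cohort=0,
                                         n_features_total=350, n_informative=0,
                                         n_corr_blocks=0, seed=0))
report = tally_features(cohort.features.columns)
print(report.format_table())
print(f"\nlow-pass-heavy wavelet features (>=2 L components): {report.lowpass_heavy}"
      f" of {report.by_filter.get('wavelet', 0)} wavelet features")
# Each map sums to the total: the tally is a partition of the feature list.
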