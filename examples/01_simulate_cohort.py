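"""Generate a two-cohort synthetic radiomics table and inspect its structure.

Emulates a multi-center glioma study: one cohort carries all seven MRI
modalities, the other only the four conventional ones (its ADC/ASL/DWI
features are missing), with a planted informative subset and correlated
feature blocks.
"""

from radadapt.synthetic import SyntheticConfig, generate_cohort, write_cohort

cfg = SyntheticConfig(
    n_full_cohort=200,
    n_conv_cohort=100,
    prevalence=0.61,
    n_features_total=140,
    n_informative=14,
    effect_size=0.8,
    n_corr_blocks=5,
    block_size=5,
    block_loading=0.9,
    seed=42,
)
cohort = generate_cohort(cfg)

print(f"patients: {cohort.table.n_patients}  features: {len(cohort.table.feature_names)}")
print(f"empirical prevalence (methylated): {cohort.table.prevalence:.3f}  (target 0.61)")
print(f"informative features planted: {len(cohort.truth)}")
print(f"correlated-block features: {len(cohort.block_map)}")

missing = cohort.features.isna()
conv = cohort.cohort_id == "CONV"
print(f"missing cells, CONV rows: {int(missing[conv].sum().sum())} "
      f"(= {conv.sum()} patients x {len(cohort.table.advanced_columns())} advanced features)")
print(f"missing cells, FULL rows: {int(missing[~conv].sum().sum())}")

csv_path, meta_path = write_cohort(cohort, "scratch/example_cohort")
print(f"written: {csv_path} + sidecar {meta_path}")
# The sidecar JSON records the config and the planted truth set, so any
# downstream selection result can be scored against known ground truth.
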