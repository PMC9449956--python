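"""Transform FAU records into classifier features and rebalance the classes.

Shows the 102 -> 41 feature reduction (30 non-rest symmetry indices + 11
movement grades), then the two preprocessing imbalance techniques:
undersampling the normal class and SMOTE-oversampling the patient classes.
"""

from palsy import (
    CohortConfig,
    NORMAL,
    generate_cohort,
    labeled_feature_set,
    random_undersample,
    raw_feature_count,
    selected_fau_count,
    smote_oversample,
)
from palsy.cohort import DATASET_CLASS_COUNTS, RAW_NORMAL_COUNT

counts = dict(DATASET_CLASS_COUNTS)
counts["N"] = RAW_NORMAL_COUNT  # the 1650 sessions originally captured
records = generate_cohort(CohortConfig(class_counts=counts, seed=7))

print(f"raw FAU values per session: {raw_feature_count()}")
print(f"FAU slots feeding the transform modules: {selected_fau_count()}")

data = labeled_feature_set(records)
print(f"\nfeature matrix: {data.matrix.shape} (41 features per record)")
print(f"class counts before balancing: {data.class_counts()}")

under = random_undersample(data, NORMAL, 289, seed=7)
print(f"\nafter undersampling normals to 289: n = {under.n}")

balanced = smote_oversample(under, k=5, seed=7)
print(f"after SMOTE: {balanced.class_counts()}")
synthetic = balanced.provenance.count("synthetic")
print(f"synthetic rows created by interpolation: {synthetic}")
# Every class now sits at the majority count (289); synthetic rows are
# convex combinations of same-class neighbours, flagged in `provenance`.
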