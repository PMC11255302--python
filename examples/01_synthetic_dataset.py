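"""Generate a study-shaped synthetic microarray dataset and inspect it.

The generator emulates a two-class colon-tumour microarray experiment:
2000 genes × 62 samples (40 cancer / 22 normal), strictly positive
right-skewed intensities, with the first 50 genes differentially expressed
(log-scale shift 3.0 in the cancer class).
"""

import numpy as np
from scipy import stats

from swarmexpr import SyntheticSpec, generate_synthetic_dataset, train_test_split

dataset = generate_synthetic_dataset(SyntheticSpec(seed=0))
print(f"shape: {dataset.values.shape[0]} genes x {dataset.values.shape[1]} samples")
print(f"classes: {dataset.labels.count('cancer')} cancer, "
      f"{dataset.labels.count('normal')} normal")

pooled = dataset.values[50:].ravel()  # non-informative genes
print(f"raw-scale skewness {stats.skew(pooled):.2f} (right-skewed, > 1)")
print(f"raw-scale kurtosis {stats.kurtosis(pooled, fisher=False):.2f} "
      "(heavy-tailed, > 6)")

train, test = train_test_split(dataset, train_fraction=0.85, seed=0)
print(f"85/15 stratified split: {train.size} train / {test.size} test samples")
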