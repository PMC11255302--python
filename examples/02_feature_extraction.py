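"""Reduce 2000 genes per sample to a handful of features three ways.

STFT summarises each sample's gene-order intensity sequence spectrally;
LASSO keeps the genes with nonzero L1-penalized regression coefficients;
EHO runs a swarm wrapper search scored by a one-Gaussian-per-class model.
"""

import numpy as np

from swarmexpr import (
    EHOFeatureConfig,
    SyntheticSpec,
    generate_synthetic_dataset,
    eho_features,
    lasso_features,
    stft_features,
)

dataset = generate_synthetic_dataset(SyntheticSpec(seed=0))

stft = stft_features(dataset)
print(f"STFT: {stft.n_features} features per sample "
      f"(15 frames x 3 statistics of |X|)")

lasso = lasso_features(dataset)
hits = int(np.sum(lasso.selected_gene_indices < 50))
print(f"LASSO: kept {lasso.n_features} genes; {hits} of the 50 truly "
      "differentially expressed genes are among them")

eho = eho_features(dataset, EHOFeatureConfig(n_select=30), seed=0)
hits = int(np.sum(eho.selected_gene_indices < 50))
print(f"EHO wrapper: kept {eho.n_features} genes; {hits} are truly "
      "differentially expressed (chance would be ~0.75)")
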