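"""Classify EHO-selected features with an FPO-tuned Gaussian mixture model
and report the pooled 10-fold confusion-matrix metric suite.

The hybrid starts from the EM solution, encodes per-class means, log
variances and weight logits as the swarm's decision vector, and minimizes
the mean squared error between each training sample's continuous score and
its class target (0.85 normal / 0.1 cancer).
"""

import warnings

import numpy as np

from swarmexpr import (
    CVPlan,
    EHOFeatureConfig,
    SyntheticSpec,
    cross_validate,
    eho_features,
    generate_synthetic_dataset,
    make_classifier,
)

warnings.filterwarnings("ignore")

dataset = generate_synthetic_dataset(SyntheticSpec(seed=1))
features = eho_features(dataset, EHOFeatureConfig(n_select=30), seed=1)

pooled, report, cm = cross_validate(
    features, make_classifier("fpo-gmm"), CVPlan(k=10, seed=1)
)
print(f"confusion matrix (cancer positive): TP={cm.tp} TN={cm.tn} "
      f"FP={cm.fp} FN={cm.fn}")
pct = report.percent()
print(f"accuracy   {pct['accuracy']:.2f} %")
print(f"F1 score   {pct['f1']:.2f} %")
print(f"MCC        {report.mcc:.4f}")
print(f"error rate {pct['error_rate']:.2f} %")
print(f"kappa      {report.kappa:.4f} ({report.kappa_band} agreement)")
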