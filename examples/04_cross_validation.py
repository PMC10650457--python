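"""Cross-validate NCA selection + quadratic SVM and print per-class metrics.

Runs leakage-free 10-fold CV on the planted-feature table: within every
fold, standardization, the NCA fit and the top-10 cut are computed on the
training split only.  Prints the confusion matrix and the metric table.
"""

import numpy as np

from pyrafex import (
    CvPlan,
    NcaConfig,
    TableFixtureSpec,
    confusion,
    cross_validate,
    make_feature_table,
    metrics,
)

table = make_feature_table(TableFixtureSpec(seed=3))
result = cross_validate(
    table,
    CvPlan(n_folds=10, seed=0, selection_mode="per_fold"),
    nca=NcaConfig(max_iter=30),
    k_select=10,
)

cm = confusion(table.labels, result.predictions, tuple(np.unique(table.labels)))
print("confusion matrix (rows true, cols predicted):")
print(cm.counts)
print()
print(metrics(cm).to_text())
# Accuracy well above 90% shows the planted signal survives the
# leakage-free protocol; per-class recall/specificity mirror each other
# because the task is binary.
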