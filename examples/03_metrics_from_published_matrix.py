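"""Recompute per-class metrics from a published accumulated confusion matrix.

The accumulated 3x3 matrix below is the black-truffle test-set table from
the study this package models (100 repetitions accumulated).  Feeding it to
the metric functions reproduces the printed sensitivities, column-wise
predictive values (labelled "specificity" in the original table) and the
99.1 % mean sensitivity.
"""

import numpy as np

from nirchem import evaluation as ev

cm = ev.ConfusionMatrix(
    labels=["T. indicum", "T. aestivum", "T. melanosporum"],
    counts=np.array([[1073, 1, 26], [3, 2897, 0], [1, 0, 999]]),
)

for lab, s_val, p_val in zip(cm.labels, ev.sensitivity(cm),
                             ev.predictive_value(cm)):
    print(f"{lab}: sensitivity {s_val:.1f} %, predictive value {p_val:.1f} %")
print(f"mean sensitivity: {ev.balanced_accuracy(cm):.1f} %")
# sensitivity = diagonal / row sum; predictive value = diagonal / column sum;
# mean sensitivity = unweighted mean of the three sensitivities.
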