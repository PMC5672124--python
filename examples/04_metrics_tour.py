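"""The evaluation-statistics suite on a worked confusion table.

All quantities derive from TP/FP/TN/FN counts; kappa additionally gets a
large-sample standard error and 95% confidence interval.
"""

import numpy as np

from lfpdecode.metrics import (ConfusionTable, DesirabilityInput, MetricsReport,
                               desirability, kappa_with_se, mcc)

ct = ConfusionTable(tp=40, tn=30, fp=10, fn=20)
rep = MetricsReport.from_confusion(ct)
for key in ("accuracy", "sensitivity", "specificity", "precision", "oer",
            "f_measure", "gmean1", "gmean2", "mcc", "auc", "bacc"):
    print(f"{key:12s} {rep[key]:.4f}")
print(f"{'kappa':12s} {rep.kappa:.4f} +/- {rep.kappa_se:.4f} "
      f"(CI {rep.kappa_ci95[0]:.3f}..{rep.kappa_ci95[1]:.3f}, "
      f"above chance: {rep.kappa_above_chance})")

# the MCC anchors: perfect, inverted and chance-level prediction
print("\nMCC anchors:",
      mcc(ConfusionTable(tp=50, tn=50, fp=0, fn=0)),
      mcc(ConfusionTable(tp=0, tn=0, fp=10, fn=10)),
      mcc(ConfusionTable(tp=25, tn=25, fp=25, fn=25)))

# desirability: product of mean/std ratios over six measures; rewards
# classifiers that are simultaneously accurate and consistent across folds
rng = np.random.default_rng(0)
steady = np.clip(rng.normal(0.85, 0.02, 10), 0, 1)
erratic = np.clip(rng.normal(0.85, 0.10, 10), 0, 1)
for name, v in (("steady", steady), ("erratic", erratic)):
    d1, d2, d = desirability(DesirabilityInput(*([v] * 6)))
    print(f"desirability ({name} classifier): {d:.2f}")
print("\nhigher desirability = same mean performance delivered with less "
      "spread across subjects/folds.")
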