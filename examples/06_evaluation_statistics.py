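"""Score predictions against ground truth and compare two models.

Per-plan confusion counts give accuracy and F1; a t-interval summarizes each
model over plans, and the pairwise comparison is gated on a Shapiro-Wilk
normality test of the paired differences.
"""

import numpy as np

from mealdecomp import (
    GroundTruthLabels,
    confusion,
    mean_ci,
    metrics_from_confusion,
    paired_compare,
)

truth = GroundTruthLabels.from_names(
    "evaluator-1", "plan-001",
    compounds=["Chicken Marsala", "Hummus"],
    basics=["olive oil", "garlic", "blueberries"],
)
counts = confusion(truth, predicted_compounds=["chicken marsala", "olive oil"])
m = metrics_from_confusion(counts)
print(f"tp {counts.tp} fp {counts.fp} fn {counts.fn} tn {counts.tn}"
      f" -> accuracy {m.accuracy:.2f}, f1 {m.f1:.2f}")

rng = np.random.default_rng(7)
model_a = np.clip(rng.normal(0.88, 0.06, size=15), 0, 1)
model_b = np.clip(model_a - rng.normal(0.05, 0.03, size=15), 0, 1)
mean, lo, hi = mean_ci(model_a.tolist())
print(f"model A accuracy {mean:.3f} (95% CI {lo:.2f}-{hi:.2f}) over 15 plans")
result = paired_compare(model_a, model_b)
print(f"gate: Shapiro-Wilk p = {result.normality_p:.3f} -> {result.test_kind}")
print(f"statistic {result.statistic:.2f}, p = {result.p_value:.4f} (n = {result.n})")

# Normality not rejected routes to the paired t-test; an outlier-ridden
# difference series would route to the Wilcoxon signed-rank test instead.
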