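"""The full evaluation protocol: simulate, extract, cross-validate, decode.

Runs stratified 5-fold cross-validation on a small session: inside each
training fold the classes are balanced with the nearest-neighbor bootstrap,
three base networks (feedforward, radial-basis, probabilistic) are trained
per binary stage, and held-out trials are decoded rest / left / right by
majority vote through the two-stage state machine.
"""

from lfpdecode import ExperimentConfig, SimConfig, format_report_table, run_experiment

config = ExperimentConfig(
    sim=SimConfig(n_left=25, n_right=25, n_rest=25, seed=42,
                  band_modulation={"low_beta": 0.4, "high_beta": 0.4,
                                   "low_gamma": 1.3, "high_gamma": 1.2}),
    k_folds=5, seed=42)
result = run_experiment(config)

print(format_report_table({"stage1 (move/rest)": result.stage1_pooled,
                           "stage2 (left/right)": result.stage2_pooled}))
print()
print("three-class confusion (rows = truth rest/left/right):")
print(result.three_class_confusion)
k = result.three_class_kappa
print(f"three-class accuracy {result.three_class_accuracy:.3f}, "
      f"kappa {k.kappa:.3f} (95% CI {k.ci95[0]:.3f}..{k.ci95[1]:.3f})")
print("per-base three-class accuracy:",
      {b: round(a, 3) for b, a in result.base_three_class_accuracy.items()})
print()
print("kappa is chance-corrected agreement: 0 = chance, 1 = perfect; a CI "
      "excluding 0 means decoding is above chance.")
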