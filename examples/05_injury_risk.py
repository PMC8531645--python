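"""Injury-risk evaluation of the four metrics on the 14 in-vivo CCI cases.

Predicts each case's metrics with the stand-in at the nominal probe
settings, then runs the exact rank-sum test, fits logistic risk curves,
extracts 50%-risk thresholds, and cross-validates (LOOCV).
"""

from contusim import StandInModel, evaluate_all_metrics, summary_table

evaluations = evaluate_all_metrics(StandInModel())
table = summary_table(evaluations)
cols = ["metric", "wilcoxon_p", "threshold50", "accuracy", "sensitivity",
        "specificity", "auc_testing", "auc_training_mean"]
print(table[cols].round(4).to_string(index=False))
print()
print("The strain metrics (MPS, MSS) separate damaged from undamaged cases")
print("(p < 0.05); the rate metrics do not. threshold50 is the metric value")
print("at 50% contusion risk, -b0/b1 of the logistic fit. Two cases share")
print("identical inputs with opposite outcomes, so perfect LOOCV accuracy")
print("is structurally impossible.")
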