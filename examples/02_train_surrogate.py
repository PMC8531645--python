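"""Train the six-member surrogate ensemble on an 80-point Sobol design.

Generates the design, evaluates the stand-in simulator, trains the
7:256:128:64:32:16:4 ensemble (72 train / 8 validation) and prints the
normalized validation errors. Takes a few minutes on one CPU.
"""

from contusim import StandInModel, TrainingConfig, build_ensemble, sobol_design

design = sobol_design(80)
model = StandInModel()
ensemble, report = build_ensemble(design, model.predict, TrainingConfig(base_seed=0))

print("Validation errors (fraction of the [0,1]-normalized output range):")
print(report.to_frame().round(4))
print()
print(f"worst statistic: {report.max_error():.4f}  (the accuracy bar is 0.04)")
print(f"ensemble weights: {ensemble.weights.round(3)}")
print("Members that converged poorly receive ~zero weight; the weighted")
print("ensemble can never do worse on validation than its best member.")
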