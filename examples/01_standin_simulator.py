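"""Evaluate the closed-form CCI stand-in simulator at a severe impact.

Builds the nominal probe configuration at the deepest experimental
indentation and prints the four region-of-interest injury metrics.
"""

from contusim import ParameterSample, evaluate

severe = ParameterSample(
    d_probe=10.0, shape=1.0, v_ind=1.7, d_ind=12.6,
    theta=0.0, mu_f=0.163, t_m=0.736,
)
metrics = evaluate(severe)

print("Severe impact (hemispherical 10 mm probe, 12.6 mm @ 1.7 m/s):")
print(f"  MPS    = {metrics.mps:.4f}   (95th-pct max principal strain, -)")
print(f"  MPSR   = {metrics.mpsr:.1f}   (strain rate, 1/s)")
print(f"  MPSXSR = {metrics.mpsxsr:.1f}    (strain x strain rate, 1/s)")
print(f"  MSS    = {metrics.mss:.4f}   (95th-pct max shear strain, -)")
print()
print("MPS scales linearly with depth; MPSR saturates with depth because")
print("the contact time grows and the viscoelastic relaxation Gamma(t)/t")
print("flattens — the rate plateau near 12 mm indentation.")
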