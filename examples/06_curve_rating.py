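"""Corridor + cross-correlation rating of two force-time curves.

Builds a synthetic reference impact pulse and a distorted test pulse
(amplitude and phase errors) and prints the rating report.
"""

import numpy as np

from contusim import SignalCurve, overall_rating

t = np.linspace(0.0, 0.04, 400)
ref = SignalCurve(t, 30.0 * np.exp(-((t - 0.02) ** 2) / (2 * 0.005**2)))
test = SignalCurve(t, 1.25 * 30.0 * np.exp(-((t - 0.0215) ** 2) / (2 * 0.005**2)))

report = overall_rating(ref, test)
print(f"corridor method:          {report.corridor:.3f}")
print(f"cross-correlation method: {report.xcorr:.3f}")
print(f"  amplitude sub-score:    {report.amplitude:.3f}")
print(f"  shape sub-score:        {report.shape:.3f}")
print(f"  phase sub-score:        {report.phase:.3f}")
print(f"overall (0.5 / 0.5):      {report.overall:.3f}")
print()
print("1.0 is a perfect match; the overall score is the equal-weight")
print("combination of the two methods, each in [0, 1].")
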