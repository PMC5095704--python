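"""Fit a section-to-atlas transform from landmark pairs.

A coronal section is aligned to the atlas with rotation, independent
mediolateral/dorsoventral scales (histology compresses tissue
anisotropically) and translation, fit by least squares on manually chosen
reference-point pairs.  Here the truth is known, so we can check recovery.
"""

import math

import numpy as np

from bfmap.registration import PlanarTransform, apply_transform, fit_transform, manual_adjust
from bfmap.synthetic import make_landmarks

true = PlanarTransform(theta=math.radians(8), s_ml=0.92, s_dv=1.07, tx=14.0, ty=-6.0)
landmarks = make_landmarks(true, n_pairs=6, noise_sigma=0.5, seed=42)

fit, report = fit_transform(landmarks)
print("true parameters:   ", np.round(true.params(), 4))
print("fitted parameters: ", np.round(fit.params(), 4))
print(f"RMS residual: {report.rms:.3f} atlas px "
      f"({report.n_iter} Gauss-Newton iterations)")
# With 0.5 px landmark noise the five parameters come back to ~1% and the
# residual sits near the noise level; with noise 0 recovery is exact.

point = np.array([100.0, 80.0])
print("image point", point, "maps to atlas", np.round(apply_transform(fit, point), 2))

nudged = manual_adjust(fit, d_theta=math.radians(0.5))
print(f"after a manual +0.5 deg nudge: theta = {math.degrees(nudged.theta):.2f} deg")
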