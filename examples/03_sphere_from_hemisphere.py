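"""Fit a sphere to a partially visible head surface.

Only the top of the head is visible from above the incubator, so the
sphere fit must work from hemisphere-only samples.  The algebraic
least-squares fit (linear in the standard-form coefficients) recovers
centre and radius exactly on noiseless data regardless of the missing
half.
"""

import numpy as np

from headcirc import fit_sphere_lsq

rng = np.random.default_rng(1)
center, radius = np.array([10.0, -20.0, 500.0]), 60.0
u = rng.normal(size=(200, 3))
u /= np.linalg.norm(u, axis=1, keepdims=True)
u[:, 2] = -np.abs(u[:, 2])          # keep only the camera-facing half

sphere = fit_sphere_lsq(center + radius * u)
print(f"true centre {center}, radius {radius} mm")
print(f"fit  centre {np.round(sphere.center, 9)}, radius {sphere.radius:.9f} mm")
print(f"standard-form (k, l, m, n) = {np.round(sphere.standard_form, 6)}")
print("the fitted centre defines where the circumference cross-section is taken")
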