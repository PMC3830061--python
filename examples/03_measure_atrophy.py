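"""Measure gray-matter atrophy on a corrupted phantom pair, end to end.

The pair carries noise, independent bias fields and a 1% scanner-scale
miscalibration on top of a -0.5% GM contraction.  The longitudinal pipeline
conditions both time-points, registers them through an isotropic halfway
space, and integrates the Jacobian determinant of the symmetric nonlinear
field over the baseline GM mask.
"""

import jacint as J

spec = J.PhantomSpec(shape=(64, 64, 64), noise_sd=2.0, bias_amplitude=0.05,
                     seed=11)
baseline, followup, labels, truth = J.make_pair(spec, target_pvc=-0.5,
                                                miscalibration_scale=1.01)

config = J.PipelineConfig(mode="lpp", interval_years=1.0, seed=11)
out = J.run_pipeline(config, [baseline, followup], [labels, labels])
res = out["result"]

print(f"true GM PVC:      {truth.true_pvc[J.Labels.GM]:+.3f} %")
print(f"measured PVC:     {res.pvc:+.3f} %")
print(f"annualized rate:  {res.annualized:+.3f} %/yr")
print(f"affine det (scanner calibration, excluded from PVC): "
      f"{res.qc['affine_det']:.5f}")
for s in out["provenance"]["stages"]:
    print(f"  stage {s['stage']:<34s} {s['seconds']:6.1f} s")
# The affine determinant ~0.971 is the recovered 1% linear miscalibration
# (1/1.01^3); treating it as scanner calibration keeps it out of the
# reported volume change.
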