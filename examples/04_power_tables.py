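"""Per-arm sample sizes for a trial detecting a treatment effect on atrophy.

Reproduces the headline power analysis: given a cohort's mean and SD of
annualized cortical atrophy (%/yr), solve the noncentral-t two-sample power
equation for each treatment effect, and compare pipelines by the ratio of
required sample sizes.
"""

import numpy as np

import jacint as J

# published one-year cohort summaries (mean %/yr, SD)
cohorts = {
    "Jacobian integration": (-0.555, 0.793),
    "XPP + SPM":            (-0.829, 2.474),
    "XPP + SIENAX":         (-0.856, 2.845),
}

spec = J.PowerSpec()  # 80% power, alpha 0.05, effects 10..90%
tables = {}
for name, (mean, sd) in cohorts.items():
    tables[name] = J.sweep_table(mean, sd, spec)
    print(f"\n{name} (mean {mean} %/yr, SD {sd}):")
    print(tables[name].to_frame().to_string(index=False))

ratio = J.ratio_report(tables["XPP + SIENAX"], tables["Jacobian integration"])
r50 = ratio.loc[np.isclose(ratio["effect"], 0.5), "ratio"].item()
print(f"\nsample-size ratio XPP+SIENAX / Jacobian at 50% effect: {r50:.2f}")
# The Jacobian-integration cohort needs ~5x fewer subjects per arm than the
# conventional cross-sectional pipeline at the same detectable effect.

# Monte-Carlo validation of the analytic solver at the 50% effect cell
d = J.effect_size(-0.555, 0.793, 0.5)
n = J.sample_size_per_arm(d)
power = J.simulate_trial_power(-0.555, 0.793, 0.5, n, reps=20_000, seed=1)
print(f"solver n = {n}/arm at d = {d:.3f}; simulated power = {power:.3f} "
      f"(target 0.80)")
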