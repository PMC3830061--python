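# jacint

Longitudinal gray-matter atrophy measurement by **Jacobian integration**,
with the clinical-trial **power analysis** that turns cohort atrophy rates
into per-arm sample sizes — plus a synthetic phantom generator with
analytically known deformations so the whole pipeline is testable without
any image download.

## Who this is for

Neuroimaging methodologists and trialists working on neurodegeneration
endpoints (e.g. cortical atrophy in multiple sclerosis). Cortical gray
matter loss is slow (a few tenths of a percent per year) and sits at the
edge of what segmentation-based cross-sectional pipelines can resolve;
registration-based longitudinal measurement recovers it with far less
variance, which translates directly into smaller trials.

## The method

Given two T1-weighted volumes of one subject:

1. **Skull-constrained affine registration** (pairreg-style): a rigid stage
   over brain NMI, then scale/skew over skull NMI — the skull does not
   atrophy, so this absorbs scanner voxel-size miscalibration, not tissue
   change.
2. **Halfway-space resampling**: the affine `A` is split by its principal
   matrix square root; each image travels half (`A^(±1/2)`) into an
   isotropic halfway grid (windowed-sinc interpolation), so interpolation
   blurring is symmetric.
3. **Symmetric nonlinear registration** of the two halfway images (an
   in-repo demons-style registrar; externally computed fields can be
   plugged in as 4-D NIfTI).
4. **Jacobian determinants** `detJ = det(I + ∇u)` of the
   baseline→follow-up displacement field `u`, by spacing-aware central
   differences.
5. **Mask-restricted integration**: the percent volume change of the
   baseline cortical-GM mask is

   `PVC = 100 · (mean detJ over mask − 1)`.

Longitudinal pre-processing (LPP) conditions the inputs first: polynomial
bias-field correction, EM tissue segmentation, lesion filling with
normal-appearing-white-matter intensities, an unbiased subject template
(log-Euclidean matrix average of all pairwise transforms), differential
intensity correction against that template, combined lesion masks and
field-of-view matching.

For trials, annualized rates `r = PVC / Δt` (outliers `|r| > 10 %/yr`
excluded a priori) feed a two-sided two-sample t-test power calculation:
with effect size `d = τ·|mean r| / SD(r)` for treatment effect `τ`, the
per-arm `n` solves the noncentral-t power equation
(`df = 2n−2`, noncentrality `d·√(n/2)`) at 80% power, α = 0.05, with
percentile-bootstrap confidence intervals.

## Worked example

```bash
python examples/04_power_tables.py
```

prints, for the Jacobian-integration cohort (mean −0.555 %/yr, SD 0.793):

```
Jacobian integration (mean -0.555 %/yr, SD 0.793):
 effect n_per_arm
    0.1      3206
    0.2       802
    0.3       357
    0.4       201
    0.5       129
    0.6        90
    0.7        66
    0.8        51
    0.9        41

sample-size ratio XPP+SIENAX / Jacobian at 50% effect: 5.39
solver n = 129/arm at d = 0.350; simulated power = 0.801 (target 0.80)
```

Reading: to detect a 50% slowing of atrophy you need 129 subjects per arm
with the Jacobian-integration endpoint, versus ~695 with a conventional
cross-sectional pipeline (ratio 5.4) — the variance of the endpoint, not
the mean rate, drives trial size. The Monte-Carlo line verifies the
analytic solver: simulated trials at the computed `n` reject at the target
rate.

End-to-end on a synthetic pair (`python examples/03_measure_atrophy.py`):
a 64³ phantom with a calibrated −0.5% GM contraction, 2% noise, independent
bias fields and a 1% scanner miscalibration comes back within a few
hundredths of a percentage point, with the miscalibration isolated in the
affine determinant (~0.971 ≈ 1/1.01³) and excluded from the reported PVC.

The command-line interface mirrors the examples:

```bash
jacint phantom --shape 64 --pvc -0.5 --noise-sd 2 --out /tmp/pair
jacint measure --baseline /tmp/pair/baseline.nii.gz \
               --followup /tmp/pair/followup.nii.gz \
               --labels   /tmp/pair/labels.nii.gz --mode lpp
jacint power --mean -0.555 --sd 0.793 --effects 10:90:10
jacint simulate --mean -0.555 --sd 0.793 --effect 0.5
```

## Layout

- `src/jacint/phantom.py` — synthetic heads, analytic atrophy fields, truth
- `src/jacint/linreg.py` — NMI, staged affine registration, halfway split
- `src/jacint/preprocess.py` — segmentation, lesion filling, bias handling
- `src/jacint/nonlinreg.py` — symmetric demons registrar, field algebra
- `src/jacint/jacobian.py` — detJ maps, PVC integration, measurement core
- `src/jacint/trialstats.py` — power solver, bootstrap, trial simulation
- `src/jacint/pipeline.py`, `cli.py` — XPP/LPP orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
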