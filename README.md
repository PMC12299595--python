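# cestpipe

Processing pipeline for amide proton transfer-weighted (APTw) CEST MRI:
WASSR-based per-voxel B0 correction, MTR-asymmetry quantification at
±3.5 ppm, ROI summarization and group statistics — plus a synthetic
z-spectrum phantom generator with analytic ground truth so every stage of
the chain can be validated without scanner data.

## Who this is for

Preclinical/clinical CEST researchers who acquire z-spectra (a saturated
image series over frequency offsets plus an unsaturated S0 image) and need
the standard APTw quantification chain as tested, scriptable Python rather
than ad-hoc MATLAB, and methodologists who want a ground-truth simulator to
probe how B0 inhomogeneity, noise and sample size propagate into group
comparisons.

## The method

A z-spectrum is the normalized water signal Z(Δω) = S_sat(Δω)/S0 as a
function of saturation offset Δω (ppm from water). The pipeline implements:

1. **WASSR B0 mapping.** Each voxel of a low-power WASSR acquisition
   (33 offsets, −0.8…+0.8 ppm) samples only the direct water line. The
   spectrum is fitted with a 12th-order polynomial (on offsets rescaled to
   [−1, 1] for conditioning), interpolated at 0.01 ppm resolution, and the
   location of the fitted minimum is the voxel's water frequency shift δ.
   Boundary minima, flat spectra and |δ| > 0.5 ppm are flagged invalid.

2. **B0 correction.** The S0-normalized APTw z-spectrum (25 offsets,
   −6…+6 ppm) is interpolated at 0.01 ppm (cubic spline), the frequency
   axis is translated by −δ so water sits at 0 ppm, and the curve is
   resampled at the original 25 offsets. Points that would need data
   beyond the acquired range are never extrapolated; they are marked
   unavailable.

3. **APTw quantification.** With MTR = 1 − S_sat/S0,

       APTw = MTRasym(3.5 ppm) = MTR(+3.5) − MTR(−3.5)
            = 100 × [Z(−3.5) − Z(+3.5)]   (percent).

   Healthy-tissue APTw is typically *negative* (≈ −2%) because the
   upfield NOE/MT background at −3.5 ppm outweighs the amide signal.

4. **Group statistics.** Per subject, the mean APTw over the left and
   right hippocampal ROIs is averaged into one value; groups are compared
   with one-way ANOVA plus Tukey HSD, normality is checked per group with
   a Lilliefors-corrected KS test, and left/right laterality with
   independent t-tests (α = 0.05 throughout).

The phantom generator models each voxel's spectrum as a multi-pool
Lorentzian superposition (water + amide at +3.5 ppm + NOE/MT at −3.5 ppm),
with a smooth bounded B0 field, additive Gaussian noise, and a per-group
amide amplitude; its closed-form MTR asymmetry is the oracle the pipeline
is tested against. See `docs/methods.md` for model details and defaults.

## Worked example

Run a complete synthetic experiment — three groups of 7 subjects (one
control-like group, two with identically elevated amide content), full
simulate → B0 → APTw → statistics chain:

```sh
cestpipe demo --outdir demo_run --seed 7
```

prints (about 2 s):

```json
{
 "group_means": {
  "CTRL": -1.8866351581288012,
  "LPS05": -0.7009331780014738,
  "LPS10": -0.7400798457270311
 },
 "anova_p": 2.4731992846891607e-06,
 "pairwise_tukey_p": {
  "CTRL|LPS05": 8.32640310299837e-06,
  "CTRL|LPS10": 1.2840742929287607e-05,
  "LPS05|LPS10": 0.9736021865966392
 },
 "elapsed_s": 2.16
}
```

Reading this: the control group's hippocampal APTw is ≈ −1.9% while both
elevated groups sit near −0.7%; the ANOVA detects a group effect, Tukey
confirms each elevated group differs from control (p < 10⁻⁴), and the two
identically-specified elevated groups do not differ from each other
(p ≈ 0.97) — the expected ceiling pattern. `demo_run/` contains per-subject
B0 and APTw NIfTI maps, MTRasym-curve CSVs, overlay PNGs, the cohort
summaries CSV, the statistics JSON, and a manifest with SHA-256 hashes of
every output (re-running with the same seed reproduces them exactly).

The same stages are available as standalone subcommands operating on files
(`simulate`, `b0`, `aptw`, `stats`, `power`, `run`) — see
`cestpipe --help` — or as library functions:

```python
import cestpipe as cp

spec = cp.PhantomSpec(noise_sd=0.01, b0_amplitude_ppm=0.15)
aptw_stack, wassr_stack, truth = cp.build_phantom(spec, seed=1)
b0 = cp.b0_map(wassr_stack, truth.roi_masks["brain"])
amap = cp.aptw_map(aptw_stack, b0, truth.roi_masks["brain"])
print(amap.values(truth.roi_masks["left_hippocampus"]).mean())
```

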