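# Methods

## Forward model

Each voxel's z-spectrum is a steady-state multi-pool Lorentzian
superposition:

    Z(Δω) = 1 − Σ_i A_i · (Γ_i²/4) / ((Δω − δ_i − δB0)² + Γ_i²/4)

with pool amplitude A_i ∈ [0, 1) (peak saturation depth), center δ_i (ppm
from water), FWHM Γ_i (ppm), and the voxel's water frequency offset δB0
(ppm). Amplitudes must sum below 1 so Z stays in (0, 1]. We deliberately do
not integrate Bloch–McConnell equations: the processing chain under test
consumes spectra, not magnetization dynamics, and the Lorentzian form
yields a closed-form MTR-asymmetry oracle,

    MTRasym(x) = 100 × [Z(−x) − Z(+x)]  (percent, noiseless, δB0 = 0),

against which the entire pipeline can be checked voxelwise. Saturation
power enters implicitly: the APTw acquisition uses the full pool set with a
broad water line, the WASSR acquisition only a narrow, shallow water line.

### Default pools and calibration

| pool | δ (ppm) | A | Γ (ppm) | role |
|---|---|---|---|---|
| water (APTw) | 0 | 0.85 | 1.6 | direct saturation |
| NOE/MT surrogate | −3.5 | 0.05 | 3.0 | asymmetric upfield background |
| amide, control-like | +3.5 | 0.028 | 1.0 | gives MTRasym(3.5) ≈ −1.99% |
| amide, inflamed-like | +3.5 | 0.043 | 1.0 | gives MTRasym(3.5) ≈ −0.50% |
| water (WASSR) | 0 | 0.5 | 0.5 | low-power direct-saturation line |

The two amide depths were solved from the closed form so that noiseless
hippocampal APTw sits near −2% (control) and −0.5% (inflamed), i.e. the
sign and magnitude reported for healthy vs. neuroinflamed rodent
hippocampus at 7 T. They are simulator calibration, not measured truth, and
no test asserts those literature values.

### Phantom geometry, field and noise

A disk "brain" (cortex tissue) holds two hippocampus disks (left/right
ROIs); geometry scales with grid size, default 32 × 32 (96 × 96 available,
smaller grids used for Monte-Carlo work). The B0 field is Gaussian-filtered
white noise rescaled so its peak equals the configured bound (default
0.15 ppm, hard limit 0.5 ppm = WASSR grid reach); shimming residuals are
spatially smooth, so a smooth random field is the appropriate stand-in.
Noise is additive Gaussian on S_sat and S0 with SD equal to `noise_sd`
times the tissue's S0 level — the high-SNR magnitude-MRI regime where
Rician noise is effectively Gaussian. Default `noise_sd` = 0.01 (1% of S0);
no SNR was available to copy, so this was chosen once as a realistic
high-quality preclinical value and is stated in the config. Between-subject
biological variation is a normal perturbation of the amide depth
(SD 0.003, ≈ 0.3 percentage points of APTw, chosen to sit in the range of
reported group SDs).

What the generator does **not** emulate: relaxation (T1/T2) and true
exchange dynamics, B1 inhomogeneity, partial volume, motion,
reconstruction/k-space effects, and spatially correlated noise. Passing
tests therefore demonstrate correctness of the *processing* (fitting,
interpolation, correction, statistics) under the stated statistical
structure — not robustness to every artifact of real scanner data.

## WASSR B0 estimation

Per voxel, the S0-normalized WASSR spectrum is least-squares fitted with a
12th-order polynomial and evaluated on a fine grid at 0.01 ppm resolution
spanning the acquired range; the fine-grid argmin is the shift estimate.
Numerical choices:

* Offsets are rescaled to [−1, 1] before building the Vandermonde basis —
  order-12 fits on raw ppm values are ill-conditioned.
* Ties at the minimum break toward the smallest |offset| (the fine grid is
  scanned in ascending-|offset| order).
* Minima on the range boundary, flat (peak-to-peak < 1e−12) curves, and
  |δ̂| > 0.5 ppm are invalid; the search never leaves the acquired range.
* All in-mask voxels share one design matrix, so the whole map is one
  batched `lstsq` solve — this is what makes 1000-cohort Monte-Carlo runs
  affordable.
* The estimator operates equally on raw or normalized signals (the argmin
  is invariant to positive scaling); normalized is used.

Measured once on the default phantom at 1% noise: RMS shift error
≈ 0.005 ppm; the regression test pins the much looser 0.05 ppm.

## B0 correction and MTRasym

The normalized APTw spectrum is cubic-spline interpolated (natural
boundary; linear available) to the 0.01 ppm fine grid, shifted by −δ̂, and
resampled at the original 25 offsets. The default resampler looks up the
nearest fine-grid node (≤ 0.005 ppm position error); exact spline
re-evaluation is available as `resample_method: spline` and agrees to
< 1e−3 in Z. Resampled points needing data beyond ±6 ppm are marked
unavailable rather than extrapolated — polynomial/spline extrapolation is
unreliable — and a voxel is invalidated only when a sample its statistic
needs (±3.5 ppm) is unavailable, since the ±6 ppm endpoints are
unavoidably lost for any nonzero shift.

Residual error after correction on noiseless phantoms is dominated by
cubic-spline interpolation of the 0.5-ppm-sampled amide line (worst case
≈ 0.3 percentage points at |δ| ≈ 0.3 ppm, derived from the closed form);
the tests bound the pipeline by exactly that derived quantity, and the
corrected map's RMS error must stay strictly below the uncorrected one.

## ROI statistics

The statistical unit is the per-subject average of the left and right ROI
means (one value per animal), matching how such studies report one bar per
group; left/right values are used only for the laterality t-tests. The
battery: one-way ANOVA (between/within sums of squares), Tukey HSD with
studentized-range adjusted p per pair, Lilliefors-corrected KS normality
per group (parameters are estimated from the data, so the plain KS null is
wrong; the familiar "p = 0.200" cap is the Lilliefors table ceiling), and
pooled-variance independent t-tests left vs right (Welch by flag; pooled is
the common statistical-package default). Degenerate identical constant
groups return F = 0, p = 1. Implementation uses scipy
(`f_oneway`, `tukey_hsd`, `ttest_ind`) and statsmodels (`lilliefors`);
tests cross-check against hand-computed sums of squares and statsmodels'
independent Tukey implementation.

## Monte-Carlo experiments and problem sizes

`power_experiment` / `effect_pattern_rate` repeat the full
simulate → B0 → APTw → summarize → compare chain per replicate. Cohort
replicates use a 16 × 16 grid with n = 7 per group (≈ 0.1 s per cohort),
sized so that 1000-replicate calibration runs complete in a couple of
minutes while every stage still runs exactly as at full size. Type-I
calibration with identical group specs lands at the nominal 5% level;
the control-vs-elevated design at n = 7 recovers the expected significance
pattern (control differs from both elevated groups; the two identical
elevated groups do not differ) in ≳ 99% of replicates.

## Determinism

Every random quantity (B0 field, noise, subject dispersion, replicate
seeds) derives from an explicit integer seed through
`numpy.random.default_rng`; identical (spec, seed) pairs give bit-identical
stacks, and `run_pipeline` writes SHA-256 hashes of all outputs so full
runs can be verified byte-for-byte.

## Known limitations

* MTRasym is the only quantification (no Lorentzian-difference or
  multi-pool fitting); B1 correction is out of scope.
* The WASSR estimator assumes a single minimum in range; severe
  off-resonance (|δ| near the grid edge) is flagged invalid, not recovered.
* Real-data ingestion is NIfTI + JSON sidecar only (no DICOM/Bruker).
* The simulator's Lorentzian pools cannot reproduce exchange-rate or
  relaxation effects; conclusions about those require Bloch–McConnell
  simulation or measured data.
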