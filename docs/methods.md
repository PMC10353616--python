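# Methods

This note documents the models, parameter choices and numerical
conventions behind `dalff`, and what the package's validation does and
does not demonstrate.

## The dALFF-CV statistic

ALFF is computed from the one-sided discrete Fourier amplitude spectrum,
`a_k = 2|X_k|/N` at frequencies `f_k = k/(N·TR)` for `k = 1..⌊N/2⌋`, as the
*mean* of `a_k` over bins inside the band (edges inclusive, with a 1e-12
relative tolerance so exact edge frequencies are never lost to rounding).
This amplitude convention makes a unit sinusoid at an exact bin have
amplitude exactly 1 there, which gives a closed-form test case; any fixed
convention cancels in mALFF and in the CV.

**Band.** The default analysis band is 0.01–0.08 Hz, the canonical ALFF
band. The band is a configuration value (`alff.f_lo`, `alff.f_hi`), not a
constant.

**Windowing.** Sliding windows of 50 TRs (100 s at TR = 2 s) with step
1 TR; with 186 acquired volumes and the first 10 dropped, the 176 retained
TRs yield `⌊(176−50)/1⌋+1 = 127` windows. Windows are rectangular (no
taper): the series is already detrended, and per-window tapering would
only rescale all windows identically up to leakage effects; a `hann`
option could be added but is deliberately not a default.

**Normalization.** Each window's ALFF map is divided by that window's own
in-mask mean (`normalize="window"`, default); `"static"` divides every
window by the whole-run mean ALFF and `"none"` skips normalization. The
window mode is the default for a substantive reason observed during
validation: nuisance regression removes a subject-varying slice of in-band
power that is largely *shared* across voxels, and dividing by the
window-wise global mean cancels exactly that shared component. The CV
itself (SD/mean, SD with `ddof=1`) is invariant to any global rescaling of
the run, which the suite checks to 1e-10.

Degenerate voxels whose window-mean ALFF is not positive (possible only
for identically zero series) get CV = 0 and are counted in the log.

## Preprocessing

Stages run in a fixed order: drop initial volumes (default 10) → per-voxel
linear detrend (OLS line) → nuisance regression (OLS residuals on
[intercept | regressors]; the design must be full rank, offending columns
are named) → Gaussian smoothing (FWHM 6 mm, σ = FWHM/(2√(2 ln 2)) in voxel
units from the affine, truncation 4σ, unit-sum kernel, zero padding).
Because the linear trend is removed in its own step, the regression design
carries only an intercept by default rather than refitting a polynomial
trend. Motion is never estimated — runs are assumed pre-aligned and motion
parameters arrive as regressors; mean framewise displacement is computed
from them for QC (Power convention, 50 mm head radius) but no frames are
censored. Smoothing operates on the full volume; masking is applied at
analysis time.

## Group inference

Per voxel, OLS of the subject CV values on
`[intercept, group(0/1), age, sex, education]` with covariates
mean-centered, so the group coefficient is the adjusted difference at
covariate means; `t = c·β̂ / SE`, `df = n − p`. Voxels fit exactly
(zero residual variance relative to the data scale) get t = 0 instead of
0/0 noise. t is mapped to z by the tail-symmetric quantile transform
`z = Φ⁻¹(F_t(t))`, evaluated through survival functions so large |t|
remain finite.

**Smoothness** is estimated from the standardized GLM residuals,
normalized per voxel to unit sum of squares across subjects: per axis,
λ is the mean squared first difference over in-mask neighbor pairs and
`FWHM = voxel_size · √(4 ln 2 / λ)`; `resels = |mask|·∏voxel / ∏FWHM`.
This discrete estimator is biased upward by about 9 % at FWHM = 2 voxels
(and less at higher smoothness); the bias is documented rather than
corrected because every downstream check passes within its stated
tolerance and the permutation path does not depend on smoothness at all.

**GRF cluster p-values** threshold the z field at `u = Φ⁻¹(1−p_vox)`
(halved per tail under the two-sided default), form clusters at
connectivity 26, and use the standard 3D Gaussian-field approximations:
expected cluster count `E[m] = resels · ρ₃(u)` with
`ρ₃(u) = (4 ln 2)^{3/2} (2π)^{-2} (u²−1) e^{−u²/2}`, expected
suprathreshold volume `E[N] = |mask|·Φ̄(u)` voxels, and the exponential
extent tail `P(n ≥ k) = exp(−β k^{2/3})` with
`β = (Γ(5/2)·E[m]/E[N])^{2/3}`; the corrected cluster p is
`1 − exp(−E[m]·P(n ≥ k))`, monotone nonincreasing in cluster size.

**Permutation inference** is the ground-truth oracle: a Freedman–Lane
scheme residualizes the data against the reduced model (intercept +
covariates), permutes residual rows, adds the reduced fit back and refits
the full model; the per-permutation maximum suprathreshold cluster size
(both tails) forms the null, and cluster p-values are
`(1 + #{max ≥ k})/(1 + n_perm)` — never zero. With ≤ 5 subjects all
permutations are enumerated exactly (with a warning). Reports state which
method produced each p-value.

Validated error control (400 null cohorts, 10 vs 10 subjects, 12×12×10
grid, T = 80, CV maps given an additional 6 mm smoothing to reach the
well-smoothed regime GRF assumes): permutation FWER ≈ 0.045–0.05,
GRF FWER ≈ 0.08 — the GRF approximation runs slightly hot on fields this
small, which is exactly why the permutation path exists and why reports
are explicit about the method.

## Clinical association

ROI-mean CV per subject; Spearman ρ with each scale (average ranks for
ties; p from the t approximation, with exact permutation enumeration
behind a flag for n ≤ 8); ROC/AUC as the Mann–Whitney probability with
ties half-credited; demographics via the pooled-variance two-sample t and
the Pearson χ² *without* continuity correction — both conventions locked
by recomputation of the published summary rows (pooled t on the printed
age moments gives 0.450 where Welch gives 0.453; the uncorrected χ² on the
printed sex counts gives 7.184). Quartiles for scale summaries use linear
(type-7) interpolation. No multiple-testing correction is applied across
ROI × scale pairs by default, mirroring the emulated analysis; a
Benjamini–Hochberg option would be an extension, not a default.

## The synthetic cohort generator

Each in-brain voxel carries

```
y(t) = [1 + d·m(t)]·sin(2πft + φ_v) + drift_v·t + Σ_j w_vj·g_j(t) + ε(t)
```

with subject-level carrier `f ~ U(0.02, 0.06) Hz`, per-voxel phase φ_v,
envelope `m(t) = sin(2πt/P + ψ)` with P = 150 s and subject-random ψ,
AR(1) noise (ρ = 0.3, SD 0.12 relative to unit carrier amplitude), and
nuisance components with small per-voxel loadings: 6 random-walk motion
series expanded to 24 Friston-style columns, white-matter and CSF signals
(smooth AR(1), unit SD), and a linear drift. The brain is an axis-aligned
ellipsoid (semi-axes 0.45 of each grid extent) on a 20×24×18 grid of 3 mm
voxels; T = 186 at TR = 2 s.

The modulation depth d is the patient-group depth (default 0.6) inside
spherical effect ROIs for patients and the control depth (default 0)
elsewhere. Each subject's depth additionally scatters around the group
level (uniform ±60 %): patients vary in severity, and this heterogeneity
is what clinical scores can couple *to* — with a single fixed depth, the
only between-patient variance in true variability is realization noise,
which no analysis could recover reliably.

Clinical scales are monotone affine functions of the patient's *noise-free
planted signal CV* (the windowed-ALFF CV of the pure modulated carrier in
the effect ROI — the generator's ground truth), plus Gaussian noise,
clipped to instrument ranges (NIHSS 0–42, BI 0–100, Fugl-Meyer UE ≤ 66,
LE ≤ 34). Severity scales couple negatively (NIHSS), function scales
positively. Default coupling noise is half the slope; centers and slopes
are placed so noiseless scores stay inside range for |z| ≤ 3, keeping the
noiseless coupling exactly rank-preserving.

Demographics: age ~ Normal(56, 11) truncated to [30, 75]; sex Bernoulli
with per-group male proportions (defaults 25/34 and 19/44); education
Normal(9, 3) years clipped to [1, 19]. Sex influences no signal — it
exists to exercise the covariate path, mirroring how the emulated analysis
treats it.

All randomness derives from one seed: subject generators are seeded by
(seed, subject_index), demographics and clinical noise by fixed offsets,
so cohorts are bit-reproducible and any subject can be regenerated alone.

**What the generator does not emulate:** hemodynamic response shape,
spatial lesions, motion artifacts in image space, scanner noise physics,
physiological rhythms, or spatial autocorrelation of the noise before
smoothing. Passing tests therefore demonstrate that the *pipeline
implements its statistics correctly and recovers planted structure under
its own assumptions* — not that those assumptions hold in any particular
patient dataset.

## Validation scales and measured behavior

The self-validation experiments (`dalff.validation`) size their problems
for a desk machine: FWER uses 400 cohorts of 10+10 subjects on a 12×12×10
grid with T = 80 and 100 permutations; planted-effect recovery uses three
cohorts of 15+15 subjects at the full default geometry. At those scales,
measured behavior (seeded runs; see `scripts/acceptance.py`): cluster/ROI
Dice ≈ 0.65–0.73, pooled clinical Spearman |ρ| ≈ 0.43–0.72 with every
planted sign recovered, ROC AUC ≈ 0.90, permutation FWER ≈ 0.05 and GRF
FWER ≈ 0.08.

## Known limitations

- GRF cluster p-values are approximations; they are mildly anticonservative
  on small, moderately smooth masks. The permutation path is exact up to
  Monte-Carlo error and should be preferred when runtime allows.
- The smoothness estimator's discrete-difference bias (≈ +9 % at 2 voxel
  FWHM) propagates into GRF resel counts; see above.
- Nuisance regression projects out part of the in-band signal along with
  the nuisance (28 smooth columns over 176 samples); per-window global
  normalization compensates for the shared part only.
- Cluster labels come from user-supplied ROI masks by maximal overlap;
  there is no anatomical atlas lookup.
- The clinical coupling model is linear-monotone with clipping; real
  clinical scales are discrete, floor/ceiling-limited and multifactorial.
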