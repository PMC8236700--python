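# Methods

## The measurement problem

Cerebrovascular reactivity (CVR) mapping probes how well the brain's
vasculature can change blood flow in response to a vasodilatory stimulus.
The stimulus modeled here is a targeted step in the end-tidal partial
pressure of CO2 (PETCO2): rest for 2 min, +10 mmHg for 2 min, return to
rest for 2 min, while BOLD fMRI is acquired (defaults TR = 2.4 s, 150
frames, 3.5 mm isotropic voxels). Two confounds limit the naive
"regress BOLD on PETCO2" analysis: the vascular response is not
instantaneous (its speed carries physiology of its own), and the large
BOLD voxels mix gray matter (GM), white matter (WM) and CSF signal.
`cvrkit` addresses both: it fits a family of voxel-wise response models
that separate magnitude from speed and delay, and it unmixes the tissue
contributions of the resulting parameter maps.

## Response models

All models are fit on the percent-normalized signal (each voxel divided
by its temporal mean, times 100) so slopes carry %BOLD/mmHg units, with a
linear drift term `alpha*t` and a constant baseline in every regression.

1. **Standard model.** `S(t) = mCVR * P(t) + alpha*t + b + eps`, where
   `P` is the PETCO2 waveform resampled to frame-center times and
   time-shifted to the point of coincidence with the brain-average BOLD
   signal. mCVR is the OLS slope.
2. **Convolution model.** `S(t) = ssCVR * (P (*) h_tau)(t) + ...` with the
   exponential kernel `h_tau(s) = exp(-s/tau)` truncated at `5*tau` and
   normalized to unit area, so a sustained step of amplitude A converges
   to A and ssCVR is the steady-state amplitude corrected for response
   speed. tau is grid-searched over 2–100 s in 2 s steps; the winner
   maximizes the Pearson correlation between the BOLD series and the
   convolved regressor with the drift partialled out (equivalently,
   minimizes the regression SSE). Ties go to the smallest tau.
3. **Time delay.** The winning convolved regressor is advanced 2 s (so it
   precedes the BOLD signal everywhere) and then delayed by a candidate
   TD in 0–5 s steps of 0.2 s; the correlation-maximizing TD is kept and
   ssCVR re-estimated at that shift. Both the grid value (TD) and the net
   physiologic delay (TD − 2 s) are stored, since conventions differ on
   which is reported.

The standard and convolution models are compared per voxel with
`BIC = n*ln(SSE/n) + (p+1)*ln(n)`, `p = 2` and `p = 3` respectively (the
parameter counts as conventionally printed for these two models); lower
is better. A perfect fit (SSE = 0) maps to a −inf sentinel with a
warning.

### Numerical choices

- **Kernel discretization.** Convolution runs on a 0.1 s working grid
  (linearly upsampled from the frame grid) because the TD step (0.2 s) is
  sub-TR. Kernel weights are the *exact integrals* of the exponential
  over each working-grid interval (the lag-0 weight is zero), normalized
  by their sum. This makes the unit-step response exact at grid times —
  `(1-e^-1)/(1-e^-5)` at `t = tau` — and the steady-state gain exactly 1;
  a point-sampled kernel would carry a half-sample bias (~2% at
  tau = 2 s). Samples before the trace start are padded with the first
  value (the protocol begins at resting baseline).
- **Alignment.** "Point of coincidence" is operationalized as the
  maximal Pearson correlation over a shift grid (default ±20 s, 0.1 s
  step), ties broken toward the smallest absolute shift; shifted-out
  samples are filled by edge-value extension. The criterion is invariant
  to affine rescaling of the BOLD series.
- **Degenerate inputs.** Constant PETCO2 raises a fit error; voxels with
  non-positive temporal mean are flagged invalid and skipped; per-voxel
  failures never abort a volume.

### A sequential-fitting caveat

tau is estimated with an *unshifted* regressor and TD only afterwards.
For data whose true net delay is nonzero, the tau search absorbs part of
the delay (a net delay of d behaves approximately like a tau increase of
d), so the cascade recovers (tau, TD) exactly only when the net delay is
zero or small against the 2 s tau grid step. This is a property of the
sequential procedure itself, not of the implementation; the exactness
tests therefore use zero-net-delay ground truth, and nonzero-delay
recovery is asserted to within one grid step.

## Partial volume correction

A low-resolution metric value mixes tissue contributions in proportion
to composition: `I0 = g0*Ig + w0*Iw + c0*Ic`. Assuming each tissue's
intensity is locally constant, every voxel within a 9 mm radius (81
voxels on the 3.5 mm grid, boundary inclusive, distances in physical mm
so anisotropic voxels are supported) contributes one equation, and
(Ig, Iw, Ic) is solved per voxel by least-absolute-deviations (LAD) —
robust to outliers such as vessel voxels. Neighbors outside the brain
mask are excluded; classes absent from the central voxel are not
assigned; with fewer than three usable neighbors or a rank-deficient
design the voxel falls back to its uncorrected value and is flagged.
The corrected value is written onto the 1 mm anatomical grid: each
high-resolution voxel takes the solution of its majority tissue class
(argmax of the three probabilities; exact ties resolve to the first
class in GM, WM, CSF order), from the low-resolution voxel whose
footprint contains it. Tissue fractions come from overlap-volume-weighted
averaging of the high-resolution probability maps under each
low-resolution footprint; they are not renormalized — the brain-exterior
remainder acts as a zero-intensity component excluded from the design.

The LAD solver is iteratively reweighted least squares with weights
`1/max(|r|, 1e-9)`, at most 100 iterations, convergence tolerance 1e-13;
it matches a linear-programming LAD formulation to better than 1e-6 on
consistent 81-equation systems with up to ~10% gross outliers. No
intercept is fit (the mixing equation has none).

A modeling subtlety: amplitude metrics (mCVR, ssCVR) scale with the
total tissue fraction of a voxel, but shape metrics (tau, TD) do not — a
voxel half-filled with tissue still exhibits the full tau. The mixing
equation is therefore only valid where `g + w + c = 1`, which holds
inside the head for real segmentations and, in this package, for every
in-mask phantom voxel (see below).

## ROI statistics

Tissue masks threshold the probability maps strictly above 0.7. Averages
follow the standard exclusion rules: voxels with mCVR above 0.7 %/mmHg
are removed from every metric's average (sinovenous contamination), and
voxels with negative ssCVR are additionally removed from TAU averages,
where tau no longer indexes vasodilatory speed (steal physiology). The
threshold is a strict "above": values exactly at 0.7 are retained. The
sinovenous filter is evaluated on the map being summarized (the same
correction route), since the order of filtering and correction is a free
choice. GM is summarized within each vascular territory (CER, ACA, MCA,
PCA — consumed as subject-space labels) and WM as a whole; cohort tables
take the mean and SD across subject means, not across pooled voxels.

## The digital phantom

The phantom exists so that every stage can be validated against known
truth. Geometry (1 mm grid, default 70×70×42): a central ventricular CSF
compartment, a WM ellipsoid core, a cortical GM ribbon of 2.5 mm
(realistic cortical thickness — deliberately thinner than the 3.5 mm
acquisition voxel, so *every* cortical low-resolution voxel is genuinely
mixed), a 2 mm outer CSF shell, and four angular sectors standing in for
vascular territories. Internal tissue borders are Gaussian-smoothed
(default sigma 1 mm) and renormalized so probabilities sum to exactly 1
inside the head and 0 outside, as anatomical segmentations do. The
low-resolution brain mask keeps only fully tissue-covered voxels,
matching the mixing model's `g + w + c = 1` domain.

Each tissue class responds to the convolved, delayed stimulus with its
own (ssCVR, tau, TD); defaults sit at normative magnitudes — GM
0.30 %/mmHg, 24 s, 2.2 s; WM 0.13 %/mmHg, 48 s, 2.8 s; CSF a small
positive fast response (0.05 %/mmHg, 10 s, 1.6 s), since surface-vein
signal extends into CSF and it should not be assumed null. A voxel's
response is the fraction-weighted mixture of class responses (the
forward model is linear in composition), plus a linear drift
(0.002 %/s) and white Gaussian noise, default SD 1% of baseline per
frame (temporal SNR ≈ 100, typical for 3 T 3.5 mm EPI; voxel-wise
correlations then span ≈0.5 in WM to ≈0.8 in GM). The percent-scale
response is mean-centered per voxel so the temporal mean equals the
baseline intensity exactly, making percent normalization an exact
inverse in the noiseless case. mCVR has no independent truth — it is
itself a regression summary — so the generator computes the per-class
reference as the standard-model slope of the noiseless pure-class
response. All randomness flows through one seeded generator; outputs are
bit-reproducible.

What the phantom does *not* emulate: convoluted gyral anatomy (its WM is
a fat core, so WM voxels are less partial-volume contaminated than real
hemispheric WM), temporally autocorrelated physiological noise, motion,
vascular trees, and hemodynamic nonlinearity. Passing tests therefore
demonstrate correctness of the estimators and of the unmixing algebra
under the stated model, not performance on real data.

### Known limitation observed with the phantom

On the noisy default phantom, partial volume correction moves GM
mCVR/ssCVR up, WM mCVR/ssCVR down and GM tau down, as expected from the
normative pattern. The expected WM tau *increase*, however, does not
materialize: noiselessly the effect is present (NN 46.0 s → PVC 50.0 s),
but at 1% noise the upward skew of the grid-search tau estimator in
low-SNR WM inflates the uncorrected WM mean by about the same amount the
partial-volume contamination deflates it, and the neighborhood
regression smooths that skew, leaving a net change near zero. Longer
acquisitions and the heavier WM mixing of real anatomy both work against
this cancellation, which is why it is visible here and not in normative
data. Relatedly, tau unmixing is only approximately linear when tissues
differ in tau (the fitted tau of a mixed response is not the mixture of
taus), so corrected GM tau overshoots downward on the default phantom;
direction, not magnitude, is the validated claim for tau under PVC.

## Problem sizes

Defaults were chosen so a full phantom pipeline (simulate → fit → PVC ×
4 metrics → stats) runs in well under a minute on one CPU: 20×20×12
acquisition voxels × 150 frames, 50 tau × 26 TD candidates, ~1300
in-mask PVC systems of 81 equations. The model-comparison experiment
simulates 50 subjects × 120 voxels.
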