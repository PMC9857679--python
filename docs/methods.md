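# Methods

This note records the models implemented in `teahsi`, the assumptions they
make, the parameter defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Radiometric correction and ROI masking

Raw line-scan intensities are converted to reflectance with the standard
two-point correction `R = (raw − dark) / (white − dark)`, applied per pixel
and band, then clipped to [0, 1] (a tea sample cannot out-reflect the white
reference tile). If `|white − dark|` falls below 1e-9 anywhere, the
correction refuses and names the offending band rather than emitting
infinities.

The tea ROI is the set of pixels whose *band-mean* reflectance strictly
exceeds 0.1. Thresholding the band mean rather than a single band makes the
mask robust to per-band noise; the strict inequality (a pixel at exactly
0.10 is background) is an arbitrary but documented convention. No
morphological cleanup is applied — the generator's foreground is a filled
ellipse and real tea piles are compact, so a plain threshold suffices. The
per-sample spectrum is the arithmetic mean over ROI pixels.

Cubes are read and written in two dialects: an ENVI-style text header
(`samples`, `lines`, `bands`, `data type`, `interleave`, brace-delimited
wavelength list, written at 17 significant digits so the axis round-trips
bit-exactly) with float64 BIL/BSQ binary, and an HDF5 container for
archival fixtures.

## PLS regression

`pls_core` implements NIPALS with X- and y-deflation for univariate
targets: weights `w ∝ X'y`, scores `t = Xw`, loadings `p = X't/t't`,
`q = y't/t't`, rank-one deflation, repeated for each latent variable. The
equivalent affine form `ŷ = b₀ + x·b` with `b = W(P'W)⁻¹q` is stored on the
model and is the only prediction path, so the latent and coefficient forms
agree to machine precision by construction (asserted in tests against an
explicit latent-path evaluation and against an independent least-squares
oracle at full rank).

Preprocessing is mean-centering only — no autoscaling, SNV or derivatives —
matching common practice when reflectance spectra feed a linear calibration
directly. The LV count is selected by 5-fold cross-validation: folds are
contiguous blocks of a seeded shuffle (sizes differ by at most one), the
RMSECV pools held-out residuals across folds, and ties go to the smallest
LV count. `max_lv` defaults to 15, capped by the smallest training fold.

Rc and Rp are Pearson correlations between measured and predicted values.
The alternative reading (determination coefficients) exists in the
chemometrics literature; the correlation interpretation was chosen because
that is what the symbols name, and RPD — the decision metric — is
unaffected.

## CARS wavelength selection

Each of N (default 50) Monte-Carlo runs draws 80% of calibration samples
without replacement, fits a working PLS on the currently retained
wavelengths, and converts coefficient magnitudes into elimination
pressure twice:

1. *Enforced elimination*: keep the `⌈r_i·p⌉` wavelengths with the largest
   |b|, where `r_i = a·exp(−k·i)` with `a = (p/2)^{1/(N−1)}`,
   `k = ln(p/2)/(N−1)` — all variables at run 1, two at run N.
2. *Adaptive reweighted sampling*: a weighted bootstrap over the survivors
   with weights `|b_j|/Σ|b_j|`, keeping distinct sampled indices. The draw
   count is fixed at p per run. This choice matters: drawing only
   `|survivors|` times loses ~37% of the subset every run regardless of the
   schedule, so the trajectory collapses to one or two variables within ~8
   runs and single unlucky eliminations become irrecoverable. With p draws
   the bootstrap covers nearly all survivors once the subset is below
   ~p/2, the subset size tracks the EDF schedule (a fast decline first,
   then schedule-paced refinement), and planted-signal recovery becomes
   reliable.

Each run's final subset is scored by 5-fold RMSECV on the *full*
calibration set with a fold plan fixed across runs, so scores are
comparable. The working LV count is re-optimised each run from that same
RMSECV curve (the curve is computed for scoring anyway, so this adds no
cost). Fixing the LV count to the full-spectrum CV choice was tried first
and rejected: the full-spectrum RMSECV curve is nearly flat on this data,
occasionally selecting a single LV, which degrades the elimination weights
and recovery. The winning run minimises RMSECV; ties break toward fewer
variables, then the earlier run. Degenerate cases never crash a run: an
all-zero coefficient vector falls back to uniform weights (logged) and the
LV count is capped by the subset size.

The final CARS-PLS model is refitted on the winning subset with its LV
count re-optimised by the same cross-validation.

## Evaluation

The 2:1 calibration/prediction split is, by default, deterministic
rank-systematic sampling: samples are sorted by the target and the middle
member of each consecutive triple goes to prediction. This keeps the target
extremes in calibration (the prediction set never extrapolates) and makes
the split reproducible without a seed; a seeded random split is available.
Because the split is target-dependent, each fatty acid gets its own split.

RPD is defined as the sample standard deviation (n−1 denominator) of the
prediction-set reference values divided by RMSEP, and the identity
`RPD = SD/RMSEP` holds bit-exactly on every report row. A model is called
accurate iff RPD strictly exceeds 2.0. Zero-variance prediction targets
raise; constant predictions yield NaN correlation with a warning; an
exactly zero RMSEP caps RPD at a sentinel (1e6) with a warning. PCA (for
day-clustering summaries) is mean-centered SVD via scikit-learn with the
full solver, reporting explained-variance percentages.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis relies on,
not tea chemistry:

- **Degradation**: eight monomer fatty acids (palmitic, stearic, arachidic;
  9-hexadecenoic, oleic, linoleic, linolenic, cis-11-eicosenoic) with
  baseline contents in arbitrary units (relative magnitudes follow typical
  green-tea profiles; absolute units are unknowable without the reference
  assay, and all decision statistics — R, RPD — are scale-free). Day means
  drop by 5% per transition except 30→60 and 120→150, which drop 35% —
  the slight/sharp/plateau/sharp shape of observed freshness loss over
  {0, 30, 60, 90, 120, 150} days.
- **Correlation structure**: within a day, monomer deviations share a
  common latent factor (correlation 0.7) plus independent noise
  (CV 8%), so one latent "degradation state" drives all targets and their
  regression-coefficient spectra look alike. Totals are computed by exact
  summation (compositional closure).
- **Spectra**: reflectance = baseline 0.62 minus concentration-weighted
  nonnegative Gaussian absorption profiles — water (peak jittered within
  1450–1500 nm, the O–H first overtone), amino acids (1160–1180 nm),
  caffeine (1650–1660 nm), and a weak, narrow fatty-acid block with peaks
  inside 1100–1400 nm. The fatty-acid loading scales with the sample's
  total fatty-acid content. Fatty-acid features are deliberately weak and
  narrow (depths of a few 1e-2 at typical loadings, widths 7–10 nm):
  visible fatty-acid peaks are not expected in tea spectra, and only a
  small fraction of the 508 bands should be genuinely informative — this
  is precisely the regime in which wavelength selection pays.
- **Noise** (`noise_sd`, default 0.01 reflectance): half enters as
  per-band frame noise shared by every pixel (detector band-gain drift,
  which ROI averaging cannot remove) and the full amount as per-pixel
  noise (which averaging mostly removes). Matrix-component loadings vary
  2% between samples as nuisance variance uncorrelated with the targets.
  Setting `noise_sd = 0` yields the exact noiseless mixture, which the
  tests exploit as a zero-noise identity. During design, a smooth
  scatter/drift nuisance (baseline offsets, slopes, broad bumps) was
  evaluated and rejected as the *dominant* term: smooth nuisance turns
  distant bands into implicit reference channels, so restricting to the
  truly informative bands then underperforms the full spectrum and no
  selector can help — the opposite of the regime this pipeline targets.
- **Geometry**: an elliptical "leaf pile" foreground (semi-axes 0.36 of
  each image dimension; images smaller than 8×8 are rejected), background
  at reflectance 0.05 (below the 0.1 mask threshold), white ≈ 0.995 and
  dark ≈ 0.005 reference frames with small noise, and the raw cube built
  as `dark + R·(white − dark)` so correction recovers R exactly.
- **Seeding**: one global seed cascades to per-sample seeds through a
  counter (`SeedSequence((seed, i))`), making every artifact bit-for-bit
  reproducible.

What it does **not** emulate: GC–MS chromatograms or assay error,
radiometric behaviour of a physical line-scanning camera (smile/keystone,
spatial illumination falloff), scattering physics, nonlinear
concentration–absorbance relations, or leaf-level spatial texture
(foreground pixels are exchangeable). Passing tests therefore demonstrate
that the pipeline's statistics behave correctly under a linear mixing
model with realistic noise structure — not that a particular RPD would be
attained on real tea.

## Problem sizes

The default study scale is 6 days × 15 samples = 90 cubes of 32×32×508
(about 380 ROI pixels each), split 60/30. Unit tests that check structure
rather than statistics run on reduced problems (4–5 samples/day, 64–96
bands, 12–16 pixel images, shortened CARS tournaments); the
pipeline-level properties (RPD > 2 for both totals; median CARS-PLS
improvement over full-spectrum PLS across 20 seeds; planted-signal
recovery of 5 informative bands among 508) run at the full default scale.

## Known limitations

- CARS is a stochastic tournament; on hard problems individual seeds can
  lose an informative wavelength early and settle on a larger, noisier
  subset. Median behaviour across seeds is the meaningful guarantee.
- The rank-systematic split uses the target values themselves; it is a
  design choice for determinism, and metrics under a random split will
  differ (typically slightly worse Rp).
- Pixel-wise maps extrapolate wherever a pixel's spectrum leaves the
  calibration cloud (single-pixel noise is much larger than ROI-mean
  noise); predictions outside the calibration target range are kept
  visible and their fraction recorded on the map rather than clipped.
- With matrix nuisance variance present, full-spectrum PLS on this
  generator is itself often accurate (RPD > 2); the value of CARS here is
  model compression at equal-or-better accuracy, and a modest median RPD
  gain, rather than rescuing a failing calibration.
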