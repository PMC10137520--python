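# Methods

This note documents the models implemented in `procmon`, the synthetic data
they are exercised on, the numerical choices that matter, and what the
passing tests do and do not demonstrate about real plant data.

## Data model and timeline reconstruction

Three asynchronous streams share one campaign timeline (15 s cadence by
default): NIR absorbance spectra of the intermediate product on a uniform
wavelength grid (1100–1650 nm at 2 nm, 276 channels), per-frame RGB means
and standard deviations from a camera watching the raw material, and sparse
off-line quality records (Bostwick consistency, cm; total lipids, %)
measured at the end of the line.

**Stops.** When the conveyor stands still the camera keeps imaging the same
material, so production stops are detected as maximal runs of constant RGB
frames: a step counts as constant when every channel (means and SDs)
changes by at most `tolerance` (default 0, exact constancy), and a run
becomes a stop when it spans at least `min_duration` points (default 4,
i.e. one minute). An optional pump-activation register can be merged in as
a second stop source.

**Cleaning.** Frames deviating from a channel median by more than `k_mad`
normal-consistent MADs (default 5, conservative) in any mean channel are
masked out. A zero-MAD channel flags exact deviants from the median only.

**Alignment.** A quality value measured at time *t* describes material that
passed the NIR probe at *t − lag*, where the residence lag is a
configuration scalar (default 300 s in the generator; at a real plant it
comes from process experts). Each record is matched to the nearest NIR time
within a tolerance of half the sampling period, injectively; unmatched
records are reported, never silently dropped. The assembled analysis table
keeps matched, clean, non-stop rows only, and the stop/cleaning filters
commute (mask intersection).

## Preprocessing

Savitzky–Golay filtering acts along the wavelength axis (default window 15,
polynomial order 2, 2nd derivative — conventional at this resolution; the
derivative is per grid step, a fixed rescaling on a uniform grid). Edges
are handled by evaluating the polynomial fitted to the first/last full
window, so output length equals input length. Mean centering and
autoscaling store their column statistics for later application to
streaming data; autoscaling uses the sample standard deviation (ddof 1) and
rejects zero-variance columns by index.

**Dynamic Orthogonal Projection.** The premise: samples with the same (or
very close) response values should show the same spectral profile, so
response-matched "virtual" spectra expose the variability that is *not*
related to the response. Source spectra are per-unique-y averages of the
calibration spectra (y grouped after rounding to the measurement precision,
0.1 cm for consistency). The association matrix uses a Gaussian kernel in
y with row normalisation — a smooth realisation of "same or very close" —
with default bandwidth 0.5 × SD of the calibration response. Virtual
targets are `X* = M X_source`; the correction basis `V_A` holds the first
`A` right singular vectors of `D = X_tar − X*` (default A = 4), and the
projector `I − V_A V_Aᵀ` is applied to the measured spectra being corrected
— calibration targets at fit time and any new spectra at prediction time,
so the correction is embedded in the model. Singular directions below
1e−12 of the largest are never extracted: a zero difference matrix yields
the identity correction rather than arbitrary directions. DOP is fitted on
raw spectra, with mean centering (of X and y) the only preprocessing
afterwards.

## Latent-variable models

**PCA** is computed by SVD of the centered matrix; score variances equal
the covariance eigenvalues (ddof 1) and the full eigen-spectrum is retained
for the monitoring limits. Cross-validated dimensionality selection uses
venetian-blind folds and held-out row reconstruction through the projector
of the training loadings; because projecting a held-out row onto *any*
a-dimensional subspace removes an expected a/p share of pure noise, the
PRESS is rescaled by p/(p − a), which makes the curve flat on structureless
data. The smallest count within one standard error (over folds) of the
minimum is selected.

**PLS1** uses NIPALS with deflation of X only — the standard
single-response form; with one response the weight vector has the closed
form `w = Xᵀy/‖Xᵀy‖`, so the iteration (tolerance 1e−10, cap 1000)
converges on its first check. The regression vector is
`B = W (PᵀW)⁻¹ q`; predictions through B equal the sequential deflation
recursion to machine precision, and at full rank B equals the minimum-norm
least-squares solution. RMSECV refits the centering inside every training
fold (no leakage) and pools squared errors over folds before taking the
root; the latent-variable count is the RMSECV argmin. VIP scores follow the
standard weighting of squared normalised weights by per-component explained
response variance; mean VIP² = 1 exactly, so 1 is the influence threshold.

**Duplex split.** The classic Snee construction: the two mutually farthest
samples seed the calibration set, the two farthest remaining seed the test
set, then the sets grow alternately by max-min Euclidean distance until the
test quota `n − round(ratio·n)` is filled; the remaining (central) samples
join calibration. Ties break toward the lower index, so the partition is
fully deterministic; 203 samples at 70/30 give 142/61. For small n the
rounding convention matters (45 samples give 31/14 here; other
implementations give 33/12). Both sets deliberately reach into the extremes
of the data cloud; the representativity property that holds (and is tested)
is that the duplex test set *covers* the dataset better than a random
subset of the same size — not that its points lie closer to the calibration
set than random ones, which is false for any duplex variant because the
test set is extreme-heavy by design.

## Monitoring charts

The MSPC model is a PCA of NOC calibration spectra (default preprocessing:
SG 2nd derivative + mean centering), with per-sample
`T² = Σ t²_a/λ_a` and `Q = ‖x(I − PPᵀ)‖²`. Limits at significance α
(default 0.05):

* T²: `a(n−1)(n+1)/(n(n−a)) · F₁₋α(a, n−a)` — the new-observation form,
  appropriate because the charts judge projected test samples;
* Q: Jackson–Mudholkar normal approximation (default) or Box's
  `g·χ²₁₋α(h)` with `g = θ₂/θ₁`, `h = θ₁²/θ₂`, both computed from the
  positive residual eigenvalues of the calibration covariance beyond the
  retained components.

The NOC calibration/test split mimics continuous monitoring: within each
stop-free period the first 65% of points (rounded) go to calibration, the
rest to test; stop points and known anomalous points always go to the test
set. Monitoring is pure projection — stored preprocessing applied, never
refit — so monitoring the calibration block reproduces its own chart. A
*flagged episode* is a run of at least 3 consecutive flagged test samples;
a calibrated chart flags a few isolated points by construction (≈5%), while
a genuine departure from NOC flags a contiguous group, and the run-length
rule separates the two.

## The synthetic campaign generator

The generator emulates the structure of a real campaign, with every scale
chosen once:

* **Bands.** Gaussian absorption bands at the wavelengths that matter in
  this system: an intense water band at 1400 nm (width 30 nm, amplitude
  1.0), oil C–H bands at 1166/1213/1236/1461 nm (the 1166 nm band, 0.50, is
  the lipids driver), an R–OH band at 1410 nm and a lignin band at 1178 nm.
  The 1213/1236/1410/1178 set carries the restart signature.
* **NOC variability.** Band amplitudes fluctuate as stationary AR(1)
  processes around their nominal values (marginal SD 5%, water scaled
  2.5×). The default autocorrelation is 0 — an in-control process whose
  chart false-alarm rates match the nominal α; persistent drift
  (`drift_phi` > 0) is available but inflates T² exceedances at desk-scale
  window sizes because a later monitoring window wanders from the
  calibration mean (measured: 6–15% at α = 5% for φ = 0.3–0.97 with
  294/165 windows). That trade-off is inherent, not an implementation
  artifact.
* **Scatter and noise.** Channel noise SD 0.0016 AU (chosen so a
  4-component NOC model explains ≈94% of the variance, emulating the
  plant-scale structure); multiplicative scatter SD 0.002; baseline offset
  SD 0.005. The scatter factor multiplies the whole spectrum, so any band
  amplitude is observable only as `amp·(1+s)` — the independent scatter
  component therefore sets a hard floor on prediction accuracy, and its
  scale is consistent with the package's noise-floor recovery property.
* **Quality links.** Lipids % = 20 + 54 × (1166 nm band amplitude),
  centred at 47% (a realistic in-specification range), with response noise
  0.3%. Consistency cm = 1.8 + 5 × (physical state), centred at 6.8 cm,
  noise 0.15 cm. The physical state is a latent texture variable that
  modulates the overall scatter level (coupling 0.08) *and* tilts the
  scatter baseline with wavelength (slope coefficient 0.02 across the
  grid) — so consistency is deliberately not tied to any absorption band;
  the slope term is what makes it identifiable at all, since common-mode
  scatter alone cannot be separated from band drift.
* **Origin structure.** Suppliers (5) and cuts (4) arrive in contiguous
  lots; each shifts one fixed spectral direction (per-tag sensitivities,
  strongest on the lignin band) by a scalar drawn per supplier/cut (SDs 3%
  and 2%). Being low-rank, origin variation stays *inside* the NOC model
  space — visible in score plots, not as off-model distance.
* **Stops and restarts.** Five stops by default; during a stop the RGB
  frames are frozen exactly. The first 5 points after each stop are restart
  anomalies: the flagged bands' amplitudes shift by 50% of their base value
  (old material residue distorting the *measured* spectrum; the quality
  links use the clean amplitudes).
* **Determinism.** One master seed; all sub-streams are spawned from it, so
  equal configs give bit-identical campaigns, and at zero noise the stored
  ground-truth drivers reproduce the observables exactly.

**What the generator does not emulate:** real NIR band shapes (broader,
asymmetric, overlapping continua), nonlinear detector/pathlength effects,
Kubelka–Munk scattering physics, raw images, seasonal covariate shifts, or
autocorrelated in-control drift under the default settings. Passing tests
therefore demonstrate correctness of the algorithms and calibrated
behaviour under the stated model of the process — not performance on any
particular plant's data.

## Problem sizes and numerical choices

The default campaign is 600 time points (≈200 quality records, ≈185
assembled rows); monitoring studies use 294-sample calibration and
165-sample test windows, and chart-calibration checks average 20 such
campaigns. Prediction recovery uses stop-free campaigns with 200 assembled
rows, five seeds. Tolerances: SG and Q-statistic oracles at 1e−8/1e−10;
PLS vs minimum-norm least squares at 1e−6; DOP orthogonality at 1e−10;
Monte-Carlo checks at binomial 3σ. Degenerate inputs fail loudly: empty
blocks, zero-variance columns, components beyond rank, all-zero difference
matrices (identity correction), zero eigenvalues in T².

## Known limitations

* PLS1 only — no multi-response PLS2, O-PLS, or variable selection beyond
  VIP reporting.
* No MSC/SNV scatter corrections; the multiplicative-scatter confound is
  documented rather than corrected.
* The T² limit assumes serially independent calibration scores; under
  autocorrelated drift the charts over-alarm (see above).
* Anomalous samples are removed from the *test* set after duplex splitting;
  any that land in calibration stay there, mildly inflating calibration
  error — matching how such campaigns are handled in practice.
* Duplex rounding for small n is implementation-defined.
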