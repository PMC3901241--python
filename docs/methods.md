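# Methods

This note records the models, algorithms, defaults and design choices
behind `hmcr`, and what the synthetic data does and does not establish.

## Curve resolution (H-MCR)

**Model.** Per retention-time window, stacked sample data
`X ((n·w) × m)` is factored `X = C Sᵀ + E` with non-negative spectra `S`
(unit Euclidean norm per component) and non-negative chromatographic
profiles `C`. Carrying all magnitude in `C` makes integrated areas
comparable across samples; the spectra are pure shape.

**Windowing.** The retention axis is tiled into non-overlapping windows
of roughly `target_width` scans (default 40). Cut points snap to the
local minimum of the mean total-ion chromatogram within ±⅓ window of
each nominal cut, so peaks are not split mid-elution; on a flat TIC the
cuts are exact multiples. A peak that still straddles a boundary appears
in both windows and is de-duplicated downstream by reference-table
matching, not during resolution.

**ALS.** Both block updates are exact multi-RHS non-negative least
squares (a combinatorial active-set solver sharing the normal equations
across right-hand sides; `scipy.optimize.nnls` is the per-column oracle
in the tests). Exact block solves make the residual non-increasing by
construction, which the implementation asserts per run. Initialization
is deterministic: the k most mutually independent scans (greedy
orthogonal selection by residual norm), clipped and normalized.
Convergence: relative residual change < 1e−8 or 500 iterations.

**Component count ("auto").** From the singular spectrum of the stacked
window, truncated by the earliest of: cumulative variance ≥ 99.5 %, a
singular-value ratio gap > 10, or the noise floor — singular values
below 3× the median of the *full* spectrum do not count. The noise rule
exists because on noisy data the variance rule alone happily absorbs
dozens of noise components (observed: k = 74 for a 2-component window at
SNR ≈ 100 when the gap fell just under 10); the median tracks the flat
noise plateau and is immune to that failure. Requested counts above the
rank bound are reduced with a logged warning.

**Predictive resolution.** With `S` fixed, each new scan's spectrum is
projected by NNLS (default) or plain least squares
(`--prediction-ls plain`). Non-negativity is the physically meaningful
choice for concentrations and is the shipped default; the plain switch
exists because the unconstrained form is the textbook formula.
Per-sample residual fractions flag out-of-model samples (ones containing
components the reference never saw).

**A/B stability validation.** Default threshold 0.95 (Pearson), applied
to all three comparisons (S_A vs S_B, C_A vs C_A-predicted-under-S_B,
C_B vs C_B-predicted-under-S_A); a profile must pass all of them. The
split is per-window and data-driven: samples are characterized by their
total mass spectrum over the window, mapped to ≤ 2 PCA scores, and half
are chosen by the maximin design. Each half is resolved with its *own*
auto-chosen component count — forcing the full-data rank onto a half
that genuinely lacks a component splits a real profile there and
corrupts the correlation of components both halves share. Profile
pairing across resolutions is greedy by spectral cosine. With fewer than
4 samples validation is skipped and everything is flagged unstable. An
explicit `split=` override exists for constructions where the carrier
set of a component must coincide with one half (this is how the
half-support specificity property is tested; the data-driven maximin
split deliberately spreads diversity over both halves, so it would put a
random half-support component into both sets).

## Subset selection

PCA is mean-centered, unit-variance scaled, computed by SVD with a
deterministic sign convention; constant columns raise a named error.
Deviating observations are screened before selection by squared score
distance against the χ²(A) 0.99 quantile — a Hotelling-T²-style rule
with the large-n reference distribution, chosen for simplicity.

The maximin design maximizes the minimum pairwise distance among the
selected points. Instances with C(n, k) ≤ 5000 are solved exactly by
enumeration; larger ones by greedy farthest-point (seeded with the
mutually farthest pair, ties to the lowest index). The exact path exists
because greedy alone can reach only ~0.65× the optimum on adversarial
small instances, while the problem sizes the selection step actually
faces (tens of subjects) enumerate instantly. Subjects are selected as
units via group centroids: both the pre- and post-condition samples of a
selected subject enter the model set.

## Compression

The "fast and crude" per-sample characterization is a fixed-window
summary: the retention axis is split into `n_windows` equal windows and
each sample is described by the windowed sums of its base-peak
chromatogram concatenated with the windowed sums of its TIC
(length 2·n_windows). This retains gross compositional differences at
negligible cost and feeds PCA for the analytical-data selection
strategy. It is a deliberate re-specification of hierarchical
compression in its stated role; no claim is made that it reproduces any
particular published algorithm's output.

## Alignment and normalization

Alignment is a global integer shift per sample maximizing the dot
product of its TIC with the medoid sample's TIC (search bounded by
`max_shift`; excess drift beyond the bound remains). The common offset
is fixed by forcing the median applied shift to zero, so shifts are
recovered up to the cohort median — exactly, in the noiseless case. A
hook for piecewise warping is left open; the simulator's drift model is
a global shift, and real unit-mass GC data is usually close to one
within a run sequence.

Peak tables are normalized by the weighted sum of the internal-standard
areas per sample (weights equal by default, configurable — the weighting
scheme is an open choice and is exposed rather than guessed).
Normalization precedes the mean-centering/unit-variance scaling done
inside the modeling layer. Standards are located in a resolved reference
table by match factor (> 700) plus retention tolerance (±1 s) against
the known standard spectra.

## OPLS-DA

Single binary response y (0/1), one predictive component, `n_ortho`
orthogonal (OSC) components. Per component: `w ∝ Xᵀy`, the orthogonal
weight is the predictive loading orthogonalized against `w`, and the
data is deflated by the orthogonal component before the predictive
component is formed; the predictive score is exactly orthogonal to every
OSC score by construction (asserted to 1e−8). With `n_ortho = 0` the
model reduces to one-component PLS1 (verified against scikit-learn).
Class threshold is ŷ = 0.5, the midpoint of the coding — nothing in the
method fixes it otherwise. `n_ortho="auto"` maximizes cross-validated
Q2 (ties to the smaller count).

Cross-validation is 7-fold *full* CV: scaling and the entire
decomposition are refit per fold; folds are class-stratified round-robin
after sorting sample IDs, so the fold assignment is reproducible.
Q2 = 1 − PRESS/SS. Under the null, CV class accuracy is mildly
pessimistic (slightly below 50 %) because held-out predictions
anti-correlate with the training fold means; the calibration tests use
the binomial band, which the pooled estimate stays inside.

**Permutation test.** y is permuted `n_perm` times (default 10 000;
reduced in tests for speed), the model refit with the same `n_ortho` as
the original (cost control, logged), and each variable's |w1| recorded.
A variable is significant when its original |w1| exceeds the (1 − α)
quantile of its own null distribution (α = 0.05 default). No
multiplicity correction is applied — the criterion is per-variable by
design, and the type-I rate is verified by simulation instead. An
exhaustive switch enumerates all n! orderings for small n and matches
the Monte-Carlo quantiles exactly in tests. Statistical power depends
on the table shape: with a unit-norm weight vector, detectability of a
variable scales with how much of the weight mass the null spreads over
competing variables; a sparse pattern (≈10 % of variables regulated at
2 within-class SD, n = 16) is detected with power ≈ 0.87, while the same
effect spread over most of the table saturates lower. The test suite
pins the sparse condition.

**Model updating (longitudinal).** New-occasion samples are first
classified by the existing model; the model is then refit on original +
newly labeled samples restricted to the permutation-significant
variables, and the final occasion is predicted by the updated model. An
empty significant set falls back to all variables with a warning. A
label-override hook supports sensitivity analysis of label-error
propagation.

## Synthetic data

The generator emulates what the processing chain assumes about
GC/TOFMS cohorts: k components with sparse non-negative unit-norm
spectra on nominal (unit-mass) m/z channels; Gaussian elution peaks
(standard chromatographic approximation, analytically integrable) with
per-component widths drawn from a configured range and unit trapezoidal
area, so integrating an elution profile recovers the concentration
exactly; per-sample concentrations = base level × multiplicative class
fold-change × lognormal biological variability; spiked internal
standards at exactly constant concentration (effect size pinned to 1);
a global integer retention drift per sample; additive Gaussian noise
clipped at zero. The default pipeline scenario is 24 subjects × pre/post
(48 samples), 15 components with every third metabolite regulated
(fold changes 1.8 / 0.55, alternating), 3 standards, drift ≤ 3 scans,
and mild noise — sized so the whole screening workflow runs in seconds
while leaving every stage a non-trivial job. A `conc_seed` draws a new
cohort (fresh concentrations, drift, noise) from the same metabolome.

Not emulated: isotope patterns, derivatization artifacts, detector
saturation, mass-calibration error, tailing/fronting peak shapes,
within-run retention warping, heteroscedastic (intensity-dependent)
noise. Consequently, passing tests demonstrate the correctness and
calibration of the algorithms under the stated generative assumptions;
they do not certify performance on real serum data, where peak-shape
deviations and nonlinear drift are the main additional difficulties.

## Numerical and interface choices

- Scan period 0.5 s on the simulated axis; areas integrate over scan
  index (trapezoid, unit spacing), so a constant unit profile over w
  scans has area w − 1.
- Match factor: `round(999 · cos²)` on √intensity·m/z-weighted spectra;
  zero spectra score 0; symmetric and scale-invariant by construction.
  Table comparison pairs greedily by descending match factor (ties by
  retention proximity, then index) under the joint MF > 700 AND
  |ΔRT| ≤ 1 s constraint.
- All JSON artifacts are written with sorted keys; every stochastic step
  takes an explicit seed. Two runs with the same config are
  byte-identical, and a saved reference table + model replayed against
  the same raw data reproduce predictions bit for bit — the property a
  diagnostic deployment depends on.
- ANDI-style netCDF is read/written through `scipy.io.netcdf_file`
  (NetCDF3 classic, centroided point lists). mzML is read by a compact
  lxml-based MS1 reader (base64, optional zlib, 32/64-bit floats)
  binned onto nominal m/z channels.

## Known limitations

- Alignment is a rigid global shift; gradient drift within a run is out
  of scope (hook left for warping).
- The per-window component count is a heuristic; heavily overlapped
  components with near-collinear spectra (cosine ≳ 0.9) can merge.
- OPLS-DA is strictly two-class, single-response.
- Compound identification against spectral libraries is out of scope;
  the match factor arithmetic is provided, library lookup is not.
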