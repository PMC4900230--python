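# Methods

## Spectral model

A baseline-corrected first-order Raman spectrum of carbonaceous matter is
modelled as the sum of five bands: G (graphite, ~1580 cm⁻¹), D1 (~1350),
D2 (~1620), D3 (~1500), D4 (~1200). Shapes follow the convention for
poorly ordered CM — Lorentzian everywhere except a Gaussian D3 — and are
configurable per band. Both shapes are parameterised by (center, height,
FWHM) so that the value at the center is exactly the height and the value
at center ± FWHM/2 is exactly half of it; the test suite asserts this
identity to 1e-9 relative.

Assumptions: the first-order window [1000, 1800] cm⁻¹ contains the whole
band system; the baseline is locally linear across that window; intensities
are additive (no absorption/self-absorption corrections); 514.5 or 532 nm
excitation (height ratios are excitation-dependent, so other lasers are
refused unless explicitly overridden).

## Baseline

The convention adopted here: a straight line through the median
(wavenumber, intensity) point of two anchor sub-windows, [1000, 1100] and
[1700, 1800] cm⁻¹, where the band system has decayed to its tails. Medians
make the anchors robust to noise; the operation is idempotent on noiseless
input. Band tails do reach the anchors: for a 60 cm⁻¹-wide D1 the induced
height distortion is ~0.8%, growing with band width — acceptable for a
screening parameter read to two figures.

## Fitting

Bounded nonlinear least squares (scipy `least_squares`, trf), ftol = xtol
= gtol = 1e-10, at most 5000 model evaluations; non-convergence is reported
in the result, never raised. Centers are confined to ±40 cm⁻¹ of their
canonical positions, widths to (5, 400) cm⁻¹, heights to [0, 3·max(I)].

Two deliberate departures from a naive five-free-band fit, both motivated
by identifiability:

* **D2 is a narrow shoulder.** With a generic ±40 cm⁻¹ box, the D2 center
  range reaches 1580 cm⁻¹ and the optimizer can park D2 on top of G,
  swapping the roles of the two bands and making R1 arbitrary (observed:
  R1 = 22 on a spectrum whose true ratio was 2.1). D2 is therefore held to
  1620 ± 20 cm⁻¹ and FWHM ≤ 100 cm⁻¹; both caps are config overrides.
* **Minor-band ridge.** The G/D2 (and D1/D3/D4) decomposition is exactly
  degenerate whenever a minor band can shadow a major one with identical
  shape. A ridge term `0.01 × height` per minor band (D2–D4) is appended
  to the residual vector, selecting the minimal-minor-band solution in
  degenerate directions while shifting well-posed height estimates by only
  O(10⁻⁴) relative.

**D1 pinning.** The screening protocol fixes the D1 height to that of the
observed D envelope rather than fitting it. Implemented self-consistently:
at every model evaluation the D1 height is set to the value that makes the
five-band total at the observed D-peak position equal the observed
(baseline-corrected) peak intensity, clipped at zero. With this rule the
generating parameters of a noiseless synthetic are an exact solution, and
recovery is exact wherever the D-envelope maximum is dominated by D1; at
the immature extreme (FWHM-D1 ≳ 280 cm⁻¹, R1 ≈ 0.4) the heavily overlapped
envelope still biases the pinned fit by up to ~15%. The naive alternative —
pinning D1 to the raw window maximum including all overlapping tails —
was tried and rejected: it overconstrains D1, deflates G and biased R1 by
up to 2.5× at the immature end. `pin_d1=False` gives the fully free fit,
which recovers noiseless synthetics essentially exactly and is the variant
used for accuracy benchmarking.

Initial guesses: canonical centers; G and D1 heights from the observed
window maxima (ties broken low for D, high for G, for determinism); D2 at
10% of G, D3/D4 at 10% of D1; width seeds (G 70, D1 150, D2 50, D3 150,
D4 100) cm⁻¹. The fitted residual RMS never exceeds the initial-guess RMS.

## Graphical estimation

R1 = (curve maximum in [1300, 1400]) / (curve maximum in [1560, 1640]),
after optional Savitzky–Golay smoothing (default window 11, order 3, which
perturbs noiseless peak heights by < 0.5%; window 1 disables smoothing).
The G window deliberately extends to 1640 cm⁻¹ so that an unresolved G+D2
envelope is read as "the G band" — that is what a human reads off a plot,
and it reproduces the documented R1-underestimation bias. FWHM-D1 is the
width of the D envelope at half its height, by linear interpolation
between grid points; the right half-width search stops at the D/G valley,
and when the curve never falls to half height before the valley the left
half-width is mirrored and the result flagged `overlap_capped`. Whether
published graphical widths were read off raw or smoothed curves is
unknowable; smoothing is configurable and defaults conservative.

## Continuum screen

Stage partition by R1 alone: stage 1 < 0.9 ≤ stage 2 < 2.5 ≤ altered. The
0.9 boundary is the midpoint of the reported 0.8–1 onset range and is
config, not constant. The carbonization box is R1 ∈ [0.4, 2.5] ×
FWHM-D1 ∈ [50, 300] cm⁻¹ — the upper R1 edge matches the altered cut so
the high-R1 end of the continuum (e.g. R1 = 2.17) stays on it. The
graphitization-suspect corner (FWHM-D1 ≤ 60 cm⁻¹ AND R1 ≤ 0.7) is an
operational reading of where partially graphitized samples fall off the
continuum; it is a default, not a published criterion. Candidates for
best-preserved Archean CM: Archean, R1 ∈ [0.72, 1], not a graphitization
suspect. R1 ≥ 1 attaches a fixed annotation citing the ~300 °C association
from the Lahfid et al. RSCM calibration; no temperature is computed, and
none of this bears on biogenicity.

## Companion indices

* Atomic H/C = (h_wt/m_H)/(c_wt/m_C); IUPAC masses (1.008, 12.011) by
  default, integer masses selectable because some published tables round
  consistently only with 1/12. Recomputation matches all 17 bundled
  reference rows within ±0.02; no single mass/rounding convention
  reproduces every row exactly at two decimals.
* NMR aromaticity = 100 × aromatic area / total area, trapezoidal, split
  at 90 ppm (aromatic [90, 240], aliphatic [−10, 90]); invariant under
  intensity scaling and stable (< 0.1%) under grid refinement. Spinning
  side bands are not excluded automatically — exclusion windows are a
  user-supplied argument, since side-band positions depend on the spinning
  rate.
* HRTEM La: difference-of-Gaussians bandpass (σ = 1, 6 px) → percentile
  threshold (92nd) → morphological thinning → pruning of fragments < 5 px;
  skeleton branch points are removed so each arm counts as a separate
  layer; path length is the sum of inter-pixel steps (1 or √2 px) × scale;
  fringes < 2 Å (≈ one aromatic ring) are discarded; La is the
  number-weighted mean (the length-weighted alternative is not computed).
  This is a simplified stand-in for the classical fringe-imaging chain:
  no d002/stacking analysis, no tortuosity, no molecular-orientation
  domains.

## Synthetic generators

All generators are pure functions of (parameters, seed).

* **Maturity series**: one index m ∈ [0, 1] moves the truth along the
  carbonization trend — R1 0.4 → 2.2, FWHM-D1 280 → 55 cm⁻¹, FWHM-G
  100 → 55 cm⁻¹, D2/D3/D4 heights 25% → 5% of G (height 1), centers fixed
  at canonical positions, minor widths fixed (D2 50, D3 150, D4 100).
  Endpoints bracket the observed natural ranges. Noise is additive
  Gaussian, default sd 2% of the D1 height; baseline optional linear.
  What it does **not** emulate: fluorescence curvature, cosmic rays, shot
  noise, center drift with maturity, multi-phase mixtures — so passing
  recovery tests show correctness of the estimator on the stated model,
  not robustness to every instrumental artifact.
* **NMR**: two Gaussian envelopes at 30 and 130 ppm (σ 12 ppm, so < 0.1%
  of either area leaks across the 90 ppm split) with areas in the
  requested ratio, plus noise.
* **Fringe images**: dark, slightly curved strokes with orientations
  scattered around horizontal (locally parallel layers), lengths from a
  shifted exponential (floor 2 Å) with the requested population mean, on a
  bright noisy field; the default 768 px canvas at 0.2 Å/px matches a
  ~15 nm field of view. Truth polylines and lengths are returned for
  end-to-end checks. Fringe crossings split skeleton arms and bias La
  slightly downward at high densities.

## Problem sizes and numerical defaults

The graphical-vs-decomposition validation uses 50 synthetic spectra
(801-point grid, 2% noise), the recovery property 30 spectra, and the
fringe end-to-end check 200 fringes on a 768² canvas — sizes at which the
statistics of interest (R², median relative errors, population means) are
stable while a full run of suite plus acceptance script stays well under a
minute. Optimizer tolerances 1e-10, evaluation cap 5000, smoothing window
11, threshold defaults as above; every default is carried in the config
objects and echoed (with a config hash) into pipeline outputs.

## Known limitations

* R1 comparability across excitation wavelengths is only asserted for
  514.5/532 nm; other lasers require an explicit override and user care.
* The decomposition's G/D2 separation is weakly identified even with the
  shoulder constraints; R1 from single noisy spectra carries ~10% spread
  at the broad-band (immature) end. Replicate averaging
  (`replicate_params`) is the intended remedy, mirroring per-sample spot
  replication.
* The graphical FWHM-D1 is ill-defined once D and G merge (flag
  `overlap_capped`); treat flagged values as plot-reading approximations.
* Whether replicate "±" spreads are standard deviations or standard errors
  in published tables is ambiguous; sample standard deviation is used.
* Mentions of a sixth band (D5) exist in parts of the protocol literature;
  the five-band reading (D1–D4, G) is implemented and D5 is not.
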