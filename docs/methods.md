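# Methods

## The DPV forward model

Differential-pulse voltammetry steps the electrode potential along a
staircase (increment 5 mV, period 5 s by default) with a superimposed pulse
(amplitude ΔE = 50 mV, width 300 ms, current sampled in the last 10 ms of
the pulse) and reports the current difference across each pulse.  For a
reversible couple whose surface population equilibrates with the electrode
potential between pulses, the differential current is the difference of two
Nernstian occupancies,

    δi(E) ∝ f(E + ΔE) − f(E),    f(u) = 1 / (1 + exp(nF(u − E⁰′)/RT)),

a non-negative, single-peaked, symmetric response with

* peak potential `E_p = E⁰′ − s·ΔE/2` (s = +1 anodic, −1 cathodic),
* full width at half maximum decreasing in n and increasing in ΔE, with the
  small-amplitude limit `2(RT/nF)·ln(3 + 2√2)` — 90.6/n mV at 25 °C.

The same sigmoid-difference family is used for surface-confined and
solution couples.  It is exact for the reversible adsorbed case; for the
diffusive case it reproduces peak position, width and height systematics,
which is all the downstream analyses consume.  Full staircase time-domain
simulation, double-layer transients and Butler–Volmer kinetics are out of
scope.  Implied assumptions: reversibility (no kinetic peak separation) and
full relaxation within the 5 s pulse period.

Defaults: T = 303.15 K (the 30 °C reactor temperature, not 25 °C), anodic
scan (the cells oxidize lactate; the electrode is the terminal acceptor),
potentials stored in volts vs SHE internally (mV only at I/O), and the
Ag/AgCl (sat. KCl) → SHE offset fixed at +0.199 V but configurable — round
numbers in common use imply 0.200 V, so fixtures are defined directly on
the SHE scale to avoid compounding the rounding.

## Baseline estimation

The capacitive charging current is modelled as a cubic polynomial plus an
optional exponential tail anchored at the negative end of the scan (onset
of an edge process; decay constrained to 20–100 mV so it cannot act as a
global trend).  The fit uses only potential windows "far from the peaks":
windows are supplied explicitly or chosen automatically as the complement
of the regions where the residual against a provisional edge polynomial
exceeds a noise-scaled threshold; the outermost samples are always kept.

A broad envelope (the multi-heme background, FWHM ≈ 250 mV over a 700 mV
scan) is nearly collinear with a cubic baseline when the baseline is
constrained only by the scan edges.  The full analysis therefore refines
the window fit by a peak-aware joint least-squares step: baseline and peak
parameters are fitted together over the whole scan, after which the final
deconvolution runs against the refined baseline.  On noise-free synthetic
data in the model class this recovers the generating baseline and peak
parameters to machine precision; the tests assert < 1% baseline error
across the peak region and < 2 mV / < 5 mV errors on E_p / ΔE_p/2.

## Deconvolution

The baseline-subtracted signal is decomposed into k components — Nernstian
sigmoid-difference peaks for flavins, a Gaussian for the heme envelope,
selectable per component — by weighted orthogonal distance regression
(ODRPACK via `scipy.odr`) with per-axis weights 1/x_sd² and 1/y_sd²:

* `x_sd` defaults to increment/√12 ≈ 1.44 mV, the quantization noise of the
  5 mV staircase;
* `y_sd` defaults to a robust MAD of the outer 10% of samples (floored at
  10⁻⁴ of the signal maximum so noise-free input stays finite).

The weights exist in the protocol but are not specified numerically
anywhere, hence these defaults.  In the x_sd → 0 limit the ODR solution
coincides with ordinary least squares (asserted to 10⁻⁴ relative); an OLS
mode is available directly.  Initialization comes from greedy peak
stripping: the strongest smoothed local maximum seeds a Nernstian
component, its crude guess is subtracted, and detection repeats — this
finds shoulder peaks (e.g. residual free flavin next to the bound-cofactor
peak) that prominence-based detection alone misses.  The heme envelope
initializes at the maximum of whatever smooth structure remains.
Convergence follows ODRPACK's sum-of-squares/parameter criteria with a
200-iteration cap; non-convergence raises a diagnostic error carrying the
last iterate.  Reported per component: E_p, FWHM, height, a charge proxy
(component area over the potential axis divided by the staircase scan rate
— a proxy, since DPV peak intensity is not strictly quantitative), and the
apparent n obtained by inverting the theoretical width.

## Electron counting

An observed half-width is assigned the candidate n (default {1, 2}) whose
theoretical width is nearest, with one convention: widths above the
smallest-candidate theoretical width still call that smallest n, because
broadening in protein films reflects site dispersion, never a fractional
electron count.  At ΔE = 50 mV and 303 K this maps 60 mV → n = 2 (ideal
two-electron, theory 62.2 mV) and 130 or 150 mV → n = 1 (broadened beyond
the 100.5 mV ideal).  A fixed 90 mV threshold would make the same calls
but would misclassify near-ideal two-electron widths at other amplitudes;
the nearest-width rule does not.  Calls whose two best distances differ by
less than 5 mV are flagged ambiguous.  No quantitative dispersion model is
fitted to the super-theoretical broadening.

## Binding analysis

Langmuir occupancy θ = C/(C + K_d).  Two K_d estimators over a
peak-current titration i(C):

* `fit_langmuir` — nonlinear least squares on i = i_max·C/(C + K_d) with
  Jacobian standard errors; the statistically sound route.
* `kd_from_half_saturation` — treats the top-concentration current as
  saturated and interpolates C at half of it.  This mirrors the
  back-of-envelope arithmetic habitually applied to titrations topping out
  around 50 µM.  When the top concentration does not truly saturate
  (θ(52 µM) = 0.84 at K_d = 10 µM) the estimate is biased **low** — on the
  default synthetic titration it returns ≈ 7.5–8 µM against a true
  10 µM.  Both estimators are exposed so the bias is visible rather than
  hidden; the tests assert its direction.

The cytochrome site-concentration estimate assumes a monolayer biofilm on
the 3.14 cm² electrode in 5 mL of electrolyte, 10–30% cytochrome surface
coverage (default 0.2), a 2 µm² cell footprint and a 50 nm² protein
footprint.  The footprints are invented geometric defaults (flagged as
such); the conclusion is an order of magnitude — a few tenths of a
nanomolar — not a point value.

## Enhancement factors

EF = (i(t₀ + 1000 s) − i_bg) / (ī_pre − i_bg), where ī_pre averages the
60 s before the addition (the protocol says "immediately before", which is
operationalized as a short pre-event mean; the post-event sample is a point
reading at exactly +1000 s by linear interpolation) and i_bg is the
matched no-lactate background at the same potential (0 with a logged
warning when absent).  EF is a ratio of background-subtracted currents and
is therefore invariant to unit rescaling and to constant offsets applied to
both trace and background — both asserted as properties.  Panels group EF
over electrode potential or pH into mean ± standard error of the mean.

## Synthetic data

The generator emulates the study conditions, not microbial physiology:

* **Voltammograms** — potential grid −0.45 … +0.25 V vs SHE at the 5 mV
  increment; fixed baseline (cubic + exponential tail); fixture peaks:
  free FMN/RF at −260 mV with the ideal n = 2 width, bound FMN (wild type)
  at −145 mV / 130 mV, bound RF (wild type) at −110 mV / 130 mV, bound RF
  (ΔmtrC) at −102 mV / 150 mV, plus a Gaussian heme envelope (center
  −50 mV, FWHM 250 mV, invented and flagged).  Bound-peak widths
  parameterize the shape directly (apparent n < 1) since observed widths
  exceed the ideal; the bound-RF width is only constrained to "more than
  double" the free width, so its 130 mV default is a choice.  Peak heights
  are invented except where a measurement pins them.  Default noise: 0.5%
  of the maximum peak height.
* **Titrations** — bound-peak height follows i_max·C/(C + K_d) with
  K_d = 10 µM; i_max = 8.35 µA cm⁻² places the 52 µM point at the measured
  7 µA cm⁻²; the free-flavin peak grows linearly (unsaturated); default
  concentrations 0.5–52 µM (8 points), 5% relative noise on peak currents
  in the series form.
* **Current traces** — logistic growth (midpoint 15 h, time constant
  2.5 h) to strain/flavin plateaus: 15 µA cm⁻² for wild type with either
  flavin (measured), 10× ratios between ΔomcA ± FMN and ΔmtrC ± RF
  (measured as ratios), sub-0.1 µA cm⁻² lag currents, a 0.02 µA cm⁻²
  no-lactate background, and an invented potential scaling.  A flavin
  addition multiplies the background-subtracted current by the target EF
  through a first-order rise (τ = 200 s, invented — chosen so the 1000 s
  sampling rule is genuinely exercised: the measured EF is ~0.7% below the
  injected target).  EF targets: 15 (FMN) and 3 (RF) at −0.2 V/pH 7.8 are
  measured values; all other potential/pH entries are invented defaults
  flagged `figure_derived_invented`, constrained to the measured shapes
  (EF increasing toward negative potentials; FMN EF non-decreasing with
  pH; RF EF minimum at pH 7, maximum at pH 6).

What the generator does **not** emulate: flavin secretion and transport
kinetics, growth variability between replicates, drifting baselines,
electrode fouling, Ohmic drop, or correlated instrument noise.  Passing
tests therefore demonstrate the correctness of the analysis chain on data
obeying its own model assumptions, and its noise robustness at realistic
amplitudes — not robustness to every artifact of real electrochemistry.

## Numerical choices

* Half-widths are solved by bisection on the closed-form shape to 10⁻¹² V;
  the width → scale and width → apparent-n inversions likewise.
* Reference values frozen in tests come from an independent numeric oracle
  (half-maximum crossings located on a dense grid by linear interpolation).
* Peak candidates are ordered by prominence with ties broken toward more
  negative potential; detection requires ≥ 20 samples.
* The joint baseline refinement runs Levenberg–Marquardt to 10⁻¹⁴
  tolerances; the exponential decay is optimized in log space.
* Degenerate inputs raise typed exceptions (empty grids, non-monotone
  potentials, under-determined windows, series that never cross half
  maximum, traces shorter than the 1000 s protocol).

## Problem sizes

Default scan: 141 points.  Monte-Carlo binding studies use 100 replicates
at 5/8/12 concentrations; the noisy-recovery study uses 50 seeds at 0.5%
noise; traces use a 20 s step over 40 h (7201 points).  These sizes keep
the full suite around ten seconds while leaving the Monte-Carlo medians
stable.

## Known limitations

* No model selection for the component count k; it is fixed by the caller
  (or the fixture's structural hint), matching practice where the count is
  chosen by inspection.
* The apparent-n report quantifies broadening but no dispersion model
  (kinetic or thermodynamic heterogeneity) is fitted.
* The half-saturation K_d estimator inherits the saturation approximation's
  low bias by design (see above).
* The exponential baseline term is anchored at the negative scan edge; a
  scan with onset processes at both edges would need a second term.
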