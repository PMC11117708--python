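# Methods

This note records the models, defaults and numerical conventions behind
mersense, and what the synthetic-data generator does and does not emulate.

## Kinetic quantities

All derived kinetics are **forward difference quotients** on the
instrument's sampling grid, never central differences or spline
derivatives.  This is deliberate: the generator writes fluorescence as
`Fluo(t+dt) = Fluo(t) + f * OD(t) * dt`, so the analyzer's difference
quotient divided by `OD(t)` inverts the generative rule exactly on the
same grid — noiseless simulations round-trip to machine precision, which
pins down sign/indexing errors that smooth estimators would hide.

Blank correction subtracts the time-matched mean of all blank wells from
both channels.  Normalized fluorescence is `(Fluo_s - Fluo_b)/(OD_s -
OD_b)`; points where the blank-corrected OD is below `od_floor = 0.005`
(below plausible instrument resolution) are masked as NaN rather than
producing huge ratios.  A run where every point is masked is an error:
the culture is indistinguishable from the blank.

Optional pre-smoothing of the fluorescence series (centered moving
average, default window 3 in the pipeline, off in the low-level function)
tames the spikiness of 15-min difference quotients on noisy plates.  The
endpoints are left unsmoothed, so locally linear series pass through
unchanged.

Growth phases are called from the specific growth rate
`mu(t) = d ln(OD)/dt`: the exponential phase is the contiguous run around
the maximum of mu where `mu >= threshold_frac * max(mu)` (default 0.5),
lag is before it, stationary after.  Manual phase calls by eye are common
in practice; the threshold rule is a determinization and both the
threshold and the window are user-overridable.  A never-growing culture
(max mu <= 0) is labelled entirely stationary.  **Fmax** is the maximum of
the normalized activity restricted to exponential-phase points, ties to
the earliest time; the OD in the denominator is the left-endpoint OD,
matching the difference-quotient convention.

## Colorimetry

The colour score is the Euclidean distance in RGB space between the
pellet's channel means (real-valued, no integer truncation) and a
reference pellet, over a 3×3-pixel region ("nine pixels").  The original
region selection was manual; the automatic rule thresholds the image
against the near-white background (foreground = channel mean below 0.9 ×
the background mode), takes the largest connected component, and centers
the region on its centroid.  Measurements record whether the region was
chosen automatically.  A reference may be supplied as a numeric triple or
measured from a reference image; the simulator supplies (255, 255, 255)
numerically because a pure-white reference pellet on a white background is
undetectable by the thresholding rule.

## Calibration

The Hill fit minimizes unweighted squared residuals of
`psi_min + psi_max * I^h / (I^h + K^h)` with all four parameters
constrained positive, initialized at `psi_min = min(S)`,
`psi_max = span(S)`, `K =` the dose whose signal is nearest the
mid-response, and a multistart over `h0 in {1, 0.5, 2}` keeping the best
residual sum.  It requires at least four non-excluded points spanning two
decades of dose.  Flat responses converge to `psi_max ≈ 0` and are
flagged degenerate rather than rejected.  Excluded points (e.g. a top
dose above the growth-toxicity threshold) are carried but never enter any
objective.

The log-log calibration is OLS of `ln S` on `ln I` (natural logs
throughout).  `sigma0` is the residual SD with the n−2 regression
denominator; the denominator is configurable because conventions differ.
Automatic linear-range selection scans contiguous dose windows of at
least four points, keeps those with R² ≥ 0.98, and picks the widest in
log-dose span (ties: higher R², then lower doses).  The published ranges
for such assays are typically chosen by eye; this rule is the package's
determinization and `range_override` is first-class.

The LOD is `exp(3.3 * sigma0 / m)`, the 3.3-sigma convention applied
literally on the log scale (the 3.3·σ/slope rule references the slope of
the *log-log line*, the only fitted quantity with a slope).  It requires
an increasing calibration (m > 0), grows with sigma0 and shrinks with m,
and equals 1 nM exactly for a zero-residual fit — a formula artifact
worth knowing when interpreting very clean calibrations.

The Hill and log-log fits are **independent views of the same dose
table**; no constraint ties them.  They are genuinely inconsistent in one
regime: a large Hill baseline (`psi_min`) puts a floor under the signal
that a pure power law cannot follow at low doses.  Fitted parameter sets
from the two views should therefore not be cross-substituted; inverse
prediction always uses the log-log line.  We fit raw signals and do not
baseline-subtract before the log transform, since subtraction conventions
are rarely reported and silently subtracting would change the slope.

## Quantification

`I_culture = exp((ln S - y0)/m)`, multiplied by the sample's dilution
factor (preparing environmental samples 1:1 with double-strength medium
gives factor 2, which doubles both estimates and detection bounds).
Censoring compares the *culture-level* estimate to the calibration LOD,
then reports the bound scaled by dilution: `< LOD × dilution`.  The
boundary is inclusive (a sample exactly at the LOD is an estimate), with
a 1e-9 relative epsilon absorbing the float round-trip of the log
inversion.  Estimates above the calibrated range are reported with an
`extrapolated` flag rather than refused.  Replicates are inverted
individually and summarized (mean decides censoring; SD, scaled by
dilution, is the reporting uncertainty).

## Synthetic-data generator

Defaults mirror the characterization conditions of the real assays:
initial OD600 0.05, sampling every 0.25 h for 16 h, triplicate wells,
additive OD noise (SD 0.002), 5% multiplicative fluorescence noise, and
the fitted Hill parameter sets of the two biosensor variants
(fluorescent: psi_min 150, psi_max 6000, K 305 nM, h 1.6; colorimetric:
0.9088, 161.74, 23.67 nM, 0.6986).  Growth is logistic with a lag
(defaults: lag 1 h, mu_max 0.7 h⁻¹, capacity 1.0 OD — an ordinary
glucose/cas-amino-acid minimal-medium profile), stepped as
`OD * exp(mu * dt)`.  The log-space step is used instead of a plain Euler
increment because it is exact in the uncrowded limit (a 2 h window at
mu = 0.7 multiplies OD by e^1.4 on the grid, not by the ~10%-low Euler
approximation) while still sharing the analyzer's grid.  Doses at or
above 2000 nM scale mu_max down by 30%, emulating mercury toxicity at
the top dose.

Reporter accumulation integrates the Hill-predicted per-density rate
against OD (baseline rate before the induction time), so promoter
activity is growth-phase-coupled at the culture level while the
per-density rate is constant — adequate for dose-response work, but it
does **not** emulate the transient induction dynamics real cultures show
(slow lag-phase activation, reporter maturation delay, the unexplained
early burst of signal, or activity decay into stationary phase).  Pellet
tiles are flat-colour discs on a white background whose deviation from
white grows with the Hill-predicted reporter level, weighted toward the
red/green channels so saturation reads as blue; they exercise the
region-selection and scoring geometry, not photography (no illumination
gradients, white-balance drift, or pellet texture).  Passing tests
therefore certify the inferential machinery under the stated noise model,
not robustness to instrument- or camera-specific artifacts.

All randomness flows from one integer seed; fixed seeds regenerate
byte-identical CSVs and PNGs.

## Problem sizes

Simulation-and-refit checks use 20 seeded replicates of the full dose
designs (8 or 7 doses × 3 wells), plates of ~30 wells × 65 time points,
and 40 seeds for the censoring-rate property; the whole suite runs in a
few seconds on one core.  Under the 5%-noise triplicate protocol the
20-seed median of the colorimetric Hill constant has a sampling spread of
roughly ±8%, so isolated seed choices can land a median near the edge of
a ±10% recovery band — a property of the protocol's size, not of the
estimator.

## Known limitations

* Inverse prediction ignores calibration-parameter uncertainty; the
  reported SD reflects replicate scatter only (no bootstrap/Bayesian
  intervals).
* Phase classification assumes a single growth episode; diauxic or
  biphasic curves will confuse the contiguous-run rule.
* The colorimetric channel weighting is a rendering convention, not a
  spectral model of the chromoprotein.
* Fluorescence-channel cross-talk, evaporation drift and edge-well
  effects are not modelled.
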