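# Methods

## The problem

A pair of positional isomers with the same protonated molecule (here the
ester pair ELF94/ELF96, [M+H]+ at 604 Th) cannot be separated on a short,
fast HPLC gradient, and their MS/MS spectra share every product ion.
What differs between them is the *yield* of each product-ion channel.
`ledams` implements the full recognition-and-quantitation workflow for
such pairs on an ion-trap instrument: characterising the collision-
induced dissociation (CID) energetics, deconvolving the unresolved
signal into per-isomer contributions, converting those contributions to
concentrations against an internal standard, and fitting first-order
plasma-degradation kinetics.

## CID energetics (module `erms`)

In an ion trap, activation is controlled by the excitation amplitude
(ExA, arbitrary units 0–50) applied for an excitation time (ExT, ms).
An energy-resolved (ERMS) ramp steps ExA at fixed ExT and records the
precursor and product abundances.  Three curves are derived per ramp:

* **SY** (survival yield) `= 100·prec/(prec + Σprod)` — precursor decay;
* **PiF** (product formation) `= 100·Σprod/(prec + Σprod)` — its exact
  complement, so SY + PiF = 100 at every defined point;
* **PiY** (product yield) `= 100·Σprod/precursor_ion_max` — the true CID
  efficiency.  `precursor_ion_max` is the mean precursor abundance over
  the pre-activation steps (those with PiF under a configurable 1%
  threshold; if none qualify the lowest-amplitude step is used with a
  warning).  Because its denominator is fixed, PiY — unlike PiF — is
  depressed by precursor ejection and low-mass cut-off losses, which is
  exactly what makes it informative.

Summary descriptors: `SY_ExA50`, the amplitude at 50% survival, read off
by linear interpolation between the bracketing grid points (the curve is
only known on the instrument's amplitude grid; an interpolation choice
is unavoidable, and linear is the least committal); and
(`PiY_max`, `ExA_max`), the PiY maximum and its grid amplitude, with
ties resolved to the lowest amplitude (minimal energy for maximal
yield).  Steps with zero total signal are undefined and are dropped from
the curves rather than imputed.

## LEDA deconvolution (module `leda`)

Every retained product ion Pi is expressed relative to a reference ion
Ri that behaves identically for both isomers — the unfragmented
precursor, re-isolated in a dedicated low-amplitude MS/MS event.  For a
mixture, each measured ratio is a linear combination of the pure-isomer
characteristic ratios:

    (Pi/Ri)_measured = Σ_x (Pi/Ri)_x · f_x

One equation per ion gives an overdetermined linear system (six ions for
the bundled two-isomer table; ions enter iff their relative abundance
reaches 5% of the base peak in at least one pure spectrum).  Design
choices:

* **Solver.** Non-negative least squares by default: percentages below
  zero are unphysical.  An unconstrained mode is kept for plain
  linear-regression semantics; the two coincide whenever the
  unconstrained optimum is already non-negative.
* **No sum-to-one constraint.** Forcing Σf = 1 would silently absorb any
  unknown co-eluting contributor; instead the raw fractions and the
  residual sum of squares are reported, and Σf ≠ 1 is itself diagnostic.
* **Renormalisation on assignment only.** When the Ri signal (a peak
  area or an interpolated scan abundance) is distributed between the
  isomers, fractions are renormalised by Σf so the assignment conserves
  the Ri signal exactly.
* **Scan pairing.** Ri and Pis events alternate and are never recorded
  simultaneously; the Ri abundance at a Pis scan time is taken by linear
  interpolation between the neighbouring Ri scans.  Scans with
  non-positive interpolated Ri, or with all fractions zero, are flagged
  undefined and leave gaps, never fabricated values.
* **Brute-force oracle.** `brute_force_mixture` minimises the same
  residual over an exhaustive fraction grid (step 0.005, range 0–1.2,
  ≤3 isomers).  It exists purely as an independent cross-check of the
  least-squares path.

Error propagation under the observed per-ratio scatter (SD 0.01, the
replicate SD of the bundled table) follows the standard OLS covariance
σ²(MᵀM)⁻¹: a single measurement of a 50/50 mixture carries a fraction SD
of ≈0.030 for this matrix, and the mean of the six replicate analyses
performed per mixture carries ≈0.012 — which is what the validation
plots below resolve.

## Quantitation and validation (module `quant`)

Peak areas are trapezoidal.  The response is the peak-area ratio (PAR)
of the analyte quantitation ion to the internal standard; calibration is
unweighted OLS over the five-level design (5–100 ng/mL).  LOD and LOQ
use the response-SE-and-slope approach with the conventional 3.3 and 10
multipliers, taking the standard error of the y-intercept as the
response SE, so LOQ/LOD = 10/3.3 identically whenever defined.
Back-calculated concentrations below zero are clipped to zero with a
warning.

The deconvolution itself is validated by regressing estimated on
expected composition across the five standard mixtures
(90/10, 75/25, 50/50, 25/75, 10/90).  Each mixture is analysed six
times and its estimate is the mean deconvolved fraction over the
replicates; the regression is on the fraction scale (0–1), where the
slope measures accuracy and SE-Lin — the residual standard error
√(SSR/(n−2)) — measures precision, ±2·SE-Lin being an approximate 95%
band on the assigned purity ratio.

## Degradation kinetics (module `kinetics`)

At substrate concentrations far below the esterases' Michaelis
constant, hydrolysis is first order: ln C is linear in incubation time.
All replicates are pooled into one OLS fit with a free intercept (only
the slope carries kinetic meaning, and pooling propagates the replicate
scatter into the slope SE); k is the slope in ln(µM)/min and
t½ = ln(0.5)/k.  Reporting rules: |k| < 0.006 ln(µM)/min is not
resolvable over the 120-min incubation, and any computed half-life
beyond 120 min is equally outside the observed window — both report the
censored bound ">120".  A resolvable positive slope (growth) has no
half-life and is flagged invalid.  The half-life SD is delta-method:
|ln 0.5|·SD(k)/k².  A panel run includes a reference substrate whose
finite half-life (≤120 min) certifies that the plasma pool is
enzymatically active; a stable reference fails the check with a warning.

## Synthetic data (module `synthgen`)

All generators are pure functions of (parameters, seed) and emit their
ground truth alongside the data.

* **ERMS ramps.** Precursor survival is logistic in ExA (default
  midpoint 30 a.u., width 3 a.u. — a mid-ramp transition typical of a
  unit-resolution trap); fragmentation channels open at midpoint −
  2·width, below which the precursor sits at a flat plateau (default
  10⁶ counts) and no products form.  The flat pre-onset plateau is a
  deliberate idealisation: it gives an exact zero-PiF region so the
  `precursor_ion_max` estimator has an unambiguous truth, while the
  survival curve equals the generating logistic everywhere above the
  onset — the region containing SY_ExA50.  Of the precursor lost, an
  `ejection_loss_fraction` disappears undetected (modelling ejection and
  low-mass cut-off) and the rest is split by per-channel branching
  fractions.  Detector noise is multiplicative lognormal (median 1).
* **Ratio vectors.** M·f plus additive Gaussian noise of SD 0.01 per
  ion (the replicate SD observed on the characteristic table), truncated
  at zero.
* **Chromatograms.** Gaussian envelopes (σ = 0.2 min); the internal
  standard elutes in segment 1 ([0, 3.28) min), the isomers co-elute at
  an identical retention time in segment 2 ([3.28, 10) min) — the worst
  case for recognition, with partial resolution available by override.
  Events fire every 0.3 s, Ri and Pis alternating in segment 2, giving
  well over 15 points across a peak despite the trap's slow MS/MS duty
  cycle.
* **Calibration and stability.** Proportional PAR responses with CV
  noise at the 5–100 ng/mL levels; first-order decay panels at 1 µM with
  triplicates at 0/30/60/120 min and 5% CV lognormal noise whose
  multiplier has median 1, so the log-scale regression is unbiased.

What the generators do *not* emulate: isotope patterns, peak tailing,
matrix interferences, correlated inter-channel noise, and drift.
Passing tests therefore demonstrate the correctness of the algorithms
under the stated noise models, not robustness to every artefact of real
plasma data.

## Numerical choices and degenerate inputs

* m/z values match within ±0.5 Th (unit-resolution trap).
* Time segments are half-open `[start, end)`, removing the boundary
  ambiguity of printed segment tables.
* A rank-deficient ratio matrix (isomers with proportional columns)
  raises a degenerate-system error naming the indistinguishable pair —
  no solution is attempted.
* CSV round trips preserve values to better than 1e-9 relative; ions
  absent from an event are written as empty fields so genuine zeros
  survive.
* Fractions are kept on the 0–1 scale internally and reported as
  percent at the interfaces.

## Problem sizes

The bundled study conditions are deliberately desk-scale: six-equation
systems, 51-step ramps, ~1300-scan chromatograms, 200-repeat Monte-Carlo
loops for rate-constant recovery and the validation study.  The full
test suite and the acceptance script each complete in seconds.

## Known limitations

* The scan-by-scan mode assumes the Ri trace is smooth enough for linear
  interpolation between alternating events; very narrow peaks sampled
  near the event period would bias the split.
* The brute-force oracle is limited to three isomers (grid explosion).
* LOD/LOQ from the intercept SE inherit the usual caveat that they are
  calibration-design-dependent, not blank-measured.
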