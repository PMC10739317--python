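# Methods

## Model

All responses are percentages of the reference-agonist span. The reference
curve (17β-estradiol, E2) defines the lower asymptote `y0` and maximum `m`
of a plate; after normalisation `y0 ≈ 0` and `m ≈ 100`. Each ligand is
described by three parameters: efficacy `a` (fraction of the E2 span it can
reach: 0 pure antagonist, 1 full agonist, >1 supra-agonist), potency `c`
(EC50, molar) and Hill slope `n` (an apparent sensitivity coefficient — in
a reporter assay it folds together binding cooperativity and everything
downstream of it, so it is not interpreted mechanistically).

The generic response addition (GRA) model follows from mass-action
occupancy of a single receptor by several ligands:

    y = y0 + (m − y0) · Σᵢ aᵢ (xᵢ/cᵢ)^nᵢ / (1 + Σᵢ (xᵢ/cᵢ)^nᵢ)

The apparent dissociation constant is `Kᵢ = cᵢ^nᵢ` and is never stored
separately; `(c, n)` is the canonical parameterisation. The denominator
keeps per-ligand exponents — no shared-slope approximation is imposed on
the cross terms. A pure antagonist (`a = 0`) appears only in the
denominator; the model therefore reproduces reversible competitive
antagonism, including the `c_ag(1 + x_ant/c_ant)` apparent-EC50 shift and
the `c_ant(1 + x_ag/c_ag)` IC50 closed form for unit slopes (both verified
against the numerical solvers in the test suite).

Concentration addition (CA) is implemented through effective
concentrations: `ECX_mix = (Σ fᵢ/ECXᵢ)⁻¹` with molar fractions `fᵢ`.
Fractions are molar fractions of the total molar concentration, because the
occupancy equations operate on molar ligand concentrations. Dosed
concentration is treated as free concentration (no depletion correction),
the standard assumption for transactivation assays. Effect levels `X` are
always relative to the E2 span, not to a compound's own maximum.

## Numerical choices

- **CA curve construction.** The CA response at a total concentration `T`
  is obtained by root-finding on the effect level: the toxic-unit equation
  `Σ fᵢT/ECXᵢ(X) (+ x_ref/ECX_ref(X) for co-exposure) = 1` is solved by
  Brent's method, exact to solver tolerance (`xtol 1e-12`). This was
  preferred over tabulating an effect grid and interpolating, which cannot
  guarantee the sub-1e-6 agreement with GRA required in the parallel
  special case. Levels above the smallest component efficacy are
  unreachable under CA; the curve is truncated there (NaN) and a warning is
  recorded in the curve metadata.
- **Root finding** (ECx inversions, apparent EC50, IC50) uses bracketed
  Brent iteration on log10 concentration, starting from ±6 decades around
  the relevant potency and expanding if needed; sigmoid monotonicity
  guarantees a unique root.
- **Saturation.** Occupancy terms are clipped at 1e300 so that fully
  saturated ratios converge to the efficacy-weighted limit instead of
  overflowing.

## Fitting

Parameters are estimated by unweighted least squares with a bounded
trust-region (damped least-squares) solver; potency is fitted as log10 c
for conditioning. Bounds: `a ∈ [0, 3]`, `n ∈ [0.1, 10]`, `c` within the
tested concentration range ± 2 decades — generous relative to the
plausible assay ranges (`a` 0.5–2, `n` 0.5–5) while preventing divergence.
Initialisation is data-driven (`a ← max response / span`, `c ←`
concentration nearest half-max, `n ← 1`) plus five deterministic log-spaced
perturbations of the initial potency; the start with the lowest SSres wins,
ties broken by the lower slope. Fits are therefore fully deterministic.

By default fits operate on the replicate means of each concentration, the
usual convention for plate dose-response work; `aggregate="none"` fits
every well. A constant-response input is flagged unidentifiable rather
than silently fitted. The E2 reference fit is a four-parameter logistic
with efficacy fixed at 1, returning `(y0, m)` for plate normalisation and
the E2 EC50 for QC dosing; `m` can be pinned at 100 for pre-normalised
plates.

Goodness of fit: `RMSE = sqrt(SSres/n_obs)` (denominator `n_obs`, not
`n_obs − p`, so RMSE reads as the average deviation) and
`RSQ = 1 − SSres/SStot` about the observed mean, reported as missing when
the observations have zero variance.

**Standard errors** use an HC3-type leverage-corrected sandwich covariance
at the optimum. Luminescence-derived responses carry CV-style
(signal-proportional) noise, and the homoscedastic `σ²(JᵀJ)⁻¹` covariance
materially understates the uncertainty of plateau-driven parameters under
such noise; the sandwich estimator restores nominal Wald coverage without
weighting the fit itself. Wald intervals use the t quantile with
`n_obs − p` degrees of freedom; the interval for `c` is formed on log10 c
and exponentiated.

QC: wells dosed at the E2 EC50 have an expected response of 50% of the
reference span; recovery must fall in 89–120% to pass. Activity
classification uses the 10%/20% limits of detection/quantification with
the thresholds themselves falling on the upper class (exactly 10% is
below-LoQ, exactly 20% is quantifiable).

## Monte-Carlo envelopes and the additivity verdict

Parameter uncertainty is specified per parameter as normal(mean, sd) —
typically `sd = SE` from a fit — or uniform(lo, hi) — typically ±10% for
nominal fixture parameters. Draws are truncated to the valid domain
(`a ≥ 0`, `c > 0`, `n > 0`) by rejection; a specification whose first pass
is more than half invalid is rejected as inconsistent. Default draw count
is 10,000 (pipeline default 2,000 for speed); quantiles (2.5/50/97.5%) are
computed by linear interpolation of the order statistics. Envelopes are
bit-reproducible for a fixed seed. The GRA envelope is fully vectorised;
the CA envelope inverts the effective-concentration relation on a 512-point
relative-effect grid per draw and interpolates in (log T → effect), which
agrees with the exact construction to ~0.005 % activity — quantile
estimation noise dominates at that scale. The co-exposure reference dose
and its parameters are held fixed during the Monte Carlo; only mixture
component parameters carry uncertainty.

The verdict interpolates the observed replicate means onto the envelope
grid (monotone cubic in log concentration) and flags each point
inside/above/below the band. The equivalence hypothesis is rejected only
when ≥ 2 consecutive points within the dynamic range (10–90% of the
envelope-median span) fall outside on the same side: above → synergy
candidate, below → antagonism candidate. Isolated single-point excursions
are reported but tolerated, which keeps the test's false-alarm rate near
nominal and mirrors how borderline left-edge observations are customarily
read. If both sides show qualifying runs the longer run decides, then the
larger excursion count (ties resolve to synergy). Model comparison reports
RMSE/RSQ of CA and GRA against the observed means over the doses where
both predictions are finite, the winner being the lower RMSE (differences
within 1e-9 relative are ties).

## Synthetic data generator

The generator emulates CALUX-style reporter plates: 8-point 1:10 serial
dilutions, triplicate wells, an E2 standard series defining the 0–100%
scale, triplicate QC wells at the E2 EC50, solvent blanks around baseline,
and 7% multiplicative Gaussian noise (sd = 7% of the true signal,
truncated at zero) — CV-type noise typical of luminescence readouts. An
additive-noise switch (constant sd as a fraction of the span) is provided.
Mixture plates are dosed on log grids centred on a harmonic-mean potency
surrogate spanning ±1.75 decades.

The compound fixture library ships synthetic Hill parameters for the 14
study compounds plus E2, frozen in code and labelled synthetic: they
respect the qualitative constraints reported for these substances
(daidzein/genistein supra-inductive near 180–200% efficacy, kaempferol a
60% partial agonist, phthalates/FCM chemicals weakly active, E2 potent in
the low picomolar range) but are placeholders, not measurements, because
the per-compound parameter tables were never deposited. Likewise the 12
fixed-ratio "food" mixtures (2–5 components, phytoestrogen-dominated) are
synthetic stand-ins for undeposited concentration ratios.

What passing tests show — and do not show. The generator reproduces the
statistical structure the analysis assumes (multiplicative noise,
triplicates, serial dilution, known ground truth), so the suite
demonstrates correctness of the mathematics, calibration of the intervals
and envelopes, and power of the verdict under those assumptions. It does
not capture cytotoxicity at high doses, plate-edge effects, solvent
effects, time-dependent induction or between-plate drift, so passing tests
do not certify behaviour of real plates exhibiting those artefacts.

## Problem sizes

The bundled acceptance study uses 100 seeded plates for the goodness-of-fit
summary, 200 curves for Wald-coverage calibration, 200 draws against a
20,000-draw envelope for coverage of the prediction band, and 1,000–10,000
Monte-Carlo draws per envelope elsewhere; these sizes give percentile
estimates stable to well within the tolerances asserted.

## Known limitations

- Single-receptor occupancy: no true independent-action model for
  dissimilar modes of action; GRA approximates the mixed CA/IA reading
  only through per-ligand parameters.
- No depletion, transport or toxicokinetic corrections; nominal = free.
- Unweighted fitting is retained for transparency; with strongly
  heteroscedastic data a variance-weighted fit would be more efficient
  (the sandwich SEs remain valid either way).
- The verdict is a screening rule, not a formal multiple-comparison
  procedure; its two-consecutive-points rule was chosen for nominal
  behaviour under the generator's noise model.
- Observed-data mode of the bundled pipeline driver expects the plate CSV
  dialect documented in `plate_io`; vendor binary formats are out of scope.
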