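# Methods

## The forward model

The simulator describes a low-voltage-activated (T-type) calcium channel
with two independent first-order gates: activation m (increasing logistic
of voltage, half-maximal at V0.5_act with slope factor k_act) and
inactivation h (decreasing logistic, V0.5_inact, k_inact). Within any
constant-voltage segment the gates have closed-form exponential solutions

    m(t) = m∞(V) + (m0 − m∞(V))·e^(−t/τ_act)
    h(t) = h∞(V) + (h0 − h∞(V))·e^(−t/τ_inact)

so the integration is exact per sample: there is no ODE-solver tolerance
anywhere in the pipeline. Gates are initialized at steady state for the
holding potential (−90 mV throughout). Current is ohmic,
I = g_max·m·h·(V − E_rev) in pA for g_max in nS and voltages in mV, so
depolarization-evoked current is inward (negative) below the reversal
potential. E_rev defaults to +45 mV, a plausible ohmic reversal for the
10 mM external Ca²⁺ recording solution; because every downstream analysis
normalizes conductance or current, this choice affects absolute
amplitudes only (the fitted V0.5 moves by <1 mV for E_rev ± 10 mV).
Goldman–Hodgkin–Katz rectification, single-channel stochasticity, and
cumulative (frequency-dependent) inactivation are deliberately out of
scope.

τ_act and τ_inact are treated as voltage-independent within a pulse; the
construct values apply at the test potentials of the standard protocols.
This is the simplest reading consistent with time constants reported at a
single test potential.

## Stimulation protocols

All protocols hold at −90 mV and sample at 0.1 ms:

* I–V (activation): 100-ms steps, −90…+60 mV in 5-mV increments, 0.2 Hz.
* Steady-state inactivation: 1-s conditioning prepulses −90…+20 mV
  (5-mV increments) followed by a 50-ms test pulse to −20 mV, 0.1 Hz.
* Kinetics: a single 100-ms depolarization to 0 mV.
* Current density: a single 100-ms pulse to −10 mV.
* pH pulse train: repeated 200-ms pulses to −20 mV, 0.1 Hz.

The 5-mV increment is a conventional choice for whole-cell I–V families.
The inter-sweep interval is carried in the protocol metadata but has no
effect on the model (no cumulative inactivation).

## Construct parameter fixtures

Six parameter sets ship with the package: the wild-type channel and the
five disease-associated variants R111G, M128L, D302G, R307H, Q1158H.
Voltage dependence (V0.5, slope), time constants, mean current densities
and pH ratios are the published per-construct characterization means.
Activation slope factors were never reported for R111G, D302G, R307H and
Q1158H; they default to the wild-type 5.8 mV and are flagged in
`SLOPE_DEFAULTED`. Maximal conductance is not a reported quantity: it is
calibrated per construct so that a default cohort's mean current density
at the −10 mV pulse equals the reported mean. The calibration divides by
E[1/C] under the default capacitance distribution (≈ 1.0748/12 pF⁻¹)
rather than 1/mean(C), since the cohort averages per-cell density
|I_peak|/C and the harmonic correction would otherwise bias the cohort
mean +7%.

## Cell-to-cell variability

The cohort generator emulates independent transfections: per-cell g_max
lognormal with CV 0.3 around the construct value (mean-preserving
parameterization), capacitance normal 12 ± 3 pF truncated below at a
physical floor of 3 pF (a whole-cell recording from a smaller cell is not
usable; without the floor the expectation of 1/C does not exist), and
normal jitter (sd 1.5 mV) on both half-maximal voltages. Gaussian
recording noise of 5 pA sd is added per sample. These defaults were
chosen to produce the per-cell scatter visible in published SuperPlot
summaries of this preparation. Cells are assigned round-robin to three
replicate-batch labels with alternating 24/48-h post-transfection time
points. A master seed fans out through `numpy.random.SeedSequence`
spawning — one child per (construct, protocol) cohort, one grandchild per
cell — so any sub-cohort is independently reproducible.

What the generator does *not* emulate, and hence what passing tests do
not establish about real recordings: series-resistance and space-clamp
errors, leak and capacitive transients (traces are ideal after the P/N
subtraction the real rig performs), liquid-junction potentials, rundown,
voltage-dependent time constants, and any non-Gaussian noise. Recovery
tests demonstrate that the estimators are unbiased for data generated by
this model, not that the model captures every feature of patch-clamp
data.

## Analysis choices

**Peak current.** Baseline is the mean current over holding-potential
samples preceding the measurement window (for the SSI protocol this
skips the conditioning prepulse); the peak is the baseline-subtracted
extremum with sign preserved, reported as a magnitude where figures
conventionally plot inward current downward.

**Conductance and availability curves.** G(V) = I_peak/(V − E_rev),
excluding voltages within ±5 mV of E_rev to avoid division blow-up,
normalized by the observed maximum (not a fitted G_max). Availability is
|I_peak| of the fixed test pulse normalized by its maximum over
prepulses.

**Boltzmann fits.** Least squares with initial V0.5 from the interpolated
0.5 crossing and initial slope from the 0.25–0.75 span. The fitted model
is amp·logistic + floor with amplitude and floor as nuisance parameters
bounded near [1, 0]; only (V0.5, slope) are reported. The nuisances
absorb two measurement artifacts that otherwise inflate the slope:
normalization by a noisy observed maximum plateaus the data slightly
below 1, and the availability curve has a genuine floor because h relaxes
toward h∞(−20 mV) > 0 during the test pulse (the measured curve is an
affine map a·h∞(V_pre) + b of the true one). Residual biases under the
default protocols are ≤ 0.4 mV in V0.5 and ≤ 0.3 mV in slope. Optimizer
failure, degenerate input, or a monotone trend contradicting the
requested orientation set `converged=False` rather than raising. Cohorts
are summarized by the mean of per-cell fitted parameters, never by a fit
to pooled points.

**Kinetics fits.** The exponential product
C·(1 − e^(−(t−t0)/τ_act))·e^(−(t−t0)/τ_inact) is fitted to the
baseline-subtracted, sign-rectified test-segment current, with initial
guesses from the closed-form time-to-peak relation
t_peak = τ_act·ln(1 + τ_inact/τ_act) (inverted by fixed-point iteration)
and a log-linear regression of the decay tail. The decay term includes a
fitted sustained fraction f_ss (decay toward f_ss rather than zero):
this matches the gating model exactly — at a test potential where
steady-state availability has not vanished the current ends on the
window-current plateau — and it removes a downward τ_inact bias at the
−20 mV pH pulses (availability there is 1–5% for these constructs). On a
strongly inactivating 0-mV pulse f_ss fits ≈ 0 and the equation reduces
to the pure product.

**Window currents.** Area under the pointwise minimum of the two
normalized fitted curves — the standard window-current construction —
integrated by trapezoid on a 0.01-mV grid over [−90, +20] mV (the SSI
prepulse range; both bounds configurable). The pointwise-minimum reading
of "overlap" was chosen over the curve product; the min construction is
the common operational definition and the tests verify it against a
closed-form logistic-integral oracle. Ratios are computed from fitted
Boltzmann parameters (reproducible from any cohort), not from empirical
mean traces; published ratios obtained from empirical mean curves are
therefore expected to agree in direction, not digit-for-digit.

**pH modulation.** The per-construct pH factor maps are defined on the
measurement scale: the conductance factor is the target relative *peak
current* I_pHX/I_pH7.4 (what a pipette measures), and the τ factor the
relative inactivation time constant. Applying a pH scales τ_inact by its
factor and g_max by peak_factor/kinetic_gain, where the kinetic gain —
the peak increase caused by slowed inactivation alone — is computed in
closed form for the standard pH pulse. When the τ factor is 1 (every
condition except Q1158H at pH 8.0) this reduces to a plain g_max
multiplication. Paired ratios compare the same cell's steady-state block
(last 3 pulses, averaged) at each pH; transition dynamics between
solutions are not modeled. Paired comparisons use a two-sided paired
t-test of ratios against 1; across-construct comparisons use one-way
ANOVA with Tukey's HSD.

**Cohort statistics.** SuperPlot-style summaries pool all cells for the
grand mean ± SEM (sd/√n, ddof 1) and carry per-batch means for display.
Wild-type/variant comparisons use the classical equal-variance Student's
t-test, two-sided (Welch available by flag), with significance tiers
*** p ≤ 0.001, ** p ≤ 0.01, * p ≤ 0.05, closed upper bounds. Groups
below n = 5 warn rather than error.

**Burden test.** Control allele counts are estimated from per-variant
MAFs as round(MAF·2N) (ties away from zero), with default cohort sizes
50,000 (gnomAD non-Finnish European, neurological conditions removed)
and 43,000 (UK Biobank, British, headache-free), both configurable. The
2×2 alternate/reference × case/control table is tested with the Pearson
chi-square without continuity correction; the reported p-value is the
upper tail of χ²₁ (the chi-square test's natural one-sided form, matching
an a-priori hypothesis of *increased* burden in cases). A Fisher exact
option exists for small counts. The odds ratio uses the aggregated
frequencies, OR = (f_case/(1−f_case))/(f_ctrl/(1−f_ctrl)). The
gnomAD-based comparison in the source cohort used a curated subset whose
per-variant MAFs are not public; it is not reproducible from the bundled
table and the package makes no attempt to do so.

## Numerical notes and edge cases

* Logistics are evaluated with `scipy.special.expit`; no overflow at
  extreme voltages.
* Degenerate inputs are contracts, not crashes: all-equal fit points →
  `converged=False`; zero-variance paired differences, all-constant
  ANOVA groups, empty variant tables, zero reference peaks → explicit
  `ValueError`s. Two constant equal groups in the t-test return t = 0,
  p = 1 by convention.
* Window-area quadrature at 0.01 mV agrees with the closed-form
  logistic-integral oracle to better than 1e-4 relative (tested on random
  parameter sets) and is stable under grid refinement to <1e-6.
* Estimated control allele counts use half-away-from-zero rounding, not
  banker's rounding.

## Problem sizes

The test suite and the acceptance script simulate 12-cell cohorts per
construct, pooled over three master seeds (36 cells per construct), with
recovery bands applied to the pooled means: with the default 1.5-mV V0.5
jitter one 12-cell cohort mean has a sampling sd of 0.43 mV, so pooling
is what makes a ±1 mV band a 4σ statement about estimator bias rather
than a coin flip on jitter draws. Reported density means use dedicated
60-cell cohorts (density is a single cheap sweep per cell) because the
lognormal conductance makes per-cell densities heavy-tailed. Statistical
calibration uses 1,000 null simulations with groups of 8.

## Known limitations

* The availability floor correction assumes the default SSI test pulse;
  radically different test potentials change the floor the fit must
  absorb.
* τ values are voltage-independent by construction, so the simulator
  cannot reproduce voltage-dependent kinetics gradients across an I–V
  family.
* The burden estimator works from per-variant MAFs, not genotypes; for
  cohorts with individual-level data the rounding step is exact only for
  heterozygous carriers.
* Window-current ratios from fitted parameters inherit any misfit of the
  Boltzmann model near the curve crossing; with the defaulted activation
  slopes for four variants, their ratios are conditional on that default.
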