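# Methods

## Model structure and assumptions

The reduced model follows dopamine through four pools in a single
well-mixed dopaminergic terminal: levodopa (*ldopa*), cytosolic dopamine
(*cda*), vesicular dopamine (*vda*), and extracellular dopamine (*eda*),
all in µM with time in hours.  Synthesis (TH), decarboxylation (AADC),
vesicular packaging (MAT, with a first-order leak back at rate k_out),
release at the firing rate, reuptake (DAT), and catabolism (MAO) are
Michaelis–Menten steps with the published kinetic constants
(`ReducedParams`).  Three upstream species are frozen at their
steady-state values — tyrosine (126 µM), tetrahydrobiopterin (319 µM),
and implicitly dihydrobiopterin — which collapses the first factor of the
TH velocity to the constant 0.56/(1 + tyr/K_i,tyr) ≈ 0.3133.
Homovanillic-acid bookkeeping is omitted as a purely downstream output.
The full nine-state parent model is documented by its parameter table
only; its blood-tyrosine input is not specified here, so it is not a
runnable system in this package.

At the nominal parameters the model has a unique biologically feasible
equilibrium, (ldopa, cda, vda, eda) ≈ (0.356, 2.646, 80.96, 0.002023) µM,
with ~97 % of intracellular dopamine stored in vesicles.

## The autoreceptor factor and its calibration

D2 autoreceptor feedback multiplies the TH velocity by

    F(eda) = a / ((eda/c)^4 + d) + b,      a = 4.58, b = 0.5, d = 1,

a declining sigmoid in eda.  The published coefficient set leaves the
factor's value at the nominal steady state over-determined: with the
inner scale read as eda* itself, F(eda*) would be a/(1+d) + b = 2.79,
which is incompatible with flux balance at the printed equilibrium
(TH and AADC fluxes must both be ≈ 27 µM/hr there, and the remaining TH
factors already supply that).  We therefore treat the inner Hill scale
``c`` as the calibrated constant: c = eda*/(a/(1−b) − 1)^(1/4) =
0.0011975 µM, the unique choice that keeps a, b, d at their published
values and makes F(eda*) = 1 exactly.

This choice fixes the *slope* of the feedback at the operating point,
d ln F / d ln eda = −1.78, and that slope is observable: it sets how much
the circadian peak of ldopa leads the forcing peak (17.33 h into the
cycle vs 18.00 for the forcing), the downstream peak lag of cda/vda/eda
(1.50 h), and the damping of the response to reuptake inhibition (the
24-h post-dose median of eda spans 13.0–26.9 % above steady state for a
half-strength dose across administration times).  The alternative
calibration that rescales the denominator constant instead
(d = a/(1−b) − 1 = 8.16, slope −0.218) reproduces the same equilibrium
but gives a visibly weaker feedback (median sweep 23–44 %, ldopa peak at
17.82 h); both are available through
`AutoreceptorCalibration.calibrated()`, with the steep variant as the
package default.  With the factor pinned to 1 ("no autoreceptors") a
doubled firing rate doubles equilibrium eda; with feedback active the
increase is damped to ~1.45×.

## Circadian forcing and DRI dosing

Clock control enters quasi-statically as multipliers C_TH(t) =
0.25 sin(π/12 (t−12)) + 1 on TH and C_MAO(t) = 0.25 sin(π/12 (t−20)) + 1
on extracellular catabolism V_CATAB only — the intracellular first-order
loss k_cda·cda is deliberately left unmodulated.  Both range over
[0.75, 1.25]; baseline-shift robustness runs scale the whole curve by
0.75 or 1.25.  Time zero is circadian time 0, so the forcing peaks at
clock times 18 (TH) and 2 (MAO).

A reuptake inhibitor is a transporter occupancy x_dose(t) that jumps by
`Dose` at each administration time and decays exponentially with
r = ln 2 / half-life (0.0462 /hr for the default 15 h, modafinil-like
half-life).  The DAT velocity in both the cda and eda equations is scaled
by max(1 − x_dose, 0); stacked doses can push occupancy above 1, which
the clamp absorbs.  Doses are implemented as integrator restarts with the
occupancy evaluated in closed form, so the jump is exact rather than a
smoothed delta.  The firing rate is the constant 1; firing-rate
homeostasis is probed with constant multipliers at steady state because
no temporal firing profile is part of the model.

## The ultradian oscillator (DUO)

Two dimensionless latent states extend the model: a shared extracellular
dopamine pool, edapool' = k1_pool·eda − k2_pool·edapool, and autoreceptor
signalling, D2' = k3_pool·edapool − k4_pool·D2.  Inside V_TH the
instantaneous factor F(eda) is replaced by
A(D2) = α + β/(1 + exp((D2 − γ(2 − s_DAT))/m)), evaluated through the
logistic function so extreme arguments saturate instead of overflowing
(important for the second preset, where m = 0.01 makes the sigmoid nearly
a switch).  The midpoint shift γ(2 − s_DAT) models autoreceptor
adaptation: lowering DAT activity raises dopaminergic tone, and the
sigmoid slides right to compensate.  DAT activity is a fixed constant
s_DAT in the DUO, not a decaying dose trajectory: ultradian period and
amplitude are properties of a steady inhibition level, and a decaying
occupancy would confound them with dose timing.

Two named presets ship verbatim: `fig6` (k1_pool = 4519.93,
k2_pool = 0.38, k3_pool = 22.3, k4_pool = 2.34, α = β = 0.5,
γ = 193.93, m = 1.1), a gently sloped feedback that oscillates with a
~4.4 h period at full DAT activity, and `fig7` (k1_pool = 21118.5,
k2_pool = 1.89, k3_pool = 34.45, k4_pool = 0.47, α = 0.5, β = 4.5,
γ = 2139.25, m = 0.01), a switch-like feedback whose period runs from
~3.5 h at s_DAT = 1 to ~9 h at s_DAT = 0.3 and which loses its limit
cycle in a Hopf bifurcation at s_DAT ≈ 0.265.

Default initial condition for DUO runs: the drug-free reduced-model
equilibrium for the four concentrations, with the latents at their
linear-chain balance values (edapool = k1/k2·eda, D2 = k3/k4·edapool).
Latin-hypercube searches sample k1_pool and γ log-uniformly (their ranges
span ≥ 2 decades) and the remaining six parameters uniformly, one sample
per equal-probability stratum, deterministically for a fixed seed.

## Equilibria, Jacobians, and bifurcation analysis

Fixed-point conditions telescope into a single scalar equation in eda
(the eda equation yields vda, the vda equation cda, the cda equation the
AADC flux and hence ldopa; for the DUO the latents are linear in eda), so
equilibria are found by bracketing that scalar residual on a log grid —
which doubles as a uniqueness check; multiple sign changes raise — and
polishing the full-dimensional root with a Newton-type solver to a
relative residual below 1e−10.  The DUO polish runs in log-space because
the states span seven orders of magnitude.

Jacobians are derived symbolically once per model (sympy), cached, and
evaluated numerically; the lambdified exponential is clipped at ±250 so
sigmoid-derivative terms underflow cleanly to 0 instead of producing
inf/inf.  Analytic entries are cross-validated against central finite
differences in the test suite (relative 1e−6).  Stability maps freeze the
circadian multipliers at each phase (quasi-static assumption), solve the
equilibrium per (s_DAT, phase) — continuation runs from s_DAT = 1
downward — and record the eigenvalues of a standard dense solver; the
characteristic polynomial is retained only as a verification oracle.
Hopf localization bisects the sign of the dominant real part along the
equilibrium branch to 1e−3 in s_DAT and requires a nonzero imaginary part
at the crossing.

Within the printed parameter family the quasi-static equilibria are
locally stable everywhere on s_DAT ∈ [0, 1] × phase ∈ [0, 24): at
s_DAT = 0 the equilibrium eda rises to ~0.03 µM, the feedback factor
saturates at its floor b, its slope vanishes, and with no active feedback
loop the Jacobian is a cascade of stable compartments.  An instability
exactly at s_DAT = 0 is therefore not attainable in this model family;
the package reports the computed spectra as they are.

## Numerical settings

* Integrator: LSODA (stiff-capable; k_eda = 400/hr and the eda relaxation
  rate ~4×10⁴/hr make the system stiff), rtol 1e−8, atol 1e−10.
* max_step = 0.1 h so sinusoidal forcing and post-dose transients are
  always resolved; trajectories are recorded on a uniform 0.01 h grid
  (0.02 h for long DUO runs), and medians/percentiles are only computed
  on uniform grids to avoid step-density bias.
* Windows are half-open (t_dose, t_dose + 24]: "the 24 hours following a
  dose" excludes the instant of administration itself.
* Components are clipped at −1e−9 inside the right-hand side to absorb
  solver round-off; anything below −1e−6 in a solution aborts the run.
* Burn-in: 10 forced periods (240 h) before any metric is taken.  The
  slowest nominal eigenvalue is ≈ −0.65/hr (τ ≈ 1.5 h), so this is
  conservative; the forced trajectory repeats to < 1e−4 relative after
  burn-in.  Dose-timing sweeps reuse a single burn-in by starting each
  protocol from the interpolated limit-cycle state at the dose time.
* Peak-based period estimation: local maxima with prominence ≥ 1e−6 µM
  after discarding the transient (half the run by default); period is the
  mean peak-to-peak interval with quadratic sub-grid refinement of peak
  times, amplitude the mean per-cycle max−min.  Traces with no prominent
  peaks are non-oscillatory with amplitude 0; one or two peaks raise an
  insufficient-data error rather than guessing.
* Tie-breaks on argmin/argmax over dose-time grids: earliest time wins.

## Problem sizes

Default experiment sizes (chosen as desk-scale runs; all grids accept
denser arrays): dose-timing sweep every 0.5 h (49 single-dose
simulations of 24 h each), repeated dosing 7 days, half-life×dose
surfaces on coarse 4×4 to 6×6 grids, stability maps 25 s_DAT values × 24
phases, DUO period/amplitude runs of 480 h with the first half
discarded, sensitivity scans at 11 scales per parameter over
[0.75, 1.25]× with a 100-day horizon and the final 4 days recorded (the
test suite uses a 15-day variant with its own burn-in, which is excluded
from any steady-state claims).

## Known limitations

* The model is a single well-mixed terminal; no spatial diffusion,
  no neuron-to-neuron heterogeneity, no stochastic release.
* Pharmacokinetics are one-compartment occupancy jumps with exponential
  decay — no absorption phase, no binding kinetics.
* The circadian multipliers are imposed sinusoids, not outputs of a
  molecular clock model; all timing conclusions are relative to their
  phases.
* edapool and D2 are intentionally dimensionless latent variables; only
  their dynamics, not their scales, carry meaning.
* The autoreceptor calibration is constrained by the printed equilibrium
  but its slope is a modelling choice (see above); quantities that depend
  on the feedback slope (peak leads, dose-response medians) shift between
  the two calibrations by up to a factor ~1.7.
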