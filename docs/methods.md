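# Methods

This note documents the models implemented in `hairbundle`, the defaults
and numerical choices, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Gating-spring model (`core`)

The quasi-static force on a hair bundle at deflection `X` (positive toward
the taller stereociliary row) is

    F(X) = K·X − F_G · P_o(X) + F_∅,
    P_o(X) = 1 / (1 + exp(−(X − X_0)/δ)).

Assumptions: the bundle is cohesive, so all transduction channels gate in
concert against a common deflection and the whole-bundle gating force
`F_G` is meaningful; gating is a two-state process with a Boltzmann open
probability; adaptation is slow enough that a quasi-static snapshot taken
a few milliseconds after a step sees the channels equilibrated but not yet
adapted.

Parameters and defaults:

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `K` | linear stiffness | pN/nm | 0.85 | control-condition ensemble mean |
| `F_G` | whole-bundle gating force | pN | 17 | control-condition ensemble mean |
| `X_0` | set point (P_o = ½) | nm | −2 | control-condition ensemble mean |
| `δ` | Boltzmann width | nm | 20 | see below |
| `F_∅` | offset enforcing F(0)=0 | pN | derived | experimental convention |
| `γ` | tip-link projection factor | — | 0.14 | bundle geometry |
| `K_SP` | pivot stiffness | pN/nm | 0.17 | post-tip-link-disruption mean, ≈ 0.2 K |

Without displacement-clamp feedback the negative-stiffness branch of a
strongly gated relation is never traversed, so `δ` is poorly constrained
experimentally.  We use 20 nm as the synthesis/example default — it keeps
the relation monotonic at the control `F_G` and `K` (4Kδ = 68 pN > 17 pN)
and the evaluation well conditioned — and the fit treats `δ` as a free
parameter bounded to [1, 100] nm.  No relation of the form δ = N·k_BT/F_G
is imposed: the channel count N is not modelled.

Regimes: `linear` (F_G = 0), `negative-stiffness` (F_G > 4Kδ, minimal
slope K − F_G/(4δ) < 0, bistable against a soft fiber), `gated-monotonic`
otherwise.  The gating swing along the tip-link axis is
`d = γ·F_G/(K − K_SP)`; it is undefined (flagged, not silently computed)
when K ≤ K_SP.

## Force-displacement fit (`fdfit`)

`GatingSpringModel.fit()` fits both a 2-parameter line and the 4-parameter
gated relation (with `F_∅` profiled out in closed form at each step:
its least-squares value given the other parameters is the mean residual).
Initialization is data driven: `K` from the pooled slope of the outer
thirds of the X-range, `F_G` from the intercept gap of separate lines to
those limbs, `X_0` at the point of maximal deviation from the single
global line, and `δ` from a 5-point log-spaced multistart over [1, 100] nm
(best of multistart by SSE).  Bounds: K > 0, F_G ≥ 0, δ ∈ [1, 100] nm.
Standard errors come from the Gauss–Newton covariance at the optimum.

Model selection uses AICc (k = 6 for the gated branch including the noise
variance, k = 3 for the line) *and* requires the fitted `F_G` to exceed
twice its standard error.  Cells failing either test are reported as
`linear` with `F_G = 0` ("undetectable"): a near-degenerate gated fit has
an unstable point estimate, and reporting zero mirrors how linear relations
enter the ensemble deltas (ΔF_G = −F_G(0), Δd/d_0 = −100%).  The AICc +
2-SE rule is this package's operationalization; only the outcome (linear
vs. gated) has an experimental counterpart.  With 18 points and 2 pN of
force noise the selection has limited power — roughly 60% of strongly
gated (17 pN) relations are called gated — which is the honest behaviour
of a 2-SE rule at that signal-to-noise, not a defect of the optimizer;
the gated-branch estimate itself stays unbiased (median within 5%).

## Synthetic data (`simulate`)

The generators define the study conditions the tests run under.

**Step protocol.**  For each base command Δ the steady position solves
`k_F(Δ − X) = F(X)`.  Roots are found by a sign-change scan plus Brent
refinement; stability requires `k_F + F'(X) > 0`.  In the bistable regime
the branch is chosen by continuation from the previous position — the
physical behaviour without displacement clamping, which is what makes
up/down sweeps hysteretic.  Steady-state roots are reported directly
instead of simulating the few-millisecond settle, because adaptation is
out of scope and the settled state is then exact.

**Cycles.**  Overdamped dynamics
`ξ·dX/dt = k_F(Δ(t) − X) − (K·X − F_G·P_o + F_∅)` with
`τ_a·dP_o/dt = P_∞(X) − P_o`, integrated with a fixed-step scheme
(explicit Euler for X, exact exponential relaxation for P_o) at
dt = 10 µs; the contract is that halving dt moves φ_MAX by < 1%, and the
integrator raises a divergence error naming dt if the state leaves 10×
the stimulus amplitude.  The first stimulus cycle is discarded as a
transient.  Defaults `k_F = 0.5 pN/nm` and `ξ = 1×10⁻⁴ pN·s/nm` are
literature-typical orders of magnitude for a fiber-coupled bundle; with
them, the bundle follows k_F/(k_F+K) ≈ 37% of the base command, so
analyses needing ≥ 80% coverage of the stimulus should use a stiff fiber
(k_F ≈ 5 pN/nm), as the tests do.

**Oscillations.**  Linear spectral surrogates: complex Gaussian Fourier
coefficients with variance proportional to the target double-Lorentzian
density, inverse transformed.  This reproduces the second-order statistics
(spectrum, variance) of a noisy oscillator but none of the non-Gaussian
waveform structure (relaxation-oscillation asymmetry, bimodality); bimodal
position histograms are generated separately as two-Gaussian mixtures.
Passing spectral tests therefore validates the estimators' spectral
behaviour, not any mechanistic oscillator model.

**Ensembles.**  Each observable delta (set point, stiffness, gating
force, relative gating swing) is drawn independently from its configured
regression line against current, with residual SD
`|slope|·SD(I)·√((1−R²)/R²)` so the expected OLS R² matches the target.
Draws are recorded as-is (no positivity clipping) so slope recovery is
unbiased; consistency between F_G and d across observables is not
enforced — the generator targets the regression structure, not a joint
mechanistic model.  Below the state-transition threshold (`I_down` on
descending ramps, `I_down + hyst` ascending) cells are weak: F_G = d = 0.

**Ramp branches.**  `gen_phi_ramp` produces φ_MAX(I) along a
descending/ascending ramp: a gentle saturating rise on the strong branch
collapsing to a weak plateau through a logistic drop of width 0.25 µA
centred at the branch's threshold.  It exists so the hysteresis detector
has a generative counterpart with known shift.

**Kinetics.**  Exponential relaxations of the cycle-averaged position
(τ_ON = 500 ms, τ_OFF = 100 ms) and of φ_MAX (τ_ON = 180 ms,
τ_OFF = 400 ms) across a current step, the documented separation of
timescales; windows are long (4 s ON, 3 s OFF) so plateaus are reached and
10–90% times are unbiased.

All generators consume an explicit seed and are bit-reproducible.

## Cycle analysis (`cycles`)

Records are folded on the stimulus phase (known sampling, integer samples
per period), split by the sign of dΔ/dt, and binned onto a common X grid
of 100 bins (bin width = X span/100, resolution-matched to 25-kHz
sampling).  φ(X) = [F₊ − F₋]/2; the outermost 5% of the X range is
excluded from φ statistics (fiber-reversal artifacts).  A profile whose
interior spread is < 5% of its level is declared flat (pure viscous drag):
φ_MAX is then the interior median and the argmax is undefined.  The
inversion point is (argmax φ, mid-force there).  The sign convention is
fixed by dissipation: φ ≥ 0 for passive cycles, and a negative interior
median raises a sign flag rather than silently flipping.

Activation time: bundle speed from finite differences after a 5-sample
moving average (raw finite differences have a degenerate argmax under
noise); τ = ΔX/(2·V_MAX) where ΔX is the shift between the positions of
maximal |dX/dt| on the two half-cycles.  On simulated cycles the estimate
is monotone in the generating τ_a and recovers its scale within ~30% at
the 40-Hz/600-nm protocol; it is a comparative, not an absolute, measure.

## Oscillation analysis (`oscillation`)

PSDs are segment-averaged periodograms (boxcar, non-overlapping, global
mean removed, ~4-s segments) in the two-sided convention: the variance
equals the full-line integral, so `X_RMS = √(4πAQ/f₀)` is literal.
Smoothing is a 1-Hz boxcar (odd bin count, nearest-edge extension,
integral preserved to ≪ 0.5%).  The double-Lorentzian fit initializes f₀
at the peak, Q from the FWHM, A from the peak height, and requires a
resolved peak: ≥ 5 bins above half maximum and ≥ 3× contrast over the
spectral median — a flat spectrum fails loudly instead of returning a
meaningless line.  The raw (unsmoothed) spectrum is used for Parseval
checks; the smoothed one for fitting.

The bimodal open-probability estimate fits a 2-component Gaussian mixture
by EM (scikit-learn, fixed random state, 3 restarts) on the raw positions
(no histogram binning, hence no bin-width choice) and reports the weight
of the mode above the sample mean as P_oSS.  It is flagged unreliable when
the mode separation is < 2 pooled SDs or a mode carries < 2% weight.

## Epithelium (`epithelium`)

The step response is fitted as `U(t) = A·(1 − e^(−t/τ))`; fitting the
decaying residual `U_∞ − U(t)` is algebraically the same problem, so a
pure-decay parameterization of the same data yields identical (A, τ) —
asserted in tests.  `R = A/I_STEP` (kΩ), `C = τ/R` (nF); kΩ·nF = µs keeps
units consistent.  Flat traces return A = 0 with τ flagged undefined.

## Ensemble statistics (`stats`)

Pearson correlations, OLS, two-tailed paired t-tests, mean ± sample SD
(n−1).  Raw p-values; no multiple-testing correction is applied, matching
the reporting convention of the kind of dataset this targets.

The hysteretic transition detector defines the strong/weak levels per
branch as plateau medians (samples above/below the φ mid-range) — a
generalization of marking single pre-/post-drop currents, robust to where
exactly the ramp starts — and the transition current as the first
midpoint crossing in ramp-time order, linearly interpolated.  The
hysteresis shift is the ascending minus the descending crossing.  The
detector is invariant under vertical scaling of φ and horizontal
translation of both branches.  A branch that never crosses its midpoint
raises a no-transition error.  The midpoint-crossing rule is this
package's operational definition of the drop current on noisy ramps.

10–90% times interpolate linearly between samples; baseline and plateau
are medians of the first/last 10% of the analysis window, and a change
below 3× the (estimated or supplied) noise SD is declared undefined.

## Problem sizes

Defaults were chosen as realistic protocol sizes: 18–20 step FD points,
10 averaged cycles at 40 Hz and 600 nm peak-to-peak (2 cycles at 100 Hz
for kinetics), 20–30 s oscillation traces at 250 Hz, 34-current ensembles,
and 50–500 seed Monte-Carlo harnesses for recovery statistics.

## Known limitations

- No adaptation-motor dynamics, thermal forcing of the bundle, or fiber
  vibrational-mode force corrections; the cycle integrator is the minimal
  drag + delayed-gating model.
- The oscillation surrogates are Gaussian; estimators that depend on
  waveform shape are untested against mechanistic oscillations.
- Ensemble observables are generated marginally per regression, so joint
  constraints between F_G, K and d are not respected in synthetic tables.
- δ is reported but should not be over-interpreted: without the
  negative-stiffness branch it is weakly identified, and its standard
  error is typically large.
- Iontophoretic control enters only as a generic control-parameter axis
  reusing the state-transition model; no chelation chemistry is modelled.
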