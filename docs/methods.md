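# Methods

This note records the models implemented in `tetherkit`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
data generator does and does not emulate.

## Polymer mechanics

The force law is the Marko–Siggia interpolation of the worm-like chain.
The working force range of the tethered-bead assays (0.02–4 pN) is far
below the enthalpic-stretching regime, so no extensible-WLC term is
included; the seventh-order Bouchiat polynomial correction is available
behind a flag (`bouchiat=True`, default off) for users who need <1%
mid-range accuracy. Thermal energy defaults to k_BT = 4.114 pN·nm
(298 K, room temperature).

The inverse `wlc_extension` uses bracketed Brent root finding on
[0, L_c) with an absolute tolerance of 1e-12·L_c; forward/inverse
round-trips are accurate to better than 1e-9·L_c.

`fit_wlc` minimises extension residuals at the measured forces — force
is the controlled variable in magnetic tweezers, so measurement error
lives in the extension. Bounds (L_p ∈ [1, 500] nm, L_c within 0.1–10×
the largest observed extension) keep the optimiser off condensed curves
passed in by mistake. Standard errors come from the Gauss–Newton
curvature at the optimum scaled by the residual variance.

One physical subtlety the test suite leans on: the *thermal average*
extension of a tether at constant force sits slightly below
`wlc_extension(F)` wherever the force law is convex (≈0.8 nm at 4 pN for
the default tether). Simulation-vs-theory comparisons therefore use the
exact Boltzmann-average extension (by quadrature) as the oracle, not the
deterministic inversion.

## Tether simulation

The bead is overdamped (drag γ = 6πηr ≈ 9.4×10⁻⁶ pN·s/nm for a 0.5 µm
radius in water), so the dynamics are Langevin:

* longitudinal: Euler–Maruyama steps
  `dz = (F − F_wlc(z; L_c,eff)) dt/γ + √(2 k_BT dt/γ) ξ`, using the full
  nonlinear WLC restoring force so condensation-induced contour jumps
  are handled without re-linearisation;
* transverse (x, y): the pendulum approximation with stiffness
  κ_x = F/z, integrated with the exact Ornstein–Uhlenbeck transition
  (unconditionally stable); the pendulum arm is floored at 50 nm so the
  stiffness stays finite at very low force.

The internal timestep is 0.1·γ/κ_z per force segment, with κ_z evaluated
at the stiffest admissible contour, and is snapped so an integer number
of steps fits one recorded sample; configurations implying
κ·dt/γ ≥ 0.5 raise an error. Samples are recorded at the acquisition
rate (120 Hz default) as instantaneous positions, which is why variance-
based force calibration is exact on the full-rate data while boxcar
filtering removes variance (motion blur).

Condensation is a continuous-time Markov jump process on the *effective
contour length*: Bell-model capture at rate k_c0·exp(−F·x_c/k_BT)
removes a truncated-normal loop; release at k_r0·exp(+F·x_r/k_BT)
restores it; the effective contour never drops below a configurable
floor (default 20% of L_c). Defaults — k_c0 = 2 s⁻¹, x_c = 30 nm,
k_r0 = 0.01 s⁻¹, x_r = 15 nm, loops 50 ± 20 nm — were chosen once from
the qualitative phenomenology these assays show (condensation only below
a few tenths of a pN, completing within minutes at ~0.3 pN; prompt
stepwise decondensation at a few pN). The kinetics are a *generator*,
not an inference target: real capture/release rates and loop sizes are
not measured quantities here.

Determinism contracts: every simulator is a pure function of
(parameters, seed); the condensation kernel consumes one uniform variate
per internal step for the jump test regardless of the rates, so a
zero-rate model reproduces the bare simulator bit for bit at equal
seeds.

The default tether (L_c = 2040 nm ≈ 6 kbp, L_p = 50 nm) and the default
force protocol (20 logarithmic steps, 4 → 0.02 pN, 13 min total) are
nominal values for this class of experiment and fully configurable. The
simulator does not model bead rotation, magnet-field gradients, camera
exposure/pixelation, tracking error, or sequence-dependent DNA
mechanics; passing tests therefore validate the analysis chain against
an idealised instrument, not against every artefact of real data.

### Rotation–extension

Supercoiling is modelled at the level of its observable: mean extension
is flat below a buckling turn number (default 30 turns at 4 pN) and
decreases linearly beyond it (27 nm/turn). With bridging enabled, each
plectonemic turn is trapped with probability 0.35 at the start of
unwinding; trapped turns are grouped into chunks (~4 turns) that release
as discrete extension steps once the magnet turn count falls below a
uniformly drawn threshold. These are nominal parameters for a ~6 kbp
tether; the assay is quantified, not calibrated, by them. OU-correlated
noise with the WLC stiffness at the holding force rides on the mean.

## Force calibration

`estimate_force_variance` implements equipartition,
F = k_BT·⟨z⟩/Var(x), on full-rate constant-force windows (≥500
samples). Standard errors come from a block bootstrap with block length
10× the estimated correlation time (1/e crossing of the autocorrelation)
and at least 10 blocks.

`estimate_force_psd` fits the transverse power spectrum by Whittle
likelihood (periodogram ordinates are exponentially distributed, so
least squares would be biased). At 120 Hz the corner frequency (~10 Hz
at 1 pN) is a sizeable fraction of Nyquist and the sampled spectrum is
strongly aliased: fitting the continuous Lorentzian A/(f²+f_c²)
overestimates f_c by tens of percent. The fit therefore uses the
Lorentzian in its exact sampled (AR(1)) form,
S(f) = B/(1 − 2a·cos(2πf/f_s) + a²) with a = exp(−κ_x/(γ f_s)), and
reports f_c = −f_s·ln(a)/2π, κ_x = 2πγf_c, F = κ_x⟨z⟩. White-noise or
drift-dominated windows push a to a boundary and raise a fit error
rather than returning a number.

`boxcar_filter` decimates by non-overlapping window means (120 → 3 Hz
default); force and turns columns carry the window's modal value so
step boundaries never average into non-physical intermediate forces.

## Condensation statistics

Force–extension curves discard the first 10% of each force step as
equilibration (configurable; the choice is conventional, and the
within-step mean is insensitive to it for the default dwell times).
Single-molecule SEMs are within-step; aggregated curves take the SEM
across molecules (sample sd over molecules / √N), which is the error
bar convention for mean curves over N molecules.

The condensation ratio uses the *measured* pre-protein extension at the
permissive force as z₀ — not the WLC prediction — because that is the
operational reference the protocol defines. A negative C_r (tether
longer than the reference) is reported unclamped with a flag. For
trajectory input, z is the mean of 120 samples of the 3 Hz-filtered
record centred at the evaluation time (default 390 s).

The work integral re-expresses both curves as F(z) by sorting on
extension. Condensed curves are generally not monotone in z; they are
made monotone by isotonic averaging and flagged. The same repair is
applied to the bare-slot curve, but there an isotonic adjustment
exceeding 5% of the force range raises an error — thermal scatter is
tolerated, a genuinely condensed curve in the bare slot is not. Both
curves are extended below their lowest measured extension as constant
force at their lowest-force value (flagged): neither curve reaches
z = 0 (bare DNA at 0.02 pN already sits at ~330 nm for the default
tether), and the integral's lower limit is 0. z_max is the bare-slot
extension at its maximum applied force. Work is reported in pN·nm and
k_BT.

Hysteresis is the trapezoidal integral of (forward − backward) extension
over the union turns grid of the overlapping range: **positive area
means the unwinding branch lies below the winding branch**, i.e.
extension recovery is deferred by trapped plectonemes. With identical
branches the area is exactly zero; a backward branch *above* forward by
δ over N turns gives −δ·N under this convention.

The step detector is a sliding two-window mean-shift test: the
difference of flanking window means over their pooled standard error,
thresholded (5σ default) with local-maximum selection and a minimum
separation of one window. It is deliberately the simplest detector with
a calibratable null (false-call rate <0.1 per 1200-sample noise trace at
5σ) rather than an HMM or penalised change-point machinery — discrete
bridging-release steps are large compared to noise, and a controllable
null matters more than asymptotic optimality here.

## Binding analysis

PIFE responses are trapezoidal emission-scan areas over 560–600 nm
relative to a DNA-only control — a fold increase by default, or a
background-subtracted increase with `additive=True` (both are supported
because either reading of "increase relative to a control" is a valid
assay convention). Concentrations are protein-dimer concentrations
throughout.

Hill fits are unweighted nonlinear least squares on the response scale
(the convention of standard graphing packages), seeded with
B_max = max response, K_d from the half-max crossing, h = 1. The global
fit shares one Hill coefficient across datasets with per-dataset
(B_max, K_d_app) and returns both residual sums of squares; since the
shared model is nested in the free one, rss_shared ≥ rss_unshared
always, and their ratio near 1 is the operational statement that
cooperativity does not differ between variants. Standard errors come
from the covariance at the optimum; lmfit performs the minimisation.

## Spectroscopy companions

CSP uses the community-standard composite
Δδ = √(Δδ_H² + (0.14·Δδ_N)²); the nitrogen weight is a parameter so
other conventions can be reproduced. Flagging is strictly greater than
the threshold (default 0.08 ppm), with a 1e-9 relative guard so a value
exactly at the threshold is never flagged through floating-point
residue. Residues present in only one list are reported unmatched,
never imputed as zero.

MRE normalisation is raw/(10·l·c·n_residues) with raw in mdeg, l in cm
and c molar — exactly linear in the raw signal and reciprocal in the
other three.

Melt fitting uses a two-state Boltzmann sigmoid between baselines. By
default the baselines are constant unless an F-test (α = 0.01) prefers
sloped ones: at a typical melt sampling (18 points, 5 °C pitch) free
baseline slopes inflate the Tm uncertainty beyond what the transition
itself supports (the information bound rises from ≈0.4 °C to ≈1.1 °C at
3% noise), so slopes are fitted only when the data demand them;
`baselines="linear"` forces the full model. A derivative-based fallback
(flagged) handles sigmoid failures, and data that do not bracket the
transition — fitted Tm at the range edge, or no resolvable baseline
gap — raise an error advising a wider range.

H/D-exchange decays are single exponentials I₀e^(−kt) with half-life
ln2/k; a rate consistent with zero (k ≤ 2 SE, or unidentifiable on flat
data) is reported as "not exchanging" with a half-life lower bound
ln2/(k + 2 SE).

Charge-series deconvolution uses adjacent-charge algebra: for
neighbouring peaks m₁ > m₂ at charges z, z+1,
z = round((m₂ − m_p)/(m₁ − m₂)) with m_p = 1.00728 Da (positive-ion
mode), and the neutral mass z·(m₁ − m_p) is averaged over all adjacent
pairs with its spread reported. It is deterministic and closed-form —
exact on noiseless series for any mass from kDa to MDa — and is *not* a
maximum-entropy deconvolution: it assumes a single resolved series, and
inconsistent inferred charges (deviation > 0.3 from integers) raise an
error instead of a mass.

## Problem sizes and defaults in the test suite

Tests run simulations at the sizes the statistics need, not larger:
60 s calibration windows (the working convention for fluctuation
calibration), a 4-minute force ramp for the end-to-end work pipeline,
7-minute condensation runs for the condensation-ratio protocol, 200
simulated titrations/melts for recovery statistics and 100 noise traces
for the step-detector null. All seeds are fixed in the tests; no test
depends on global random state.

## Known limitations

* The condensation kinetics module generates plausible trajectories; it
  is not calibrated against measured rates and should not be inverted.
* The rotation–extension model is phenomenological (no torque or
  buckling-transition physics); its buckling point and slope are
  user-set nominal values.
* Step sizes from the detector are flanking-window mean differences;
  closely spaced steps (< one window) merge.
* The PSD calibrator assumes a single Lorentzian component; slow drift
  must be removed (or the variance method avoided) before trusting
  either estimator on real traces.
* Hairpin folding counts only contiguous terminal Watson–Crick pairs
  (no G·T wobble, no internal loops) — adequate for designed perfect
  stems, not a general secondary-structure predictor.
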