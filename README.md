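# tetherkit

Quantitative analysis of magnetic-tweezers experiments on DNA-condensing
proteins — and a Brownian-dynamics engine that simulates those experiments
so every stage of the analysis can be tested without instrument data.

Centromere-binding proteins such as ParB (Spo0J) condense the DNA around
their *parS* sites into bridged, loopy networks. In a magnetic-tweezers
assay, this shows up as the shortening of a single bead-tethered DNA
molecule held at sub-piconewton force, as hysteresis when supercoils are
unwound through a bridged tether, and as the extra mechanical work needed
to stretch a protein-bound molecule. `tetherkit` implements the full
analysis chain for such experiments, together with the accompanying
solution assays: cooperative-binding (PIFE/Hill) fits, NMR chemical-shift
perturbation mapping, CD melt fitting, H/D-exchange half-lives, and
native-MS charge-series mass determination.

## Core models and statistics

**Worm-like chain.** Bare DNA elasticity follows the Marko–Siggia
interpolation
`F(z) = (k_BT/L_p) [ 1/(4(1 − z/L_c)²) − 1/4 + z/L_c ]`
with persistence length `L_p` (~50 nm) and contour length `L_c`
(0.34 nm/bp). Force–extension curves of non-condensed molecules are
fitted over `(L_p, L_c)` with the residual in extension.

**Force calibration.** The applied force is not measured; it is inferred
from bead fluctuations by equipartition, `F = k_BT ⟨z⟩ / Var(x)`, with
block-bootstrap errors, or spectrally from the corner frequency of the
transverse power spectrum (fitted in its exact sampled form to avoid
aliasing bias).

**Condensation statistics.**
- condensation ratio `C_r = (z₀ − z)/z₀`, the fractional shortening
  relative to the pre-protein extension `z₀` at the permissive force
  (0.34 pN), with `z` averaged over 120 points (3 Hz) at the evaluation
  time;
- condensation work `ΔW = ∫₀^{z_max} (F_protein − F_DNA) dz` by the
  trapezoidal rule, `z_max` being the bare-DNA extension at the maximum
  applied force (4 pN);
- plectoneme-stabilisation hysteresis: the area between winding and
  unwinding rotation–extension branches, plus a calibrated mean-shift
  step detector for discrete bridging-release events.

**Cooperative binding.** PIFE titrations are quantified as emission-scan
area (560–600 nm) relative to a DNA-only control and fitted with the Hill
model `Y = B_max [P]ʰ / (K_d_appʰ + [P]ʰ)`, singly or globally across
variants with one shared Hill coefficient.

**Synthetic data.** `tethersim` integrates the overdamped Langevin
dynamics of the bead–DNA system (transverse pendulum stiffness `F/⟨z⟩`,
longitudinal WLC restoring force), overlays Bell-model loop
capture/release kinetics for condensation, and generates rotation-
extension curves, titrations, melts and charge-state series. Every
generator is a pure function of its parameters and an explicit seed.

## Worked example

```python
import tetherkit as tk

cfg = tk.TetherConfig()                       # 1 um bead, ~6 kbp tether, 120 Hz
sched = tk.ForceSchedule.force_steps(total_s=240.0)   # 4 -> 0.02 pN in 20 steps

bare = tk.build_fec(tk.simulate_tether(cfg, sched, seed=600), sched)
cond = tk.build_fec(
    tk.simulate_condensation(cfg, tk.CondensationModel(), sched, seed=601), sched)
work = tk.condensation_work(cond, bare)
print(f"dW = {work.delta_w:.0f} pN nm = {work.delta_w_kbt:.0f} kBT")
# dW = 105 pN nm = 26 kBT (zmax = 1892 nm)

est = tk.estimate_force_variance(
    tk.simulate_tether(cfg, tk.ForceSchedule(((60.0, 1.0),)), seed=101))
print(f"F = {est.force:.3f} +/- {est.standard_error:.3f} pN")
# F = 1.023 +/- 0.025 pN

wt  = tk.simulate_titration(noise_sd=0.02, replicates=3, seed=7, label="wild-type")
mut = tk.simulate_titration(kd_app=493.0, noise_sd=0.02, replicates=3,
                            seed=8, label="R149G")
for f in tk.fit_hill_global([wt, mut]).shared:
    print(f"{f.label}: Kd_app = {f.kd_app:.0f} +/- {f.kd_se:.0f} nM, "
          f"h = {f.hill_coefficient:.2f} +/- {f.hill_se:.2f}")
# wild-type: Kd_app = 369 +/- 5 nM, h = 3.12 +/- 0.08
# R149G:     Kd_app = 499 +/- 7 nM, h = 3.12 +/- 0.08
```

The condensation work says the protein stored ~26 k_BT of mechanical work
in the tether relative to bare DNA over this (shortened, 4-minute)
force ramp; the force estimate recovers the simulated 1 pN hold to ~2%;
and the global Hill fit recovers the generator affinities of the two
variants with a common cooperativity.

A command-line surface mirrors the library
(`tetherkit pipeline run.cfg simulate-condense fec work`, plus
per-stage subcommands); every output TSV carries a provenance header with
the tool version, config hash, seed and input digests.

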