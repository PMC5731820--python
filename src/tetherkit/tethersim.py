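"""Synthetic-data engine: Brownian bead-tether dynamics and assay fixtures.

The central simulator reproduces the observable of a magnetic-tweezers
experiment: a micron-scale superparamagnetic bead tethered to a surface by
a single DNA molecule, held at a constant (stepped) force and tracked at
the camera rate.  The bead is overdamped, so its motion is a Langevin
process with drag ``gamma = 6 pi eta r``:

* transversally (x, y) it behaves as an inverted pendulum of length <z>,
  i.e. an Ornstein-Uhlenbeck process with stiffness ``kx = F/<z>`` and
  diffusion ``kBT/gamma``;
* longitudinally (z) it fluctuates about the worm-like-chain extension at
  the applied force, restored by ``F - F_wlc(z)``.

Protein-induced condensation is overlaid as a continuous-time Markov jump
process on the *effective* contour length: capture events (loop
formation) shorten it by a truncated-normal loop size at a Bell-model
rate ``k_c0 * exp(-F x_c / kBT)``, release events restore it at
``k_r0 * exp(+F x_r / kBT)``.  This generates the qualitative
phenomenology seen for condensing DNA-bridging proteins -- condensation
only below a few tenths of a pN, stepwise force-induced decondensation --
without claiming the (unmeasured) microscopic rates.

The module also generates rotation-extension (plectoneme) curves with
optional bridging-induced hysteresis, Hill-model titrations, two-state
thermal melts and native-MS charge-state series, and folds the hairpin
substrates used to probe non-specific DNA binding.  Every generator is a
pure function of its parameters and an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.signal import lfilter

from .binding import TitrationDataset, hill_response
from .polymer import KBT_ROOM, WLCParams, wlc_extension, wlc_stiffness
from .spectra import PROTON_MASS, MeltCurve

__all__ = [
    "BOLTZMANN_PN_NM",
    "TetherConfig",
    "ForceSchedule",
    "CondensationModel",
    "Trajectory",
    "ConfigurationError",
    "NoHairpinError",
    "simulate_tether",
    "simulate_condensation",
    "simulate_rotation_extension",
    "winding_schedule",
    "simulate_titration",
    "simulate_melt",
    "simulate_charge_series",
    "hairpin_stem",
]

BOLTZMANN_PN_NM = 1.380649e-2
"""Boltzmann constant in pN*nm per kelvin."""

FORCE_FLOOR = 0.01
"""Minimum admissible applied force (pN); keeps the pendulum stiffness finite."""


class ConfigurationError(ValueError):
    """Raised for unstable or inconsistent simulation settings."""


class NoHairpinError(ValueError):
    """Raised when a sequence cannot fold into a stem-loop."""


@dataclass(frozen=True)
class TetherConfig:
    """Geometry and sampling of the bead-DNA assembly.

    Defaults describe the nominal instrument: a 1 um superparamagnetic
    bead (radius 0.5 um) in water at room temperature, tracked at 120 Hz,
    on a ~6 kbp tether (Lc = 2040 nm at 0.34 nm/bp, Lp = 50 nm).
    """

    bead_radius: float = 0.5  # um
    viscosity: float = 1.0e-3  # Pa*s
    temperature: float = 298.0  # K
    dna: WLCParams = field(default_factory=lambda: WLCParams(50.0, 2040.0))
    acquisition_rate: float = 120.0  # Hz

    def __post_init__(self):
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")
        if self.viscosity <= 0 or self.temperature <= 0:
            raise ValueError("viscosity and temperature must be positive")
        if self.acquisition_rate <= 0:
            raise ValueError("acquisition_rate must be positive")

    @property
    def kbt(self) -> float:
        """Thermal energy in pN*nm."""
        return BOLTZMANN_PN_NM * self.temperature

    @property
    def gamma(self) -> float:
        """Stokes drag 6*pi*eta*r in pN*s/nm."""
        # eta [Pa*s] * r [m] gives N*s/m; 1 N*s/m = 1e3 pN*s/nm
        return 6.0 * math.pi * self.viscosity * (self.bead_radius * 1e-6) * 1e3


@dataclass(frozen=True)
class ForceSchedule:
    """Ordered constant-force segments, optionally with a turns profile."""

    segments: tuple[tuple[float, float], ...]  # (duration_s, force_pN)
    turns_profile: tuple[tuple[float, float], ...] | None = None  # (time_s, turns)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        object.__setattr__(self, "segments", tuple((float(d), float(f))
                                                   for d, f in self.segments))
        for d, f in self.segments:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            if f < FORCE_FLOOR:
                raise ValueError(
                    f"forces must be >= the {FORCE_FLOOR} pN floor (got {f} pN)"
                )

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    @classmethod
    def force_steps(
        cls,
        f_max: float = 4.0,
        f_min: float = 0.02,
        n_steps: int = 20,
        total_s: float = 780.0,
    ) -> "ForceSchedule":
        """Stepped force-extension protocol: ``n_steps`` logarithmically
        spaced forces from ``f_max`` down to ``f_min``, equal dwell times,
        13 minutes in total by default."""
        forces = np.geomspace(f_max, f_min, n_steps)
        dwell = total_s / n_steps
        return cls(tuple((dwell, float(f)) for f in forces))


@dataclass(frozen=True)
class CondensationModel:
    """Bell-model loop capture/release kinetics on the effective contour.

    Rates are force dependent: capture slows with force as
    ``exp(-F*bell_distance/kBT)``, release accelerates as
    ``exp(+F*release_bell_distance/kBT)``.  Loop sizes are truncated
    normal; the effective contour never drops below
    ``min_tether_fraction`` of the full contour length.  Defaults give a
    tether that condenses fully within minutes below ~0.34 pN and
    decondenses promptly at a few pN.
    """

    capture_rate_zero_force: float = 2.0  # 1/s
    bell_distance: float = 30.0  # nm
    release_rate_zero_force: float = 0.01  # 1/s
    release_bell_distance: float = 15.0  # nm
    loop_size_mean: float = 50.0  # nm
    loop_size_sd: float = 20.0  # nm
    min_tether_fraction: float = 0.2

    def __post_init__(self):
        if self.capture_rate_zero_force < 0 or self.release_rate_zero_force < 0:
            raise ValueError("rates must be non-negative")
        if self.loop_size_mean <= 0 or self.loop_size_sd < 0:
            raise ValueError("loop_size_mean must be positive, sd non-negative")
        if not (0 < self.min_tether_fraction <= 1):
            raise ValueError("min_tether_fraction must lie in (0, 1]")

    def capture_rate(self, force: float, kbt: float = KBT_ROOM) -> float:
        return self.capture_rate_zero_force * math.exp(-force * self.bell_distance / kbt)

    def release_rate(self, force: float, kbt: float = KBT_ROOM) -> float:
        return self.release_rate_zero_force * math.exp(
            force * self.release_bell_distance / kbt
        )


@dataclass
class Trajectory:
    """Time-stamped bead coordinates plus the applied force/turns schedule.

    ``effective_contour`` is simulation ground truth and absent (None) for
    real data.
    """

    time: np.ndarray  # s
    x: np.ndarray  # nm
    y: np.ndarray  # nm
    z: np.ndarray  # nm
    applied_force: np.ndarray  # pN
    turns: np.ndarray
    effective_contour: np.ndarray | None = None
    acquisition_rate: float = 120.0  # Hz

    def __post_init__(self):
        n = self.time.size
        for name in ("x", "y", "z", "applied_force", "turns"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} length mismatch")
        if self.effective_contour is not None and self.effective_contour.size != n:
            raise ValueError("column 'effective_contour' length mismatch")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.time.size)

    def window(self, t_min: float, t_max: float) -> "Trajectory":
        """Sub-trajectory with t_min <= t < t_max."""
        m = (self.time >= t_min) & (self.time < t_max)
        return Trajectory(
            self.time[m], self.x[m], self.y[m], self.z[m],
            self.applied_force[m], self.turns[m],
            None if self.effective_contour is None else self.effective_contour[m],
            self.acquisition_rate,
        )

    def constant_force_segments(self) -> list[tuple[float, slice]]:
        """Maximal runs of constant applied force, as (force, slice) pairs."""
        f = self.applied_force
        edges = np.nonzero(np.diff(f) != 0)[0] + 1
        bounds = np.concatenate([[0], edges, [f.size]])
        return [(float(f[a]), slice(int(a), int(b)))
                for a, b in zip(bounds[:-1], bounds[1:])]

    @classmethod
    def concatenate(cls, parts: list["Trajectory"]) -> "Trajectory":
        """Join trajectories end to end, shifting times to stay uniform."""
        rate = parts[0].acquisition_rate
        times, offset = [], 0.0
        for p in parts:
            if p.acquisition_rate != rate:
                raise ValueError("acquisition rates differ between parts")
            times.append(p.time - p.time[0] + offset)
            offset = times[-1][-1] + 1.0 / rate
        has_lc = all(p.effective_contour is not None for p in parts)
        return cls(
            np.concatenate(times),
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.z for p in parts]),
            np.concatenate([p.applied_force for p in parts]),
            np.concatenate([p.turns for p in parts]),
            np.concatenate([p.effective_contour for p in parts]) if has_lc else None,
            rate,
        )


# ---------------------------------------------------------------------------
# Brownian-dynamics kernel
# ---------------------------------------------------------------------------

# Minimum pendulum arm (nm) entering kx = F/z; keeps the transverse
# stiffness finite when z fluctuates toward zero at very low force.
_PENDULUM_FLOOR = 50.0


@njit(cache=True)
def _bd_segment(rng, out_x, out_y, out_z, out_lc, i0, n_rec, spp, dt,
                force, lp, kbt, gamma, x, y, z, lc_eff,
                kc, kr, loop_mu, loop_sd, lc_min, lc_full):
    """Integrate one constant-force segment, recording every ``spp`` steps.

    One uniform variate is consumed per internal step for the jump test
    regardless of the rates, so zeroed kinetics reproduce the bare tether
    bit-for-bit at equal seeds.  Returns the updated state.
    """
    sz = math.sqrt(2.0 * kbt * dt / gamma)
    c = kbt / lp
    p_cap = kc * dt
    p_rel = kr * dt
    for k in range(n_rec):
        for _ in range(spp):
            # longitudinal Euler-Maruyama step with the nonlinear WLC force
            t = z / lc_eff
            if t > 0.999:
                t = 0.999
            one_m = 1.0 - t
            fw = c * (0.25 / (one_m * one_m) - 0.25 + t)
            z += (force - fw) * dt / gamma + sz * rng.standard_normal()
            if z < 0.0:
                z = -z
            z_cap = 0.999 * lc_eff
            if z > z_cap:
                z = z_cap
            # transverse OU steps (pendulum stiffness F/z), exact update
            zp = z if z > _PENDULUM_FLOOR else _PENDULUM_FLOOR
            kx = force / zp
            a = math.exp(-kx * dt / gamma)
            s = math.sqrt(kbt / kx * (1.0 - a * a))
            x = a * x + s * rng.standard_normal()
            y = a * y + s * rng.standard_normal()
            # condensation jump process
            u = rng.random()
            if u < p_cap:
                if lc_eff > lc_min:
                    loop = loop_mu + loop_sd * rng.standard_normal()
                    while loop <= 0.0:
                        loop = loop_mu + loop_sd * rng.standard_normal()
                    lc_eff -= loop
                    if lc_eff < lc_min:
                        lc_eff = lc_min
                    if z > 0.999 * lc_eff:
                        z = 0.999 * lc_eff
            elif u < p_cap + p_rel:
                if lc_eff < lc_full:
                    loop = loop_mu + loop_sd * rng.standard_normal()
                    while loop <= 0.0:
                        loop = loop_mu + loop_sd * rng.standard_normal()
                    lc_eff += loop
                    if lc_eff > lc_full:
                        lc_eff = lc_full
        out_x[i0 + k] = x
        out_y[i0 + k] = y
        out_z[i0 + k] = z
        out_lc[i0 + k] = lc_eff
    return x, y, z, lc_eff


def _segment_timestep(config: TetherConfig, force: float, lc_stiff: float,
                      dt_override: float | None) -> tuple[float, int]:
    """Internal timestep and steps-per-sample for one segment.

    dt <= 0.1 * gamma / kz, with kz the WLC stiffness at the equilibrium
    extension of the stiffest admissible contour, then snapped so an
    integer number of steps fits one recorded sample.
    """
    params = WLCParams(config.dna.persistence_length, lc_stiff, config.kbt)
    z_eq = wlc_extension(force, params)
    kz = wlc_stiffness(z_eq, params)
    if dt_override is not None:
        dt_max = dt_override
        if kz * dt_max / config.gamma >= 0.5:
            raise ConfigurationError(
                f"timestep unstable: kz*dt/gamma = {kz * dt_max / config.gamma:.2f} >= 0.5"
            )
    else:
        dt_max = 0.1 * config.gamma / kz
    spp = max(1, math.ceil(1.0 / (config.acquisition_rate * dt_max)))
    dt = 1.0 / (config.acquisition_rate * spp)
    return dt, spp


def _simulate(config: TetherConfig, cmodel: CondensationModel | None,
              schedule: ForceSchedule, seed: int,
              dt_override: float | None = None) -> Trajectory:
    rng = np.random.default_rng(seed)
    dna = config.dna
    kbt = config.kbt
    lc_full = dna.contour_length
    condensing = cmodel is not None and cmodel.capture_rate_zero_force > 0
    lc_min = cmodel.min_tether_fraction * lc_full if cmodel is not None else lc_full
    lc_stiff = lc_min if condensing else lc_full

    rate = config.acquisition_rate
    n_per_seg = [max(1, round(d * rate)) for d, _ in schedule.segments]
    n_total = sum(n_per_seg)
    out_x = np.empty(n_total)
    out_y = np.empty(n_total)
    out_z = np.empty(n_total)
    out_lc = np.empty(n_total)
    forces = np.empty(n_total)

    params_full = WLCParams(dna.persistence_length, lc_full, kbt)
    x, y = 0.0, 0.0
    z = float(wlc_extension(schedule.segments[0][1], params_full))
    lc_eff = lc_full
    i0 = 0
    for (duration, force), n_rec in zip(schedule.segments, n_per_seg):
        dt, spp = _segment_timestep(config, force, lc_stiff, dt_override)
        if cmodel is not None:
            kc = cmodel.capture_rate(force, kbt)
            kr = cmodel.release_rate(force, kbt)
            loop_mu, loop_sd = cmodel.loop_size_mean, cmodel.loop_size_sd
        else:
            kc = kr = 0.0
            loop_mu, loop_sd = 1.0, 0.0
        x, y, z, lc_eff = _bd_segment(
            rng, out_x, out_y, out_z, out_lc, i0, n_rec, spp, dt,
            force, dna.persistence_length, kbt, config.gamma,
            x, y, z, lc_eff, kc, kr, loop_mu, loop_sd, lc_min, lc_full,
        )
        forces[i0:i0 + n_rec] = force
        i0 += n_rec

    time = np.arange(n_total) / rate
    return Trajectory(time, out_x, out_y, out_z, forces,
                      np.zeros(n_total), out_lc, rate)


def simulate_tether(config: TetherConfig, schedule: ForceSchedule, seed: int,
                    *, dt_override: float | None = None) -> Trajectory:
    """Brownian dynamics of a bare bead-DNA tether under a force schedule.

    Overdamped Langevin integration (see module docstring); identical
    seeds give identical trajectories.  ``dt_override`` forces a specific
    internal timestep and raises :class:`ConfigurationError` when it is
    unstable.
    """
    return _simulate(config, None, schedule, seed, dt_override)


def simulate_condensation(config: TetherConfig, cmodel: CondensationModel,
                          schedule: ForceSchedule, seed: int,
                          *, dt_override: float | None = None) -> Trajectory:
    """Tether dynamics with force-dependent loop capture/release overlaid.

    The recorded z follows the instantaneous worm-like chain with the
    jumping effective contour; ``effective_contour`` in the output is the
    ground truth.  With zero capture rate this degenerates bit-for-bit to
    :func:`simulate_tether` at the same seed.
    """
    return _simulate(config, cmodel, schedule, seed, dt_override)


# ---------------------------------------------------------------------------
# Rotation-extension (plectoneme) simulator
# ---------------------------------------------------------------------------


def winding_schedule(n_max: int = 60, dwell_s: float = 0.25,
                     unwind: bool = True) -> list[tuple[float, int]]:
    """Turn-by-turn winding (0 -> n_max) and optional unwinding profile."""
    steps = [(dwell_s, n) for n in range(0, n_max + 1)]
    if unwind:
        steps += [(dwell_s, n) for n in range(n_max - 1, -1, -1)]
    return steps


def simulate_rotation_extension(
    config: TetherConfig,
    turns_schedule: list[tuple[float, int]],
    bridged: bool,
    seed: int,
    *,
    force: float = 4.0,
    n_buckling: int = 30,
    slope_nm_per_turn: float = 27.0,
    trap_probability: float = 0.35,
    mean_chunk_turns: float = 4.0,
) -> Trajectory:
    """Rotation-extension curve of a torsionally constrained tether.

    Mean extension is flat up to the buckling turn number and decreases
    linearly (``slope_nm_per_turn``) beyond it as plectonemes absorb the
    added linking number.  With ``bridged=True``, protein bridges trap a
    random subset of the plectonemic turns at the start of unwinding: each
    plectonemic turn is trapped with ``trap_probability``, trapped turns
    are grouped into chunks (~``mean_chunk_turns`` each) and each chunk is
    only released -- as a discrete extension step -- once the magnet turn
    count falls below a uniformly drawn threshold.  The unwinding branch
    therefore lies below the winding branch, producing hysteresis; with
    ``bridged=False`` both branches coincide in expectation.

    Gaussian-correlated (OU) extension noise rides on the mean, with the
    stiffness of the worm-like chain at the holding force.
    """
    if force < FORCE_FLOOR:
        raise ValueError(f"force must be >= the {FORCE_FLOOR} pN floor")
    rng = np.random.default_rng(seed)
    rate = config.acquisition_rate
    dna = config.dna
    z0 = float(wlc_extension(force, dna))

    # per-sample turns trace
    counts = [max(1, round(d * rate)) for d, _ in turns_schedule]
    turns = np.concatenate([
        np.full(c, float(n)) for c, (_, n) in zip(counts, turns_schedule)
    ])
    n_total = turns.size

    # trapped-chunk bookkeeping (drawn up front for determinism)
    step_turns = np.array([n for _, n in turns_schedule], dtype=float)
    peak_idx = int(np.argmax(step_turns))
    n_peak = step_turns[peak_idx]
    chunks: list[tuple[int, float]] = []  # (release threshold, turns in chunk)
    if bridged:
        p_plect = int(max(0.0, n_peak - n_buckling))
        trapped = int(rng.binomial(p_plect, trap_probability))
        remaining = trapped
        while remaining > 0:
            size = int(min(remaining, 1 + rng.poisson(mean_chunk_turns - 1)))
            threshold = int(rng.integers(3, max(4, n_buckling - 2)))
            chunks.append((threshold, float(size)))
            remaining -= size

    # stored plectonemic turns per schedule step
    stored_steps = np.empty(step_turns.size)
    for i, n in enumerate(step_turns):
        base = max(0.0, abs(n) - n_buckling)
        if bridged and i > peak_idx:
            trapped_now = sum(size for thr, size in chunks if n > thr)
            stored_steps[i] = max(base, trapped_now)
        else:
            stored_steps[i] = base
    stored = np.concatenate([
        np.full(c, s) for c, s in zip(counts, stored_steps)
    ])
    z_mean = np.maximum(z0 - slope_nm_per_turn * stored, 0.05 * z0)

    # OU noise about the mean (AR(1) via lfilter), longitudinal & transverse
    kz = wlc_stiffness(z0, dna)
    kx = force / max(z0, _PENDULUM_FLOOR)

    def ou(k: float) -> np.ndarray:
        a = math.exp(-k / (config.gamma * rate))
        sig = math.sqrt(config.kbt / k)
        innov = rng.standard_normal(n_total) * sig * math.sqrt(1.0 - a * a)
        innov[0] = rng.standard_normal() * sig
        return lfilter([1.0], [1.0, -a], innov)

    z = z_mean + ou(kz)
    x = ou(kx)
    y = ou(kx)
    time = np.arange(n_total) / rate
    return Trajectory(time, x, y, z, np.full(n_total, force), turns,
                      None, rate)


# ---------------------------------------------------------------------------
# Fixture generators for the binding and spectroscopy stages
# ---------------------------------------------------------------------------


def simulate_titration(
    bmax: float = 1.0,
    hill_coefficient: float = 3.2,
    kd_app: float = 361.0,
    concentrations=None,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    label: str = "wild-type",
) -> TitrationDataset:
    """Hill-model titration with Gaussian noise.

    Defaults reproduce the wild-type binding isotherm (Kd_app = 361 nM,
    h = 3.2); a weakened-affinity variant fixture uses kd_app = 493 nM.
    Concentrations are nM dimer; default grid is 12 log-spaced points
    spanning a factor ~30 either side of Kd_app.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if concentrations is None:
        concentrations = np.geomspace(kd_app / 30.0, kd_app * 30.0, 12)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    conc_all = np.tile(conc, replicates)
    rep_ids = np.repeat(np.arange(replicates), conc.size)
    y = hill_response(conc_all, bmax, hill_coefficient, kd_app)
    y = y + rng.normal(0.0, noise_sd, size=y.shape) if noise_sd > 0 else y
    return TitrationDataset(label, conc_all, y, rep_ids)


def simulate_melt(
    tm: float = 68.0,
    transition_width: float = 4.0,
    baseline_folded: float = -15000.0,
    baseline_unfolded: float = -3000.0,
    temperatures=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
) -> MeltCurve:
    """Two-state thermal melt between linear baselines plus Gaussian noise.

    Defaults emulate the wild-type CTD melt (Tm = 68 degC); the
    destabilised triple-mutant fixture uses tm = 53.  Temperatures default
    to 5..90 degC at 5 degC increments.
    """
    if transition_width <= 0:
        raise ValueError("transition_width must be positive")
    if temperatures is None:
        temperatures = np.arange(5.0, 91.0, 5.0)
    t = np.asarray(temperatures, dtype=float)
    if np.any(t < -50) or np.any(t > 150):
        raise ValueError("temperatures outside a physically sensible range")
    folded = baseline_folded + baseline_slopes[0] * t
    unfolded = baseline_unfolded + baseline_slopes[1] * t
    frac = 1.0 / (1.0 + np.exp((tm - t) / transition_width))
    signal = folded + (unfolded - folded) * frac
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0.0, noise_sd, t.shape)
    return MeltCurve(t, signal, units="mre")


def simulate_charge_series(
    neutral_mass: float,
    charges,
    mz_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """m/z peaks of one species at the given positive charge states.

    Peaks sit at (M + z*mp)/z with mp the proton mass, plus optional
    Gaussian m/z noise; returned sorted by descending m/z (ascending
    charge).
    """
    zs = np.asarray(list(charges), dtype=int)
    if zs.size == 0:
        raise ValueError("charge list must not be empty")
    if np.any(zs < 1) or np.unique(zs).size != zs.size:
        raise ValueError("charges must be distinct integers >= 1")
    zs = np.sort(zs)
    mz = (neutral_mass + zs * PROTON_MASS) / zs
    if mz_noise > 0:
        mz = mz + np.random.default_rng(seed).normal(0.0, mz_noise, mz.shape)
    return mz


# ---------------------------------------------------------------------------
# Hairpin folding of printed oligonucleotide substrates
# ---------------------------------------------------------------------------

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def hairpin_stem(sequence: str) -> tuple[int, int]:
    """Stem and loop lengths of a self-complementary hairpin oligo.

    Base i pairs with base L+1-i (1-based); contiguous Watson-Crick pairs
    (A-T and G-C only, no wobble) are counted inward from the termini
    until the first mismatch, or until fewer than 3 unpaired bases would
    remain for the loop.  Returns (stem_bp, loop_nt).

    Raises
    ------
    ValueError
        Sequence shorter than 7 nt or containing non-ACGT characters.
    NoHairpinError
        No admissible stem (terminal bases do not pair).
    """
    seq = sequence.strip().upper()
    if any(b not in _WC for b in seq):
        bad = sorted({b for b in seq if b not in _WC})
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")
    n = len(seq)
    if n < 7:
        raise ValueError("sequence must be at least 7 nt")
    max_stem = (n - 3) // 2
    stem = 0
    for i in range(max_stem):
        if _WC[seq[i]] == seq[n - 1 - i]:
            stem += 1
        else:
            break
    if stem == 0:
        raise NoHairpinError("no hairpin: terminal bases cannot form a Watson-Crick pair")
    return stem, n - 2 * stem
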