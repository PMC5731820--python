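"""Condensation statistics: force-extension curves, condensation ratio,
condensation work, plectoneme hysteresis and step detection.

Three quantities summarise protein-induced DNA condensation in a
tethered-bead experiment:

* the force-extension curve, built per constant-force step (discarding an
  equilibration transient) and averaged across molecules with the SEM
  taken over molecules;
* the condensation ratio ``Cr = (z0 - z)/z0``, the fractional shortening
  of the tether relative to its pre-protein extension z0 at the
  permissive force (0.34 pN);
* the condensation work ``dW = integral_0^zmax (F_protein - F_DNA) dz``
  (trapezoidal rule), the excess mechanical work stored by the protein
  relative to bare DNA up to the extension zmax reached at the maximum
  applied force (4 pN).

Plectoneme-stabilisation assays are quantified by the hysteresis area
between winding and unwinding rotation-extension branches, and discrete
bridging-release events are located with a sliding two-window mean-shift
step detector with a calibrated null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

from .calibrate import boxcar_filter
from .polymer import KBT_ROOM
from .tethersim import ForceSchedule, Trajectory

__all__ = [
    "ForceExtensionCurve",
    "CondensationStats",
    "WorkResult",
    "HysteresisResult",
    "build_fec",
    "aggregate_fec",
    "condensation_ratio",
    "condensation_ratio_from_traj",
    "condensation_work",
    "hysteresis",
    "rotation_branches",
    "detect_steps",
]


@dataclass
class ForceExtensionCurve:
    """Per-force-step mean extensions with SEM and molecule count."""

    force: np.ndarray  # pN, distinct
    mean_extension: np.ndarray  # nm
    sem: np.ndarray  # nm
    n_molecules: np.ndarray  # count per step
    label: str = ""

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.mean_extension = np.asarray(self.mean_extension, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_molecules = np.asarray(self.n_molecules, dtype=int)
        n = self.force.size
        for name in ("mean_extension", "sem", "n_molecules"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} length mismatch")
        if np.unique(self.force).size != n:
            raise ValueError("forces must be distinct")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")
        if np.any(self.n_molecules < 1):
            raise ValueError("n_molecules must be >= 1")

    def __len__(self) -> int:
        return int(self.force.size)


@dataclass(frozen=True)
class CondensationStats:
    """Condensation ratio Cr = (z0 - z)/z0."""

    z0: float  # nm, pre-protein extension at the permissive force
    z: float  # nm, post-treatment equilibrium extension
    cr: float
    negative: bool = False  # True when the tether ended up longer than z0

    def __post_init__(self):
        if self.z0 <= 0:
            raise ValueError("z0 must be positive")
        if not np.isclose(self.cr, (self.z0 - self.z) / self.z0):
            raise ValueError("cr inconsistent with (z0 - z)/z0")


@dataclass(frozen=True)
class WorkResult:
    """Condensation work dW in pN*nm and thermal units."""

    delta_w: float  # pN*nm
    delta_w_kbt: float
    zmax: float  # nm, bare extension at the maximum applied force
    monotonised: bool = False  # protein curve made monotone by isotonic averaging
    extrapolated: bool = False  # constant-force extension below measured range


@dataclass(frozen=True)
class HysteresisResult:
    """Hysteresis between winding (forward) and unwinding (backward) branches.

    ``area`` = trapezoidal integral of (forward - backward) extension over
    turns: positive when the unwinding branch lies below the winding one,
    i.e. when extension recovery is deferred by trapped plectonemes.
    """

    area: float  # nm*turns
    max_deviation: float  # nm, signed value of the largest |difference|
    steps_detected: tuple[tuple[float, float], ...]  # (turns, size nm)


def build_fec(
    traj: Trajectory,
    schedule: ForceSchedule | None = None,
    *,
    discard_fraction: float = 0.1,
    label: str = "",
) -> ForceExtensionCurve:
    """Single-molecule force-extension curve from a stepped-force trajectory.

    Per force step, the first ``discard_fraction`` of samples is discarded
    as equilibration and the remainder averaged; the SEM is the
    within-segment standard error and ``n_molecules`` is 1.  When
    ``schedule`` is omitted, segments are inferred from constant-force
    runs of the trajectory.

    Raises
    ------
    ValueError
        Schedule extends past the trajectory, a segment retains < 10
        samples, or forces are not constant within segments.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    if schedule is not None:
        if schedule.total_duration > traj.time[-1] - traj.time[0] + 1.5 / traj.acquisition_rate:
            raise ValueError("schedule extends past the end of the trajectory")
        t0 = traj.time[0]
        segs = []
        for duration, force in schedule.segments:
            w = traj.window(t0, t0 + duration)
            if w.applied_force.size and not np.allclose(w.applied_force, force, rtol=1e-6):
                raise ValueError(
                    f"trajectory force differs from schedule near t = {t0:g} s"
                )
            segs.append((force, w.z))
            t0 += duration
    else:
        segs = [(f, traj.z[s]) for f, s in traj.constant_force_segments()]

    forces, means, sems = [], [], []
    for force, zvals in segs:
        n_skip = int(np.floor(discard_fraction * zvals.size))
        kept = zvals[n_skip:]
        if kept.size < 10:
            raise ValueError(
                f"force step at {force:g} pN retains only {kept.size} samples (< 10)"
            )
        forces.append(force)
        means.append(float(np.mean(kept)))
        sems.append(float(np.std(kept, ddof=1) / np.sqrt(kept.size)))
    return ForceExtensionCurve(
        np.array(forces), np.array(means), np.array(sems),
        np.ones(len(forces), dtype=int), label,
    )


def aggregate_fec(curves: list[ForceExtensionCurve], *,
                  label: str = "") -> ForceExtensionCurve:
    """Mean curve across molecules; SEM is over molecules (sd/sqrt(N)).

    All curves must share the same force grid.  The molecule-to-molecule
    standard deviation uses the sample convention (ddof=1), so two curves
    offset by +/-delta give sem = delta.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    ref = curves[0].force
    bad = [i for i, c in enumerate(curves)
           if c.force.size != ref.size or not np.allclose(c.force, ref)]
    if bad:
        raise ValueError(
            f"curves {bad} have force grids differing from curve 0; "
            "aggregate requires identical force steps"
        )
    z = np.vstack([c.mean_extension for c in curves])
    n = len(curves)
    # sample sd over molecules (ddof=1) divided by sqrt(N)
    sem = np.std(z, axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(ref.size)
    return ForceExtensionCurve(
        ref.copy(), z.mean(axis=0), sem,
        np.full(ref.size, n, dtype=int), label,
    )


def condensation_ratio(z0: float, z: float) -> CondensationStats:
    """Cr = (z0 - z)/z0; may be negative (flagged) if the tether lengthened."""
    if z0 <= 0:
        raise ValueError("z0 must be positive")
    cr = (z0 - z) / z0
    return CondensationStats(z0=float(z0), z=float(z), cr=float(cr), negative=cr < 0)


def condensation_ratio_from_traj(
    traj: Trajectory,
    t_eval: float = 390.0,
    permissive_force: float = 0.34,
    *,
    z0: float | None = None,
    filter_rate: float = 3.0,
    n_points: int = 120,
    discard_fraction: float = 0.1,
) -> CondensationStats:
    """Condensation ratio from a trajectory, following the standard protocol.

    z0 is the equilibrated mean extension of the first contiguous run at
    the permissive force (the pre-protein reference), unless supplied
    explicitly.  z is the mean of ``n_points`` samples of the trajectory
    filtered to ``filter_rate`` Hz, centred at ``t_eval`` seconds.

    Raises
    ------
    ValueError
        No reference segment at the permissive force, or fewer than
        ``n_points`` filtered samples available around ``t_eval``.
    """
    if z0 is None:
        for force, sl in traj.constant_force_segments():
            if np.isclose(force, permissive_force, rtol=1e-3):
                zvals = traj.z[sl]
                n_skip = int(np.floor(discard_fraction * zvals.size))
                z0 = float(np.mean(zvals[n_skip:]))
                break
        else:
            raise ValueError(
                f"no reference segment at the permissive force {permissive_force} pN"
            )
    filt = boxcar_filter(traj, filter_rate)
    centre = int(np.argmin(np.abs(filt.time - t_eval)))
    if abs(filt.time[centre] - t_eval) > 1.0 / filter_rate:
        raise ValueError(f"t_eval = {t_eval} s lies outside the trajectory")
    half = n_points // 2
    lo, hi = centre - half, centre - half + n_points
    if lo < 0 or hi > len(filt):
        raise ValueError(
            f"fewer than {n_points} filtered samples available around t = {t_eval} s"
        )
    z = float(np.mean(filt.z[lo:hi]))
    return condensation_ratio(z0, z)


def _as_force_of_extension(curve: ForceExtensionCurve,
                           strict: bool) -> tuple[np.ndarray, np.ndarray, bool]:
    """Sort a curve by extension and isotonic-average the force.

    With ``strict=True`` (the bare-DNA slot) substantial non-monotonicity
    -- isotonic adjustments above 5% of the force range -- is an error;
    thermal scatter near plateaus is repaired silently either way.
    """
    order = np.argsort(curve.mean_extension, kind="stable")
    z = curve.mean_extension[order]
    f = curve.force[order]
    # collapse exactly duplicated extensions by averaging force
    if np.unique(z).size != z.size:
        zu, inv = np.unique(z, return_inverse=True)
        fu = np.zeros_like(zu)
        cnt = np.zeros_like(zu)
        np.add.at(fu, inv, f)
        np.add.at(cnt, inv, 1.0)
        z, f = zu, fu / cnt
    monotonised = False
    if np.any(np.diff(f) < 0):
        f_iso = isotonic_regression(f, increasing=True).x
        adjustment = float(np.max(np.abs(f_iso - f)))
        if strict and adjustment > 0.05 * max(float(np.ptp(f)), 1e-300):
            raise ValueError("bare curve is non-monotone in extension")
        f = f_iso
        monotonised = True
    return z, f, monotonised


def condensation_work(
    curve_protein: ForceExtensionCurve,
    curve_bare: ForceExtensionCurve,
    thermal_energy: float = KBT_ROOM,
) -> WorkResult:
    """Condensation work dW = integral over [0, zmax] of (F_protein - F_DNA) dz.

    Both curves are re-expressed as F(z) by sorting on extension; the
    protein curve, which may be non-monotone while condensed, is made
    monotone by isotonic averaging (flagged).  Both are linearly
    interpolated onto the union extension grid clipped to [0, zmax], with
    zmax the bare-curve extension at its maximum applied force.  Below a
    curve's measured range, the force is extrapolated as constant at its
    lowest-force value (flagged).  The integral uses the trapezoidal rule.

    Raises
    ------
    ValueError
        Non-overlapping extension ranges or a non-monotone bare curve.
    """
    zb, fb, mono_b = _as_force_of_extension(curve_bare, strict=True)
    zp, fp, mono_p = _as_force_of_extension(curve_protein, strict=False)
    monotonised = mono_b or mono_p
    if zp.max() < zb.min() or zb.max() < zp.min():
        raise ValueError("protein and bare curves span non-overlapping extension ranges")

    zmax = float(zb[np.argmax(fb)])
    grid = np.unique(np.concatenate([[0.0, zmax], zb, zp]))
    grid = grid[(grid >= 0.0) & (grid <= zmax)]
    f_protein = np.interp(grid, zp, fp)  # constant beyond measured range
    f_bare = np.interp(grid, zb, fb)
    extrapolated = bool(grid[0] < zp.min() or grid[0] < zb.min())

    dw = float(np.trapezoid(f_protein - f_bare, grid))
    return WorkResult(
        delta_w=dw,
        delta_w_kbt=dw / thermal_energy,
        zmax=zmax,
        monotonised=monotonised,
        extrapolated=extrapolated,
    )


def rotation_branches(traj: Trajectory) -> tuple[np.ndarray, np.ndarray,
                                                 np.ndarray, np.ndarray]:
    """Split a rotation-extension trajectory at the turns maximum.

    Returns per-turn mean extensions for the winding (forward) and
    unwinding (backward) branches as (turns_f, ext_f, turns_b, ext_b).
    """
    peak = int(np.argmax(traj.turns))
    # extend the forward branch to the end of the peak plateau
    peak_val = traj.turns[peak]
    while peak + 1 < len(traj) and traj.turns[peak + 1] == peak_val:
        peak += 1

    def per_turn(turns: np.ndarray, z: np.ndarray):
        vals = np.unique(turns)
        means = np.array([z[turns == v].mean() for v in vals])
        return vals, means

    tf, zf = per_turn(traj.turns[: peak + 1], traj.z[: peak + 1])
    tb, zb = per_turn(traj.turns[peak + 1 :], traj.z[peak + 1 :])
    return tf, zf, tb, zb


def hysteresis(forward, backward, *,
               step_threshold: float = 5.0,
               step_window: int = 4) -> HysteresisResult:
    """Hysteresis between a winding and an unwinding rotation-extension trace.

    ``forward`` and ``backward`` are (turns, extension) arrays.  Both are
    interpolated onto the union turns grid of their overlapping range;
    the area is the trapezoidal integral of (forward - backward) over
    turns (positive when unwinding lags, see :class:`HysteresisResult`),
    and ``max_deviation`` the signed difference of largest magnitude.
    Steps are detected on the backward trace in its acquisition order.

    Raises
    ------
    ValueError
        Disjoint turns ranges.
    """
    def prep(trace):
        arr = np.asarray(trace, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            arr = np.column_stack(trace)
        order = np.argsort(arr[:, 0], kind="stable")
        return arr[order, 0], arr[order, 1]

    tf, zf = prep(forward)
    tb, zb = prep(backward)
    lo, hi = max(tf.min(), tb.min()), min(tf.max(), tb.max())
    if lo >= hi:
        raise ValueError("forward and backward traces cover disjoint turns ranges")
    grid = np.unique(np.concatenate([tf, tb]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    diff = np.interp(grid, tf, zf) - np.interp(grid, tb, zb)
    area = float(np.trapezoid(diff, grid))
    max_dev = float(diff[np.argmax(np.abs(diff))]) if diff.size else 0.0

    steps: tuple[tuple[float, float], ...] = ()
    back = np.asarray(backward, dtype=float)
    if back.ndim != 2 or back.shape[1] != 2:
        back = np.column_stack(backward)
    if back.shape[0] >= 3 * step_window:
        found = detect_steps(back[:, 1], threshold_sigmas=step_threshold,
                             window=step_window)
        steps = tuple((float(back[i, 0]), size) for i, size in found)
    return HysteresisResult(area=area, max_deviation=max_dev, steps_detected=steps)


def detect_steps(signal, threshold_sigmas: float = 5.0,
                 window: int = 20) -> list[tuple[int, float]]:
    """Locate abrupt level shifts with a sliding two-window mean-shift test.

    At each admissible index the means of the ``window`` samples before
    and after are compared; the test statistic is their difference over
    the pooled standard error.  A step is called at local maxima of the
    statistic that exceed ``threshold_sigmas``, keeping calls at least
    ``window`` samples apart.  Returns (index, size_nm) pairs ordered by
    index; the size is the mean difference at the call.

    Raises
    ------
    ValueError
        window < 4 or signal shorter than 3*window.
    """
    s = np.asarray(signal, dtype=float)
    if window < 4:
        raise ValueError("window must be >= 4 samples")
    if s.size < 3 * window:
        raise ValueError("signal must be at least 3*window samples long")

    csum = np.concatenate([[0.0], np.cumsum(s)])
    csq = np.concatenate([[0.0], np.cumsum(s**2)])
    idx = np.arange(window, s.size - window + 1)
    sum_l = csum[idx] - csum[idx - window]
    sum_r = csum[idx + window] - csum[idx]
    mean_l, mean_r = sum_l / window, sum_r / window
    var_l = (csq[idx] - csq[idx - window]) / window - mean_l**2
    var_r = (csq[idx + window] - csq[idx]) / window - mean_r**2
    var_l = np.clip(var_l * window / (window - 1), 0.0, None)
    var_r = np.clip(var_r * window / (window - 1), 0.0, None)
    diff = mean_r - mean_l
    se = np.sqrt((var_l + var_r) / window)
    se = np.maximum(se, 1e-12)
    stat = np.abs(diff) / se

    above = stat > threshold_sigmas
    order = np.argsort(stat, kind="stable")[::-1]
    taken: list[int] = []
    for j in order:
        if not above[j]:
            break
        if all(abs(j - k) >= window for k in taken):
            taken.append(j)
    taken.sort()
    return [(int(idx[j]), float(diff[j])) for j in taken]
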