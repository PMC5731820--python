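"""Force calibration from bead Brownian excursions, and trajectory filtering.

Magnetic tweezers do not measure force directly: it is inferred from the
thermal motion of the tethered bead.  For a bead at mean height <z> under
force F, the transverse coordinate is a pendulum with stiffness
``kx = F/<z>``, so equipartition gives ``F = kBT <z> / Var(x)`` -- the
variance estimator used here, with block-bootstrap standard errors.  A
spectral alternative fits a Lorentzian ``A/(f^2 + fc^2)`` to the
periodogram of x; the corner frequency gives the stiffness via
``kx = 2 pi gamma fc`` and is insensitive to slow drift, at the cost of
needing the drag coefficient.

The boxcar decimator reproduces the common practice of recording at the
full camera rate and filtering down (e.g. 120 Hz to 3 Hz) for analysis
and display.  Note that variance-based calibration must use the
full-rate data: window averaging removes transverse variance (motion
blur), biasing the force estimate upward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import periodogram

from .polymer import KBT_ROOM, FitError
from .tethersim import Trajectory

__all__ = ["ForceEstimate", "boxcar_filter", "estimate_force_variance",
           "estimate_force_psd"]


@dataclass(frozen=True)
class ForceEstimate:
    """Applied-force estimate from bead fluctuations."""

    force: float  # pN
    standard_error: float  # pN
    mean_extension: float  # nm
    transverse_variance: float  # nm^2
    n_samples: int
    method: str  # "variance" | "psd"

    def __post_init__(self):
        if self.force <= 0:
            raise ValueError("force must be positive")
        if self.standard_error < 0:
            raise ValueError("standard_error must be non-negative")


def boxcar_filter(traj: Trajectory, target_rate: float) -> Trajectory:
    """Decimate a trajectory by non-overlapping window means.

    Coordinate columns (time, x, y, z, effective contour) carry the window
    mean; the force and turns columns carry the window's modal value.  If
    the acquisition rate is not an integer multiple of ``target_rate`` the
    nearest integer decimation factor is used and a warning emitted.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > traj.acquisition_rate:
        raise ValueError("target_rate exceeds the acquisition rate")
    ratio = traj.acquisition_rate / target_rate
    factor = max(1, round(ratio))
    if not math.isclose(ratio, factor, rel_tol=1e-9):
        warnings.warn(
            f"acquisition rate is not an integer multiple of {target_rate} Hz; "
            f"using decimation factor {factor}",
            stacklevel=2,
        )
    n_win = len(traj) // factor
    if n_win == 0:
        raise ValueError("trajectory shorter than one decimation window")

    def mean_col(a: np.ndarray) -> np.ndarray:
        return a[: n_win * factor].reshape(n_win, factor).mean(axis=1)

    def mode_col(a: np.ndarray) -> np.ndarray:
        w = a[: n_win * factor].reshape(n_win, factor)
        out = np.empty(n_win)
        for i in range(n_win):
            vals, counts = np.unique(w[i], return_counts=True)
            out[i] = vals[np.argmax(counts)]
        return out

    return Trajectory(
        mean_col(traj.time),
        mean_col(traj.x),
        mean_col(traj.y),
        mean_col(traj.z),
        mode_col(traj.applied_force),
        mode_col(traj.turns),
        None if traj.effective_contour is None else mean_col(traj.effective_contour),
        traj.acquisition_rate / factor,
    )


def _check_window(traj: Trajectory, min_samples: int = 500) -> None:
    if len(traj) < min_samples:
        raise ValueError(f"need >= {min_samples} samples in the window")
    if np.unique(traj.applied_force).size != 1:
        raise ValueError("window mixes applied forces; calibrate per constant-force segment")


def _correlation_time_samples(x: np.ndarray) -> int:
    """1/e crossing of the empirical autocorrelation, in samples (>= 1)."""
    xc = x - x.mean()
    var = float(np.dot(xc, xc))
    if var == 0:
        return 1
    max_lag = min(x.size // 2, 5000)
    target = var / math.e
    for lag in range(1, max_lag):
        if np.dot(xc[:-lag], xc[lag:]) < target:
            return max(1, lag)
    return max_lag


def estimate_force_variance(
    traj: Trajectory,
    *,
    kbt: float = KBT_ROOM,
    n_bootstrap: int = 200,
    rng: np.random.Generator | None = None,
) -> ForceEstimate:
    """Equipartition force estimate F = kBT <z> / Var(x) for one window.

    The window must be at a single applied force and contain at least 500
    full-rate samples.  The standard error comes from a block bootstrap
    with block length 10x the estimated correlation time of x (at least
    10 blocks; the block length is shortened if needed).

    Raises
    ------
    ValueError
        Mixed-force window, too few samples, or zero transverse variance.
    """
    _check_window(traj)
    x, z = traj.x, traj.z
    var_x = float(np.var(x, ddof=1))
    if var_x == 0:
        raise ValueError("degenerate window: transverse variance is zero")
    mean_z = float(np.mean(z))
    force = kbt * mean_z / var_x

    tau = _correlation_time_samples(x)
    block = max(1, min(10 * tau, len(traj) // 10))
    n_blocks = len(traj) // block
    xb = x[: n_blocks * block].reshape(n_blocks, block)
    zb = z[: n_blocks * block].reshape(n_blocks, block)
    rng = rng if rng is not None else np.random.default_rng(0)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_blocks, n_blocks)
        xs = xb[idx].ravel()
        zs = zb[idx].ravel()
        v = np.var(xs, ddof=1)
        boots[b] = kbt * np.mean(zs) / v if v > 0 else np.nan
    se = float(np.nanstd(boots))

    return ForceEstimate(force, se, mean_z, var_x, len(traj), "variance")


def estimate_force_psd(
    traj: Trajectory,
    gamma: float,
    *,
    kbt: float = KBT_ROOM,
) -> ForceEstimate:
    """Spectral force estimate from a Lorentzian fit of the x periodogram.

    The spectrum of an Ornstein-Uhlenbeck process is the Lorentzian
    ``A/(f^2 + fc^2)`` with corner frequency ``fc = kx/(2 pi gamma)``.
    Camera sampling aliases it: at typical tracking rates the corner is a
    sizeable fraction of Nyquist, so the fit uses the Lorentzian in its
    exact sampled (AR(1)) form,

        S(f) = B / (1 - 2 a cos(2 pi f / fs) + a^2),   a = exp(-kx/(gamma fs)),

    maximising the Whittle likelihood (periodogram ordinates are
    exponential about the spectrum, so least squares would be biased).
    Then ``kx = -gamma fs ln(a)``, equivalently ``fc = -fs ln(a)/(2 pi)``,
    and ``F = kx <z>``.

    ``gamma`` is the bead drag in pN*s/nm (see TetherConfig.gamma).

    Raises
    ------
    FitError
        Corner frequency outside (0, Nyquist), e.g. for white-noise or
        drift-dominated input.
    ValueError
        Window preconditions as for the variance estimator.
    """
    _check_window(traj)
    x = traj.x - np.mean(traj.x)
    fs = traj.acquisition_rate
    freqs, pxx = periodogram(x, fs=fs)
    freqs, pxx = freqs[1:], pxx[1:]  # drop DC
    nyquist = fs / 2.0
    cosine = np.cos(2.0 * math.pi * freqs / fs)

    var_x = float(np.var(x, ddof=1))
    # seed from equipartition: kx0 = kBT/Var(x)
    kx0 = kbt / var_x
    a0 = min(max(math.exp(-kx0 / (gamma * fs)), 1e-3), 1.0 - 1e-3)
    b0 = 2.0 * var_x * (1.0 - a0**2) / fs

    def unpack(p):
        b = math.exp(p[0])
        a = 1.0 / (1.0 + math.exp(-p[1]))  # logit keeps a in (0, 1)
        return b, a

    def nll(p):
        b, a = unpack(p)
        s = b / (1.0 - 2.0 * a * cosine + a * a)
        return float(np.sum(np.log(s) + pxx / s))

    p0 = [math.log(b0), math.log(a0 / (1.0 - a0))]
    res = minimize(nll, p0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000})
    _, a_hat = unpack(res.x)
    fc_hat = -fs * math.log(a_hat) / (2.0 * math.pi)
    if not res.success or not (freqs[0] * 0.5 < fc_hat < nyquist * 0.98):
        raise FitError(
            f"corner frequency fc = {fc_hat:.3g} Hz outside (0, Nyquist); "
            "spectrum is not Lorentzian in-band (white noise or drift dominated)",
            best=(a_hat, fc_hat),
        )

    mean_z = float(np.mean(traj.z))
    kx = 2.0 * math.pi * gamma * fc_hat
    force = kx * mean_z

    # curvature-based SE on logit(a), propagated to the force
    h = 1e-4
    p_opt = np.asarray(res.x, dtype=float)

    def nll_a(pa):
        return nll([p_opt[0], pa])

    d2 = (nll_a(p_opt[1] + h) - 2 * nll_a(p_opt[1]) + nll_a(p_opt[1] - h)) / h**2
    # dF/d logit(a) = -gamma <z> fs * (1 - a)
    dfdp = abs(-gamma * mean_z * fs * (1.0 - a_hat))
    se = dfdp / math.sqrt(d2) if d2 > 0 else float("nan")

    var_x_full = float(np.var(traj.x, ddof=1))
    return ForceEstimate(force, se, mean_z, var_x_full, len(traj), "psd")
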