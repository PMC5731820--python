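"""Spectroscopy companions: CSP mapping, CD melts, H/D exchange, native MS.

Four small analyses that accompany the single-molecule work:

* NMR chemical-shift perturbation (CSP) mapping of amide peak lists with
  the standard composite shift sqrt(dH^2 + (alpha*dN)^2), alpha = 0.14,
  and a configurable flagging threshold (default: perturbations strictly
  exceeding 0.08 ppm);
* molar-residue-ellipticity normalisation of raw CD signals and two-state
  Boltzmann fitting of thermal melts to extract the midpoint Tm;
* single-exponential H/D-exchange decays yielding amide-proton exchange
  half-lives;
* neutral-mass determination from a native-ESI charge-state series by
  adjacent-charge algebra (a deterministic, closed-form alternative to
  maximum-entropy deconvolution).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .polymer import FitError

__all__ = [
    "PROTON_MASS",
    "PeakList",
    "CSPRecord",
    "MeltCurve",
    "MeltFit",
    "ExchangeFit",
    "MassEstimate",
    "csp",
    "mre_normalise",
    "fit_tm",
    "fit_exchange_halflife",
    "deconvolve_charge_series",
]

PROTON_MASS = 1.00728  # Da


@dataclass
class PeakList:
    """Assigned amide peak positions (1H, 15N chemical shifts in ppm)."""

    shifts: dict[str, tuple[float, float]]
    label: str = ""

    def __post_init__(self):
        for res, (dh, dn) in self.shifts.items():
            if not (np.isfinite(dh) and np.isfinite(dn)):
                raise ValueError(f"non-finite chemical shift for residue {res!r}")

    def __len__(self) -> int:
        return len(self.shifts)


@dataclass(frozen=True)
class CSPRecord:
    """Composite chemical-shift perturbations between two conditions."""

    deltas: dict[str, float]  # residue -> composite delta-delta (ppm)
    flagged: tuple[str, ...]  # residues with delta strictly above threshold
    unmatched: tuple[str, ...]  # residues present in only one list
    threshold: float
    nitrogen_weight: float


@dataclass
class MeltCurve:
    """CD thermal-melt observations.

    ``signal`` is molar residue ellipticity (deg cm^2 dmol^-1) unless
    ``units`` says otherwise (e.g. raw "mdeg").
    """

    temperature: np.ndarray  # degC, strictly increasing
    signal: np.ndarray
    units: str = "mre"

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class MeltFit:
    """Two-state melt fit: sigmoid between linear baselines."""

    tm: float  # degC
    transition_width: float  # degC
    baseline_folded: tuple[float, float]  # (intercept, slope)
    baseline_unfolded: tuple[float, float]
    tm_se: float
    width_se: float
    fallback: bool = False  # True when Tm came from the derivative method

    def predict(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        return _melt_model(
            t, self.tm, self.transition_width,
            *self.baseline_folded, *self.baseline_unfolded,
        )


@dataclass(frozen=True)
class ExchangeFit:
    """Single-exponential H/D-exchange decay fit."""

    half_life: float  # s; inf when not exchanging
    rate: float  # 1/s
    rate_se: float
    amplitude: float
    not_exchanging: bool
    half_life_lower_bound: float  # s; meaningful when not_exchanging


@dataclass(frozen=True)
class MassEstimate:
    """Neutral mass inferred from a charge-state series."""

    mass: float  # Da
    sd: float  # Da, spread across adjacent-pair estimates
    charges: tuple[int, ...]
    n_pairs: int


def csp(
    free: PeakList,
    bound: PeakList,
    nitrogen_weight: float = 0.14,
    *,
    threshold: float = 0.08,
) -> CSPRecord:
    """Composite chemical-shift perturbation per residue.

    For each residue present in both lists,
    ``delta = sqrt(ddH^2 + (alpha*ddN)^2)`` with ``alpha =
    nitrogen_weight`` (0.14 is the community-standard amide weighting).
    Residues whose delta strictly exceeds ``threshold`` (ppm) are flagged;
    residues found in only one list are reported unmatched and never
    imputed as zero.

    Raises
    ------
    ValueError
        If no residue is common to both lists.
    """
    common = sorted(set(free.shifts) & set(bound.shifts))
    if not common:
        raise ValueError("peak lists share no residues")
    deltas: dict[str, float] = {}
    for res in common:
        dh = bound.shifts[res][0] - free.shifts[res][0]
        dn = bound.shifts[res][1] - free.shifts[res][1]
        deltas[res] = float(np.hypot(dh, nitrogen_weight * dn))
    # strict ">" at the threshold, robust to floating-point residue in the
    # shift differences
    flagged = tuple(
        r for r in common
        if deltas[r] > threshold and not np.isclose(deltas[r], threshold,
                                                    rtol=1e-9, atol=0.0)
    )
    unmatched = tuple(sorted(set(free.shifts) ^ set(bound.shifts)))
    return CSPRecord(
        deltas=deltas,
        flagged=flagged,
        unmatched=unmatched,
        threshold=threshold,
        nitrogen_weight=nitrogen_weight,
    )


def mre_normalise(raw, protein_conc: float, n_residues: int, path_length: float):
    """Convert raw CD ellipticity (mdeg) to molar residue ellipticity.

    MRE = raw / (10 * path_length_cm * conc_M * n_residues), in
    deg cm^2 dmol^-1; the factor 10 collects the unit conversions of the
    standard definition.  Linear in the raw signal.
    """
    if protein_conc <= 0 or path_length <= 0 or n_residues <= 0:
        raise ValueError("concentration, path length and residue count must be positive")
    r = np.asarray(raw, dtype=float)
    out = r / (10.0 * path_length * protein_conc * n_residues)
    return out if np.ndim(raw) else float(out)


def _melt_model(t, tm, width, b_f, m_f, b_u, m_u):
    folded = b_f + m_f * t
    unfolded = b_u + m_u * t
    frac = 1.0 / (1.0 + np.exp((tm - t) / width))
    return folded + (unfolded - folded) * frac


def fit_tm(melt: MeltCurve, *, baselines: str = "auto") -> MeltFit:
    """Two-state Boltzmann fit of a thermal melt; returns the midpoint Tm.

    The model is a sigmoid between pre- and post-transition baselines.
    With ``baselines="auto"`` (default) constant baselines are used unless
    sloped ones improve the fit significantly (F-test, alpha = 0.01):
    a typical melt scan has too few points for free slopes not to inflate
    the Tm variance, so slopes are only fitted when the data demand them.
    ``"constant"`` and ``"linear"`` force either model.  If the sigmoid
    fit fails, the temperature of steepest signal change on a lightly
    smoothed curve is used instead (flagged in ``fallback``).

    Raises
    ------
    ValueError
        Fewer than 8 points, or the transition is not bracketed by the
        data (fitted Tm outside the measured range, or no resolvable gap
        between the baselines) -- widen the temperature range.
    """
    if baselines not in ("auto", "constant", "linear"):
        raise ValueError("baselines must be 'auto', 'constant' or 'linear'")
    t, s = melt.temperature, melt.signal
    if t.size < 8:
        raise ValueError("need >= 8 points spanning both baselines")

    n_edge = max(2, t.size // 5)
    bf0 = float(np.mean(s[:n_edge]))
    bu0 = float(np.mean(s[-n_edge:]))
    mid = 0.5 * (bf0 + bu0)
    cross = np.nonzero(np.diff(np.sign(s - mid)))[0]
    tm0 = float(t[cross[0]]) if cross.size else float(t[t.size // 2])
    span = float(t[-1] - t[0])

    def flat_model(tt, tm, w, b_f, b_u):
        return _melt_model(tt, tm, w, b_f, 0.0, b_u, 0.0)

    popt = perr = None
    fallback = False
    try:
        p4, c4 = curve_fit(flat_model, t, s, p0=[tm0, 3.0, bf0, bu0],
                           maxfev=20000)
        rss4 = float(np.sum((s - flat_model(t, *p4)) ** 2))
        popt = [p4[0], p4[1], p4[2], 0.0, p4[3], 0.0]
        perr_d = np.sqrt(np.clip(np.diag(c4), 0.0, None))
        perr = [perr_d[0], perr_d[1]]
        if baselines != "constant":
            try:
                p6, c6 = curve_fit(_melt_model, t, s, p0=popt, maxfev=20000)
                rss6 = float(np.sum((s - _melt_model(t, *p6)) ** 2))
                dof6 = max(t.size - 6, 1)
                f_stat = ((rss4 - rss6) / 2.0) / max(rss6 / dof6, 1e-300)
                from scipy.stats import f as f_dist

                prefer_sloped = (baselines == "linear"
                                 or (rss6 < rss4
                                     and f_dist.sf(f_stat, 2, dof6) < 0.01))
                if prefer_sloped:
                    popt = list(p6)
                    perr_d = np.sqrt(np.clip(np.diag(c6), 0.0, None))
                    perr = [perr_d[0], perr_d[1]]
            except (RuntimeError, ValueError):
                if baselines == "linear":
                    raise
        tm, width = float(popt[0]), float(abs(popt[1]))
    except (RuntimeError, ValueError):
        # derivative fallback on a 3-point smoothed curve
        fallback = True
        sm = np.convolve(s, np.ones(3) / 3.0, mode="valid")
        ts = t[1:-1]
        d = np.gradient(sm, ts)
        tm = float(ts[np.argmax(np.abs(d))])
        width = np.nan
        popt = [tm, width, bf0, 0.0, bu0, 0.0]
        perr = [np.nan, np.nan]

    gap = abs((popt[4] + popt[5] * tm) - (popt[2] + popt[3] * tm))
    if (not (t[0] < tm < t[-1])
            or (not fallback and width > span)
            or gap < 0.05 * max(float(np.ptp(s)), 1e-300)):
        raise ValueError(
            "transition not bracketed by the data; acquire a wider temperature range"
        )
    return MeltFit(
        tm=tm,
        transition_width=width,
        baseline_folded=(float(popt[2]), float(popt[3])),
        baseline_unfolded=(float(popt[4]), float(popt[5])),
        tm_se=float(perr[0]),
        width_se=float(perr[1]),
        fallback=fallback,
    )


def fit_exchange_halflife(times, intensities) -> ExchangeFit:
    """Half-life of an H/D-exchange decay, I(t) = I0 * exp(-k t).

    Least-squares single-exponential fit; half-life = ln(2)/k.  A rate
    consistent with zero (k <= 2 SE, or non-positive) is reported as "not
    exchanging" with half_life = inf and a lower bound ln(2)/(k + 2 SE).
    A warning is emitted when intensities increase beyond noise.

    Raises
    ------
    ValueError
        Fewer than 3 time points or non-positive intensities.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 time points")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    # log-linear seed (exact on noiseless data)
    slope, intercept = np.polyfit(t, np.log(y), 1)
    k0, i0 = max(-slope, 0.0), float(np.exp(intercept))

    def model(tt, i0_, k_):
        return i0_ * np.exp(-k_ * tt)

    popt, pcov = curve_fit(model, t, y, p0=[i0, k0], maxfev=20000)
    i0_hat, k_hat = float(popt[0]), float(popt[1])
    k_se = float(np.sqrt(max(pcov[1, 1], 0.0))) if np.all(np.isfinite(pcov)) else np.inf

    if slope > 0 and slope > 2.0 * np.std(np.log(y)) / (np.ptp(t) or 1.0):
        warnings.warn("intensities increase with time beyond noise; "
                      "exchange fit is unreliable", stacklevel=2)

    ln2 = float(np.log(2.0))
    if k_hat <= 0.0:
        not_exch = True
    elif not np.isfinite(k_se):
        # unidentifiable rate (e.g. flat data): no measurable decay in-window
        not_exch = k_hat * np.ptp(t) < 1e-6
    else:
        not_exch = k_hat <= 2.0 * k_se and not np.isclose(k_se, 0.0)
    if not_exch:
        upper_k = max(k_hat, 0.0) + 2.0 * (k_se if np.isfinite(k_se) else 0.0)
        lower = ln2 / upper_k if upper_k > 0 else np.inf
        return ExchangeFit(np.inf, k_hat, k_se, i0_hat, True, lower)
    return ExchangeFit(ln2 / k_hat, k_hat, k_se, i0_hat, False, ln2 / k_hat)


def deconvolve_charge_series(peaks) -> MassEstimate:
    """Neutral mass from a single positive-ion charge-state series.

    For adjacent peaks m1 > m2 carrying charges z and z+1, the charge
    follows from z = round((m2 - mp)/(m1 - m2)) with mp the proton mass,
    and the neutral mass is z*(m1 - mp); estimates are averaged over all
    adjacent pairs and their spread reported.

    Raises
    ------
    ValueError
        Fewer than 2 peaks, or inferred charges inconsistent across pairs
        (spread of the raw charge estimates > 0.3), indicating the peaks
        do not form a single series.
    """
    mz = np.sort(np.asarray(list(peaks), dtype=float))[::-1]
    if mz.size < 2:
        raise ValueError("need >= 2 peaks from a charge-state series")
    m1, m2 = mz[:-1], mz[1:]
    if np.any(m1 - m2 <= 0):
        raise ValueError("duplicate m/z peaks; not a charge-state series")
    z_raw = (m2 - PROTON_MASS) / (m1 - m2)
    z = np.round(z_raw).astype(int)
    if np.any(z < 1):
        raise ValueError("inferred charge below 1; not a valid series")
    if np.max(np.abs(z_raw - z)) > 0.3 or np.any(np.diff(z) != 1):
        raise ValueError(
            "inconsistent charges inferred across adjacent pairs; "
            "peaks do not form a single charge-state series"
        )
    masses = z * (m1 - PROTON_MASS)
    charges = tuple(int(c) for c in z) + (int(z[-1]) + 1,)
    return MassEstimate(
        mass=float(np.mean(masses)),
        sd=float(np.std(masses)),
        charges=charges,
        n_pairs=int(masses.size),
    )
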