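"""PIFE quantification and Hill-equation analysis of protein-DNA titrations.

Protein-induced fluorescence enhancement (PIFE) reports binding of a
protein near a Cy3 dye as an increase in emission.  The binding readout is
the emission-scan area over 560-600 nm relative to a DNA-only control, and
the resulting concentration-response data is fitted with the Hill model

    Y = Bmax * [P]^h / (Kd_app^h + [P]^h),

where Bmax is the maximal fluorescence increase, h the Hill coefficient
(h > 1 indicates positive cooperativity) and Kd_app the apparent
dissociation constant.  Concentrations refer to the protein dimer
throughout.  A global variant fits several titrations jointly with one
shared Hill coefficient and per-dataset (Bmax, Kd_app), which tests
whether variants differ in cooperativity or only in affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .polymer import FitError

__all__ = [
    "TitrationDataset",
    "HillFit",
    "GlobalHillResult",
    "hill_response",
    "pife_response",
    "fit_hill",
    "fit_hill_global",
]


@dataclass
class TitrationDataset:
    """Concentration-response observations for one protein variant.

    ``concentrations`` are dimer concentrations in nM; ``responses`` are
    fluorescence increases relative to the DNA-only control (fold increase
    by default, see :func:`pife_response`).
    """

    label: str
    concentrations: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive (nM, dimer)")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.concentrations.shape:
                raise ValueError("replicate_ids must match the data length")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill-model parameters for one titration."""

    label: str
    bmax: float
    hill_coefficient: float
    kd_app: float  # nM
    bmax_se: float
    hill_se: float
    kd_se: float
    shared_h: bool = False
    rss: float = np.nan

    def __post_init__(self):
        if self.kd_app <= 0 or self.hill_coefficient <= 0:
            raise ValueError("kd_app and hill_coefficient must be positive")

    def predict(self, concentrations) -> np.ndarray:
        return hill_response(
            concentrations, self.bmax, self.hill_coefficient, self.kd_app
        )


@dataclass(frozen=True)
class GlobalHillResult:
    """Joint shared-h fit next to the per-dataset unshared fits.

    ``rss_ratio`` = rss_shared / rss_unshared >= 1 by nesting; values close
    to 1 mean the shared Hill coefficient describes the data as well as
    letting it float.
    """

    shared: tuple[HillFit, ...]
    unshared: tuple[HillFit, ...]
    rss_shared: float
    rss_unshared: float

    @property
    def rss_ratio(self) -> float:
        return self.rss_shared / self.rss_unshared


def hill_response(concentrations, bmax: float, h: float, kd: float):
    """Hill-model response at the given (nM) concentrations."""
    c = np.asarray(concentrations, dtype=float)
    ch = c**h
    y = bmax * ch / (kd**h + ch)
    return y if np.ndim(concentrations) else float(y)


def pife_response(sample_spectrum, control_spectrum, *, band=(560.0, 600.0),
                  additive: bool = False) -> float:
    """Fluorescence increase of a sample emission scan over a DNA-only control.

    Each spectrum is a (wavelength_nm, intensity) array.  Both are
    integrated by the trapezoidal rule over the emission band (560-600 nm
    by default) and the ratio sample/control is returned.  With
    ``additive=True`` the background-subtracted increase
    (sample-control)/control is returned instead.

    Raises
    ------
    ValueError
        If either spectrum does not cover the band, or the control area is
        not positive.
    """
    lo, hi = band

    def area(spec) -> float:
        arr = np.asarray(spec, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("spectrum must be (wavelength_nm, intensity) pairs")
        wl = arr[:, 0]
        order = np.argsort(wl)
        wl, inten = wl[order], arr[order, 1]
        if wl[0] > lo or wl[-1] < hi:
            raise ValueError(
                f"spectrum covers {wl[0]:g}-{wl[-1]:g} nm; needs {lo:g}-{hi:g} nm"
            )
        grid = np.unique(np.concatenate([[lo, hi], wl[(wl >= lo) & (wl <= hi)]]))
        return float(np.trapezoid(np.interp(grid, wl, inten), grid))

    a_control = area(control_spectrum)
    if a_control <= 0:
        raise ValueError("control spectrum area must be positive")
    ratio = area(sample_spectrum) / a_control
    return ratio - 1.0 if additive else ratio


def _hill_params(data: TitrationDataset, suffix: str = "") -> lmfit.Parameters:
    params = lmfit.Parameters()
    ymax = float(np.max(data.responses))
    ymin = float(np.min(data.responses))
    # half-max crossing by interpolation on the mean response per concentration
    conc = np.unique(data.concentrations)
    means = np.array(
        [data.responses[data.concentrations == c].mean() for c in conc]
    )
    half = ymin + 0.5 * (ymax - ymin)
    idx = np.searchsorted(means, half)
    if 0 < idx < conc.size:
        kd0 = float(np.interp(half, means[idx - 1 : idx + 1], conc[idx - 1 : idx + 1]))
    else:
        kd0 = float(np.sqrt(conc[0] * conc[-1]))
    params.add(f"bmax{suffix}", value=max(ymax, 1e-12), min=0.0)
    params.add(f"kd{suffix}", value=max(kd0, 1e-6), min=1e-9)
    params.add(f"h{suffix}", value=1.0, min=1e-3, max=20.0)
    return params


_LSQ_KWS = {"xtol": 1e-13, "ftol": 1e-13, "gtol": 1e-13}


def fit_hill(data: TitrationDataset, *, fix_h: float | None = None) -> HillFit:
    """Unweighted nonlinear least-squares Hill fit of one titration.

    Initial guesses: Bmax = max response, Kd_app = half-max concentration
    by interpolation, h = 1.  Standard errors are from the covariance
    matrix at the optimum.  ``fix_h`` pins the Hill coefficient (h = 1
    reduces the model to a rectangular hyperbola).

    Raises
    ------
    ValueError
        Fewer than 4 distinct concentrations, or all responses equal.
    FitError
        Optimiser failure.
    """
    if data.n_distinct < 4:
        raise ValueError("need responses at >= 4 distinct concentrations")
    if np.allclose(data.responses, data.responses[0]):
        raise ValueError("all responses are equal; nothing to fit")

    params = _hill_params(data)
    if fix_h is not None:
        params["h"].set(value=fix_h, vary=False)

    def resid(p):
        return data.responses - hill_response(
            data.concentrations, p["bmax"].value, p["h"].value, p["kd"].value
        )

    out = lmfit.minimize(resid, params, method="leastsq", **_LSQ_KWS)
    if not out.success:
        raise FitError(f"Hill fit failed for {data.label!r}: {out.message}",
                       best=out.params)

    def se(name: str) -> float:
        err = out.params[name].stderr
        return float(err) if err is not None else np.nan

    return HillFit(
        label=data.label,
        bmax=float(out.params["bmax"].value),
        hill_coefficient=float(out.params["h"].value),
        kd_app=float(out.params["kd"].value),
        bmax_se=se("bmax"),
        hill_se=0.0 if fix_h is not None else se("h"),
        kd_se=se("kd"),
        shared_h=False,
        rss=float(np.sum(out.residual**2)),
    )


def fit_hill_global(
    datasets, *, share: tuple[str, ...] = ("hill_coefficient",)
) -> GlobalHillResult:
    """Joint Hill fit of several titrations with a shared Hill coefficient.

    Each dataset keeps its own (Bmax, Kd_app); a single h is fitted across
    all of them.  The per-dataset free fits and both residual sums of
    squares are returned as well, so the shared-vs-free comparison can be
    made (the shared model is nested in the free one, hence
    rss_shared >= rss_unshared always).

    Raises
    ------
    ValueError
        Fewer than 2 datasets, unsupported ``share`` spec, or any dataset
        failing the single-fit preconditions.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise ValueError("global fit needs at least 2 datasets")
    if tuple(share) != ("hill_coefficient",):
        raise ValueError("only sharing of the Hill coefficient is supported")
    for d in datasets:
        if d.n_distinct < 4:
            raise ValueError(f"dataset {d.label!r}: need >= 4 distinct concentrations")

    # free (unshared) fits first; they seed the joint fit
    unshared = tuple(fit_hill(d) for d in datasets)

    params = lmfit.Parameters()
    params.add("h", value=float(np.mean([f.hill_coefficient for f in unshared])),
               min=1e-3, max=20.0)
    for i, f in enumerate(unshared):
        params.add(f"bmax_{i}", value=f.bmax, min=0.0)
        params.add(f"kd_{i}", value=f.kd_app, min=1e-9)

    def resid(p):
        parts = [
            d.responses
            - hill_response(d.concentrations, p[f"bmax_{i}"].value, p["h"].value,
                            p[f"kd_{i}"].value)
            for i, d in enumerate(datasets)
        ]
        return np.concatenate(parts)

    out = lmfit.minimize(resid, params, method="leastsq", **_LSQ_KWS)
    if not out.success:
        raise FitError(f"global Hill fit failed: {out.message}", best=out.params)

    def se(name: str) -> float:
        err = out.params[name].stderr
        return float(err) if err is not None else np.nan

    rss_shared = float(np.sum(out.residual**2))
    shared = tuple(
        HillFit(
            label=d.label,
            bmax=float(out.params[f"bmax_{i}"].value),
            hill_coefficient=float(out.params["h"].value),
            kd_app=float(out.params[f"kd_{i}"].value),
            bmax_se=se(f"bmax_{i}"),
            hill_se=se("h"),
            kd_se=se(f"kd_{i}"),
            shared_h=True,
            rss=rss_shared,
        )
        for i, d in enumerate(datasets)
    )
    return GlobalHillResult(
        shared=shared,
        unshared=unshared,
        rss_shared=rss_shared,
        rss_unshared=float(sum(f.rss for f in unshared)),
    )
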