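"""Fluorescence spectra and thermal-unfolding curve analysis.

Tryptophan emission spectra are fitted with the Siano-Metzler log-normal
band shape to read off the peak position (lambda_max) and height (I_max)
from the fitted curve rather than the raw grid. Thermal denaturation is
monitored either through lambda_max(T), fitted with a two-state Boltzmann
sigmoid with sloping native/denatured baselines, or through the
intensity ratio I350/I330, whose mid-transition temperature is taken from
the extremum of the first derivative. Heat-induced aggregation (T_agg)
comes from the rise of 350 nm light scattering, using the same smoothed
derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

__all__ = ["SpectrumScan", "SpectrumFit", "MeltCurve", "UnfoldingResult",
           "lognormal_band", "boltzmann", "fit_lognormal_spectrum",
           "fit_boltzmann", "tm_from_ratio_derivative", "tagg_from_scattering"]

MELT_KINDS = ("lambda_max", "ratio", "scattering")


@dataclass
class SpectrumScan:
    """An emission scan: wavelengths (nm, strictly increasing) and intensities."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class SpectrumFit:
    lambda_max: float
    i_max: float
    width: float
    asymmetry: float
    rss: float
    reliable: bool = True


@dataclass
class MeltCurve:
    """Temperature scan of one observable; ``kind`` tags its meaning."""

    temperatures: np.ndarray
    observable: np.ndarray
    kind: str = "lambda_max"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.kind not in MELT_KINDS:
            raise ValueError(f"kind must be one of {MELT_KINDS}")


@dataclass
class UnfoldingResult:
    t_m: Optional[float]
    slope: Optional[float]
    baselines: dict[str, float] = field(default_factory=dict)
    method: str = "boltzmann"
    t_agg: Optional[float] = None
    converged: bool = True
    rss: Optional[float] = None


def lognormal_band(wavelengths: np.ndarray, lambda_max: float, i_max: float,
                   width: float, asymmetry: float) -> np.ndarray:
    """Siano-Metzler log-normal band.

    ``width`` is the full width at half maximum and ``asymmetry`` (rho > 1)
    the ratio of the red to blue half-widths; as rho -> 1 the band tends to
    a Gaussian of the same FWHM.
    """
    lam = np.asarray(wavelengths, dtype=float)
    rho = asymmetry
    if rho <= 1.0 + 1e-9:
        return i_max * np.exp(-4.0 * np.log(2.0) * ((lam - lambda_max) / width) ** 2)
    arg = 1.0 + (lam - lambda_max) * (rho * rho - 1.0) / (rho * width)
    out = np.zeros_like(lam)
    pos = arg > 0
    out[pos] = i_max * np.exp(-(np.log(2.0) / np.log(rho) ** 2)
                              * np.log(arg[pos]) ** 2)
    return out


def fit_lognormal_spectrum(scan: SpectrumScan) -> SpectrumFit:
    """Fit the four-parameter log-normal band to an emission scan.

    A peak at the edge of the scanned range is flagged unreliable.
    """
    lam, inten = scan.wavelengths, scan.intensities
    if len(lam) < 10:
        raise ValueError("need at least 10 points bracketing the peak")
    i0 = int(np.argmax(inten))
    peak0, height0 = lam[i0], inten[i0]
    # FWHM estimate from half-maximum crossings
    above = inten >= height0 / 2.0
    idx = np.flatnonzero(above)
    width0 = max(lam[idx[-1]] - lam[idx[0]], 2.0 * float(np.mean(np.diff(lam))))

    def residual(theta: np.ndarray) -> np.ndarray:
        return lognormal_band(lam, *theta) - inten

    lo = np.array([lam[0], 1e-12, 0.1 * width0, 1.0 + 1e-6])
    hi = np.array([lam[-1], 10.0 * height0, 10.0 * width0, 5.0])
    best = None
    for rho0 in (1.1, 1.3, 1.6):
        start = np.clip(np.array([peak0, height0, width0, rho0]),
                        lo + 1e-12, hi - 1e-12)
        sol = least_squares(residual, start, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x.copy())
    rss, theta = best
    lam_max, i_max, width, rho = theta
    span = lam[-1] - lam[0]
    reliable = (lam[0] + 0.02 * span) < lam_max < (lam[-1] - 0.02 * span)
    return SpectrumFit(lambda_max=float(lam_max), i_max=float(i_max),
                       width=float(width), asymmetry=float(rho), rss=rss,
                       reliable=reliable)


def boltzmann(temps: np.ndarray, t_m: float, slope: float,
              a_native: float, b_native: float,
              a_denat: float, b_denat: float) -> np.ndarray:
    """Two-state sigmoid with linear native and denatured baselines."""
    t = np.asarray(temps, dtype=float)
    sig = 1.0 / (1.0 + np.exp(np.clip((t_m - t) / slope, -500.0, 500.0)))
    native = a_native + b_native * t
    denat = a_denat + b_denat * t
    return native + (denat - native) * sig


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(values, dtype=float)
    return uniform_filter1d(np.asarray(values, dtype=float), size=window,
                            mode="nearest")


def fit_boltzmann(curve: MeltCurve, with_baseline_slopes: bool = True,
                  smoothing_window: int = 5) -> UnfoldingResult:
    """Boltzmann fit of a melt curve; returns the mid-transition temperature.

    The transition midpoint and width are optimized nonlinearly while the
    four baseline coefficients are profiled out by linear least squares
    (the model is linear in them for fixed midpoint/width). A curve with
    no detectable transition is flagged non-converged.
    """
    t, y = curve.temperatures, curve.observable
    if np.ptp(y) <= 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        return UnfoldingResult(t_m=None, slope=None, method="boltzmann",
                               converged=False)

    ones = np.ones_like(t)

    def linear_solve(nl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t_m, width = nl
        sig = 1.0 / (1.0 + np.exp(np.clip((t_m - t) / width, -500.0, 500.0)))
        if with_baseline_slopes:
            design = np.stack([ones, t, sig, sig * t], axis=1)
        else:
            design = np.stack([ones, sig], axis=1)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return coef, design @ coef - y

    # midpoint start from the steepest point of the smoothed curve
    smoothed = _smooth(y, smoothing_window)
    deriv = np.gradient(smoothed, t)
    tm0 = float(t[np.argmax(np.abs(deriv))])
    lo = np.array([t[0], 0.05])
    hi = np.array([t[-1], (t[-1] - t[0])])

    best = None
    for width0 in (1.0, 3.0, 8.0):
        start = np.clip(np.array([tm0, width0]), lo + 1e-9, hi - 1e-9)
        sol = least_squares(lambda nl: linear_solve(nl)[1], start,
                            bounds=(lo, hi), xtol=1e-13, ftol=1e-13, gtol=1e-13)
        rss = float(np.sum(sol.fun ** 2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x.copy())
    if best is None:
        return UnfoldingResult(t_m=None, slope=None, method="boltzmann",
                               converged=False)
    rss, nl = best
    coef, _ = linear_solve(nl)
    if with_baseline_slopes:
        baselines = {"native_intercept": float(coef[0]),
                     "native_slope": float(coef[1]),
                     "denatured_intercept": float(coef[0] + coef[2]),
                     "denatured_slope": float(coef[1] + coef[3])}
    else:
        baselines = {"native_intercept": float(coef[0]), "native_slope": 0.0,
                     "denatured_intercept": float(coef[0] + coef[1]),
                     "denatured_slope": 0.0}
    return UnfoldingResult(t_m=float(nl[0]), slope=float(nl[1]),
                           baselines=baselines, method="boltzmann",
                           converged=True, rss=rss)


def _derivative_extremum(curve: MeltCurve, smoothing_window: int,
                         signed: bool) -> tuple[Optional[float], bool]:
    t, y = curve.temperatures, curve.observable
    if len(t) < 20:
        raise ValueError("need at least 20 points")
    smoothed = _smooth(y, smoothing_window)
    if np.ptp(smoothed) <= 1e-6 * max(1.0, float(np.max(np.abs(smoothed)))):
        return None, False
    deriv = np.gradient(smoothed, t)
    score = deriv if signed else np.abs(deriv)
    if signed and np.max(score) <= 0:
        return None, False
    # np.argmax returns the first (lowest-temperature) tie
    return float(t[int(np.argmax(score))]), True


def tm_from_ratio_derivative(curve: MeltCurve,
                             smoothing_window: int = 5) -> UnfoldingResult:
    """T_m as the temperature of the extremal first derivative of the ratio.

    Sign-agnostic (uses |d ratio / dT|), so it applies regardless of
    whether the ratio rises or falls on unfolding.
    """
    t_m, ok = _derivative_extremum(curve, smoothing_window, signed=False)
    return UnfoldingResult(t_m=t_m, slope=None, method="derivative",
                           converged=ok)


def tagg_from_scattering(curve: MeltCurve,
                         smoothing_window: int = 5) -> UnfoldingResult:
    """Aggregation temperature from the steepest rise of 350 nm scattering."""
    t_agg, ok = _derivative_extremum(curve, smoothing_window, signed=True)
    return UnfoldingResult(t_m=None, slope=None, method="derivative",
                           t_agg=t_agg, converged=ok)
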