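"""Equilibrium-dialysis binding curves and Hill fitting.

In a two-chamber dialysis well the free metal equilibrates across the
membrane, so the bound amount is the protein-side total minus the
buffer-side total, and the buffer-side total is the free concentration.
Bound-per-protein versus free metal is then fitted with the Hill equation

    B(f) = B_max * f^h / (K_half^h + f^h)

where ``K_half`` is the free concentration at half-maximal binding and
``h`` the Hill coefficient (reported as a free parameter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["DialysisWell", "BindingPoint", "BindingCurve", "HillFit",
           "hill", "bound_from_well", "fit_hill"]


@dataclass(frozen=True)
class DialysisWell:
    """Measured totals (molar) for one well."""

    total_metal_protein_side: float
    total_metal_buffer_side: float
    protein_conc: float

    def __post_init__(self) -> None:
        if self.total_metal_protein_side < 0 or self.total_metal_buffer_side < 0:
            raise ValueError("totals must be non-negative")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")


@dataclass(frozen=True)
class BindingPoint:
    free_metal: float
    bound_per_protein: float
    clipped: bool = False


@dataclass
class BindingCurve:
    """Bound-per-protein stoichiometry versus free metal, sorted by free."""

    free_metal: np.ndarray
    bound_per_protein: np.ndarray
    clipped: np.ndarray

    @classmethod
    def from_points(cls, points: Sequence[BindingPoint]) -> "BindingCurve":
        pts = sorted(points, key=lambda p: p.free_metal)
        return cls(free_metal=np.array([p.free_metal for p in pts]),
                   bound_per_protein=np.array([p.bound_per_protein for p in pts]),
                   clipped=np.array([p.clipped for p in pts]))

    @classmethod
    def from_wells(cls, wells: Sequence[DialysisWell]) -> "BindingCurve":
        return cls.from_points([bound_from_well(w) for w in wells])

    def __len__(self) -> int:
        return len(self.free_metal)


@dataclass
class HillFit:
    b_max: float
    k_half: float
    h: float
    param_errors: dict[str, float]
    rss: float
    converged: bool


def hill(free: np.ndarray, b_max: float, k_half: float, h: float) -> np.ndarray:
    free = np.asarray(free, dtype=float)
    fh = free ** h
    return b_max * fh / (k_half ** h + fh)


def bound_from_well(well: DialysisWell) -> BindingPoint:
    """One binding-curve point from paired-chamber totals.

    A protein-side total below the buffer side (possible from measurement
    noise near zero binding) is clipped to zero bound and flagged.
    """
    diff = well.total_metal_protein_side - well.total_metal_buffer_side
    clipped = diff < 0
    bound = max(diff, 0.0) / well.protein_conc
    return BindingPoint(free_metal=well.total_metal_buffer_side,
                        bound_per_protein=bound, clipped=clipped)


def fit_hill(curve: BindingCurve, n_starts: int = 8, seed: int = 0,
             h_fixed: Optional[float] = None) -> HillFit:
    """Least-squares Hill fit with multi-start over the Hill coefficient.

    Starts cycle h over {0.5, 1, 2, 4} with K_half seeded at the median
    free concentration (log-spaced jitter beyond the first cycle). With
    sparse curves the Hill coefficient and K_half are strongly correlated;
    ``h_fixed`` pins the coefficient (e.g. at 1 for non-cooperative
    binding) and fits only B_max and K_half.
    """
    f = np.asarray(curve.free_metal, dtype=float)
    b = np.asarray(curve.bound_per_protein, dtype=float)
    if len(f) < 4:
        raise ValueError("need at least 4 points to fit the Hill equation")
    scale_f = float(np.median(f[f > 0])) if np.any(f > 0) else 1.0
    scale_b = float(np.max(np.abs(b))) or 1.0

    def residual(theta: np.ndarray) -> np.ndarray:
        b_max, log_k, h = theta
        return hill(f, b_max, 10.0 ** log_k, h) - b

    h_grid = [h_fixed] if h_fixed is not None else [0.5, 1.0, 2.0, 4.0]
    rng = np.random.default_rng(seed)
    h_lo, h_hi = ((h_fixed - 1e-12, h_fixed + 1e-12) if h_fixed is not None
                  else (0.05, 10.0))
    lo = np.array([1e-6, np.log10(scale_f) - 4.0, h_lo])
    hi = np.array([10.0 * scale_b, np.log10(scale_f) + 4.0, h_hi])

    best = None
    for s in range(n_starts):
        log_k0 = np.log10(scale_f) + (0.0 if s < len(h_grid)
                                      else rng.uniform(-1.5, 1.5))
        start = np.clip(np.array([scale_b, log_k0, h_grid[s % len(h_grid)]]),
                        lo + 1e-13, hi - 1e-13)
        try:
            sol = least_squares(residual, start, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x.copy())

    if best is None:
        return HillFit(b_max=scale_b, k_half=scale_f, h=1.0, param_errors={},
                       rss=float("inf"), converged=False)
    rss, theta = best
    b_max, log_k, h = theta
    k_half = 10.0 ** log_k

    # local quadratic errors in natural units
    def model_nat(th: np.ndarray) -> np.ndarray:
        return hill(f, th[0], th[1], th[2])

    nat = np.array([b_max, k_half, h])
    jac = np.empty((len(f), 3))
    base = model_nat(nat)
    for j in range(3):
        step = 1e-6 * max(abs(nat[j]), 1e-12)
        th = nat.copy()
        th[j] += step
        jac[:, j] = (model_nat(th) - base) / step
    dof = max(len(f) - 3, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sig = np.full(3, float("nan"))
    errors = {"b_max": sig[0], "k_half": sig[1], "h": sig[2]}
    return HillFit(b_max=float(b_max), k_half=float(k_half), h=float(h),
                   param_errors=errors, rss=rss, converged=True)
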