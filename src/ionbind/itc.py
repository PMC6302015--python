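"""Isothermal titration calorimetry: binding models, simulation and fitting.

Three equilibrium binding models describe the heat evolved when a metal ion
is titrated into a protein solution:

* **one set of sites** -- ``n`` identical independent sites per protein with
  association constant ``K_a`` and molar enthalpy ``dH``;
* **two sets of sites** -- two independent classes ``(n1, K1, dH1)`` and
  ``(n2, K2, dH2)``;
* **sequential binding** -- ordered macroscopic stepwise constants
  ``K1..Kk`` with stepwise enthalpies ``dH1..dHk`` via the binding
  polynomial ``P(x) = 1 + sum_i (prod_{j<=i} Kj) x^i``.

For any model, the free-ligand concentration ``x`` after injection ``i``
solves the mass balance ``X_t = x + M_t * B(x)`` where ``B`` is the mean
number of ligands bound per protein. The cumulative heat content of the
cell is ``Q = V0 * M_t * Hbar(x)`` with ``Hbar`` the mean cumulative
enthalpy per protein, and the measured per-injection heat applies the
standard displaced-volume correction for an overflow cell:

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2

Heats are reported per mole of injectant (kcal/mol), the unit of the
instrument software's integrated isotherms.

Fitting uses nonlinear least squares with variable projection: for fixed
capacities and association constants the model heats are linear in the
enthalpies, which are therefore solved exactly by linear least squares
inside the outer optimization over ``(N, log10 K)``. A multi-start over
log-spaced K (1e3-1e9 M^-1) guards against the multi-modal sequential
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "R_KCAL", "TitrationProtocol", "OneSetParams", "TwoSetsParams",
    "SequentialParams", "Isotherm", "FitResult", "ThermodynamicState",
    "bound_per_protein", "free_ligand", "cell_composition_after_injection",
    "simulate_isotherm", "wiseman_cumulative_heat", "fit_isotherm",
    "derive_thermo",
]

#: Gas constant in kcal K^-1 mol^-1.
R_KCAL = 1.98720e-3


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell and syringe composition of one titration.

    Volumes in liters, concentrations molar, temperature kelvin. The
    default geometry matches a MicroCal iTC200 (200 uL cell). A syringe
    refill is represented simply by continuing ``injection_volumes``.
    """

    cell_volume: float
    cell_protein_conc: float
    syringe_ligand_conc: float
    injection_volumes: tuple[float, ...]
    temperature: float = 298.15
    competitor_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "injection_volumes", tuple(self.injection_volumes))
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("all volumes must be positive")
        if self.cell_protein_conc <= 0 or self.syringe_ligand_conc <= 0:
            raise ValueError("concentrations must be positive")
        if len(self.injection_volumes) < 2:
            raise ValueError("need at least 2 injections")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    @classmethod
    def itc200(cls, protein_conc: float, syringe_conc: float,
               n_injections: int = 30, injection_volume: float = 2e-6,
               temperature: float = 298.15,
               competitor_label: Optional[str] = None) -> "TitrationProtocol":
        """Convenience constructor for the common 200 uL / 2 uL protocol."""
        return cls(cell_volume=200e-6, cell_protein_conc=protein_conc,
                   syringe_ligand_conc=syringe_conc,
                   injection_volumes=(injection_volume,) * n_injections,
                   temperature=temperature, competitor_label=competitor_label)


@dataclass(frozen=True)
class OneSetParams:
    """Identical independent sites: capacity ``n``, ``k_a`` (M^-1), ``dh`` (kcal/mol)."""

    n: float
    k_a: float
    dh: float

    def __post_init__(self) -> None:
        if self.n <= 0 or self.k_a <= 0:
            raise ValueError("n and k_a must be positive")


@dataclass(frozen=True)
class TwoSetsParams:
    """Two independent classes of sites."""

    n1: float
    k_a1: float
    dh1: float
    n2: float
    k_a2: float
    dh2: float

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.k_a1, self.k_a2) <= 0:
            raise ValueError("capacities and constants must be positive")


@dataclass(frozen=True)
class SequentialParams:
    """Ordered stepwise macroscopic constants and enthalpies.

    Trailing constants may be zero, which truncates the binding polynomial
    (a site that never fills); the first constant must be positive.
    """

    k_list: tuple[float, ...]
    dh_list: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_list", tuple(self.k_list))
        object.__setattr__(self, "dh_list", tuple(self.dh_list))
        if len(self.k_list) != len(self.dh_list) or not self.k_list:
            raise ValueError("k_list and dh_list must have equal positive length")
        if self.k_list[0] <= 0 or any(k < 0 for k in self.k_list):
            raise ValueError("K1 must be positive and all K >= 0")

    @property
    def betas(self) -> np.ndarray:
        """Cumulative products beta_i = K1 * ... * Ki."""
        return np.cumprod(self.k_list)

    @property
    def cumulative_dh(self) -> np.ndarray:
        return np.cumsum(self.dh_list)


ModelParams = Union[OneSetParams, TwoSetsParams, SequentialParams]


@dataclass
class Isotherm:
    """Per-injection molar ratios and heats (kcal per mol of injectant)."""

    molar_ratio: np.ndarray
    heat: np.ndarray
    model_free_ligand: Optional[np.ndarray] = None
    cumulative_heat: Optional[np.ndarray] = None
    heat_units: str = "kcal/mol-injectant"

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heat = np.asarray(self.heat, dtype=float)
        if np.any(np.diff(self.molar_ratio) <= 0):
            raise ValueError("molar_ratio must be strictly increasing")
        if not np.all(np.isfinite(self.heat)):
            raise ValueError("heats must be finite")

    def __len__(self) -> int:
        return len(self.heat)


@dataclass
class FitResult:
    model_kind: str
    params: ModelParams
    param_errors: dict[str, float]
    rss: float
    n_points: int
    converged: bool
    n_starts: int


@dataclass(frozen=True)
class ThermodynamicState:
    """Secondary thermodynamics of one association constant at temperature T."""

    k_a: float
    k_d: float
    dg: float
    dh: float
    ds: float
    temperature: float


# ---------------------------------------------------------------------------
# equilibrium species accounting


def bound_per_protein(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Mean ligands bound per protein at free-ligand concentration ``x``."""
    x = np.asarray(x, dtype=float)
    if isinstance(params, OneSetParams):
        kx = params.k_a * x
        return params.n * kx / (1.0 + kx)
    if isinstance(params, TwoSetsParams):
        k1x = params.k_a1 * x
        k2x = params.k_a2 * x
        return params.n1 * k1x / (1.0 + k1x) + params.n2 * k2x / (1.0 + k2x)
    if isinstance(params, SequentialParams):
        betas = params.betas
        i = np.arange(1, len(betas) + 1)
        terms = betas * x[..., None] ** i
        poly = 1.0 + terms.sum(axis=-1)
        return (i * terms).sum(axis=-1) / poly
    raise TypeError(f"unsupported model parameters: {type(params)!r}")


def _mean_cumulative_enthalpy(params: ModelParams, x: np.ndarray) -> np.ndarray:
    """Mean cumulative binding enthalpy per protein, kcal/mol protein."""
    x = np.asarray(x, dtype=float)
    if isinstance(params, OneSetParams):
        kx = params.k_a * x
        return params.n * kx / (1.0 + kx) * params.dh
    if isinstance(params, TwoSetsParams):
        k1x = params.k_a1 * x
        k2x = params.k_a2 * x
        return (params.n1 * k1x / (1.0 + k1x) * params.dh1
                + params.n2 * k2x / (1.0 + k2x) * params.dh2)
    if isinstance(params, SequentialParams):
        betas = params.betas
        i = np.arange(1, len(betas) + 1)
        terms = betas * x[..., None] ** i
        poly = 1.0 + terms.sum(axis=-1)
        return (terms * params.cumulative_dh).sum(axis=-1) / poly
    raise TypeError(f"unsupported model parameters: {type(params)!r}")


def free_ligand(total_ligand: float, total_protein: float,
                model_params: ModelParams) -> float:
    """Free-ligand concentration solving ``X_t = x + M_t * B(x)``.

    The left side minus the right is monotone in ``x`` and brackets a
    unique root in ``[0, X_t]``, located here by Brent's method at machine
    precision.
    """
    if total_ligand < 0 or total_protein < 0:
        raise ValueError("totals must be non-negative")
    if total_ligand == 0:
        return 0.0

    def f(x: float) -> float:
        return x + total_protein * float(bound_per_protein(model_params, np.array(x))) - total_ligand

    lo, hi = 0.0, total_ligand
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError("free-ligand root is not bracketed in [0, total_ligand]")
    return float(brentq(f, lo, hi, xtol=1e-30, rtol=4 * np.finfo(float).eps,
                        maxiter=200))


def _free_ligand_many(total_ligand: np.ndarray, total_protein: np.ndarray,
                      params: ModelParams, iters: int = 85) -> np.ndarray:
    # Vectorized bisection over all injections at once; 85 halvings of
    # [0, X_t] reach relative precision far below 1e-12.
    xt = np.asarray(total_ligand, dtype=float)
    mt = np.asarray(total_protein, dtype=float)
    lo = np.zeros_like(xt)
    hi = xt.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        over = mid + mt * bound_per_protein(params, mid) > xt
        hi = np.where(over, mid, hi)
        lo = np.where(over, lo, mid)
    return 0.5 * (lo + hi)


def cell_composition_after_injection(protocol: TitrationProtocol,
                                     i: int) -> tuple[float, float]:
    """Total protein and ligand concentrations in the cell after injection ``i``.

    Uses the discrete overflow-cell dilution: each injection of ``dV``
    displaces a fraction ``dV/V0`` of the current cell content, so
    ``M_t(i) = M_t(0) * prod_j (1 - dV_j/V0)`` and the ligand total accrues
    from the syringe with the same per-injection dilution.
    """
    if not (1 <= i <= protocol.n_injections):
        raise IndexError(f"injection index {i} out of range 1..{protocol.n_injections}")
    mt, xt = _composition_series(protocol)
    return float(mt[i - 1]), float(xt[i - 1])


def _composition_series(protocol: TitrationProtocol) -> tuple[np.ndarray, np.ndarray]:
    v0 = protocol.cell_volume
    mt = np.empty(protocol.n_injections)
    xt = np.empty(protocol.n_injections)
    m, x = protocol.cell_protein_conc, 0.0
    for j, dv in enumerate(protocol.injection_volumes):
        f = dv / v0
        m *= (1.0 - f)
        x = x * (1.0 - f) + protocol.syringe_ligand_conc * f
        mt[j], xt[j] = m, x
    return mt, xt


# ---------------------------------------------------------------------------
# simulation


def _heats_per_mol(protocol: TitrationProtocol, params: ModelParams
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Clean per-injection heats (kcal/mol injectant) plus diagnostics."""
    v0 = protocol.cell_volume
    mt, xt = _composition_series(protocol)
    x_free = _free_ligand_many(xt, mt, params)
    q = v0 * mt * _mean_cumulative_enthalpy(params, x_free)  # kcal in cell
    dv = np.asarray(protocol.injection_volumes)
    q_prev = np.concatenate(([0.0], q[:-1]))
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = dv * protocol.syringe_ligand_conc
    return dq / moles_injected, x_free, q, mt


def simulate_isotherm(protocol: TitrationProtocol, model_params: ModelParams,
                      noise_sd: float = 0.0,
                      seed: Optional[int] = None) -> Isotherm:
    """Simulate an integrated titration isotherm under one binding model.

    ``noise_sd`` is the Gaussian standard deviation added to each heat, in
    kcal per mol of injectant.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    heats, x_free, q, mt = _heats_per_mol(protocol, model_params)
    _, xt = _composition_series(protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return Isotherm(molar_ratio=xt / mt, heat=heats, model_free_ligand=x_free,
                    cumulative_heat=q)


def wiseman_cumulative_heat(total_ligand: float, total_protein: float,
                            cell_volume: float, params: OneSetParams) -> float:
    """Closed-form cumulative heat for identical independent sites.

    With ``r = X_t / (n M_t)`` and ``c = n K M_t``:

        Q = (n M_t dH V0 / 2) [1 + r + 1/c - sqrt((1 + r + 1/c)^2 - 4 r)]
    """
    n, k, dh = params.n, params.k_a, params.dh
    nm = n * total_protein
    r = total_ligand / nm
    inv_c = 1.0 / (k * nm)
    s = 1.0 + r + inv_c
    return 0.5 * nm * dh * cell_volume * (s - math.sqrt(s * s - 4.0 * r))


# ---------------------------------------------------------------------------
# fitting


def _n_nonlinear(model_kind: str, n_sites: int) -> int:
    return {"one_set": 2, "two_sets": 4, "sequential": n_sites}[model_kind]


def _make_params(model_kind: str, nl: np.ndarray, dh: np.ndarray) -> ModelParams:
    if model_kind == "one_set":
        return OneSetParams(n=nl[1], k_a=10.0 ** nl[0], dh=dh[0])
    if model_kind == "two_sets":
        return TwoSetsParams(n1=nl[2], k_a1=10.0 ** nl[0], dh1=dh[0],
                             n2=nl[3], k_a2=10.0 ** nl[1], dh2=dh[1])
    return SequentialParams(k_list=tuple(10.0 ** nl), dh_list=tuple(dh))


def _heat_design_matrix(protocol: TitrationProtocol, model_kind: str,
                        nl: np.ndarray) -> np.ndarray:
    """Columns: per-injection heats with one unit enthalpy and the rest zero.

    The free-ligand series depends only on the nonlinear parameters, so it
    is solved once and shared by all columns; the displaced-volume
    correction is linear in the cumulative heat and is applied per column.
    """
    n_dh = 1 if model_kind == "one_set" else (2 if model_kind == "two_sets"
                                              else len(nl))
    v0 = protocol.cell_volume
    mt, xt = _composition_series(protocol)
    params0 = _make_params(model_kind, nl, np.zeros(n_dh))
    x = _free_ligand_many(xt, mt, params0)

    if model_kind == "one_set":
        kx = params0.k_a * x
        fracs = [params0.n * kx / (1.0 + kx)]
    elif model_kind == "two_sets":
        k1x, k2x = params0.k_a1 * x, params0.k_a2 * x
        fracs = [params0.n1 * k1x / (1.0 + k1x), params0.n2 * k2x / (1.0 + k2x)]
    else:
        betas = params0.betas
        i = np.arange(1, len(betas) + 1)
        terms = betas * x[:, None] ** i
        poly = 1.0 + terms.sum(axis=1)
        species = terms / poly[:, None]        # fraction with exactly i bound
        # unit dh_j contributes to every species with >= j ligands
        fracs = [species[:, j:].sum(axis=1) for j in range(len(betas))]

    dv = np.asarray(protocol.injection_volumes)
    moles_injected = dv * protocol.syringe_ligand_conc
    cols = []
    for frac in fracs:
        q = v0 * mt * frac
        q_prev = np.concatenate(([0.0], q[:-1]))
        dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
        cols.append(dq / moles_injected)
    return np.stack(cols, axis=1)


def fit_isotherm(isotherm: Isotherm, protocol: TitrationProtocol,
                 model_kind: str, n_starts: int = 8, seed: int = 0,
                 n_sites: int = 3) -> FitResult:
    """Least-squares fit of one binding model to an isotherm.

    Multi-start over log-spaced association constants (1e3-1e9 M^-1);
    for each trial of the nonlinear parameters the enthalpies are profiled
    out by linear least squares. Parameter errors come from the local
    quadratic approximation at the optimum. A flat isotherm is flagged as
    non-converged rather than raising.
    """
    if model_kind not in ("one_set", "two_sets", "sequential"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    y = isotherm.heat
    m = len(y)
    p_nl = _n_nonlinear(model_kind, n_sites)
    n_dh = 1 if model_kind == "one_set" else (2 if model_kind == "two_sets" else n_sites)
    n_free = p_nl + n_dh
    if m < 2 * n_free:
        raise ValueError(f"need at least {2 * n_free} points to fit {model_kind}")

    flat_params = _make_params(model_kind, np.full(p_nl, 5.0), np.zeros(n_dh))
    if np.ptp(y) <= 1e-12 * max(1.0, np.max(np.abs(y))):
        return FitResult(model_kind=model_kind, params=flat_params,
                         param_errors={}, rss=float(np.sum((y - y.mean()) ** 2)),
                         n_points=m, converged=False, n_starts=n_starts)

    def solve_dh(nl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        design = _heat_design_matrix(protocol, model_kind, nl)
        dh, *_ = np.linalg.lstsq(design, y, rcond=None)
        return dh, design @ dh - y

    def residual(nl: np.ndarray) -> np.ndarray:
        return solve_dh(nl)[1]

    rng = np.random.default_rng(seed)
    log_k_grid = np.linspace(3.0, 9.0, max(n_starts, 2))
    lo = np.concatenate((np.full(p_nl if model_kind == "sequential" else
                                 (1 if model_kind == "one_set" else 2), 1.0),
                         [] if model_kind == "sequential" else
                         np.full(1 if model_kind == "one_set" else 2, 0.05)))
    hi = np.concatenate((np.full(p_nl if model_kind == "sequential" else
                                 (1 if model_kind == "one_set" else 2), 11.0),
                         [] if model_kind == "sequential" else
                         np.full(1 if model_kind == "one_set" else 2, 10.0)))

    best = None
    for s in range(n_starts):
        if model_kind == "one_set":
            start = np.array([log_k_grid[s % len(log_k_grid)],
                              rng.uniform(0.5, 3.5)])
        elif model_kind == "two_sets":
            start = np.array([log_k_grid[s % len(log_k_grid)],
                              log_k_grid[(s + n_starts // 2) % len(log_k_grid)],
                              rng.uniform(0.3, 2.0), rng.uniform(0.5, 3.5)])
        else:
            start = rng.uniform(3.0, 9.0, size=n_sites)
            start[0] = log_k_grid[s % len(log_k_grid)]
        start = np.clip(start, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(residual, start, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=400)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rss = float(np.sum(sol.fun ** 2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x.copy())

    if best is None:
        return FitResult(model_kind=model_kind, params=flat_params,
                         param_errors={}, rss=float("inf"), n_points=m,
                         converged=False, n_starts=n_starts)

    rss, nl_opt = best
    dh_opt, _ = solve_dh(nl_opt)
    params = _make_params(model_kind, nl_opt, dh_opt)
    errors = _quadratic_errors(protocol, model_kind, nl_opt, dh_opt, y, rss)
    return FitResult(model_kind=model_kind, params=params, param_errors=errors,
                     rss=rss, n_points=m, converged=True, n_starts=n_starts)


def _param_names(model_kind: str, n_sites: int) -> list[str]:
    if model_kind == "one_set":
        return ["log10_k_a", "n", "dh"]
    if model_kind == "two_sets":
        return ["log10_k_a1", "log10_k_a2", "n1", "n2", "dh1", "dh2"]
    return ([f"log10_k_a{i + 1}" for i in range(n_sites)]
            + [f"dh{i + 1}" for i in range(n_sites)])


def _quadratic_errors(protocol: TitrationProtocol, model_kind: str,
                      nl: np.ndarray, dh: np.ndarray, y: np.ndarray,
                      rss: float) -> dict[str, float]:
    """1-sigma errors from the Gauss-Newton covariance at the optimum."""
    theta = np.concatenate((nl, dh))
    names = _param_names(model_kind, len(nl) if model_kind == "sequential" else 0)

    def model(th: np.ndarray) -> np.ndarray:
        design = _heat_design_matrix(protocol, model_kind, th[:len(nl)])
        return design @ th[len(nl):]

    m, p = len(y), len(theta)
    jac = np.empty((m, p))
    base = model(theta)
    for j in range(p):
        h = 1e-6 * max(1.0, abs(theta[j]))
        th = theta.copy()
        th[j] += h
        jac[:, j] = (model(th) - base) / h
    dof = max(m - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sig = np.full(p, float("nan"))
    return dict(zip(names, sig))


def derive_thermo(k_a: float, dh: float, temperature: float = 298.15) -> ThermodynamicState:
    """Secondary thermodynamics from an association constant and enthalpy.

    ``dG = -R T ln K_a`` (kcal/mol, R = 1.98720e-3 kcal K^-1 mol^-1),
    ``K_d = 1 / K_a`` (M), ``dS = 1000 (dH - dG) / T`` (cal K^-1 mol^-1).
    """
    if k_a <= 0 or temperature <= 0:
        raise ValueError("k_a and temperature must be positive")
    dg = -R_KCAL * temperature * math.log(k_a)
    ds = 1000.0 * (dh - dg) / temperature
    return ThermodynamicState(k_a=k_a, k_d=1.0 / k_a, dg=dg, dh=dh, ds=ds,
                              temperature=temperature)
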