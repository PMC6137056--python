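"""Thermodynamic curve models: two-state thermal unfolding, hyperbolic
band-shift (EMSA) binding, and the sequential two-site ITC isotherm.

Thermal unfolding follows the usual two-state treatment of a CD melt: the
fraction curve f(T) = (theta_t - theta_U) / (theta_F - theta_U) with a
Boltzmann sigmoid for the transition and Tm at f = 0.5.  EMSA densitometry
follows the single-site hyperbola y = Vmax * x / (Kd + x).  The calorimetric
model is the standard sequential-sites formulation: binding polynomial
P = 1 + K1[X] + K1*K2*[X]^2, cumulative heat
Q = V0 * M_t * (dH1*F1 + (dH1 + dH2)*F2), free ligand solved per injection
from mass balance by bisection, per-injection heats with the MicroCal
displaced-volume correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

__all__ = [
    "MeltingCurve",
    "TwoStateFit",
    "BindingCurve",
    "HyperbolicFit",
    "ITCExperiment",
    "SequentialSitesModel",
    "unfolded_fraction",
    "fit_two_state_melt",
    "fit_hyperbolic",
    "itc_sequential_heats",
    "itc_single_site_heats",
    "fit_itc",
]

R_GAS_CAL = 1.98720425864083  # cal / (mol K)


# ---------------------------------------------------------------------------
# thermal unfolding
# ---------------------------------------------------------------------------


@dataclass
class MeltingCurve:
    """CD melt: temperatures in Celsius, ellipticities in mdeg."""

    temperatures: np.ndarray
    ellipticities: np.ndarray
    theta_F: float | None = None
    theta_U: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticities = np.asarray(self.ellipticities, dtype=float)
        if len(self.temperatures) < 8:
            raise ValueError("melting curve needs at least 8 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TwoStateFit:
    Tm: float
    width: float
    theta_F: float
    theta_U: float
    slope_F: float
    slope_U: float
    dH_vantHoff: float  # cal/mol, derived quantity (from the fitted width)
    fraction: np.ndarray
    residual_rmse: float


def _estimate_baselines(curve: MeltingCurve, k: int = 4) -> tuple[float, float]:
    thF = float(np.mean(curve.ellipticities[:k]))
    thU = float(np.mean(curve.ellipticities[-k:]))
    return thF, thU


def unfolded_fraction(
    curve: MeltingCurve, complement: bool = False, clip: bool = False
) -> np.ndarray:
    """The ratio (theta_t - theta_U) / (theta_F - theta_U) at each T.

    This ratio is 1 in the fully folded limit and 0 when unfolded; pass
    ``complement=True`` for 1 minus the ratio (the unfolded fraction under
    the usual sign convention).  Baselines default to the first/last points
    of the curve when not supplied.  ``clip`` restricts values to [0, 1];
    the raw ratio is returned otherwise.
    """
    thF = curve.theta_F
    thU = curve.theta_U
    if thF is None or thU is None:
        eF, eU = _estimate_baselines(curve)
        thF = eF if thF is None else thF
        thU = eU if thU is None else thU
    if thF == thU:
        raise ZeroDivisionError("degenerate baselines: theta_F == theta_U")
    f = (curve.ellipticities - thU) / (thF - thU)
    if complement:
        f = 1.0 - f
    if clip:
        f = np.clip(f, 0.0, 1.0)
    return f


def _boltzmann(T, Tm, width, thF, thU, mF, mU):
    frac_u = 1.0 / (1.0 + np.exp((Tm - T) / width))
    base_f = thF + mF * (T - T.min())
    base_u = thU + mU * (T - T.min())
    return base_f + (base_u - base_f) * frac_u


def fit_two_state_melt(curve: MeltingCurve, linear_baselines: bool = False) -> TwoStateFit:
    """Boltzmann-sigmoid fit of a CD melt; Tm is the f = 0.5 temperature.

    Raises a fit error if no transition is detectable (monotone baseline-like
    curve with no inflection amplitude).
    """
    T, y = curve.temperatures, curve.ellipticities
    amplitude = float(np.ptp(y))
    noise_scale = float(np.std(np.diff(y))) / np.sqrt(2.0)
    if amplitude < 6.0 * noise_scale or amplitude == 0.0:
        raise RuntimeError("no unfolding transition detected (flat curve)")
    dy = np.gradient(y, T)
    Tm0 = float(T[np.argmax(np.abs(dy))])
    thF0, thU0 = _estimate_baselines(curve)
    p0 = [Tm0, 3.0, thF0, thU0, 0.0, 0.0]
    if linear_baselines:
        fun = _boltzmann
        bounds = (
            [T.min(), 0.05, -np.inf, -np.inf, -np.inf, -np.inf],
            [T.max(), 0.5 * np.ptp(T), np.inf, np.inf, np.inf, np.inf],
        )
    else:
        fun = lambda T, Tm, width, thF, thU: _boltzmann(T, Tm, width, thF, thU, 0.0, 0.0)
        p0 = p0[:4]
        bounds = (
            [T.min(), 0.05, -np.inf, -np.inf],
            [T.max(), 0.5 * np.ptp(T), np.inf, np.inf],
        )
    try:
        popt, _ = curve_fit(fun, T, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"melt fit failed: {exc}") from exc
    Tm, width, thF, thU = popt[:4]
    mF, mU = (popt[4], popt[5]) if linear_baselines else (0.0, 0.0)
    frac_u = 1.0 / (1.0 + np.exp((Tm - T) / width))
    resid = y - fun(T, *popt)
    # two-state van't Hoff enthalpy implied by the transition width
    dH_vh = R_GAS_CAL * (Tm + 273.15) ** 2 / width
    return TwoStateFit(
        Tm=float(Tm),
        width=float(width),
        theta_F=float(thF),
        theta_U=float(thU),
        slope_F=float(mF),
        slope_U=float(mU),
        dH_vantHoff=float(dH_vh),
        fraction=frac_u,
        residual_rmse=float(np.sqrt(np.mean(resid**2))),
    )


# ---------------------------------------------------------------------------
# EMSA hyperbolic binding
# ---------------------------------------------------------------------------


@dataclass
class BindingCurve:
    """Densitometry titration: x in uM, y in arbitrary intensity units."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) < 3:
            raise ValueError("binding curve needs at least 3 points")
        if np.any(self.x < 0):
            raise ValueError("negative concentration")


@dataclass(frozen=True)
class HyperbolicFit:
    Vmax: float
    Kd: float
    sigma_Kd: float
    R: float  # correlation coefficient of observed vs fitted


def fit_hyperbolic(curve: BindingCurve) -> HyperbolicFit:
    """Least-squares fit of y = Vmax * x / (Kd + x).

    Seeded with Vmax ~ max(y) and Kd ~ the x where y reaches half of that
    (the model satisfies y(Kd) = Vmax/2 exactly).  The reported R is the
    Pearson correlation between observed and fitted intensities.
    """
    x, y = curve.x, curve.y
    if np.allclose(y, 0):
        raise RuntimeError("all-zero intensities: nothing to fit")
    vmax0 = float(y.max()) * 1.2
    half = vmax0 / 2.0
    kd0 = float(x[np.argmin(np.abs(y - half))]) or float(np.median(x[x > 0]))
    popt, pcov = curve_fit(
        lambda x, vmax, kd: vmax * x / (kd + x),
        x,
        y,
        p0=[vmax0, kd0],
        bounds=([0, 1e-9], [np.inf, np.inf]),
        maxfev=20000,
    )
    vmax, kd = popt
    fitted = vmax * x / (kd + x)
    if np.std(fitted) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(y, fitted)[0, 1])
    return HyperbolicFit(
        Vmax=float(vmax),
        Kd=float(kd),
        sigma_Kd=float(np.sqrt(np.abs(pcov[1, 1]))),
        R=r,
    )


# ---------------------------------------------------------------------------
# ITC sequential two-site isotherm
# ---------------------------------------------------------------------------


@dataclass
class ITCExperiment:
    """Calorimeter titration geometry and observed per-injection heats.

    ``cell_volume_ml``: active cell volume V0.  ``cell_conc_uM``: initial
    macromolecule concentration M in the cell.  ``syringe_conc_uM``: ligand
    X in the syringe.  Heats are integrated injection areas in ucal.
    """

    cell_volume_ml: float
    cell_conc_uM: float
    syringe_conc_uM: float
    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
            if len(self.heats_ucal) != len(self.injection_volumes_uL):
                raise ValueError("heats and injection volumes differ in length")
        if min(self.cell_volume_ml, self.cell_conc_uM, self.syringe_conc_uM) <= 0:
            raise ValueError("cell volume and concentrations must be positive")
        if len(self.injection_volumes_uL) < 5:
            raise ValueError("need at least 5 injections")

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """(M_t, X_t) in molar after each injection, MicroCal displaced-volume
        bookkeeping: M_t = M0 (1 - v/2V0)/(1 + v/2V0), X_t = X0 (v/V0)/(1 + v/2V0)."""
        V0 = self.cell_volume_ml * 1e-3  # L
        v = np.cumsum(self.injection_volumes_uL) * 1e-6  # L
        M0 = self.cell_conc_uM * 1e-6
        X0 = self.syringe_conc_uM * 1e-6
        Mt = M0 * (1 - v / (2 * V0)) / (1 + v / (2 * V0))
        Xt = X0 * (v / V0) / (1 + v / (2 * V0))
        return Mt, Xt


@dataclass(frozen=True)
class SequentialSitesModel:
    """Two sequential binding constants (M^-1) and stepwise enthalpies (cal/mol)."""

    K1: float
    K2: float = 0.0
    dH1: float = 0.0
    dH2: float = 0.0
    offset_ucal: float = 0.0  # heat of dilution per injection

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.K2 < 0:
            raise ValueError("binding constants must be non-negative")

    @property
    def effective_Kd_M(self) -> float:
        """1/K of the dominant (tighter) step."""
        return 1.0 / max(self.K1, self.K2) if max(self.K1, self.K2) > 0 else float("inf")


def _free_ligand(Xt: float, Mt: float, K1: float, K2: float) -> float:
    """Solve X_t = [X] + M_t (K1[X] + 2 K1 K2 [X]^2) / P for free [X] by
    bisection (brentq) on [0, X_t]; P = 1 + K1[X] + K1 K2 [X]^2."""
    if Xt <= 0:
        return 0.0

    def g(x: float) -> float:
        p = 1.0 + K1 * x + K1 * K2 * x * x
        bound = Mt * (K1 * x + 2.0 * K1 * K2 * x * x) / p
        return x + bound - Xt

    if g(Xt) <= 0:  # no macromolecule binding
        return Xt
    return brentq(g, 0.0, Xt, xtol=1e-30, rtol=1e-14, maxiter=200)


def itc_cumulative_heat(
    model: SequentialSitesModel, exp: ITCExperiment
) -> np.ndarray:
    """Cumulative evolved heat Q(i) in ucal after each injection."""
    Mt, Xt = exp.totals()
    V0 = exp.cell_volume_ml * 1e-3
    Q = np.empty(len(Mt))
    for i, (m, x) in enumerate(zip(Mt, Xt)):
        xf = _free_ligand(x, m, model.K1, model.K2)
        p = 1.0 + model.K1 * xf + model.K1 * model.K2 * xf * xf
        F1 = model.K1 * xf / p
        F2 = model.K1 * model.K2 * xf * xf / p
        Q[i] = V0 * m * (model.dH1 * F1 + (model.dH1 + model.dH2) * F2) * 1e6
    return Q


def itc_sequential_heats(
    model: SequentialSitesModel,
    exp: ITCExperiment,
    volume_correction: bool = True,
) -> np.ndarray:
    """Predicted per-injection heats (ucal).

    dQ(i) = Q(i) - Q(i-1) + (dV_i/V0) * (Q(i) + Q(i-1))/2 when the
    displaced-volume correction is on, plus the constant dilution offset.
    With the correction off the heats telescope exactly to Q(N).
    """
    Q = itc_cumulative_heat(model, exp)
    V0 = exp.cell_volume_ml * 1e-3
    dv = exp.injection_volumes_uL * 1e-6
    Qprev = np.concatenate(([0.0], Q[:-1]))
    dQ = Q - Qprev
    if volume_correction:
        dQ = dQ + (dv / V0) * (Q + Qprev) / 2.0
    return dQ + model.offset_ucal


def itc_single_site_heats(
    K: float,
    dH: float,
    exp: ITCExperiment,
    volume_correction: bool = True,
) -> np.ndarray:
    """Closed-form single-site (Wiseman, n = 1) per-injection heats in ucal.

    Q = (V0 M_t dH / 2) * [b - sqrt(b^2 - 4 X_t/M_t)] with
    b = 1 + X_t/M_t + 1/(K M_t); used as the independent oracle for the
    sequential model at K2 = 0.
    """
    Mt, Xt = exp.totals()
    V0 = exp.cell_volume_ml * 1e-3
    b = 1.0 + Xt / Mt + 1.0 / (K * Mt)
    Q = (V0 * Mt * dH / 2.0) * (b - np.sqrt(b * b - 4.0 * Xt / Mt)) * 1e6
    dv = exp.injection_volumes_uL * 1e-6
    Qprev = np.concatenate(([0.0], Q[:-1]))
    dQ = Q - Qprev
    if volume_correction:
        dQ = dQ + (dv / V0) * (Q + Qprev) / 2.0
    return dQ


def fit_itc(
    exp: ITCExperiment,
    n_sites: int = 2,
    fit_offset: bool = True,
    k_grid: np.ndarray | None = None,
) -> SequentialSitesModel:
    """Nonlinear least-squares fit of the sequential-sites isotherm.

    Parameters are (log10 K1[, log10 K2], dH1[, dH2][, offset]); a
    multi-start over log-spaced K grids guards against the shallow valleys
    typical of two-constant isotherms, and the best residual sum wins.
    Warns when the Wiseman c-value (K1 * M0) is far outside [1, 1000].
    """
    import warnings

    if exp.heats_ucal is None:
        raise ValueError("experiment carries no observed heats")
    y = exp.heats_ucal
    if np.allclose(y, 0.0, atol=1e-12):
        warnings.warn("all-zero heats: K unidentifiable, returning dH = 0", stacklevel=2)
        return SequentialSitesModel(K1=1.0, K2=0.0, dH1=0.0, dH2=0.0)
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")

    Mt, Xt = exp.totals()
    V0 = exp.cell_volume_ml * 1e-3
    total_heat = float(np.sum(y))
    dH_scale = total_heat / (V0 * Mt[-1] * 1e6) or 1.0

    def unpack(theta):
        logK1 = theta[0]
        if n_sites == 2:
            logK2, dH1, dH2 = theta[1], theta[2], theta[3]
            off = theta[4] if fit_offset else 0.0
        else:
            logK2, dH1, dH2 = -np.inf, theta[1], 0.0
            off = theta[2] if fit_offset else 0.0
        return SequentialSitesModel(
            K1=10.0**logK1,
            K2=0.0 if np.isinf(logK2) else 10.0**logK2,
            dH1=dH1,
            dH2=dH2,
            offset_ucal=off,
        )

    def resid(theta):
        return itc_sequential_heats(unpack(theta), exp) - y

    grid = k_grid if k_grid is not None else np.arange(3.0, 8.1, 0.5)
    if n_sites == 2:
        lo = [0.0, 0.0, -np.inf, -np.inf]
        hi = [12.0, 12.0, np.inf, np.inf]
    else:
        lo, hi = [0.0, -np.inf], [12.0, np.inf]
    if fit_offset:
        lo, hi = lo + [-np.inf], hi + [np.inf]
    best, best_cost = None, np.inf
    for logk1 in grid:
        starts = [logk1 - 2.0, logk1 - 1.0, logk1] if n_sites == 2 else [None]
        for logk2 in starts:
            if n_sites == 2:
                theta0 = [logk1, logk2, dH_scale / 2, dH_scale / 2]
            else:
                theta0 = [logk1, dH_scale]
            if fit_offset:
                theta0 = theta0 + [0.0]
            try:
                sol = least_squares(
                    resid, theta0, method="trf", bounds=(lo, hi), max_nfev=2000
                )
            except Exception:
                continue
            if sol.cost < best_cost:
                best, best_cost = sol, sol.cost
    if best is None:
        raise RuntimeError("ITC fit failed from every start")
    model = unpack(best.x)
    c_value = model.K1 * exp.cell_conc_uM * 1e-6
    if not (0.5 <= c_value <= 5000):
        warnings.warn(
            f"c-value {c_value:.3g} outside the well-conditioned range [1, 1000]",
            stacklevel=2,
        )
    return model
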