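"""Per-residue 15N relaxation analysis: R1/R2 decay fits, heteronuclear NOE,
R2/R1 ratios and region statistics.

Longitudinal (R1 = 1/T1) and transverse (R2 = 1/T2) rates are obtained from
two-parameter exponential fits I(t) = I0 * exp(-R t) of peak-intensity decay
series; a three-parameter inversion-recovery model A + B*exp(-R t) is
available for T1 data acquired that way.  Delay points recorded twice give a
pooled noise estimate used for Monte-Carlo rate uncertainties.

The steady-state {1H}-15N NOE is the plain intensity ratio I_sat / I_eq of
spectra recorded with and without proton saturation; values near 1 mark a
rigid backbone amide, low or negative values mark fast internal motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .structure_io import ResidueRange

__all__ = [
    "DecaySeries",
    "RateResult",
    "HetNoeRecord",
    "RegionStats",
    "fit_decay",
    "duplicate_noise",
    "compute_hetnoe",
    "r2_over_r1",
    "region_stats",
    "classify_flexibility",
]

#: delay schedules used for the 800 MHz T1 (inversion recovery) and T2 (CPMG)
#: series, in seconds; starred entries of the schedule were recorded twice.
T1_DELAYS_S = (0.050, 0.100, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.020)
T1_DUPLICATE_DELAYS_S = (0.200, 0.600)
T2_DELAYS_S = (0.010, 0.030, 0.050, 0.070, 0.090, 0.110, 0.130, 0.150, 0.170, 0.190)
T2_DUPLICATE_DELAYS_S = (0.050, 0.110)


@dataclass
class DecaySeries:
    """Intensity decay for one residue over a relaxation delay schedule."""

    res_seq: int
    delays: np.ndarray
    intensities: np.ndarray
    duplicate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.duplicate_mask is None:
            self.duplicate_mask = np.zeros(len(self.delays), dtype=bool)
        else:
            self.duplicate_mask = np.asarray(self.duplicate_mask, dtype=bool)
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have the same length")
        if np.any(self.delays < 0):
            raise ValueError("negative relaxation delay")
        if len(np.unique(self.delays)) < 4:
            raise ValueError("need at least 4 distinct delays for a rate fit")


@dataclass(frozen=True)
class RateResult:
    res_seq: int
    R: float
    sigma_R: float
    I0: float
    fit_rmse: float

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"fitted rate must be positive, got {self.R}")


@dataclass(frozen=True)
class HetNoeRecord:
    res_seq: int
    I_sat: float
    I_eq: float
    noe: float
    sigma: float


@dataclass(frozen=True)
class RegionStats:
    label: str
    mean: float
    sd: float
    n: int


def duplicate_noise(series_list: Iterable[DecaySeries]) -> float:
    """Pooled intensity noise from duplicate-delay pairs.

    RMS of paired differences divided by sqrt(2), pooled over residues.
    Returns nan when no duplicates exist.
    """
    diffs: list[float] = []
    for s in series_list:
        dup_delays = np.unique(s.delays[s.duplicate_mask])
        for d in dup_delays:
            vals = s.intensities[s.delays == d]
            if len(vals) >= 2:
                diffs.extend(np.diff(vals))
    if not diffs:
        return float("nan")
    return float(np.sqrt(np.mean(np.square(diffs))) / np.sqrt(2.0))


def _exp2(t: np.ndarray, I0: float, R: float) -> np.ndarray:
    return I0 * np.exp(-R * t)


def _exp3(t: np.ndarray, A: float, B: float, R: float) -> np.ndarray:
    return A + B * np.exp(-R * t)


def fit_decay(
    series: DecaySeries,
    model: str = "exp",
    noise: float | None = None,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> RateResult:
    """Fit an exponential relaxation decay and return the rate in 1/s.

    The initial guess comes from log-linear regression on the
    positive-intensity points.  ``sigma_R`` is the larger of the
    nonlinear-fit covariance estimate and, when ``noise`` (for example from
    :func:`duplicate_noise`) is given, a Monte-Carlo resampling estimate with
    ``n_boot`` replicates.
    """
    scale = float(np.abs(series.intensities).max())
    if scale == 0:
        raise ValueError("all-zero intensities")
    t, y = series.delays, series.intensities / scale  # exact scale invariance
    if noise is not None:
        noise = noise / scale
    pos = y > 0
    if pos.sum() < 3:
        raise ValueError("too few positive intensities for a decay fit")
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    R0 = max(-slope, 1e-3)
    I0_0 = float(np.exp(intercept))

    if model == "exp":
        fun, p0 = _exp2, [I0_0, R0]
    elif model == "inv_recovery":
        fun, p0 = _exp3, [0.0, I0_0, R0]
    else:
        raise ValueError(f"unknown decay model {model!r}")
    try:
        popt, pcov = curve_fit(fun, t, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit failed for residue {series.res_seq}: {exc}; "
            f"residual range {np.ptp(y):.3g}"
        ) from exc
    if model == "exp":
        I0, R = popt
        r_idx = 1
    else:
        _, B, R = popt
        I0 = popt[0] + B
        r_idx = 2
    if R <= 0:
        raise RuntimeError(f"non-physical rate {R:.3g} for residue {series.res_seq}")
    resid = y - fun(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    sigma_cov = float(np.sqrt(np.abs(pcov[r_idx, r_idx])))

    sigma_mc = 0.0
    if noise is not None and np.isfinite(noise) and noise > 0 and n_boot > 0:
        rng = rng or np.random.default_rng(0)
        rates = []
        for _ in range(n_boot):
            y_b = fun(t, *popt) + rng.normal(0.0, noise, size=len(t))
            try:
                popt_b, _ = curve_fit(fun, t, y_b, p0=popt, maxfev=5000)
                if popt_b[r_idx] > 0:
                    rates.append(popt_b[r_idx])
            except RuntimeError:
                continue
        if len(rates) >= 10:
            sigma_mc = float(np.std(rates, ddof=1))

    return RateResult(
        res_seq=series.res_seq,
        R=float(R),
        sigma_R=max(sigma_cov, sigma_mc),
        I0=float(I0) * scale,
        fit_rmse=rmse * scale,
    )


def fit_decay_table(
    table: pd.DataFrame,
    model: str = "exp",
    use_duplicate_noise: bool = True,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Fit every residue of a tidy decay table.

    Expects columns ``res_seq, delay_s, intensity`` and optionally
    ``is_duplicate``.  Returns per-residue columns ``res_seq, R, sigma_R, I0,
    fit_rmse``.
    """
    series = []
    for res, grp in table.groupby("res_seq"):
        dup = (
            grp["is_duplicate"].to_numpy(dtype=bool)
            if "is_duplicate" in grp
            else None
        )
        series.append(
            DecaySeries(
                res_seq=int(res),
                delays=grp["delay_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                duplicate_mask=dup,
            )
        )
    noise = duplicate_noise(series) if use_duplicate_noise else None
    rows = [fit_decay(s, model=model, noise=noise, n_boot=n_boot) for s in series]
    return pd.DataFrame(
        [(r.res_seq, r.R, r.sigma_R, r.I0, r.fit_rmse) for r in rows],
        columns=["res_seq", "R", "sigma_R", "I0", "fit_rmse"],
    )


def compute_hetnoe(
    res_seq: int,
    I_sat: float,
    I_eq: float,
    noise_sat: float = 0.0,
    noise_eq: float = 0.0,
) -> HetNoeRecord:
    """Steady-state heteronuclear NOE ratio I_sat/I_eq with propagated error.

    Negative ratios are valid (fast-motion termini); I_eq = 0 is undefined.
    """
    if I_eq == 0:
        raise ZeroDivisionError(f"residue {res_seq}: I_eq is zero, NOE undefined")
    noe = I_sat / I_eq
    # first-order ratio error propagation, written to stay finite at I_sat = 0
    sigma = np.sqrt((noise_sat / I_eq) ** 2 + (noe * noise_eq / I_eq) ** 2)
    return HetNoeRecord(res_seq=res_seq, I_sat=I_sat, I_eq=I_eq, noe=float(noe), sigma=float(sigma))


def hetnoe_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`compute_hetnoe` to a table (res_seq, I_sat, I_eq[, noise])."""
    rows = []
    for row in table.itertuples():
        noise = getattr(row, "noise", 0.0)
        rec = compute_hetnoe(int(row.res_seq), row.I_sat, row.I_eq, noise, noise)
        rows.append((rec.res_seq, rec.noe, rec.sigma))
    return pd.DataFrame(rows, columns=["res_seq", "noe", "sigma"])


def r2_over_r1(r1: pd.DataFrame, r2: pd.DataFrame) -> pd.DataFrame:
    """Per-residue R2/R1 ratio with first-order propagated uncertainty.

    Both inputs are per-residue rate tables (``res_seq, R, sigma_R``); the
    residue sets must match exactly.  Region averages should be taken over
    these per-residue ratios, not as a ratio of region-average rates.
    """
    s1, s2 = set(r1["res_seq"]), set(r2["res_seq"])
    if s1 != s2:
        raise ValueError(
            f"R1/R2 residue sets differ: only-in-R1={sorted(s1 - s2)[:5]}, "
            f"only-in-R2={sorted(s2 - s1)[:5]}"
        )
    m = r1.merge(r2, on="res_seq", suffixes=("_1", "_2")).sort_values("res_seq")
    ratio = m["R_2"] / m["R_1"]
    sigma = ratio * np.sqrt(
        (m["sigma_R_1"] / m["R_1"]) ** 2 + (m["sigma_R_2"] / m["R_2"]) ** 2
    )
    return pd.DataFrame(
        {"res_seq": m["res_seq"], "ratio": ratio, "sigma": sigma}
    ).reset_index(drop=True)


def region_stats(
    values: Mapping[int, float] | pd.Series,
    ranges: Sequence[ResidueRange],
    label: str = "",
    exclusions: Sequence[int] = (),
) -> RegionStats:
    """Mean +/- SD of a per-residue quantity over residue ranges.

    ``exclusions`` removes residues (prolines, overlapped peaks) before
    averaging.  SD uses n-1 weighting.
    """
    if not ranges:
        raise ValueError("no ranges given")
    if isinstance(values, pd.Series):
        values = values.to_dict()
    excl = set(exclusions)
    included = [
        v
        for res, v in sorted(values.items())
        if res not in excl and any(res in r for r in ranges)
    ]
    if not included:
        raise ValueError(f"region {label!r}: no residues left after exclusions")
    arr = np.asarray(included, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else float("nan")
    return RegionStats(label=label, mean=float(arr.mean()), sd=sd, n=len(arr))


def classify_flexibility(
    noe_profile: Mapping[int, float] | pd.Series,
    ratio_profile: Mapping[int, float] | pd.Series,
    structured_ranges: Sequence[ResidueRange],
    noe_threshold: float = 0.65,
    ratio_fraction: float = 0.75,
) -> pd.DataFrame:
    """Label residues rigid/flexible from NOE and R2/R1 profiles.

    A residue is flexible when its NOE falls below ``noe_threshold`` or its
    R2/R1 falls below ``ratio_fraction`` times the median ratio of the
    structured regions.
    """
    if isinstance(noe_profile, pd.Series):
        noe_profile = noe_profile.to_dict()
    if isinstance(ratio_profile, pd.Series):
        ratio_profile = ratio_profile.to_dict()
    structured_ratios = [
        v
        for res, v in ratio_profile.items()
        if any(res in r for r in structured_ranges)
    ]
    ratio_cut = ratio_fraction * float(np.median(structured_ratios))
    rows = []
    for res in sorted(set(noe_profile) & set(ratio_profile)):
        flexible = noe_profile[res] < noe_threshold or ratio_profile[res] < ratio_cut
        rows.append((res, "flexible" if flexible else "rigid"))
    return pd.DataFrame(rows, columns=["res_seq", "label"])
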