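"""Closed-chamber CH4 flux estimation and cumulative emissions.

A sealed jar over soil accumulates (or depletes) headspace CH4; the flux is
the slope of headspace CH4 mass against time, normalised by dry soil mass.
Mixing ratios (ppm, i.e. µmol CH4 per mol headspace gas) are converted to
mass with the ideal gas law; an early transient while the closed loop
stabilises is trimmed before an ordinary least-squares fit.

Units throughout: time s, pressure atm, volume L, temperature K, mass µg,
flux µg (C–CH4 or CH4) per g dry soil per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Ideal gas constant in L·atm·mol⁻¹·K⁻¹ (two-decimal convention used in
#: chamber-flux work; kept at this precision deliberately).
R_L_ATM = 0.082

MOLAR_MASS_CH4 = 16.043  # g/mol
MOLAR_MASS_C = 12.011  # g/mol

#: Factor converting a CH4 mass to its carbon mass.
C_PER_CH4 = MOLAR_MASS_C / MOLAR_MASS_CH4


class InsufficientDataError(ValueError):
    """Trimming or fitting left too few readings to proceed."""


class SingularFitError(ValueError):
    """Regression design is singular (e.g. all times identical)."""


@dataclass(frozen=True)
class ChamberSeries:
    """One jar × day headspace CH4 concentration time course.

    Parameters
    ----------
    times : array of s, strictly increasing
    ch4_ppm : mixing ratio, µmol mol⁻¹
    pressure_atm, volume_L, temp_K, soil_dry_mass_g : jar physical metadata
    """

    jar_id: str
    times: np.ndarray
    ch4_ppm: np.ndarray
    pressure_atm: float
    volume_L: float
    temp_K: float
    soil_dry_mass_g: float
    site: str = ""
    temperature_level: float = float("nan")
    flooding_level: str = ""
    replicate: int = 0
    day: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.ch4_ppm, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ch4_ppm", c)
        if t.size != c.size:
            raise ValueError("times and ch4_ppm must have equal length")
        if t.size < 2:
            raise ValueError("a chamber series needs at least 2 readings")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("pressure_atm", "volume_L", "temp_K", "soil_dry_mass_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FluxEstimate:
    """OLS flux estimate for one chamber series.

    ``slope_ug_per_h`` is the raw mass slope (µg h⁻¹, on the chosen mass
    basis); ``flux`` divides it by dry soil mass. Negative flux means net
    CH4 consumption by the soil.
    """

    jar_id: str
    slope_ug_per_h: float
    flux: float
    intercept: float
    r2: float
    n_points: int
    window_s: tuple[float, float]
    mass_basis: str
    qc_pass: bool | None = None
    site: str = ""
    temperature_level: float = float("nan")
    flooding_level: str = ""
    replicate: int = 0
    day: int = 0


@dataclass(frozen=True)
class CumulativeFlux:
    """Per-treatment daily mean fluxes and their time integral."""

    treatment: tuple
    days: tuple[int, ...]
    daily_means: tuple[float, ...]
    cumulative: float  # µg g dw⁻¹ over the experiment window
    daily_sd: tuple[float, ...] = ()
    daily_n: tuple[int, ...] = ()


def ppm_to_mass(
    ppm: float | np.ndarray,
    pressure_atm: float,
    volume_L: float,
    temp_K: float,
    molar_mass_g_mol: float = MOLAR_MASS_CH4,
) -> float | np.ndarray:
    """Convert a CH4 mixing ratio to headspace CH4 mass in µg.

    ppm is µmol CH4 per mol headspace; the headspace holds
    ``P·V/(R·T)`` mol, so ``mass = ppm · MM · P·V/(R·T)`` µg
    (µmol × g mol⁻¹ = µg). Linear and homogeneous in ppm.
    """
    if pressure_atm <= 0 or volume_L <= 0 or temp_K <= 0:
        raise ValueError("pressure, volume and temperature must be positive")
    if np.any(np.asarray(ppm) < 0):
        raise ValueError("ppm must be non-negative")
    return ppm * molar_mass_g_mol * (pressure_atm * volume_L) / (R_L_ATM * temp_K)


def trim_window(
    series: ChamberSeries, exclude_first_s: float = 100.0, end_s: float = 600.0
) -> ChamberSeries:
    """Drop the stabilization transient: keep readings with
    ``exclude_first_s < t ≤ end_s``, order preserved."""
    keep = (series.times > exclude_first_s) & (series.times <= end_s)
    if keep.sum() == 0:
        raise InsufficientDataError(
            f"no readings in ({exclude_first_s}, {end_s}] s for jar {series.jar_id}"
        )
    return replace(series, times=series.times[keep], ch4_ppm=series.ch4_ppm[keep])


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r² of y on x; r² defined as 0 for zero-variance y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise SingularFitError("all time points identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0.0:
        return slope, intercept, 0.0
    resid = y - (intercept + slope * x)
    r2 = 1.0 - float(np.sum(resid**2)) / syy
    return slope, intercept, min(max(r2, 0.0), 1.0)


def fit_flux(series: ChamberSeries, mass_basis: str = "C") -> FluxEstimate:
    """Estimate the CH4 flux of a (trimmed) chamber series by OLS.

    Each reading is converted to headspace CH4 mass (µg), mass is regressed
    on time (s), and the slope is scaled to per-hour and divided by the dry
    soil mass. With ``mass_basis="C"`` the result is µg C–CH4 g dw⁻¹ h⁻¹
    (CH4 mass × 12.011/16.043); ``"CH4"`` reports the full molecular mass.
    The slope sign is preserved: negative = net consumption.
    """
    if mass_basis not in ("C", "CH4"):
        raise ValueError("mass_basis must be 'C' or 'CH4'")
    mass_ug = ppm_to_mass(
        series.ch4_ppm, series.pressure_atm, series.volume_L, series.temp_K
    )
    if mass_basis == "C":
        mass_ug = mass_ug * C_PER_CH4
    slope_per_s, intercept, r2 = _ols(series.times, mass_ug)
    slope_per_h = slope_per_s * 3600.0
    return FluxEstimate(
        jar_id=series.jar_id,
        slope_ug_per_h=slope_per_h,
        flux=slope_per_h / series.soil_dry_mass_g,
        intercept=intercept,
        r2=r2,
        n_points=series.n,
        window_s=(float(series.times[0]), float(series.times[-1])),
        mass_basis=mass_basis,
        site=series.site,
        temperature_level=series.temperature_level,
        flooding_level=series.flooding_level,
        replicate=series.replicate,
        day=series.day,
    )


def qc_flux(estimate: FluxEstimate, r2_threshold: float = 0.9) -> FluxEstimate:
    """Flag the estimate with ``qc_pass = r² > threshold`` (strict).

    QC failures are flagged, never dropped here; exclusion is a downstream
    decision.
    """
    return replace(estimate, qc_pass=bool(estimate.r2 > r2_threshold))


def estimate_flux(
    series: ChamberSeries,
    exclude_first_s: float = 100.0,
    end_s: float = 600.0,
    mass_basis: str = "C",
    r2_threshold: float = 0.9,
) -> FluxEstimate:
    """Trim, fit and QC-flag in one call (the per-jar pipeline step)."""
    return qc_flux(
        fit_flux(trim_window(series, exclude_first_s, end_s), mass_basis),
        r2_threshold,
    )


def daily_treatment_flux(estimates: Sequence[FluxEstimate]) -> tuple[float, float, int]:
    """Arithmetic mean of replicate fluxes for one treatment × day.

    Returns ``(mean, sd, n)``; sd is the sample standard deviation (ddof=1,
    NaN for a single replicate).
    """
    if len(estimates) == 0:
        raise ValueError("no replicate estimates for this treatment/day")
    fluxes = np.array([e.flux for e in estimates], dtype=float)
    sd = float(np.std(fluxes, ddof=1)) if fluxes.size > 1 else float("nan")
    return float(fluxes.mean()), sd, int(fluxes.size)


def cumulative_emission(daily_means: Mapping[int, float]) -> float:
    """Cumulative emission by linear interpolation of daily fluxes.

    Trapezoidal rule over consecutive sampling days:
    ``Σ 0.5·(f_i + f_{i+1}) · 24·(d_{i+1} − d_i)`` — exact for a
    piecewise-linear flux profile. Input flux units per hour; days are
    converted to hours. Missing days are simply absent nodes (the
    interpolation spans the gap).
    """
    days = list(daily_means.keys())
    if len(days) < 2:
        raise ValueError("cumulative emission needs at least 2 sampling days")
    if len(set(days)) != len(days) or sorted(days) != days:
        raise ValueError("days must be sorted and unique")
    d = np.asarray(days, dtype=float)
    f = np.asarray([daily_means[k] for k in days], dtype=float)
    return float(np.trapezoid(f, d * 24.0))


def flux_table(estimates: Iterable[FluxEstimate]) -> pd.DataFrame:
    """Tidy DataFrame of flux estimates (one row per jar × day)."""
    rows = [
        {
            "jar_id": e.jar_id,
            "site": e.site,
            "temperature": e.temperature_level,
            "flooding": e.flooding_level,
            "replicate": e.replicate,
            "day": e.day,
            "flux": e.flux,
            "slope_ug_per_h": e.slope_ug_per_h,
            "intercept": e.intercept,
            "r2": e.r2,
            "n_points": e.n_points,
            "mass_basis": e.mass_basis,
            "qc_pass": e.qc_pass,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def cumulative_by_treatment(
    estimates: Iterable[FluxEstimate], qc_drop: bool = False
) -> list[CumulativeFlux]:
    """Daily treatment means and cumulative emissions for every treatment.

    Treatments are keyed by (site, temperature, flooding). With
    ``qc_drop=True`` estimates flagged ``qc_pass=False`` are excluded from
    the daily means (days losing all replicates drop out of the integral).
    """
    df = flux_table(estimates)
    if qc_drop:
        df = df[df["qc_pass"].fillna(True)]
    out: list[CumulativeFlux] = []
    for key, grp in df.groupby(["site", "temperature", "flooding"], sort=True):
        daily = grp.groupby("day")["flux"].agg(["mean", "std", "count"]).sort_index()
        if len(daily) < 2:
            continue
        means = {int(d): float(m) for d, m in daily["mean"].items()}
        out.append(
            CumulativeFlux(
                treatment=key,
                days=tuple(means.keys()),
                daily_means=tuple(means.values()),
                cumulative=cumulative_emission(means),
                daily_sd=tuple(float(s) for s in daily["std"]),
                daily_n=tuple(int(c) for c in daily["count"]),
            )
        )
    return out


def read_series_csv(path) -> list[ChamberSeries]:
    """Read chamber series from a long-format CSV.

    Expected columns: ``jar_id,site,temperature,flooding,replicate,day,
    time_s,ch4_ppm,pressure_atm,volume_L,temp_K,soil_dry_mass_g`` — one row
    per reading.
    """
    df = pd.read_csv(path)
    series = []
    for (jar, day), grp in df.groupby(["jar_id", "day"], sort=True):
        grp = grp.sort_values("time_s")
        first = grp.iloc[0]
        series.append(
            ChamberSeries(
                jar_id=str(jar),
                times=grp["time_s"].to_numpy(float),
                ch4_ppm=grp["ch4_ppm"].to_numpy(float),
                pressure_atm=float(first["pressure_atm"]),
                volume_L=float(first["volume_L"]),
                temp_K=float(first["temp_K"]),
                soil_dry_mass_g=float(first["soil_dry_mass_g"]),
                site=str(first.get("site", "")),
                temperature_level=float(first.get("temperature", math.nan)),
                flooding_level=str(first.get("flooding", "")),
                replicate=int(first.get("replicate", 0)),
                day=int(day),
            )
        )
    return series
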