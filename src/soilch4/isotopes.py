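"""Stable-isotope δ arithmetic, Keeling plots, and pathway classification.

δ notation expresses an isotope ratio R as a per-mil deviation from an
international standard (VPDB for ¹³C/¹²C, VSMOW for ²H/¹H):
``δ = (R_sample/R_standard − 1) × 1000``.

A Keeling plot regresses the δ of a two-member mixture (atmospheric
background + soil-derived CH4) against inverse total concentration; mass
conservation makes the mixing line exactly linear in 1/C and its intercept
(1/C → 0) is the δ of the added source. The source (δ¹³C, δ²H) pair then
places the CH4 on the classical production-pathway diagram: hydrogenotrophic
(CO2/H2) methanogenesis yields more ¹³C-depleted but ²H-enriched CH4 than
acetoclastic methanogenesis, while oxidation enriches the residual CH4 in
both heavy isotopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeSample",
    "KeelingFit",
    "PathwayRegions",
    "PathwaySignature",
    "delta_value",
    "ratio_from_delta",
    "keeling_intercept",
    "classify_pathway",
]


class DegenerateDesignError(ValueError):
    """All concentrations identical: the Keeling regression is undefined."""


@dataclass(frozen=True)
class IsotopeSample:
    """End-of-incubation headspace gas sample with dual isotope values."""

    ch4_ppm: float
    d13C: float  # ‰ vs VPDB
    d2H: float  # ‰ vs VSMOW
    is_background: bool = False
    sample_id: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.ch4_ppm <= 0:
            raise ValueError("ch4_ppm must be positive")
        if not (np.isfinite(self.d13C) and np.isfinite(self.d2H)):
            raise ValueError("delta values must be finite")


@dataclass(frozen=True)
class KeelingFit:
    intercept: float  # ‰, mean-source δ
    slope: float  # ‰·ppm
    r2: float
    n: int
    isotope_system: str  # "13C" | "2H"


@dataclass(frozen=True)
class PathwayRegions:
    """Rectangular (δ¹³C, δ²H) regions for the production pathways.

    Defaults follow the classical diagram: hydrogenotrophic CH4 at
    δ¹³C −110…−60 ‰ / δ²H −250…−170 ‰, acetoclastic CH4 at δ¹³C −60…−50 ‰ /
    δ²H −400…−250 ‰. Values enriched beyond both oxidation thresholds
    (defaults: the upper production-box edges) are classed as
    oxidation-enriched residual CH4.
    """

    hydrogenotrophic_d13C: tuple[float, float] = (-110.0, -60.0)
    hydrogenotrophic_d2H: tuple[float, float] = (-250.0, -170.0)
    acetoclastic_d13C: tuple[float, float] = (-60.0, -50.0)
    acetoclastic_d2H: tuple[float, float] = (-400.0, -250.0)
    oxidation_d13C_above: float = -50.0
    oxidation_d2H_above: float = -170.0

    def __post_init__(self) -> None:
        for name in (
            "hydrogenotrophic_d13C",
            "hydrogenotrophic_d2H",
            "acetoclastic_d13C",
            "acetoclastic_d2H",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing (lo, hi) pair")
        # the two boxes must be separable on at least one axis
        overlap_c = (
            self.hydrogenotrophic_d13C[0] < self.acetoclastic_d13C[1]
            and self.acetoclastic_d13C[0] < self.hydrogenotrophic_d13C[1]
        )
        overlap_h = (
            self.hydrogenotrophic_d2H[0] < self.acetoclastic_d2H[1]
            and self.acetoclastic_d2H[0] < self.hydrogenotrophic_d2H[1]
        )
        if overlap_c and overlap_h:
            raise ValueError("pathway boxes overlap on both axes")


@dataclass(frozen=True)
class PathwaySignature:
    d13C_source: float
    d2H_source: float
    category: str  # hydrogenotrophic | acetoclastic | oxidation-enriched | mixed/indeterminate
    boundary_distances: dict = field(default_factory=dict)


def delta_value(r_sample: float, r_standard: float) -> float:
    """δ (‰) of an isotope ratio against a standard ratio."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_value`: recover R_sample from δ (‰)."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    return (delta / 1000.0 + 1.0) * r_standard


def keeling_intercept(
    samples: list[IsotopeSample] | pd.DataFrame, isotope_system: str = "13C"
) -> KeelingFit:
    """OLS Keeling fit: δ regressed on 1/[CH4]; intercept = mean-source δ.

    ``samples`` must span at least two distinct concentrations (the
    background sample supplies the low-concentration anchor) and contain at
    least three points.
    """
    if isotope_system not in ("13C", "2H"):
        raise ValueError("isotope_system must be '13C' or '2H'")
    if isinstance(samples, pd.DataFrame):
        conc = samples["ch4_ppm"].to_numpy(float)
        delta = samples["d13C" if isotope_system == "13C" else "d2H"].to_numpy(float)
    else:
        conc = np.array([s.ch4_ppm for s in samples], dtype=float)
        attr = "d13C" if isotope_system == "13C" else "d2H"
        delta = np.array([getattr(s, attr) for s in samples], dtype=float)
    if conc.size < 3:
        raise ValueError("a Keeling fit needs at least 3 samples")
    x = 1.0 / conc
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all CH4 concentrations identical")
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (delta - delta.mean()))) / sxx
    intercept = float(delta.mean() - slope * x.mean())
    syy = float(np.sum((delta - delta.mean()) ** 2))
    if syy == 0.0:
        r2 = 0.0
    else:
        resid = delta - (intercept + slope * x)
        r2 = min(max(1.0 - float(np.sum(resid**2)) / syy, 0.0), 1.0)
    return KeelingFit(
        intercept=intercept, slope=slope, r2=r2, n=int(conc.size),
        isotope_system=isotope_system,
    )


def _interval_distance(v: float, lo: float, hi: float) -> float:
    """Signed distance from v to [lo, hi]: 0 inside, negative below, positive above."""
    if v < lo:
        return v - lo
    if v > hi:
        return v - hi
    return 0.0


def classify_pathway(
    d13C_source: float,
    d2H_source: float,
    regions: PathwayRegions | None = None,
) -> PathwaySignature:
    """Place a source (δ¹³C, δ²H) on the pathway diagram.

    Point-in-box tests with closed (inclusive) boundaries; the shared
    δ¹³C = −60 ‰ edge resolves to the hydrogenotrophic box, which is tested
    first. Points enriched beyond both oxidation thresholds are
    ``oxidation-enriched``; everything else is ``mixed/indeterminate`` with
    signed per-axis distances to each production box reported.
    """
    if regions is None:
        regions = PathwayRegions()
    if not (np.isfinite(d13C_source) and np.isfinite(d2H_source)):
        raise ValueError("source delta values must be finite")

    dist = {
        "hydrogenotrophic": (
            _interval_distance(d13C_source, *regions.hydrogenotrophic_d13C),
            _interval_distance(d2H_source, *regions.hydrogenotrophic_d2H),
        ),
        "acetoclastic": (
            _interval_distance(d13C_source, *regions.acetoclastic_d13C),
            _interval_distance(d2H_source, *regions.acetoclastic_d2H),
        ),
    }

    def make(category: str) -> PathwaySignature:
        return PathwaySignature(d13C_source, d2H_source, category, dist)

    if dist["hydrogenotrophic"] == (0.0, 0.0):
        return make("hydrogenotrophic")
    if dist["acetoclastic"] == (0.0, 0.0):
        return make("acetoclastic")
    if d13C_source > regions.oxidation_d13C_above and d2H_source > regions.oxidation_d2H_above:
        return make("oxidation-enriched")
    return make("mixed/indeterminate")


def keeling_by_group(
    df: pd.DataFrame, group_by: str, systems: tuple[str, ...] = ("13C", "2H")
) -> pd.DataFrame:
    """Keeling fits per group, sharing the background sample across groups.

    ``df`` columns: sample_id, treatment (or another grouping column),
    ch4_ppm, d13C, d2H, is_background. Background rows are appended to every
    group's sample set.
    """
    bg = df[df["is_background"].astype(bool)]
    fg = df[~df["is_background"].astype(bool)]
    rows = []
    for key, grp in fg.groupby(group_by, sort=True):
        sub = pd.concat([grp, bg], ignore_index=True)
        for system in systems:
            fit = keeling_intercept(sub, system)
            rows.append(
                {
                    group_by: key,
                    "isotope_system": system,
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "r2": fit.r2,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
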