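"""qPCR standard curves and absolute quantification.

A dilution series of known template copies gives the log-linear calibration
``Cq = intercept + slope · log10(copies)``; amplification efficiency is
``E = 10^(−1/slope) − 1`` (100 % at slope −3.3219, i.e. perfect per-cycle
doubling). Unknown samples are inverted through the curve and scaled to gene
copies per gram of dry soil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StandardCurve", "AbundanceEstimate", "fit_standard_curve", "quantify"]


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float  # cycles per log10 copies
    intercept: float  # Cq at 1 copy
    r2: float
    n_levels: int
    valid: bool  # False when slope >= 0

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = 100 %)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency

    def copies_from_cq(self, cq) -> np.ndarray | float:
        """Invert the calibration: copies per reaction from Cq."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)


@dataclass(frozen=True)
class AbundanceEstimate:
    gene: str
    sample_id: str
    copies_per_g_dw: float
    log10_copies: float
    copies_per_reaction: float
    cq_mean: float
    cq_sd: float
    n_replicates: int
    flagged: bool  # replicate Cq spread above the gate


def fit_standard_curve(
    log10_copies, cq, gene: str = ""
) -> StandardCurve:
    """OLS fit of Cq on log10(copies) over a dilution series.

    Requires at least 3 distinct dilution levels. A non-negative slope is
    physically invalid (more template cannot amplify later) and flags the
    curve rather than raising.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size != y.size:
        raise ValueError("log10_copies and cq must have equal length")
    if np.unique(x).size < 3:
        raise ValueError("a standard curve needs at least 3 dilution levels")
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - y.mean()))) / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    if syy == 0.0:
        r2 = 0.0
    else:
        resid = y - (intercept + slope * x)
        r2 = min(max(1.0 - float(np.sum(resid**2)) / syy, 0.0), 1.0)
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_levels=int(np.unique(x).size),
        valid=bool(slope < 0),
    )


def quantify(
    cq_values,
    curve: StandardCurve,
    sample_id: str = "",
    soil_equivalent_g_dw: float = 1.0,
    scale_factor: float = 1.0,
    aggregate: str = "cq",
    cq_sd_gate: float = 0.5,
) -> AbundanceEstimate:
    """Convert replicate Cq values to gene copies per gram dry soil.

    ``soil_equivalent_g_dw`` is the dry-soil mass represented by one
    reaction's template; ``scale_factor`` collects explicit
    extraction/elution/dilution factors (no hidden defaults). With
    ``aggregate="cq"`` (cycler-software convention) replicate Cq values are
    averaged before inversion; ``"copies"`` averages the per-replicate copy
    numbers instead. Replicate spread above ``cq_sd_gate`` cycles flags the
    estimate.
    """
    if not curve.valid:
        raise ValueError(f"invalid standard curve for {curve.gene or 'gene'}")
    if soil_equivalent_g_dw <= 0:
        raise ValueError("soil_equivalent_g_dw must be positive")
    if aggregate not in ("cq", "copies"):
        raise ValueError("aggregate must be 'cq' or 'copies'")
    cq = np.asarray(cq_values, dtype=float)
    if cq.size == 0:
        raise ValueError("no Cq replicates")
    cq_mean = float(cq.mean())
    cq_sd = float(cq.std(ddof=1)) if cq.size > 1 else 0.0
    if aggregate == "cq":
        per_rxn = float(curve.copies_from_cq(cq_mean))
    else:
        per_rxn = float(np.mean(curve.copies_from_cq(cq)))
    per_g = per_rxn * scale_factor / soil_equivalent_g_dw
    return AbundanceEstimate(
        gene=curve.gene,
        sample_id=sample_id,
        copies_per_g_dw=per_g,
        log10_copies=float(np.log10(per_g)) if per_g > 0 else float("-inf"),
        copies_per_reaction=per_rxn,
        cq_mean=cq_mean,
        cq_sd=cq_sd,
        n_replicates=int(cq.size),
        flagged=bool(cq_sd > cq_sd_gate),
    )


def analyze_qpcr_table(
    df: pd.DataFrame,
    soil_equivalent_g_dw: float = 1.0,
    scale_factor: float = 1.0,
    **quant_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit per-gene standard curves and quantify every unknown sample.

    ``df`` columns: ``gene, role (standard|unknown), sample_id,
    log10_copies, cq, replicate``. Returns (curves, abundances) frames.
    """
    curves = {}
    curve_rows = []
    for gene, grp in df[df["role"] == "standard"].groupby("gene", sort=True):
        c = fit_standard_curve(grp["log10_copies"], grp["cq"], gene=gene)
        curves[gene] = c
        curve_rows.append(
            {
                "gene": gene, "slope": c.slope, "intercept": c.intercept,
                "r2": c.r2, "efficiency_percent": c.efficiency_percent,
                "n_levels": c.n_levels, "valid": c.valid,
            }
        )
    est_rows = []
    unknowns = df[df["role"] == "unknown"]
    for (gene, sample), grp in unknowns.groupby(["gene", "sample_id"], sort=True):
        if gene not in curves:
            raise ValueError(f"no standard curve for gene {gene}")
        e = quantify(
            grp["cq"].to_numpy(), curves[gene], sample_id=sample,
            soil_equivalent_g_dw=soil_equivalent_g_dw,
            scale_factor=scale_factor, **quant_kwargs,
        )
        est_rows.append(
            {
                "gene": gene, "sample_id": sample,
                "copies_per_g_dw": e.copies_per_g_dw,
                "log10_copies": e.log10_copies, "cq_mean": e.cq_mean,
                "cq_sd": e.cq_sd, "n_replicates": e.n_replicates,
                "flagged": e.flagged,
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(est_rows)
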