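"""Aligned-rank-transform (ART) factorial ANOVA.

Nonparametric factorial inference for skewed responses (fluxes, relative
abundances, copy numbers): for each effect in the full factorial model the
response is *aligned* — stripped, via cell-mean algebra, of every estimated
effect except the target — then converted to mid-ranks, and a fixed-effects
full-factorial ANOVA on those ranks supplies the F test for that one effect.
Repeating this once per effect yields one F/df/p row per main effect and
interaction.

Replicate microcosms are treated as independent units (no random replicate
term). Unbalanced designs use unweighted cell means for alignment and
type-III sums of squares for testing; all full-cross cells must be occupied.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["art_align", "art_anova"]


class InestimableEffectError(ValueError):
    """An empty design cell makes an interaction inestimable."""


def _check_design(df: pd.DataFrame, factors: Sequence[str]) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor '{f}' has fewer than 2 levels")
    # groupby drops unobserved combinations, so reindex over the full cross
    full = pd.MultiIndex.from_product(
        [sorted(df[f].unique()) for f in factors], names=list(factors)
    )
    sizes = df.groupby(list(factors), observed=False).size()
    if len(factors) == 1:
        sizes.index = pd.MultiIndex.from_arrays([sizes.index], names=list(factors))
    sizes = sizes.reindex(full, fill_value=0)
    empty = sizes[sizes == 0]
    if len(empty) > 0:
        cell = dict(zip(factors, empty.index[0]))
        raise InestimableEffectError(f"empty design cell: {cell}")


def _effect_terms(factors: Sequence[str]) -> list[tuple[str, ...]]:
    """All main effects and interactions, by increasing order."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(factors) + 1):
        out.extend(itertools.combinations(factors, k))
    return out


def _unweighted_means(df: pd.DataFrame, response: str,
                      factors: Sequence[str], subset: tuple[str, ...]) -> pd.Series:
    """Unweighted marginal means: full-cross cell means averaged over the
    factors outside ``subset`` (equal cell weights, type-III style)."""
    cell = df.groupby(list(factors), observed=False)[response].mean()
    if len(subset) == len(factors):
        return cell
    return cell.groupby(level=list(subset), observed=False).mean()


def _effect_estimates(
    df: pd.DataFrame, response: str, factors: Sequence[str]
) -> tuple[float, dict[tuple[str, ...], pd.Series]]:
    """Grand mean and per-term effect estimates via inclusion–exclusion."""
    grand = float(
        df.groupby(list(factors), observed=False)[response].mean().mean()
    )
    est: dict[tuple[str, ...], pd.Series] = {}
    for term in _effect_terms(factors):
        marg = _unweighted_means(df, response, factors, term)
        vals = marg - grand
        for k in range(1, len(term)):
            for sub in itertools.combinations(term, k):
                sub_est = est[sub]
                idx = marg.index.to_frame(index=False)[list(sub)]
                aligned = sub_est.loc[pd.MultiIndex.from_frame(idx)] \
                    if len(sub) > 1 else sub_est.loc[idx.iloc[:, 0]].to_numpy()
                vals = vals - (aligned.to_numpy() if hasattr(aligned, "to_numpy") else aligned)
        est[term] = vals
    return grand, est


def _lookup(series: pd.Series, df: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    if len(term) == 1:
        return series.loc[df[term[0]]].to_numpy()
    idx = pd.MultiIndex.from_frame(df[list(term)])
    return series.loc[idx].to_numpy()


def art_align(
    df: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    target: tuple[str, ...] | str,
) -> np.ndarray:
    """Align the response for one target effect (pre-rank ART step).

    Returns ``y − cellmean(full cross) + estimated target effect``: the
    residual plus only the target effect's cell-mean estimate, so every
    other effect's contribution is stripped. The diagnostic property: the
    cell-mean estimate of every non-target effect, recomputed from the
    aligned values, is zero to numerical precision.
    """
    target = (target,) if isinstance(target, str) else tuple(target)
    if not set(target) <= set(factors):
        raise ValueError(f"target {target} not within factors {factors}")
    _check_design(df, factors)
    grand, est = _effect_estimates(df, response, factors)
    full_cell = df.groupby(list(factors), observed=False)[response].transform("mean")
    resid = df[response].to_numpy(dtype=float) - full_cell.to_numpy(dtype=float)
    return resid + _lookup(est[target], df, target)


def _anova_on_ranks(
    ranks: np.ndarray, df: pd.DataFrame, factors: Sequence[str],
    term: tuple[str, ...]
) -> tuple[float, int, int, float]:
    """F test for ``term`` from a full-factorial fixed-effects ANOVA on ranks.

    Balanced designs use the exact cell-mean decomposition; unbalanced
    designs fall back to a type-III OLS fit (sum-to-zero contrasts).
    """
    work = df[list(factors)].copy()
    work["_y"] = ranks
    sizes = work.groupby(list(factors), observed=False).size()
    levels = {f: work[f].nunique() for f in factors}
    n = len(work)
    df_num = int(np.prod([levels[f] - 1 for f in term]))
    df_den = n - int(np.prod(list(levels.values())))
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom (one observation per cell)")
    if sizes.nunique() == 1:
        _, est = _effect_estimates(work, "_y", factors)
        reps = n // int(np.prod([levels[f] for f in term]))
        ss_term = float((est[term] ** 2).sum()) * reps
        full_cell = work.groupby(list(factors), observed=False)["_y"].transform("mean")
        ss_resid = float(((work["_y"] - full_cell) ** 2).sum())
        if ss_resid <= 0:
            f_stat = np.inf if ss_term > 0 else 0.0
        else:
            f_stat = (ss_term / df_num) / (ss_resid / df_den)
        p = float(sps.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0
        return float(f_stat), df_num, df_den, p
    return _anova_type3(work, factors, term, df_num, df_den)


def _anova_type3(work, factors, term, df_num, df_den):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    safe = {f: f"f{i}" for i, f in enumerate(factors)}
    renamed = work.rename(columns=safe)
    rhs = " * ".join(f"C({safe[f]}, Sum)" for f in factors)
    fit = smf.ols(f"_y ~ {rhs}", data=renamed).fit()
    tab = sm.stats.anova_lm(fit, typ=3)
    row_name = ":".join(f"C({safe[f]}, Sum)" for f in term)
    row = tab.loc[row_name]
    return float(row["F"]), int(row["df"]), int(tab.loc["Residual", "df"]), float(
        row["PR(>F)"]
    )


def art_anova(
    df: pd.DataFrame,
    response: str,
    factors: Sequence[str],
) -> pd.DataFrame:
    """Full ART ANOVA: one aligned-rank F test per effect.

    ``factors`` defines the model: two factors → two mains + their
    interaction; three factors → 3 mains, 3 two-way and 1 three-way
    interaction. Returns a frame with columns ``effect, df_num, df_den, F,
    p``, one row per effect, mirroring the usual df/F/p table layout.
    """
    _check_design(df, factors)
    rows = []
    for term in _effect_terms(factors):
        aligned = art_align(df, response, factors, term)
        ranks = sps.rankdata(aligned)  # mid-ranks for ties
        f_stat, df_num, df_den, p = _anova_on_ranks(ranks, df, factors, term)
        rows.append(
            {
                "effect": " × ".join(term),
                "df_num": df_num,
                "df_den": df_den,
                "F": f_stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
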