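"""Pathway-level aggregation of population effects and latitude regression.

Each pathway's per-population profile is the median (optionally mean) of its
member proteins' population-effect values on the log scale. The aggregate is
then regressed on the absolute latitude A of each population's breeder origin
with the quadratic model

    Y = b0 + b1 * A + b2 * A**2

fitted by ordinary least squares; the fit reports the coefficients with their
standard errors, R-squared and the Pearson correlation between fitted and
observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LatitudeFit", "pathway_profile", "latitude_regression"]


@dataclass(frozen=True)
class LatitudeFit:
    beta0: float
    beta1: float
    beta2: float
    se: tuple[float, float, float]
    r_squared: float
    pearson_r: float


def pathway_profile(
    effects_table: pd.DataFrame,
    pathway_map: Mapping[str, Sequence[str]],
    stat: str = "median",
) -> pd.DataFrame:
    """Aggregate per-population effects over pathway membership.

    ``effects_table`` is proteins x populations (e.g. the ``effect_*`` columns
    of the LME results); ``pathway_map`` maps pathway id -> member protein
    ids. Composite pathways are simply unions of member lists. Pathways with
    no member present in the table are skipped with a warning; a population
    with no member effect is NaN.
    """
    if stat not in {"median", "mean"}:
        raise ValueError("stat must be 'median' or 'mean'")
    rows = {}
    for pw, members in pathway_map.items():
        present = [m for m in dict.fromkeys(members) if m in effects_table.index]
        if not present:
            warnings.warn(f"pathway {pw!r}: no member proteins in the effects table")
            continue
        sub = effects_table.loc[present]
        rows[pw] = sub.median(axis=0) if stat == "median" else sub.mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "pathway_id"
    return out


def latitude_regression(
    values_per_population: Sequence[float] | pd.Series,
    latitudes: Sequence[float],
) -> LatitudeFit:
    """OLS fit of aggregate effect on (1, A, A^2), A = |latitude| in degrees."""
    y = np.asarray(values_per_population, float)
    A = np.abs(np.asarray(latitudes, float))
    if len(y) != len(A):
        raise ValueError("values and latitudes must align")
    keep = np.isfinite(y) & np.isfinite(A)
    y, A = y[keep], A[keep]
    if len(np.unique(A)) < 3:
        raise ValueError("need >= 3 populations with distinct absolute latitude")
    X = np.column_stack([np.ones_like(A), A, A**2])
    with warnings.catch_warnings():
        # three points interpolate exactly: zero residual df is fine here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(y, X).fit()
        fitted = res.fittedvalues
        if np.ptp(fitted) == 0 or np.ptp(y) == 0:
            pearson = 0.0
        else:
            pearson = float(np.corrcoef(fitted, y)[0, 1])
        r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0
        b = res.params
        se = tuple(float(v) for v in res.bse)
    return LatitudeFit(
        beta0=float(b[0]),
        beta1=float(b[1]),
        beta2=float(b[2]),
        se=se,
        r_squared=r2,
        pearson_r=pearson,
    )
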