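"""Quadratic thermal performance curves and viability deviance analysis.

Egg-to-adult viability as a function of rearing temperature is modelled as
viability = a*T^2 + b*T + c fitted by (egg-count weighted) least squares --
for a quadratic, nonlinear least squares reduces to linear least squares, so
no multi-start machinery is needed. Thermal traits follow in closed form:

* rmax  = c - b^2/(4a)        maximal performance,
* Topt  = -b/(2a)             optimal temperature,
* CTmin/CTmax                 real roots of the quadratic (performance = 0),
* tolerance = CTmax - CTmin   span of temperatures with positive performance,
* breadth = 2*sqrt(0.2*rmax/(-a))  span with performance >= 80% of rmax.

Karyotype x temperature x continent effects on viability are assessed with
the shared aggregated binomial GLM engine, using type-II likelihood-ratio
tests (each term tested against the model containing all terms that do not
include it, respecting marginality).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
from scipy.stats import chi2

from .cline_stats import fit_binomial_glm


@dataclass
class TPCFit:
    """Quadratic thermal-performance coefficients and derived traits."""

    a: float
    b: float
    c: float
    rmax: float | None
    topt: float | None
    ctmin: float | None
    ctmax: float | None
    tolerance: float | None
    breadth: float | None
    concave: bool
    rss: float
    n: int
    group: str | None = None


def thermal_traits(a: float, b: float, c: float) -> dict[str, float | None]:
    """Closed-form thermal traits of a*T^2 + b*T + c; None when undefined."""
    if a >= 0:
        return {"rmax": None, "topt": None, "ctmin": None, "ctmax": None,
                "tolerance": None, "breadth": None}
    topt = -b / (2 * a)
    rmax = c - b * b / (4 * a)
    disc = b * b - 4 * a * c
    if disc >= 0:
        r1 = (-b + np.sqrt(disc)) / (2 * a)
        r2 = (-b - np.sqrt(disc)) / (2 * a)
        ctmin, ctmax = sorted((float(r1), float(r2)))
        tolerance = ctmax - ctmin
    else:
        ctmin = ctmax = tolerance = None
    breadth = 2 * float(np.sqrt(0.2 * rmax / (-a))) if rmax > 0 else None
    return {"rmax": float(rmax), "topt": float(topt), "ctmin": ctmin,
            "ctmax": ctmax, "tolerance": tolerance, "breadth": breadth}


def fit_quadratic_tpc(table: pd.DataFrame, group: str | None = None,
                      weight_by_eggs: bool = True) -> TPCFit:
    """Least-squares quadratic fit of viability proportion on temperature.

    ``table`` needs columns temperature, eggs, adults (and line when
    ``group`` is given). Replicate-level proportions are weighted by egg
    counts unless ``weight_by_eggs`` is off.
    """
    df = table if group is None else table[table["line"] == group]
    if df["temperature"].nunique() < 3:
        raise ValueError("need >= 3 distinct temperatures")
    t = df["temperature"].to_numpy(dtype=float)
    y = (df["adults"] / df["eggs"]).to_numpy(dtype=float)
    w = np.sqrt(df["eggs"].to_numpy(dtype=float)) if weight_by_eggs else None
    coef = np.polyfit(t, y, 2, w=w)
    a, b, c = (float(v) for v in coef)
    resid = y - np.polyval(coef, t)
    traits = thermal_traits(a, b, c)
    return TPCFit(a, b, c, traits["rmax"], traits["topt"], traits["ctmin"],
                  traits["ctmax"], traits["tolerance"], traits["breadth"],
                  concave=a < 0, rss=float((resid ** 2).sum()), n=len(df),
                  group=group)


def filter_low_viability(table: pd.DataFrame, min_viability: float = 0.05,
                         min_replicates: int = 2) -> pd.DataFrame:
    """Drop temperatures whose pooled viability falls below a floor.

    Mirrors the practice of excluding a rearing temperature from analysis
    when nearly nothing survives there (pooled survival < ``min_viability``
    or fewer than ``min_replicates`` replicates with any survivor).
    """
    keep = []
    for t, grp in table.groupby("temperature"):
        pooled = grp["adults"].sum() / grp["eggs"].sum()
        alive = int((grp["adults"] > 0).sum())
        if pooled >= min_viability and alive >= min_replicates:
            keep.append(t)
    return table[table["temperature"].isin(keep)].copy()


# ---------------------------------------------------------------------------
# deviance analysis
# ---------------------------------------------------------------------------

def _term_formula(terms: list[tuple[str, ...]]) -> str:
    parts = [":".join(f"C({f})" for f in t) for t in terms]
    return "1" if not parts else "1 + " + " + ".join(parts)


def _fit_terms(df: pd.DataFrame, terms: list[tuple[str, ...]]):
    X = patsy.dmatrix(_term_formula(terms), df, return_type="dataframe")
    res = fit_binomial_glm(df["adults"].to_numpy(),
                           (df["eggs"] - df["adults"]).to_numpy(),
                           X.to_numpy())
    return res, X.shape[1]


@dataclass
class DevianceAnalysis:
    """Type-II likelihood-ratio table for a binomial viability GLM."""

    table: pd.DataFrame             # term, df, chi2, p_value
    residual_deviance: float
    null_deviance: float
    deviance_r2: float


def viability_deviance_analysis(table: pd.DataFrame,
                                factors: tuple[str, ...] = (
                                    "karyotype", "temperature", "continent"),
                                interactions: bool = True
                                ) -> DevianceAnalysis:
    """Binomial GLM of adults/eggs on experimental factors, type-II LRTs.

    All factors are treated as categorical. The model contains all main
    effects and (optionally) all two-way interactions; interactions of more
    than two factors are never included. Each term's chi-square compares the
    model of all terms not containing it with and without the term.
    """
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    if interactions:
        terms += list(combinations(factors, 2))

    full, _ = _fit_terms(table, terms)
    rows = []
    for t in terms:
        base = [u for u in terms if not set(t) <= set(u)]
        res_base, k_base = _fit_terms(table, base)
        res_with, k_with = _fit_terms(table, base + [t])
        stat = float(res_base.deviance - res_with.deviance)
        df = k_with - k_base
        rows.append({"term": ":".join(t), "df": df, "chi2": stat,
                     "p_value": float(chi2.sf(stat, df))})
    return DevianceAnalysis(pd.DataFrame(rows), float(full.deviance),
                            float(full.null_deviance),
                            float(1 - full.deviance / full.null_deviance))
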