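"""Arrangement frequencies, Hardy-Weinberg tests, and binomial clines.

The cline model is an aggregated binomial GLM with logit link: per location
the response is (successes = 2*n_SS + n_SN, failures = n_SN + 2*n_NN), i.e.
counts of S and N arrangements, regressed on latitude or on annual mean
temperature. Aggregation by location weights each location by its sample
size. Fit quality is summarised by the likelihood-ratio chi-square against
the intercept-only model (df = 1) and the deviance R-squared
1 - residual deviance / null deviance.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint

from .io_formats import LocationCounts

#: IRLS convergence settings of the shared binomial GLM engine
GLM_TOL = 1e-10
GLM_MAXITER = 100


def fit_binomial_glm(successes, failures, exog: np.ndarray):
    """Aggregated binomial GLM with logit link (IRLS via statsmodels)."""
    endog = np.column_stack([successes, failures])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    return model.fit(maxiter=GLM_MAXITER, tol=GLM_TOL)


# ---------------------------------------------------------------------------
# per-location summaries
# ---------------------------------------------------------------------------

def arrangement_frequency(counts: LocationCounts
                          ) -> tuple[float, tuple[float, float]]:
    """Frequency of the S arrangement with a Wilson 95% CI (allele scale)."""
    n_alleles = 2 * counts.n
    if n_alleles == 0:
        raise ValueError("no individuals")
    s_alleles = 2 * counts.n_ss + counts.n_sn
    p = s_alleles / n_alleles
    lo, hi = proportion_confint(s_alleles, n_alleles, alpha=0.05,
                                method="wilson")
    return p, (float(lo), float(hi))


@dataclass
class HWEResult:
    """Chi-square goodness-of-fit of karyotype counts to HWE (df = 1)."""

    observed: tuple[int, int, int]      # SS, SN, NN
    p_s: float
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


def hwe_test(counts: LocationCounts) -> HWEResult:
    """Pearson chi-square against HWE proportions, no continuity correction."""
    n = counts.n
    obs = (counts.n_ss, counts.n_sn, counts.n_nn)
    p, _ = arrangement_frequency(counts)
    if p in (0.0, 1.0):
        return HWEResult(obs, p, (n * p * p, 2 * n * p * (1 - p),
                                  n * (1 - p) ** 2), np.nan, 1, np.nan, True)
    exp = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)
    stat = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return HWEResult(obs, p, exp, float(stat), 1, float(chi2.sf(stat, 1)))


def location_summary(table: Sequence[LocationCounts]) -> pd.DataFrame:
    """Table-style report: frequency (2 dp) and HWE test per location."""
    rows = []
    for c in table:
        p, (lo, hi) = arrangement_frequency(c)
        h = hwe_test(c)
        rows.append({"location": c.location, "latitude": c.latitude,
                     "temperature": c.temperature, "n": c.n,
                     "freq_s": round(p, 2), "ci_low": lo, "ci_high": hi,
                     "hwe_chi2": h.chi2, "hwe_p": h.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binomial cline regression
# ---------------------------------------------------------------------------

@dataclass
class ClineFit:
    """Aggregated binomial logit regression of S frequency on a predictor."""

    predictor: str
    beta0: float
    beta1: float
    se: tuple[float, float]
    lrt_chi2: float
    df: int
    p_value: float
    deviance_r2: float
    null_deviance: float
    residual_deviance: float
    cov_params: np.ndarray
    x: np.ndarray
    fitted: np.ndarray                  # fitted S frequency per location
    separation_flag: bool = False


def fit_binomial_cline(table: Sequence[LocationCounts],
                       predictor: str = "latitude") -> ClineFit:
    """Fit logit(p_S) = beta0 + beta1 * x over locations.

    ``predictor`` is ``latitude`` or ``temperature``. The likelihood-ratio
    chi-square is null deviance minus residual deviance (df = 1).
    """
    if len(table) < 3:
        raise ValueError("need >= 3 locations")
    if predictor not in ("latitude", "temperature"):
        raise ValueError(f"unknown predictor {predictor!r}")
    x = np.array([getattr(c, predictor) for c in table], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant across locations")
    succ = np.array([2 * c.n_ss + c.n_sn for c in table], dtype=float)
    fail = np.array([c.n_sn + 2 * c.n_nn for c in table], dtype=float)
    exog = sm.add_constant(x)
    res = fit_binomial_glm(succ, fail, exog)
    if not res.converged:
        raise RuntimeError("IRLS did not converge")
    lrt = float(res.null_deviance - res.deviance)
    r2 = float(1 - res.deviance / res.null_deviance)
    separation = bool(np.any(np.abs(res.params) > 30)
                      or np.any(res.bse > 1e3))
    return ClineFit(predictor, float(res.params[0]), float(res.params[1]),
                    (float(res.bse[0]), float(res.bse[1])), lrt, 1,
                    float(chi2.sf(lrt, 1)), r2, float(res.null_deviance),
                    float(res.deviance), np.asarray(res.cov_params()), x,
                    np.asarray(res.fittedvalues), separation)


def predict_cline(fit: ClineFit, grid: "np.typing.ArrayLike",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Fitted S frequency with a Wald CI on the linear predictor scale.

    The CI is computed on eta = beta0 + beta1*x and mapped through the
    inverse logit, so it always contains the fitted curve.
    """
    from scipy.stats import norm
    grid = np.asarray(grid, dtype=float)
    X = np.column_stack([np.ones_like(grid), grid])
    eta = X @ np.array([fit.beta0, fit.beta1])
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params, X))
    z = norm.ppf(1 - alpha / 2)
    return pd.DataFrame({
        fit.predictor: grid,
        "fit": expit(eta),
        "lo": expit(eta - z * se),
        "hi": expit(eta + z * se),
    })
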