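"""Mediation of a variant-phenotype association through lung function.

The model has a single independent variable X (risk-allele dosage), a
single mediator M (a forced-vital-capacity-like lung-function measure)
and a single outcome Y (a deconfounded IDP), with adjustment covariates
(age, sex, height).  Three OLS fits give the paths:

    M ~ X + covars          -> a  (X on mediator)
    Y ~ X + M + covars      -> c' (direct) and b (mediator on outcome)
    Y ~ X + covars          -> c  (total)

On a shared complete-case sample the identity c = c' + a*b holds exactly.
The indirect effect a*b is tested with the Sobel normal approximation
z = a*b / sqrt(a^2 se_b^2 + b^2 se_a^2), known to be conservative under
the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import MediationResult

__all__ = ["fit_paths", "sobel_test", "summarise_mediation", "mediate"]


def _ols(y: np.ndarray, x: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return res.params, res.bse


def fit_paths(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> MediationResult:
    """Fit the three path regressions on a shared complete-case sample."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.asarray(covariates, dtype=float)
    if not (len(x) == len(m) == len(y) == len(cov)):
        raise ValueError("X, M, Y and covariates must have equal length")
    obs = ~(np.isnan(x) | np.isnan(m) | np.isnan(y) | np.isnan(cov).any(axis=1))
    x, m, y, cov = x[obs], m[obs], y[obs], cov[obs]
    n = len(x)
    if n <= cov.shape[1] + 3:
        raise ValueError("too few complete cases for the mediation design")
    if np.ptp(x) == 0 or np.ptp(m) == 0:
        raise ValueError("constant X or M cannot be fitted")

    # M ~ X + covars: path a is the X coefficient (index 1 after the constant)
    par, se = _ols(m, np.column_stack([x, cov]))
    a, se_a = par[1], se[1]
    # Y ~ X + M + covars: c' and b
    par, se = _ols(y, np.column_stack([x, m, cov]))
    c_prime, se_c_prime = par[1], se[1]
    b, se_b = par[2], se[2]
    # Y ~ X + covars: total effect c
    par, se = _ols(y, np.column_stack([x, cov]))
    c, se_c = par[1], se[1]
    return MediationResult(
        a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b),
        c=float(c), se_c=float(se_c),
        c_prime=float(c_prime), se_c_prime=float(se_c_prime), n=n,
    )


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z and two-sided normal p for the indirect effect a*b."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(a**2 * se_b**2 + b**2 * se_a**2)
    if denom == 0:  # a = b = 0: no indirect effect, by convention z = 0
        return 0.0, 1.0
    z = a * b / denom
    return float(z), float(2 * stats.norm.sf(abs(z)))


def summarise_mediation(result: MediationResult, alpha: float = 0.05) -> dict:
    """Attach the Sobel test, proportion mediated and mediation flags.

    Proportion mediated is ab / (c' + ab) (the standard definition; the
    denominator equals the total effect on the shared sample).  The
    partial-mediation flag requires a significant Sobel test together
    with a direct path retaining the sign of the total effect.
    """
    z, p = sobel_test(result.a, result.se_a, result.b, result.se_b)
    result.sobel_z = z
    result.sobel_p = p
    ab = result.indirect
    total = result.c_prime + ab
    if ab == 0:
        proportion = 0.0
    elif total == 0:
        proportion = np.nan  # undefined: direct and indirect cancel exactly
    else:
        proportion = ab / total
    result.proportion_mediated = proportion
    row = result.to_dict()
    row["proportion_defined"] = not (isinstance(proportion, float) and np.isnan(proportion))
    row["partial_mediation"] = bool(
        p < alpha and np.sign(result.c_prime) == np.sign(result.c) and result.c_prime != 0
    )
    return row


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Convenience wrapper: fit paths then summarise with the Sobel test."""
    return summarise_mediation(fit_paths(x, m, y, covariates), alpha=alpha)
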