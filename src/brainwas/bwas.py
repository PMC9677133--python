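"""Mass-univariate association of risk variants against brain phenotypes.

Every (variant, IDP) pair is tested with ordinary least squares of the
deconfounded, inverse-normal-transformed IDP on risk-allele dosage under
an additive genetic model, adjusting for demographic, body, genetic-PC
and lifestyle covariates.  Family-wise error is controlled by Bonferroni
correction across all variant x IDP tests; Benjamini-Hochberg FDR is
reported alongside.  Complete cases are taken per pair, so per-record n
tracks each IDP's missingness.

The fits use closed-form normal equations, batched across IDP columns
sharing a missingness pattern — at cohort scale (tens of thousands of
regressions) per-fit model objects are prohibitively slow; agreement with
statsmodels OLS is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, IDPMatrix

__all__ = [
    "AssociationRecord",
    "derive_alcohol_units",
    "build_covariates",
    "fit_additive_glm",
    "run_bwas",
    "bonferroni_threshold",
    "bh_fdr",
    "count_significant",
    "WEEKS_PER_MONTH",
]

#: 365.25 / 12 / 7 — average weeks in a month
WEEKS_PER_MONTH = 4.345


@dataclass
class AssociationRecord:
    """Result of one additive-model fit: effect of dosage on one IDP."""

    variant: str
    idp: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n: int
    flagged: bool = False  # monomorphic dosage in complete cases


def derive_alcohol_units(
    drinker_status,
    weekly_counts: pd.DataFrame | None = None,
    monthly_counts: pd.DataFrame | None = None,
    units_per_drink: dict[str, float] | None = None,
) -> pd.Series:
    """Weekly UK alcohol units from per-drink-type intake counts.

    Weekly counts contribute count x units directly; monthly counts are
    divided by 4.345 weeks/month.  Subjects with ``drinker_status`` falsy
    get 0 regardless of counts.  ``units_per_drink`` maps drink-type
    column names to standard units per drink.
    """
    drinker = pd.Series(drinker_status).astype(bool)
    units = pd.Series(0.0, index=drinker.index)
    if units_per_drink is None:
        units_per_drink = {}
    for counts, scale in ((weekly_counts, 1.0), (monthly_counts, 1.0 / WEEKS_PER_MONTH)):
        if counts is None:
            continue
        if (counts.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative drink counts")
        for drink in counts.columns:
            per = units_per_drink.get(drink)
            if per is None:
                raise KeyError(f"no unit content configured for drink type {drink!r}")
            units = units.add(counts[drink].astype(float) * per * scale, fill_value=0.0)
    units[~drinker] = 0.0
    return units


def build_covariates(
    table: pd.DataFrame,
    n_genetic_pcs: int = 10,
    impute_missing: bool = True,
) -> pd.DataFrame:
    """Assemble the standardised BWAS covariate design.

    Expects columns ``age``, ``sex`` (0/1), ``height``, ``weight``,
    ``dbp``, ``sbp``, ``ever_smoker``, ``alcohol_units`` and genetic PCs
    ``pc1``..``pc{n}``; derives age^2, age x sex and age^2 x sex, then
    de-means and unit-variance scales every column.  Missing height,
    weight and blood pressures are median-imputed when ``impute_missing``
    (the study imputed them from other assessment visits, a structure not
    carried here).
    """
    need = ["age", "sex", "height", "weight", "dbp", "sbp", "ever_smoker", "alcohol_units"]
    pcs = [f"pc{k + 1}" for k in range(n_genetic_pcs)]
    missing_cols = [c for c in need + pcs if c not in table.columns]
    if missing_cols:
        raise KeyError(f"covariate table lacks columns {missing_cols}")
    df = table[need + pcs].astype(float).copy()
    if impute_missing:
        for col in ("height", "weight", "dbp", "sbp"):
            df[col] = df[col].fillna(df[col].median())
    if df.isna().any().any():
        raise ValueError("covariate table has missing values after imputation")
    df["age_sq"] = df["age"] ** 2
    df["age_x_sex"] = df["age"] * df["sex"]
    df["age_sq_x_sex"] = df["age_sq"] * df["sex"]
    order = (
        ["age", "sex", "age_sq", "age_x_sex", "age_sq_x_sex", "height", "weight", "dbp", "sbp"]
        + pcs
        + ["ever_smoker", "alcohol_units"]
    )
    df = df[order]
    mean = df.mean()
    sd = df.std(ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant columns stay constant (at zero)
    return (df - mean) / sd


def _batched_ols(y: np.ndarray, g: np.ndarray, covars: np.ndarray):
    """OLS of each column of y on [1, covars, g]; stats for the g term.

    All y columns must share the same complete-case rows (already
    subset).  Returns (beta, se, t, p, df_resid) arrays over columns.
    """
    n = y.shape[0]
    x = np.column_stack([np.ones(n), covars, g])
    q = x.shape[1]
    xtx = x.T @ x
    xty = x.T @ y
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ xty
    resid = y - x @ coef
    df_resid = n - q
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df_resid
    var_g = sigma2 * xtx_inv[-1, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(var_g)
        beta = coef[-1]
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    return beta, se, t, p, df_resid


def fit_additive_glm(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> AssociationRecord:
    """Additive-model OLS of one phenotype on one dosage vector.

    Missing phenotype values are dropped (complete cases); the model is
    y ~ intercept + dosage + covariates and the record reports the dosage
    term.  A dosage that is constant in the complete cases cannot be
    tested: the record is flagged and its statistics set missing.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if covariates is None:
        covars = np.empty((len(y), 0))
    else:
        covars = np.asarray(covariates, dtype=float)
    obs = ~np.isnan(y)
    y, g, covars = y[obs], g[obs], covars[obs]
    n = len(y)
    if n <= covars.shape[1] + 2:
        raise ValueError("too few complete cases for the design")
    if np.ptp(g) == 0:
        return AssociationRecord("g", "y", np.nan, np.nan, np.nan, np.nan, n, flagged=True)
    beta, se, t, p, _ = _batched_ols(y[:, None], g, covars)
    return AssociationRecord("g", "y", float(beta[0]), float(se[0]), float(t[0]), float(p[0]), n)


def run_bwas(
    genotypes: GenotypeMatrix,
    idps: IDPMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Test every variant against every IDP; one record per pair.

    Returns an AssociationTable DataFrame with columns
    (variant, idp, idp_group, beta, se, t, p, n, flagged).  IDP columns
    sharing a missingness pattern are fitted in one batched solve.
    """
    if not genotypes.subject_ids.equals(idps.subject_ids):
        raise ValueError("genotype and IDP subjects must align")
    if covariates is not None:
        if not genotypes.subject_ids.equals(covariates.index):
            raise ValueError("covariate subjects must align")
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.empty((genotypes.n_subjects, 0))
    y_all = idps.values.to_numpy(dtype=float)
    g_all = genotypes.dosages.to_numpy(dtype=float)
    n, p = y_all.shape
    miss = np.isnan(y_all)

    groups: dict[bytes, list[int]] = {}
    for j in range(p):
        groups.setdefault(miss[:, j].tobytes(), []).append(j)

    records = []
    idp_ids = idps.values.columns
    idp_groups = idps.groups
    for v_idx, variant in enumerate(genotypes.variant_ids):
        g = g_all[:, v_idx]
        for key, cols in groups.items():
            rows = ~miss[:, cols[0]]
            m = int(rows.sum())
            gv = g[rows]
            if m <= cov.shape[1] + 2 or np.ptp(gv) == 0:
                for j in cols:
                    records.append((variant, idp_ids[j], idp_groups.iloc[j],
                                    np.nan, np.nan, np.nan, np.nan, m, True))
                continue
            beta, se, t, pv, _ = _batched_ols(y_all[np.ix_(rows, cols)], gv, cov[rows])
            for k, j in enumerate(cols):
                records.append((variant, idp_ids[j], idp_groups.iloc[j],
                                beta[k], se[k], t[k], pv[k], m, False))
    table = pd.DataFrame(
        records,
        columns=["variant", "idp", "idp_group", "beta", "se", "t", "p", "n", "flagged"],
    )
    # restore IDP order within variant blocks
    table["_j"] = table["idp"].map({idp: j for j, idp in enumerate(idp_ids)})
    table = (
        table.sort_values(["variant", "_j"], kind="stable")
        .drop(columns="_j")
        .reset_index(drop=True)
    )
    return table


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def count_significant(table: pd.DataFrame, threshold: float) -> pd.Series:
    """Per-variant count of association records with p < threshold."""
    hits = table["p"] < threshold
    return hits.groupby(table["variant"]).sum().astype(int)
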