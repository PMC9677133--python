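"""Imaging-confound construction and deconfounding.

The confound set combines raw acquisition covariates (head motion, head
size, head/table position, site indicators) with derived columns: a
quantile-normalised and a centred-squared version of every continuous
confound, and the scan-date drift components.  The drift procedure is:
impute missing IDP cells with a low-rank (iterative truncated-SVD)
imputer, discard gross outliers by a median/MAD rule, smooth every column
against scan date with a regression spline, and keep the top principal
components of the smoothed matrix as slowly-varying drift regressors.
Deconfounding residualises each IDP on the complete confound design by
ordinary least squares on that IDP's non-missing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .datatypes import ConfoundMatrix, IDPMatrix
from .preprocess import inverse_normal_transform

__all__ = [
    "DriftSpec",
    "impute_low_rank",
    "mad_outlier_removal",
    "temporal_smooth",
    "drift_components",
    "augment_confounds",
    "deconfound",
    "build_drift_confounds",
]


@dataclass
class DriftSpec:
    """Parameters of the scan-date drift construction."""

    rank: int = 10
    mad_k: float = 5.0
    spline_df: int = 10
    n_components: int = 10
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("imputation rank must be >= 1")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if self.spline_df < 2:
            raise ValueError("spline_df must be >= 2")


def impute_low_rank(
    matrix: np.ndarray, rank: int = 10, tol: float = 1e-6, max_iter: int = 200
) -> np.ndarray:
    """Fill missing cells by iterative rank-truncated SVD.

    Missing cells start at their column means; the matrix is alternately
    truncated to ``rank`` singular values and restored on observed cells
    until the relative change of the imputed entries falls below ``tol``
    or ``max_iter`` is reached.  Observed cells are returned unchanged.
    """
    x = np.asarray(matrix, dtype=float).copy()
    if rank < 1:
        raise ValueError("rank must be >= 1")
    miss = np.isnan(x)
    if not miss.any():
        return x
    if miss.all(axis=1).any() or miss.all(axis=0).any():
        raise ValueError("fully missing row or column cannot be imputed")
    col_means = np.nanmean(x, axis=0)
    filled = np.where(miss, col_means, x)
    prev = filled[miss]
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        low = (u[:, :rank] * s[:rank]) @ vt[:rank]
        filled = np.where(miss, low, x)
        cur = filled[miss]
        denom = max(np.linalg.norm(prev), 1e-12)
        if np.linalg.norm(cur - prev) / denom < tol:
            break
        prev = cur
    return filled


def mad_outlier_removal(matrix: np.ndarray, mad_k: float = 5.0) -> np.ndarray:
    """Set cells missing when further than ``mad_k`` raw MADs from the median.

    The MAD is the unscaled median absolute deviation (no 1.4826 normal
    consistency factor).  Columns with MAD 0 are left untouched.
    """
    x = np.asarray(matrix, dtype=float).copy()
    med = np.nanmedian(x, axis=0)
    mad = np.nanmedian(np.abs(x - med), axis=0)
    with np.errstate(invalid="ignore"):
        bad = (np.abs(x - med) > mad_k * mad) & (mad > 0)
    x[bad] = np.nan
    return x


def _spline_basis(dates: np.ndarray, df: int) -> np.ndarray:
    """Design matrix (incl. intercept span) of df columns over the dates.

    Cubic B-splines with interior knots at date quantiles for df >= 4; a
    plain polynomial basis of degree df-1 for df in {2, 3} (too few
    degrees of freedom for a cubic spline).
    """
    t = np.asarray(dates, dtype=float)
    uniq = np.unique(t)
    if uniq.size < df:
        raise ValueError("need at least spline_df distinct dates")
    if df < 4:
        return np.vander(t, df, increasing=True)
    n_interior = df - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(uniq, qs)
    else:
        interior = np.array([])
    knots = np.r_[[uniq[0]] * 4, interior, [uniq[-1]] * 4]
    basis = BSpline.design_matrix(t, knots, 3, extrapolate=True).toarray()
    return basis


def temporal_smooth(matrix: np.ndarray, scan_dates: np.ndarray, spline_df: int = 10) -> np.ndarray:
    """Replace each column by its regression-spline fit over scan date.

    Fitted values are returned in the original subject order.  The basis
    spans polynomials up to its degree, so a column already linear in date
    is reproduced exactly.
    """
    x = np.asarray(matrix, dtype=float)
    basis = _spline_basis(np.asarray(scan_dates, dtype=float), spline_df)
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    return basis @ coef


def drift_components(smoothed: np.ndarray, n_components: int = 10) -> np.ndarray:
    """Top principal-component scores of the column-centred smoothed matrix.

    Components are ordered by decreasing explained variance; the sign of
    each is fixed so its largest-magnitude loading is positive.
    """
    x = np.asarray(smoothed, dtype=float)
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    centred = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components]
    sign = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    sign[sign == 0] = 1.0
    return scores * sign


def build_drift_confounds(
    idps: IDPMatrix, scan_dates: pd.Series, spec: DriftSpec | None = None
) -> ConfoundMatrix:
    """Run the full drift chain: impute -> MAD -> smooth -> PCA.

    ``scan_dates`` is indexed by subject id (numeric days or datetimes).
    Returns the drift PCs as a ConfoundMatrix tagged ``drift-PC``.
    """
    if spec is None:
        spec = DriftSpec()
    dates = scan_dates.reindex(idps.subject_ids)
    if dates.isna().any():
        raise ValueError("every subject needs a scan date")
    if np.issubdtype(dates.dtype, np.datetime64):
        dates = (dates - dates.min()).dt.days.astype(float)
    dates = dates.to_numpy(dtype=float)

    filled = impute_low_rank(
        idps.values.to_numpy(dtype=float), spec.rank, spec.tol, spec.max_iter
    )
    trimmed = mad_outlier_removal(filled, spec.mad_k)
    # MAD removal reintroduces holes; refill them the same way before smoothing
    if np.isnan(trimmed).any():
        trimmed = impute_low_rank(trimmed, spec.rank, spec.tol, spec.max_iter)
    smoothed = temporal_smooth(trimmed, dates, spec.spline_df)
    scores = drift_components(smoothed, spec.n_components)
    cols = pd.Index([f"drift_pc{k + 1}" for k in range(spec.n_components)])
    values = pd.DataFrame(scores, index=idps.subject_ids, columns=cols)
    return ConfoundMatrix(values, pd.Series("drift-PC", index=cols))


def augment_confounds(
    raw: ConfoundMatrix, categorical: list[str] | None = None, mad_k: float = 5.0
) -> ConfoundMatrix:
    """Expand the raw confound set with derived versions.

    Per continuous column: the raw column, its inverse-normal-transformed
    version, and its centred square after MAD outlier removal (outlying
    cells are set to the column median before squaring so the output stays
    complete).  Categorical columns (e.g. site) become binary indicators,
    dropping the first level, and are not otherwise augmented.
    """
    categorical = list(categorical or [])
    pieces: list[pd.Series] = []
    tags: list[tuple[str, str]] = []
    for name in raw.values.columns:
        col = raw.values[name]
        if name in categorical:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for d in dummies.columns:
                pieces.append(dummies[d])
                tags.append((d, "indicator"))
            continue
        x = col.to_numpy(dtype=float)
        pieces.append(col)
        tags.append((name, "raw"))
        try:
            qn = inverse_normal_transform(x)
        except ValueError:  # constant column carries no rank information
            qn = np.zeros_like(x)
        pieces.append(pd.Series(qn, index=col.index, name=f"{name}_qnorm"))
        tags.append((f"{name}_qnorm", "quantile-normalised"))
        trimmed = mad_outlier_removal(x[:, None], mad_k)[:, 0]
        med = np.nanmedian(trimmed) if np.isnan(trimmed).any() else None
        if med is not None:
            trimmed = np.where(np.isnan(trimmed), med, trimmed)
        sq = (trimmed - trimmed.mean()) ** 2
        pieces.append(pd.Series(sq, index=col.index, name=f"{name}_csq"))
        tags.append((f"{name}_csq", "centred-squared"))
    values = pd.concat(pieces, axis=1)
    values.columns = [t[0] for t in tags]
    prov = pd.Series(dict(tags)).reindex(values.columns)
    return ConfoundMatrix(values, prov)


def deconfound(idps: IDPMatrix, confounds: ConfoundMatrix, add_intercept: bool = True) -> IDPMatrix:
    """Residualise every IDP on the confound design.

    Per IDP column the residual y - C (C^+ y) is computed on that column's
    non-missing subjects (complete confounds assumed); missing cells stay
    missing.  Columns sharing a missingness pattern are solved together.
    """
    if not idps.values.index.equals(confounds.values.index):
        raise ValueError("subjects of IDPs and confounds must align")
    c = confounds.values.to_numpy(dtype=float)
    if add_intercept:
        c = np.column_stack([np.ones(c.shape[0]), c])
    y = idps.values.to_numpy(dtype=float)
    n, p = y.shape
    if c.shape[1] >= n:
        raise ValueError("more confounds than subjects")
    out = np.full_like(y, np.nan)
    miss = np.isnan(y)
    # group IDP columns by identical missingness pattern for batched solves
    pattern_ids = {}
    groups: dict[int, list[int]] = {}
    for j in range(p):
        key = miss[:, j].tobytes()
        gid = pattern_ids.setdefault(key, len(pattern_ids))
        groups.setdefault(gid, []).append(j)
    for gid, cols in groups.items():
        rows = ~miss[:, cols[0]]
        if rows.sum() <= c.shape[1]:
            continue  # too few observations to residualise; stays missing
        cc = c[rows]
        yy = y[np.ix_(rows, cols)]
        coef, *_ = np.linalg.lstsq(cc, yy, rcond=None)
        out[np.ix_(rows, cols)] = yy - cc @ coef
    return IDPMatrix(
        pd.DataFrame(out, index=idps.values.index, columns=idps.values.columns),
        idps.groups,
    )
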