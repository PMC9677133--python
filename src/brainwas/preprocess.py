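"""Cohort and IDP quality control.

Implements the QC chain applied before association testing: flagging of
technical outliers per IDP (5-SD rule about the cohort mean), exclusion
of subjects with an excessive outlier burden (>10 flagged IDPs),
selection of a maximally unrelated subject subset from a KING-style
kinship table (cut-off 0.0884, between 2nd- and 3rd-degree relatives),
rank-based inverse normal transformation of each phenotype, and an
exclusion-ledger audit that reconciles removal counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .datatypes import ExclusionLedger, IDPMatrix

__all__ = [
    "flag_technical_outliers",
    "exclude_by_outlier_burden",
    "select_unrelated",
    "inverse_normal_transform",
    "audit_exclusion_ledger",
    "KINSHIP_THRESHOLD",
]

#: conventional KING cut-off separating 2nd- from 3rd-degree relatives
KINSHIP_THRESHOLD = 0.0884


def flag_technical_outliers(idps: IDPMatrix, k_sd: float = 5.0) -> pd.DataFrame:
    """Flag cells more than ``k_sd`` standard deviations from the column mean.

    Mean and SD are computed over the non-missing cells of each IDP column.
    Columns with zero SD (constant) flag nothing; missing cells are never
    flagged.  Returns a boolean DataFrame aligned with ``idps.values``.
    """
    if idps.values.size == 0:
        raise ValueError("empty IDP matrix")
    arr = idps.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    dev = np.abs(arr - mean)
    with np.errstate(invalid="ignore"):
        flags = (dev > k_sd * sd) & (sd > 0) & ~np.isnan(arr)
    return pd.DataFrame(flags, index=idps.values.index, columns=idps.values.columns)


def apply_outlier_mask(idps: IDPMatrix, mask: pd.DataFrame) -> IDPMatrix:
    """Set flagged cells missing (the downstream fate of technical outliers)."""
    values = idps.values.mask(mask)
    return IDPMatrix(values, idps.groups)


def exclude_by_outlier_burden(mask: pd.DataFrame, max_outliers: int = 10) -> pd.Index:
    """Subjects retained after dropping those with > ``max_outliers`` flags.

    A subject flagged in strictly more than ``max_outliers`` IDPs is
    removed; exactly ``max_outliers`` flags is still acceptable.
    """
    burden = mask.sum(axis=1)
    return mask.index[burden <= max_outliers]


def select_unrelated(
    pairs: pd.DataFrame,
    subjects: pd.Index | list,
    threshold: float = KINSHIP_THRESHOLD,
) -> pd.Index:
    """Choose one representative per group of related subjects.

    ``pairs`` is a KING-style table with columns (ID1, ID2, kinship).
    Edges with kinship >= ``threshold`` define a relatedness graph; from
    each connected component a single representative — the
    lexicographically smallest subject id, for determinism — is retained,
    and all isolated subjects are kept.  No retained pair is related at or
    above the threshold.
    """
    subjects = pd.Index(subjects)
    if subjects.has_duplicates:
        raise ValueError("duplicate subject ids")
    strong = pairs[pairs["kinship"] >= threshold]
    # pairs may mention subjects already excluded upstream; ignore those edges
    strong = strong[strong["ID1"].isin(subjects) & strong["ID2"].isin(subjects)]
    if strong.empty:
        return subjects
    pos = pd.Series(np.arange(len(subjects)), index=subjects)
    i = pos[strong["ID1"]].to_numpy()
    j = pos[strong["ID2"]].to_numpy()
    n = len(subjects)
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    keep = np.ones(n, dtype=bool)
    comp_sizes = np.bincount(labels)
    for comp in np.flatnonzero(comp_sizes > 1):
        members = np.flatnonzero(labels == comp)
        rep = members[np.argmin(subjects[members])]
        keep[members] = False
        keep[rep] = True
    return subjects[keep]


def inverse_normal_transform(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse Gaussian (Blom) transformation.

    Non-missing entries are replaced by Phi^{-1}((r - c) / (n - 2c + 1))
    with average ranks r over the n non-missing values and offset
    c = 3/8; missing entries stay missing.  Requires at least two distinct
    non-missing values (ranks are undefined for a constant vector).
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    xs = x[obs]
    if np.unique(xs).size < 2:
        raise ValueError("inverse normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(xs, method="average")
    n = xs.size
    out[obs] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


def transform_idps(idps: IDPMatrix) -> IDPMatrix:
    """Apply the inverse normal transformation to every IDP column.

    Columns that are constant in their non-missing part are left as all
    missing (they carry no rank information) rather than raising, so a
    single degenerate phenotype cannot abort a cohort-level run.
    """
    arr = idps.values.to_numpy(dtype=float).copy()
    for j in range(arr.shape[1]):
        col = arr[:, j]
        try:
            arr[:, j] = inverse_normal_transform(col)
        except ValueError:
            arr[:, j] = np.nan
    return IDPMatrix(
        pd.DataFrame(arr, index=idps.values.index, columns=idps.values.columns),
        idps.groups,
    )


def audit_exclusion_ledger(ledger: ExclusionLedger) -> int:
    """Return the remaining cohort size; raise if the ledger over-removes."""
    return ledger.remaining
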