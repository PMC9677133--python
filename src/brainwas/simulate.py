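"""Synthetic cohort generation.

Generates data with the statistical structure the downstream analysis
assumes: LD-structured Hardy-Weinberg genotypes at a small risk-variant
panel, confound-contaminated imaging phenotypes with planted additive
genetic effects, a lung-function-like mediator sitting on a specified
mediation path, and case-control GWAS summary statistics with a shared or
distinct causal variant.  QC stressors (missingness, technical outliers,
related pairs) are injected separately from clean generation so that
round-trip tests against the QC code can be exact.

Genotype model
--------------
Each subject is the sum of two independent haplotypes.  A haplotype is
drawn by thresholding a latent AR(1) Gaussian vector (lag-one correlation
``ld_rho``) at the per-variant MAF quantile: variant j carries the risk
allele iff Z_j < Phi^{-1}(maf_j).  Because the two haplotypes are
independent, Hardy-Weinberg equilibrium holds exactly per variant, while
pairwise dosage LD decays geometrically with marker separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfoundMatrix, GenotypeMatrix, IDPMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_idps",
    "simulate_mediator",
    "build_mediated_idp",
    "simulate_cc_summary",
    "simulate_quant_summary",
    "simulate_covariate_table",
    "simulate_imaging_confounds",
    "inject_stressors",
]


def _default_positions(n: int) -> np.ndarray:
    # evenly spaced 100 kb apart inside a 2 Mb-scale region
    return 100_000_000 + 100_000 * np.arange(n)


def _default_mafs(n: int) -> np.ndarray:
    # documented default spread for the demo panel (not values from any study)
    return np.linspace(0.05, 0.45, n)


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    ``idp_effects`` lists planted additive effects as
    (variant index, IDP index, beta in phenotype-SD units per risk allele).
    ``mediation_params`` is (a, b, c_prime, sd_m, sd_y);
    ``cc_params`` is (n_cases, n_controls, causal variant index, log-odds
    per risk allele).
    """

    n_subjects: int = 2000
    n_variants: int = 17
    n_idps: int = 200
    variant_positions: np.ndarray | None = None
    maf: np.ndarray | float | None = None
    ld_rho: float = 0.6
    idp_effects: list[tuple[int, int, float]] = field(default_factory=list)
    confound_loading_scale: float = 0.0
    noise_sd: float = 1.0
    mediation_params: tuple[float, float, float, float, float] = (0.5, 0.3, 0.2, 1.0, 1.0)
    cc_params: tuple[int, int, int, float] = (2668, 8951, 0, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_variants <= 0 or self.n_idps <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.variant_positions is None:
            self.variant_positions = _default_positions(self.n_variants)
        self.variant_positions = np.asarray(self.variant_positions)
        if len(self.variant_positions) != self.n_variants:
            raise ValueError("one position per variant required")
        if self.maf is None:
            self.maf = _default_mafs(self.n_variants)
        self.maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.n_variants,)).copy()
        if np.any(self.maf < 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5] (0 allowed only as a degenerate column)")
        for v, i, _ in self.idp_effects:
            if not (0 <= v < self.n_variants and 0 <= i < self.n_idps):
                raise IndexError(f"planted effect ({v}, {i}) outside the panel")


@dataclass
class SimTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    idp_effects: list[tuple[int, int, float]] = field(default_factory=list)
    mediation_paths: tuple[float, float, float] = (0.0, 0.0, 0.0)
    causal_variant: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "idp_effects": [list(e) for e in self.idp_effects],
            "mediation_paths": list(self.mediation_paths),
            "causal_variant": self.causal_variant,
        }


def _ar1_cholesky(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of the AR(1) correlation matrix rho^|i-j|."""
    corr = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.linalg.cholesky(corr)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw HWE dosages with AR(1)-latent LD structure.

    Dosage = sum of two haplotypes; each haplotype thresholds a latent
    AR(1) Gaussian at Phi^{-1}(maf) per variant, so each column is
    Binomial(2, maf) marginally and adjacent columns correlate through the
    latent process.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_variants
    chol = _ar1_cholesky(p, config.ld_rho)
    # maf=0 -> threshold -inf -> all-zero column (degenerate but allowed)
    with np.errstate(divide="ignore"):
        thresholds = stats.norm.ppf(config.maf)
    z = rng.standard_normal((2 * n, p)) @ chol.T
    haplotypes = (z < thresholds).astype(np.int8)
    dosages = haplotypes[:n] + haplotypes[n:]
    subj = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    var = pd.Index([f"var{j:03d}" for j in range(p)], name="variant_id")
    meta = pd.DataFrame(
        {"chrom": "8", "position": config.variant_positions, "maf": config.maf}, index=var
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=subj, columns=var), meta)


def simulate_idps(
    genotypes: GenotypeMatrix,
    confounds: ConfoundMatrix | None = None,
    truth: SimTruth | None = None,
    *,
    n_idps: int,
    confound_loadings: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    groups: pd.Series | None = None,
) -> IDPMatrix:
    """Build IDPs = planted genetic effects + confound loadings + noise.

    IDPs without planted effects are pure confound+noise null phenotypes.
    ``confound_loadings`` has shape (n_confounds, n_idps).
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    y = rng.standard_normal((n, n_idps)) * noise_sd
    if truth is not None:
        g = genotypes.dosages.to_numpy(dtype=float)
        for v, i, beta in truth.idp_effects:
            if not (0 <= v < genotypes.n_variants and 0 <= i < n_idps):
                raise IndexError(f"planted effect ({v}, {i}) outside the panel")
            y[:, i] += beta * g[:, v]
    if confounds is not None and confound_loadings is not None:
        loadings = np.asarray(confound_loadings, dtype=float)
        if loadings.shape != (confounds.n_confounds, n_idps):
            raise ValueError("confound_loadings must be (n_confounds, n_idps)")
        y += confounds.values.to_numpy(dtype=float) @ loadings
    idp_ids = pd.Index([f"idp{i:04d}" for i in range(n_idps)], name="idp_id")
    if groups is None:
        # thirds: grey-matter morphology, white-matter microstructure, functional
        labels = np.array(["GM-morphology", "WM-microstructure", "functional"])
        groups = pd.Series(labels[(3 * np.arange(n_idps)) // n_idps], index=idp_ids)
    else:
        groups = pd.Series(np.asarray(groups), index=idp_ids)
    return IDPMatrix(pd.DataFrame(y, index=genotypes.subject_ids, columns=idp_ids), groups)


def simulate_mediator(
    genotype_col: np.ndarray, a: float, noise_sd: float = 1.0, seed: int = 0
) -> np.ndarray:
    """M = a*X + eps, the lung-function-like mediator."""
    x = np.asarray(genotype_col, dtype=float)
    rng = np.random.default_rng(seed)
    return a * x + rng.standard_normal(x.shape[0]) * noise_sd


def build_mediated_idp(
    genotype_col: np.ndarray,
    mediator: np.ndarray,
    b: float,
    c_prime: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Y = c'*X + b*M + eps, an IDP lying on the mediation path."""
    x = np.asarray(genotype_col, dtype=float)
    m = np.asarray(mediator, dtype=float)
    if x.shape != m.shape:
        raise ValueError("genotype and mediator vectors must have equal length")
    rng = np.random.default_rng(seed)
    return c_prime * x + b * m + rng.standard_normal(x.shape[0]) * noise_sd


def _marginal_logistic(y: np.ndarray, g: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton fit of logit P(y=1) = b0 + b1*g for each column of g.

    Vectorised across variants (closed-form 2x2 Newton steps); returns
    (beta, se, converged).  Separation / non-convergence leaves beta at its
    last value with converged=False.
    """
    n, p = g.shape
    ybar = y.mean()
    b0 = np.full(p, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    for _ in range(max_iter):
        eta = b0 + g * b1
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (g * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01 * h01
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
        bad = ~np.isfinite(d0) | ~np.isfinite(d1)
        d0[bad] = 0.0
        d1[bad] = 0.0
        b0 += d0
        b1 += d1
        converged = (np.abs(d0) < tol) & (np.abs(d1) < tol) & ~bad
        if converged.all():
            break
    # SE from the observed information at the solution
    eta = b0 + g * b1
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g * g).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h00 / det)
    # flag separation: diverging coefficients or unusable information matrix
    ok = converged & np.isfinite(se) & (np.abs(b1) < 15)
    return b1, se, ok


def simulate_cc_summary(
    genotypes: GenotypeMatrix,
    causal_idx: int,
    log_or: float,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control GWAS summary statistics with one causal variant.

    Case status is Bernoulli from a logistic model on the causal dosage,
    with the intercept set so the expected case fraction matches
    ``n_cases / (n_cases + n_controls)`` at the mean dosage; realised
    counts therefore fluctuate around the targets (recorded in
    ``result.attrs``).  Each variant then gets a marginal logistic fit;
    non-causal variants pick up association only through LD with the
    causal one.  Separation is flagged and the SE set missing.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    if not 0 <= causal_idx < genotypes.n_variants:
        raise IndexError("causal_idx outside the variant panel")
    rng = np.random.default_rng(seed)
    g = genotypes.dosages.to_numpy(dtype=float)
    s = n_cases / (n_cases + n_controls)
    causal = g[:, causal_idx]
    alpha = np.log(s / (1 - s)) - log_or * causal.mean()
    prob = 1.0 / (1.0 + np.exp(-(alpha + log_or * causal)))
    y = (rng.random(g.shape[0]) < prob).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("degenerate case-control draw: all cases or all controls")
    beta, se, ok = _marginal_logistic(y, g)
    z = np.where(ok, beta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "position": genotypes.variants["position"].to_numpy(),
            "beta": beta,
            "se": np.where(ok, se, np.nan),
            "p": p,
            "separation_flag": ~ok,
        },
        index=genotypes.variant_ids,
    )
    out.attrs["n_cases"] = int(y.sum())
    out.attrs["n_controls"] = int((1 - y).sum())
    out.attrs["case_fraction"] = s
    out.attrs["causal_idx"] = causal_idx
    return out


def simulate_quant_summary(
    genotypes: GenotypeMatrix,
    causal_idx: int | None,
    beta: float,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantitative-trait GWAS summary statistics with one causal variant.

    Draws y = beta * g_causal + noise (pure noise when ``causal_idx`` is
    None) and runs a marginal simple linear regression per variant,
    vectorised.  Returns a table with position/beta/se/p per variant.
    """
    rng = np.random.default_rng(seed)
    g = genotypes.dosages.to_numpy(dtype=float)
    n = g.shape[0]
    y = rng.standard_normal(n) * noise_sd
    if causal_idx is not None:
        if not 0 <= causal_idx < genotypes.n_variants:
            raise IndexError("causal_idx outside the variant panel")
        y = y + beta * g[:, causal_idx]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ss_g = (gc**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        bhat = (gc * yc[:, None]).sum(axis=0) / ss_g
    resid_ss = (yc**2).sum() - bhat**2 * ss_g
    sigma2 = resid_ss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / ss_g)
        t = bhat / se
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return pd.DataFrame(
        {
            "position": genotypes.variants["position"].to_numpy(),
            "beta": bhat,
            "se": se,
            "p": p,
            "n": n,
        },
        index=genotypes.variant_ids,
    )


def simulate_covariate_table(n_subjects: int, seed: int = 0, n_genetic_pcs: int = 10) -> pd.DataFrame:
    """Draw a BWAS covariate table emulating a middle-aged imaging cohort.

    Age 45-82 (mean ~64, SD ~7.5), binary sex, height/weight/blood
    pressures at population-typical scales, standard-normal genetic PCs,
    an ever-smoker indicator and weekly/monthly drink-type counts from
    which alcohol units are derived downstream.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:06d}" for i in range(n_subjects)], name="subject_id")
    age = np.clip(rng.normal(64.2, 7.5, n_subjects), 45, 82)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    height = rng.normal(163, 6, n_subjects) + 13 * sex
    weight = rng.normal(70, 10, n_subjects) + 8 * sex
    dbp = rng.normal(80, 10, n_subjects)
    sbp = dbp + rng.normal(45, 12, n_subjects)
    table = pd.DataFrame(
        {
            "age": age, "sex": sex, "height": height, "weight": weight,
            "dbp": dbp, "sbp": sbp,
            "ever_smoker": (rng.random(n_subjects) < 0.45).astype(float),
            "drinker": (rng.random(n_subjects) < 0.9).astype(float),
            "beer_weekly": rng.poisson(3, n_subjects).astype(float),
            "wine_weekly": rng.poisson(2, n_subjects).astype(float),
            "spirits_monthly": rng.poisson(4, n_subjects).astype(float),
        },
        index=idx,
    )
    for k in range(n_genetic_pcs):
        table[f"pc{k + 1}"] = rng.standard_normal(n_subjects)
    return table


def simulate_imaging_confounds(
    n_subjects: int, seed: int = 0, n_sites: int = 3, span_days: int = 1095
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw imaging confounds and scan dates for a synthetic cohort.

    Emulates head motion (right-skewed), head-size scaling, head/table
    position and a multi-site assignment, plus scan dates spread over
    ``span_days`` — the substrate for the date-drift confound chain.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:06d}" for i in range(n_subjects)], name="subject_id")
    table = pd.DataFrame(
        {
            "head_motion": rng.lognormal(-1.8, 0.4, n_subjects),
            "head_size": rng.normal(1.25, 0.08, n_subjects),
            "pos_x": rng.normal(0, 2.5, n_subjects),
            "pos_y": rng.normal(0, 2.5, n_subjects),
            "pos_z": rng.normal(0, 3.5, n_subjects),
            "table_pos": rng.normal(50, 4, n_subjects),
            "site": rng.integers(1, n_sites + 1, n_subjects),
        },
        index=idx,
    )
    scan_dates = pd.Series(
        rng.integers(0, span_days, n_subjects).astype(float), index=idx, name="scan_date"
    )
    return table, scan_dates


def inject_stressors(
    idps: IDPMatrix,
    rate_missing: float = 0.0,
    outlier_spec: list[tuple[int, int, float]] | int | None = None,
    related_pairs_spec: int = 0,
    seed: int = 0,
) -> tuple[IDPMatrix, pd.DataFrame]:
    """Corrupt a clean IDP matrix with QC stressors.

    * ``rate_missing`` of cells set missing at random.
    * ``outlier_spec``: either an integer count of random cells, or an
      explicit list of (row, col, n_sd) displacements; displacement is
      always >= 6 cohort SDs so the 5-SD QC rule must catch them.
    * ``related_pairs_spec`` duplicated-with-noise subjects appended, each
      paired with its source in the returned kinship table at coefficient
      0.25 (first-degree-like, above the 0.0884 cut-off).

    Returns the corrupted matrix and a KING-style kinship table
    (columns ID1, ID2, kinship).
    """
    if not 0 <= rate_missing <= 1:
        raise ValueError("rate_missing must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = idps.values.copy()
    arr = values.to_numpy(dtype=float)
    n, p = arr.shape

    col_mean = np.nanmean(arr, axis=0)
    col_sd = np.nanstd(arr, axis=0, ddof=1)

    if outlier_spec is not None:
        if isinstance(outlier_spec, int):
            flat = rng.choice(n * p, size=outlier_spec, replace=False)
            outlier_spec = [(int(f // p), int(f % p), 8.0) for f in flat]
        for row, col, n_sd in outlier_spec:
            if abs(n_sd) < 6:
                raise ValueError("outlier displacement must be at least 6 SDs")
            arr[row, col] = col_mean[col] + np.sign(n_sd) * abs(n_sd) * col_sd[col]

    if rate_missing > 0:
        mask = rng.random((n, p)) < rate_missing
        arr[mask] = np.nan

    values.iloc[:, :] = arr

    kin_rows = []
    if related_pairs_spec > 0:
        sources = rng.choice(n, size=related_pairs_spec, replace=False)
        dup_rows = []
        dup_ids = []
        for k, src in enumerate(sources):
            sid = values.index[src]
            dup_id = f"{sid}_rel"
            noise = rng.standard_normal(p) * 0.05 * np.where(col_sd > 0, col_sd, 1.0)
            dup_rows.append(arr[src] + noise)
            dup_ids.append(dup_id)
            kin_rows.append((sid, dup_id, 0.25))
        dup = pd.DataFrame(dup_rows, index=pd.Index(dup_ids, name="subject_id"),
                           columns=values.columns)
        values = pd.concat([values, dup])

    kinship = pd.DataFrame(kin_rows, columns=["ID1", "ID2", "kinship"])
    return IDPMatrix(values, idps.groups), kinship
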