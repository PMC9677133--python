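"""Bayesian colocalisation of two association signals at a locus.

Under the single-causal-variant assumption, each variant's evidence for
association with a trait is summarised by a Wakefield approximate Bayes
factor computed from the effect estimate beta and its variance
varbeta = SE^2, with a N(0, W) prior on the true effect:

    log ABF = 1/2 [ log(V / (V + W)) + z^2 W / (V + W) ],   z = beta / SE.

Summing ABFs over the causal-configuration space yields posterior
probabilities for five hypotheses: H0 neither trait associated, H1/H2
only trait 1/2 associated, H3 both associated through distinct causal
variants, H4 both associated through one shared causal variant.  PP4 at
or above a decision threshold (0.8 by convention) is read as evidence of
a shared causal variant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .datatypes import ColocResult, SummaryStats

__all__ = [
    "extract_window",
    "log_abf",
    "varbeta_from_p",
    "abf_for_trait",
    "coloc_posteriors",
    "run_coloc",
    "DEFAULT_PRIORS",
    "PRIOR_SD_QUANT",
    "PRIOR_SD_CC",
]

#: per-variant prior probabilities (p1, p2, p12)
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
#: prior effect SD for a quantitative trait (phenotype-SD units)
PRIOR_SD_QUANT = 0.15
#: prior effect SD for a case-control trait (log-odds units)
PRIOR_SD_CC = 0.2


def extract_window(
    stats1: SummaryStats,
    stats2: SummaryStats,
    lead_position: int,
    half_width: int = 1_000_000,
) -> tuple[SummaryStats, SummaryStats]:
    """Restrict both traits to variants within +/- half_width of the lead.

    Endpoints are inclusive; the two traits are further restricted to the
    intersection of their variant sets so the ABF vectors align.
    """
    keep1 = stats1.table.index[
        (stats1.table["position"] - lead_position).abs() <= half_width
    ]
    keep2 = stats2.table.index[
        (stats2.table["position"] - lead_position).abs() <= half_width
    ]
    common = keep1.intersection(keep2)
    if len(common) == 0:
        raise ValueError("no variants shared by both traits inside the window")
    return stats1.restrict(common), stats2.restrict(common)


def log_abf(beta, varbeta, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association vs null."""
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(varbeta, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(v))):
        raise ValueError("beta and varbeta must be finite")
    if np.any(v <= 0) or prior_sd <= 0:
        raise ValueError("varbeta and prior_sd must be positive")
    w = prior_sd**2
    z2 = beta**2 / v
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def varbeta_from_p(
    p, maf, n, trait_type: str = "quant", s: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Recover (|beta|, varbeta) from p, MAF and sample size.

    For a standardised quantitative trait varbeta = 1 / (2 maf (1-maf) n);
    for case-control (log-odds scale) the denominator gains s(1-s) with
    case fraction s.  |beta| = |z| sqrt(varbeta), z the two-sided normal
    quantile of p.  Signs are not recoverable from p alone.
    """
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if np.any(n <= 0):
        raise ValueError("n must be positive")
    denom = 2 * maf * (1 - maf) * n
    if trait_type == "cc":
        if s is None or not 0 < s < 1:
            raise ValueError("case-control traits need case fraction s in (0,1)")
        denom = denom * s * (1 - s)
    varbeta = 1.0 / denom
    z = stats.norm.isf(p / 2)
    return z * np.sqrt(varbeta), varbeta


def abf_for_trait(ss: SummaryStats, prior_sd: float | None = None) -> np.ndarray:
    """Per-variant log ABFs for one trait's summary statistics.

    Uses beta/varbeta when present (less approximation error), otherwise
    reconstructs them from p/MAF/n.
    """
    if prior_sd is None:
        prior_sd = PRIOR_SD_CC if ss.trait_type == "cc" else PRIOR_SD_QUANT
    t = ss.table
    if {"beta", "varbeta"} <= set(t.columns) and t["varbeta"].notna().all():
        beta = t["beta"].to_numpy(dtype=float)
        varbeta = t["varbeta"].to_numpy(dtype=float)
    else:
        beta, varbeta = varbeta_from_p(
            t["p"].to_numpy(), t["maf"].to_numpy(), t["n"].to_numpy(), ss.trait_type, ss.s
        )
    return log_abf(beta, varbeta, prior_sd)


def coloc_posteriors(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
) -> ColocResult:
    """Posterior probabilities of H0..H4 from per-variant log ABFs.

    The configuration sums S1 = sum_i ABF1_i, S2 = sum_i ABF2_i,
    S12 = sum_i ABF1_i ABF2_i are accumulated in log space; the
    cross-trait term for H3 is S1*S2 - S12 (distinct causal variants).
    Unnormalised hypothesis weights are (1, p1 S1, p2 S2,
    p1 p2 (S1 S2 - S12), p12 S12), normalised to sum to one.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("log-ABF vectors must be 1-D and aligned on the same variants")
    n = l1.size
    if n == 0:
        raise ValueError("need at least one variant")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    # log(S1*S2 - S12) via the complement inside the log-sum-exp
    lcross_terms = np.add.outer(l1, l2)[~np.eye(n, dtype=bool)]
    lcross = logsumexp(lcross_terms) if n > 1 else -np.inf

    logw = np.array(
        [
            0.0,
            np.log(p1) + ls1,
            np.log(p2) + ls2,
            np.log(p1) + np.log(p2) + lcross,
            np.log(p12) + ls12,
        ]
    )
    pp = np.exp(logw - logsumexp(logw))
    pp /= pp.sum()
    return ColocResult(*pp, n_snps=n, priors=(p1, p2, p12))


def run_coloc(
    trait1: SummaryStats,
    trait2: SummaryStats,
    lead_position: int,
    half_width: int = 1_000_000,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
    decision_threshold: float = 0.8,
) -> tuple[ColocResult, bool]:
    """Window extraction -> per-trait ABFs -> posteriors -> verdict.

    The verdict is True when PP4 (shared causal variant) reaches the
    decision threshold (0.8 by the field's convention).
    """
    w1, w2 = extract_window(trait1, trait2, lead_position, half_width)
    labf1 = abf_for_trait(w1, prior_sd1)
    labf2 = abf_for_trait(w2, prior_sd2)
    result = coloc_posteriors(labf1, labf2, *priors)
    return result, bool(result.pp4 >= decision_threshold)
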