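"""Core in-memory containers shared across the pipeline.

All tabular data ride on pandas objects indexed by subject id so that the
pipeline stages can align cohorts by label rather than by position.  The
thin dataclass wrappers exist to carry the metadata that a bare DataFrame
cannot: variant positions and coded (risk) alleles, per-IDP modality
groups, confound provenance tags, and trait type for GWAS summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "IDPMatrix",
    "ConfoundMatrix",
    "SummaryStats",
    "ExclusionLedger",
    "ColocResult",
    "MediationResult",
]


@dataclass
class GenotypeMatrix:
    """Subjects x variants risk-allele dosage matrix.

    Parameters
    ----------
    dosages
        DataFrame indexed by subject id, one column per variant, values in
        {0, 1, 2} (hard calls) or [0, 2] (imputed dosages).
    variants
        Per-variant metadata indexed by variant id.  Must carry a
        ``position`` column (1-based bp); may carry ``chrom``, ``maf``,
        ``risk_allele``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.variants.index):
            raise ValueError("dosage columns and variant metadata index differ")
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate subject ids in genotype matrix")
        if "position" not in self.variants.columns:
            raise ValueError("variant metadata requires a 'position' column")

    @property
    def subject_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class IDPMatrix:
    """Subjects x imaging-derived phenotypes, continuous, missing allowed.

    ``groups`` labels each IDP with its modality class (e.g. GM-morphology,
    WM-microstructure, functional); downstream reporting is grouped by it.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("subject and IDP identifiers must be unique")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every IDP needs a modality group label")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def idp_ids(self) -> pd.Index:
        return self.values.columns

    def subset_subjects(self, subjects) -> "IDPMatrix":
        return IDPMatrix(self.values.loc[subjects], self.groups)


# provenance tags a confound column may carry
CONFOUND_PROVENANCE = ("raw", "indicator", "quantile-normalised", "centred-squared", "drift-PC")


@dataclass
class ConfoundMatrix:
    """Subjects x confound regressors; complete (no missing values).

    Each column carries a provenance tag: ``raw``, ``indicator`` (site
    dummies), ``quantile-normalised``, ``centred-squared`` or ``drift-PC``.
    """

    values: pd.DataFrame
    provenance: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("confound matrix must be complete (no missing values)")
        self.provenance = self.provenance.reindex(self.values.columns)
        if self.provenance.isna().any():
            raise ValueError("every confound column needs a provenance tag")
        bad = set(self.provenance) - set(CONFOUND_PROVENANCE)
        if bad:
            raise ValueError(f"unknown provenance tags: {sorted(bad)}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_confounds(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "ConfoundMatrix") -> "ConfoundMatrix":
        if not self.values.index.equals(other.values.index):
            raise ValueError("subject ids differ")
        return ConfoundMatrix(
            pd.concat([self.values, other.values], axis=1),
            pd.concat([self.provenance, other.provenance]),
        )


@dataclass
class SummaryStats:
    """Per-variant GWAS summary statistics for one trait.

    ``table`` is indexed by variant id with a 1-based bp ``position``
    column, and either (``beta``, ``varbeta``) or (``p``, ``maf``, ``n``)
    per variant — both may be present, in which case beta/varbeta wins.
    ``trait_type`` is ``"quant"`` or ``"cc"``; case-control traits carry
    the case fraction ``s``.
    """

    table: pd.DataFrame
    trait_type: str = "quant"
    s: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quant", "cc"):
            raise ValueError("trait_type must be 'quant' or 'cc'")
        if self.trait_type == "cc" and self.s is None:
            raise ValueError("case-control summary stats need the case fraction s")
        if "position" not in self.table.columns:
            raise ValueError("summary statistics require a 'position' column")
        has_bv = {"beta", "varbeta"} <= set(self.table.columns)
        has_p = {"p", "maf", "n"} <= set(self.table.columns)
        if not (has_bv or has_p):
            raise ValueError("need beta/varbeta or p/maf/n columns")
        if has_bv and (self.table["varbeta"] <= 0).any():
            raise ValueError("varbeta must be positive")
        pos = self.table["position"].to_numpy()
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def variant_ids(self) -> pd.Index:
        return self.table.index

    def restrict(self, variant_ids) -> "SummaryStats":
        return SummaryStats(self.table.loc[variant_ids], self.trait_type, self.s)


@dataclass
class ExclusionLedger:
    """Ordered audit trail of cohort exclusions.

    ``steps`` is an ordered list of (criterion label, count removed)
    applied to ``start`` subjects.
    """

    start: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("starting count must be non-negative")
        for label, count in self.steps:
            if count < 0:
                raise ValueError(f"negative removal count for {label!r}")

    def record(self, label: str, count: int) -> None:
        if count < 0:
            raise ValueError(f"negative removal count for {label!r}")
        self.steps.append((label, int(count)))

    @property
    def remaining(self) -> int:
        rem = self.start - sum(c for _, c in self.steps)
        if rem < 0:
            raise ValueError("ledger removes more subjects than it started with")
        return rem

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "steps": [{"criterion": lab, "removed": c} for lab, c in self.steps],
            "remaining": self.remaining,
        }


@dataclass
class ColocResult:
    """Posterior probabilities over the five colocalisation hypotheses.

    H0 no association; H1/H2 trait-specific association; H3 two distinct
    causal variants; H4 one shared causal variant.
    """

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: tuple[float, float, float]

    def __post_init__(self) -> None:
        total = self.pp0 + self.pp1 + self.pp2 + self.pp3 + self.pp4
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"posteriors sum to {total!r}, not 1")
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    def to_dict(self) -> dict:
        return {
            "pp0": self.pp0,
            "pp1": self.pp1,
            "pp2": self.pp2,
            "pp3": self.pp3,
            "pp4": self.pp4,
            "n_snps": self.n_snps,
            "p1": self.priors[0],
            "p2": self.priors[1],
            "p12": self.priors[2],
        }


@dataclass
class MediationResult:
    """Path coefficients and Sobel test for a single X -> M -> Y model.

    a: X->M; b: M->Y given X; c: total X->Y; c_prime: direct X->Y given M.
    The indirect effect is a*b; on a shared complete-case sample the OLS
    identity c = c_prime + a*b holds exactly.
    """

    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    c_prime: float
    se_c_prime: float
    n: int
    sobel_z: float | None = None
    sobel_p: float | None = None
    proportion_mediated: float | None = None

    @property
    def indirect(self) -> float:
        return self.a * self.b

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "se_a": self.se_a,
            "b": self.b,
            "se_b": self.se_b,
            "c": self.c,
            "se_c": self.se_c,
            "c_prime": self.c_prime,
            "se_c_prime": self.se_c_prime,
            "indirect": self.indirect,
            "n": self.n,
            "sobel_z": self.sobel_z,
            "sobel_p": self.sobel_p,
            "proportion_mediated": self.proportion_mediated,
        }
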