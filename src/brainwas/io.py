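"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is TSV with a header row (floats at 10 significant digits for
stable diffs); confound provenance and IDP modality groups travel in
sidecar files; ground truth, ledgers and manifests are JSON.  Genotypes
can additionally be exchanged as VCF with a GT field, the risk allele
written as ALT (cyvcf2, optional dependency, is used for reading).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfoundMatrix, GenotypeMatrix, IDPMatrix, SummaryStats

FLOAT_FMT = "%.10g"

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_idps",
    "read_idps",
    "write_confounds",
    "read_confounds",
    "write_kinship",
    "read_kinship",
    "write_summary_stats",
    "read_summary_stats",
    "write_json",
    "read_json",
    "write_vcf",
    "read_vcf_dosages",
]


def write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


_tsv = write_tsv


def write_genotypes(g: GenotypeMatrix, prefix: Path) -> None:
    """Write <prefix>.tsv (dosages) and <prefix>.variants.tsv (metadata)."""
    prefix = Path(prefix)
    _tsv(g.dosages, prefix.with_suffix(".tsv"), index_label="subject_id")
    _tsv(g.variants, Path(str(prefix) + ".variants.tsv"), index_label="variant_id")


def read_genotypes(prefix: Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dosages = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="subject_id")
    variants = pd.read_csv(Path(str(prefix) + ".variants.tsv"), sep="\t", index_col="variant_id")
    variants.index = pd.Index(variants.index.astype(str), name="variant_id")
    dosages.columns = pd.Index(dosages.columns.astype(str), name="variant_id")
    return GenotypeMatrix(dosages, variants)


def write_idps(idps: IDPMatrix, prefix: Path) -> None:
    """Write <prefix>.tsv (values) and <prefix>.groups.tsv (modality labels)."""
    prefix = Path(prefix)
    _tsv(idps.values, prefix.with_suffix(".tsv"), index_label="subject_id")
    groups = idps.groups.rename("idp_group").to_frame()
    _tsv(groups, Path(str(prefix) + ".groups.tsv"), index_label="idp_id")


def read_idps(prefix: Path) -> IDPMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="subject_id")
    groups = pd.read_csv(
        Path(str(prefix) + ".groups.tsv"), sep="\t", index_col="idp_id"
    )["idp_group"]
    groups.index = pd.Index(groups.index.astype(str), name="idp_id")
    values.columns = pd.Index(values.columns.astype(str), name="idp_id")
    return IDPMatrix(values, groups)


def write_confounds(c: ConfoundMatrix, prefix: Path) -> None:
    """Write <prefix>.tsv plus a provenance sidecar <prefix>.provenance.json."""
    prefix = Path(prefix)
    _tsv(c.values, prefix.with_suffix(".tsv"), index_label="subject_id")
    with open(Path(str(prefix) + ".provenance.json"), "w") as fh:
        json.dump(c.provenance.to_dict(), fh, indent=1)


def read_confounds(prefix: Path) -> ConfoundMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="subject_id")
    with open(Path(str(prefix) + ".provenance.json")) as fh:
        prov = pd.Series(json.load(fh))
    values.columns = values.columns.astype(str)
    return ConfoundMatrix(values.astype(float), prov)


def write_kinship(pairs: pd.DataFrame, path: Path) -> None:
    """KING-layout kinship table: columns ID1, ID2, kinship."""
    pairs[["ID1", "ID2", "kinship"]].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_kinship(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"ID1": str, "ID2": str})


def write_summary_stats(ss: SummaryStats, path: Path) -> None:
    table = ss.table.copy()
    table.attrs["trait_type"] = ss.trait_type
    _tsv(table, Path(path), index_label="snp_id")
    meta = {"trait_type": ss.trait_type, "s": ss.s}
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh)


def read_summary_stats(path: Path) -> SummaryStats:
    table = pd.read_csv(path, sep="\t", index_col="snp_id")
    table.index = table.index.astype(str)
    meta_path = Path(str(path) + ".meta.json")
    trait_type, s = "quant", None
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        trait_type, s = meta.get("trait_type", "quant"), meta.get("s")
    return SummaryStats(table, trait_type, s)


def write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def read_json(path: Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_vcf(g: GenotypeMatrix, path: Path, ref_allele: str = "A") -> None:
    """Write hard-call dosages as a minimal VCF; risk allele is ALT.

    Dosage 0/1/2 maps to GT 0/0, 0/1, 1/1.  Imputed (fractional) dosages
    are rounded to the nearest hard call.
    """
    dos = np.rint(g.dosages.to_numpy(dtype=float)).astype(int)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.subject_ids))
            + "\n"
        )
        for j, vid in enumerate(g.variant_ids):
            meta = g.variants.loc[vid]
            alt = meta.get("risk_allele", "G")
            row = [
                str(meta.get("chrom", "1")),
                str(int(meta["position"])),
                str(vid),
                ref_allele,
                str(alt),
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_map[int(d)] for d in dos[:, j]]
            fh.write("\t".join(row) + "\n")


def read_vcf_dosages(path: Path) -> GenotypeMatrix:
    """Read GT-field dosages from a VCF (requires cyvcf2); ALT is the risk allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = pd.Index(vcf.samples, name="subject_id")
    cols, meta_rows, ids = [], [], []
    for rec in vcf:
        gts = np.asarray(rec.genotypes)[:, :2]
        dosage = (gts > 0).sum(axis=1)
        cols.append(dosage)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        meta_rows.append(
            {"chrom": rec.CHROM, "position": rec.POS, "risk_allele": rec.ALT[0] if rec.ALT else "."}
        )
    var = pd.Index(ids, name="variant_id")
    dosages = pd.DataFrame(np.column_stack(cols), index=subjects, columns=var)
    return GenotypeMatrix(dosages, pd.DataFrame(meta_rows, index=var))
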