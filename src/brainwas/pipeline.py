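"""End-to-end orchestration: simulate -> QC -> confounds -> BWAS -> coloc -> mediation.

Each stage reads its inputs from, and writes its outputs to, the run
directory, so any stage can be re-run from its on-disk inputs; a JSON
manifest records seeds, row counts, thresholds and output hashes.  A
single global seed fans out to per-stage child seeds by stable hashing,
so stages are reproducible independently of one another.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bwas as bwas_mod
from . import coloc as coloc_mod
from . import confounds as conf_mod
from . import io as io_mod
from . import mediation as med_mod
from . import preprocess as prep_mod
from . import simulate as sim_mod
from .datatypes import ConfoundMatrix, ExclusionLedger, GenotypeMatrix, SummaryStats

__all__ = ["default_config", "load_config", "child_seed", "run_pipeline"]


def default_config() -> dict:
    """The demo configuration: a desk-scale cohort with planted signal."""
    return {
        "seed": 0,
        "alpha": 0.05,
        "kinship_threshold": prep_mod.KINSHIP_THRESHOLD,
        "outlier_k_sd": 5.0,
        "max_outlier_idps": 10,
        "int_before_deconfound": True,
        "simulate": {
            "n_subjects": 2000,
            "n_variants": 17,
            "n_idps": 200,
            "ld_rho": 0.6,
            # planted additive effects: (variant index, IDP index, beta in SD units)
            "idp_effects": [[8, 0, 0.25], [8, 1, 0.2], [5, 10, 0.3]],
            "confound_loading_scale": 0.1,
            "drift_amplitude": 0.15,
            "noise_sd": 1.0,
            "mediation": {
                "a": 0.5, "b": 0.3, "c_prime": 0.2,
                "sd_m": 1.0, "sd_y": 1.0, "variant": 8, "idp": None,
            },
            "cc": {"n_cases": 2668, "n_controls": 8951, "causal_idx": 8, "log_or": 0.4},
            "stressors": {"rate_missing": 0.02, "n_outlier_cells": 20, "n_related_pairs": 5},
            "units_per_drink": {"beer_weekly": 2.3, "wine_weekly": 2.1, "spirits_monthly": 1.0},
        },
        "drift": {"rank": 10, "mad_k": 5.0, "spline_df": 10, "n_components": 10},
        "coloc": {"window": 1_000_000, "p1": 1e-4, "p2": 1e-4, "p12": 1e-5, "threshold": 0.8},
        "mediation": {"covars": ["age", "sex", "height"], "int_mediator": False},
    }


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the defaults (shallow per top-level block)."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def child_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: dict, out: Path) -> dict:
    """Generate the cohort and write every raw input table."""
    sc = cfg["simulate"]
    seed = child_seed(cfg["seed"], "simulate")
    sim_cfg = sim_mod.SimConfig(
        n_subjects=sc["n_subjects"],
        n_variants=sc["n_variants"],
        n_idps=sc["n_idps"],
        ld_rho=sc["ld_rho"],
        idp_effects=[tuple(e) for e in sc["idp_effects"]],
        confound_loading_scale=sc["confound_loading_scale"],
        noise_sd=sc["noise_sd"],
        seed=seed,
    )
    genotypes = sim_mod.simulate_genotypes(sim_cfg)
    raw_conf, scan_dates = sim_mod.simulate_imaging_confounds(
        sc["n_subjects"], seed=child_seed(cfg["seed"], "confound-sim")
    )
    covars = sim_mod.simulate_covariate_table(
        sc["n_subjects"], seed=child_seed(cfg["seed"], "covariate-sim")
    )
    truth = sim_mod.SimTruth(
        idp_effects=sim_cfg.idp_effects,
        mediation_paths=(sc["mediation"]["a"], sc["mediation"]["b"], sc["mediation"]["c_prime"]),
        causal_variant={"ipf": sc["cc"]["causal_idx"]},
    )

    # confound contamination rides on the standardised continuous confounds
    rng = np.random.default_rng(child_seed(cfg["seed"], "loadings"))
    cont = raw_conf.drop(columns=["site"]).astype(float)
    z = (cont - cont.mean()) / cont.std(ddof=0)
    loadings = rng.normal(0.0, sc["confound_loading_scale"], (z.shape[1], sc["n_idps"]))
    conf_for_sim = ConfoundMatrix(z, pd.Series("raw", index=z.columns))
    idps = sim_mod.simulate_idps(
        genotypes,
        conf_for_sim,
        truth,
        n_idps=sc["n_idps"],
        confound_loadings=loadings,
        noise_sd=sc["noise_sd"],
        seed=child_seed(cfg["seed"], "idps"),
    )

    # slowly varying scan-date drift shared across IDPs
    amp = sc.get("drift_amplitude", 0.0)
    if amp > 0:
        t = (scan_dates - scan_dates.min()) / max(scan_dates.max() - scan_dates.min(), 1.0)
        basis = np.column_stack([t - t.mean(), np.sin(2 * np.pi * t)])
        drift_load = rng.normal(0.0, amp, (2, sc["n_idps"]))
        idps.values.iloc[:, :] = idps.values.to_numpy() + basis @ drift_load

    # the mediated phenotype replaces one IDP column
    med = sc["mediation"]
    med_idp = med["idp"] if med["idp"] is not None else sc["n_idps"] - 1
    x = genotypes.dosages.iloc[:, med["variant"]].to_numpy(dtype=float)
    mediator = sim_mod.simulate_mediator(
        x, med["a"], med["sd_m"], seed=child_seed(cfg["seed"], "mediator")
    )
    idps.values.iloc[:, med_idp] = sim_mod.build_mediated_idp(
        x, mediator, med["b"], med["c_prime"], med["sd_y"],
        seed=child_seed(cfg["seed"], "mediated-idp"),
    )

    # trait-1 GWAS comes from an independent case-control collection with
    # the same variant panel, at the collection's own sample size
    cc = sc["cc"]
    cc_cohort_cfg = sim_mod.SimConfig(
        n_subjects=cc["n_cases"] + cc["n_controls"],
        n_variants=sc["n_variants"],
        n_idps=sc["n_idps"],
        ld_rho=sc["ld_rho"],
        seed=child_seed(cfg["seed"], "cc-cohort"),
    )
    cc_genotypes = sim_mod.simulate_genotypes(cc_cohort_cfg)
    cc_table = sim_mod.simulate_cc_summary(
        cc_genotypes, cc["causal_idx"], cc["log_or"], cc["n_cases"], cc["n_controls"],
        seed=child_seed(cfg["seed"], "cc"),
    )

    st = sc["stressors"]
    idps_noisy, kinship = sim_mod.inject_stressors(
        idps,
        rate_missing=st["rate_missing"],
        outlier_spec=st["n_outlier_cells"],
        related_pairs_spec=st["n_related_pairs"],
        seed=child_seed(cfg["seed"], "stressors"),
    )
    # appended related subjects inherit covariates/confounds of their source
    extra = idps_noisy.subject_ids.difference(idps.subject_ids)
    src = [i.rsplit("_rel", 1)[0] for i in extra]
    for df in (raw_conf, covars):
        dup = df.loc[src].set_axis(extra, axis=0)
        df_new = pd.concat([df, dup])
        df_new.index.name = "subject_id"
        if df is raw_conf:
            raw_conf = df_new
        else:
            covars = df_new
    scan_dates = pd.concat(
        [scan_dates, scan_dates.loc[src].set_axis(extra)]
    ).rename("scan_date")
    scan_dates.index.name = "subject_id"
    mediator_s = pd.Series(mediator, index=idps.subject_ids, name="fvc")
    mediator_s = mediator_s.reindex(idps_noisy.subject_ids)
    mediator_s.loc[extra] = mediator_s.loc[src].to_numpy()

    io_mod.write_genotypes(genotypes, out / "genotypes")
    io_mod.write_vcf(genotypes, out / "genotypes.vcf")
    io_mod.write_idps(idps_noisy, out / "idps_raw")
    io_mod.write_tsv(raw_conf, out / "confounds_raw.tsv", index_label="subject_id")
    io_mod.write_tsv(covars, out / "covariates.tsv", index_label="subject_id")
    io_mod.write_tsv(scan_dates.to_frame(), out / "scan_dates.tsv", index_label="subject_id")
    io_mod.write_tsv(mediator_s.to_frame(), out / "mediator.tsv", index_label="subject_id")
    io_mod.write_kinship(kinship, out / "kinship.tsv")
    cc_table_out = cc_table.copy()
    io_mod.write_tsv(cc_table_out, out / "ipf_summary.tsv", index_label="snp_id")
    io_mod.write_json(
        {
            "truth": truth.to_dict(),
            "mediated_idp": int(med_idp),
            "cc_attrs": dict(cc_table.attrs),
        },
        out / "truth.json",
    )
    return {"n_subjects_with_relatives": int(idps_noisy.values.shape[0])}


def stage_preprocess(cfg: dict, out: Path) -> dict:
    """QC chain: outlier flagging, burden exclusion, relatedness, INT."""
    idps = io_mod.read_idps(out / "idps_raw")
    kinship = io_mod.read_kinship(out / "kinship.tsv")
    ledger = ExclusionLedger(start=idps.values.shape[0])

    mask = prep_mod.flag_technical_outliers(idps, cfg["outlier_k_sd"])
    idps = prep_mod.apply_outlier_mask(idps, mask)
    keep = prep_mod.exclude_by_outlier_burden(mask, cfg["max_outlier_idps"])
    ledger.record("unreliable imaging features (> max outlier IDPs)",
                  idps.values.shape[0] - len(keep))
    idps = idps.subset_subjects(keep)

    unrelated = prep_mod.select_unrelated(kinship, idps.subject_ids, cfg["kinship_threshold"])
    ledger.record("relatedness (KING kinship >= threshold)",
                  idps.values.shape[0] - len(unrelated))
    idps = idps.subset_subjects(unrelated)

    if cfg["int_before_deconfound"]:
        idps = prep_mod.transform_idps(idps)

    io_mod.write_idps(idps, out / "idps_qc")
    io_mod.write_json(ledger.to_dict(), out / "exclusion_ledger.json")
    return {
        "n_subjects": int(idps.values.shape[0]),
        "n_flagged_cells": int(mask.to_numpy().sum()),
        "ledger_remaining": ledger.remaining,
    }


def stage_confounds(cfg: dict, out: Path) -> dict:
    """Drift components + augmented confounds; deconfound the IDPs."""
    idps = io_mod.read_idps(out / "idps_qc")
    raw = pd.read_csv(out / "confounds_raw.tsv", sep="\t", index_col="subject_id")
    dates = pd.read_csv(out / "scan_dates.tsv", sep="\t", index_col="subject_id")["scan_date"]
    raw = raw.loc[idps.subject_ids]
    dates = dates.loc[idps.subject_ids]

    raw_cm = ConfoundMatrix(raw, pd.Series("raw", index=raw.columns))
    augmented = conf_mod.augment_confounds(raw_cm, categorical=["site"])
    spec = conf_mod.DriftSpec(**cfg["drift"])
    drift = conf_mod.build_drift_confounds(idps, dates, spec)
    full = augmented.hstack(drift)

    deconf = conf_mod.deconfound(idps, full)
    if not cfg["int_before_deconfound"]:
        # alternative ordering: residualise the raw IDPs first, then INT
        deconf = prep_mod.transform_idps(deconf)

    io_mod.write_confounds(full, out / "confounds_full")
    io_mod.write_idps(deconf, out / "idps_deconfounded")
    return {"n_confounds": int(full.n_confounds)}


def stage_bwas(cfg: dict, out: Path) -> dict:
    """Covariate assembly and the mass-univariate association scan."""
    genotypes = io_mod.read_genotypes(out / "genotypes")
    idps = io_mod.read_idps(out / "idps_deconfounded")
    covars_raw = pd.read_csv(out / "covariates.tsv", sep="\t", index_col="subject_id")
    covars_raw = covars_raw.loc[idps.subject_ids]
    genotypes_sub = genotypes.dosages.loc[idps.subject_ids]
    genotypes = GenotypeMatrix(genotypes_sub, genotypes.variants)

    units = bwas_mod.derive_alcohol_units(
        covars_raw["drinker"],
        weekly_counts=covars_raw[["beer_weekly", "wine_weekly"]],
        monthly_counts=covars_raw[["spirits_monthly"]],
        units_per_drink=cfg["simulate"]["units_per_drink"],
    )
    covars_raw = covars_raw.assign(alcohol_units=units)
    design = bwas_mod.build_covariates(covars_raw)

    table = bwas_mod.run_bwas(genotypes, idps, design)
    n_tests = len(table)
    bonf = bwas_mod.bonferroni_threshold(cfg["alpha"], n_tests)
    valid = table["p"].notna()
    reject, adjusted = bwas_mod.bh_fdr(table.loc[valid, "p"], cfg["alpha"])
    table["fdr_significant"] = False
    table.loc[valid, "fdr_significant"] = reject
    table["p_fdr"] = np.nan
    table.loc[valid, "p_fdr"] = adjusted
    table["bonferroni_significant"] = table["p"] < bonf
    counts = bwas_mod.count_significant(table, bonf)

    table.to_csv(out / "associations.tsv", sep="\t", index=False, float_format=io_mod.FLOAT_FMT)
    counts.rename("n_significant").to_frame().to_csv(
        out / "significant_counts.tsv", sep="\t", index_label="variant"
    )
    return {
        "n_tests": int(n_tests),
        "bonferroni_threshold": bonf,
        "bonferroni_threshold_3sf": float(f"{bonf:.3g}"),
        "n_bonferroni_significant": int(table["bonferroni_significant"].sum()),
        "n_fdr_significant": int(table["fdr_significant"].sum()),
        "per_variant_counts": {str(k): int(v) for k, v in counts.items()},
    }


def stage_coloc(cfg: dict, out: Path) -> dict:
    """Colocalise the top-associated IDP's profile with the IPF signal."""
    genotypes = io_mod.read_genotypes(out / "genotypes")
    assoc = pd.read_csv(out / "associations.tsv", sep="\t")
    ipf = pd.read_csv(out / "ipf_summary.tsv", sep="\t", index_col="snp_id")
    ipf.index = ipf.index.astype(str)
    truth = io_mod.read_json(out / "truth.json")

    t1 = pd.DataFrame(
        {
            "position": ipf["position"],
            "beta": ipf["beta"],
            "varbeta": ipf["se"] ** 2,
            "p": ipf["p"],
        },
        index=ipf.index,
    ).dropna(subset=["varbeta"])
    cc_attrs = truth["cc_attrs"]
    trait1 = SummaryStats(t1, "cc", s=cc_attrs["case_fraction"])

    # IDP most associated with the trait-1 lead variant (the paper
    # colocalises the IDPs that are significant at the risk locus)
    lead_variant = t1["p"].idxmin()
    valid = assoc[assoc["p"].notna() & (assoc["variant"] == lead_variant)]
    if valid.empty:
        valid = assoc[assoc["p"].notna()]
    top_idp = valid.loc[valid["p"].idxmin(), "idp"]
    rows = assoc[assoc["idp"] == top_idp].set_index("variant")
    rows.index = rows.index.astype(str)
    pos = genotypes.variants["position"]
    t2 = pd.DataFrame(
        {
            "position": pos,
            "beta": rows["beta"].reindex(pos.index),
            "varbeta": (rows["se"] ** 2).reindex(pos.index),
            "p": rows["p"].reindex(pos.index),
        }
    ).dropna(subset=["varbeta"])
    trait2 = SummaryStats(t2.sort_values("position"), "quant")

    lead = lead_variant
    lead_pos = int(t1.loc[lead, "position"])
    cc_cfg = cfg["coloc"]
    result, shared = coloc_mod.run_coloc(
        trait1, trait2, lead_pos,
        half_width=cc_cfg["window"],
        priors=(cc_cfg["p1"], cc_cfg["p2"], cc_cfg["p12"]),
        decision_threshold=cc_cfg["threshold"],
    )
    payload = result.to_dict() | {
        "idp": str(top_idp), "lead_snp": str(lead), "lead_position": lead_pos,
        "shared_causal_variant": shared,
    }
    io_mod.write_json(payload, out / "coloc.json")
    pd.DataFrame([payload]).to_csv(out / "coloc.tsv", sep="\t", index=False,
                                   float_format=io_mod.FLOAT_FMT)
    return payload


def stage_mediate(cfg: dict, out: Path) -> dict:
    """Mediation of the planted variant-IDP association through the mediator."""
    genotypes = io_mod.read_genotypes(out / "genotypes")
    idps = io_mod.read_idps(out / "idps_deconfounded")
    covars = pd.read_csv(out / "covariates.tsv", sep="\t", index_col="subject_id")
    mediator = pd.read_csv(out / "mediator.tsv", sep="\t", index_col="subject_id")["fvc"]
    truth = io_mod.read_json(out / "truth.json")

    subjects = idps.subject_ids
    med_cfg = cfg["simulate"]["mediation"]
    variant = genotypes.variant_ids[med_cfg["variant"]]
    x = genotypes.dosages.loc[subjects, variant].to_numpy(dtype=float)
    m = mediator.loc[subjects].to_numpy(dtype=float)
    if cfg["mediation"].get("int_mediator", False):
        m = prep_mod.inverse_normal_transform(m)
    idp_name = idps.idp_ids[truth["mediated_idp"]]
    y = idps.values.loc[subjects, idp_name].to_numpy(dtype=float)
    adj = covars.loc[subjects, cfg["mediation"]["covars"]]

    row = med_mod.mediate(x, m, y, adj, alpha=cfg["alpha"])
    row["variant"] = str(variant)
    row["idp"] = str(idp_name)
    row["sobel_p_bonferroni"] = min(1.0, row["sobel_p"] * genotypes.n_variants)
    io_mod.write_json(row, out / "mediation.json")
    pd.DataFrame([row]).to_csv(out / "mediation.tsv", sep="\t", index=False,
                               float_format=io_mod.FLOAT_FMT)
    return row


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "confounds": stage_confounds,
    "bwas": stage_bwas,
    "coloc": stage_coloc,
    "mediate": stage_mediate,
}

_ORDER = ["simulate", "preprocess", "confounds", "bwas", "coloc", "mediate"]


def run_pipeline(cfg: dict, out_dir: str | Path, stages: list[str] | None = None) -> dict:
    """Run the stage chain and write a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg["seed"],
        "stage_seeds": {s: child_seed(cfg["seed"], s) for s in _ORDER},
        "stages": {},
    }
    for name in stages or _ORDER:
        try:
            manifest["stages"][name] = STAGES[name](cfg, out)
        except Exception as exc:  # preserve partial outputs, report the stage
            manifest["stages"][name] = {"error": str(exc)}
            io_mod.write_json(manifest, out / "manifest.json")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["output_hashes"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    io_mod.write_json(manifest, out / "manifest.json")
    return manifest
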