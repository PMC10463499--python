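"""End-to-end orchestration: simulate or load a cohort, then run features ->
network -> kinship -> varcomp -> assoc -> recursive, writing TSV outputs and
a manifest per run.

The manifest records the package version, seed, a hash of the resolved
configuration, per-stage output files and the counts at every filter, so two
runs with the same seed produce identical manifests and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .assoc import adjust_phenotype, bonferroni, mbgwas_scan, mlm_gwas, mwas_two_part
from .containers import ConfigurationError
from .features import build_feature_set, filter_genera, rarefy
from .kinship import compute_grm, compute_mrm, genetic_pcs, mantel_test, qc_genotypes
from .network import build_network, core_taxa, detect_modules, zi_pi
from .recursive import recursive_report
from .simcohort import (SimConfig, recursive_design_config, simulate_cohort,
                        to_counts)
from .varcomp import (build_design, estimate_h2, estimate_joint, estimate_m2,
                      feature_h2_scan, lrt, reml_null)

logger = logging.getLogger("rumenlink")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Every threshold of the analysis, with the study's printed defaults."""

    out_dir: str = "rumenlink_run"
    seed: int = 0
    # inputs: either a simulation block or file paths
    simulate: dict | None = None
    genotype_tsv: str | None = None
    abundance_tsv: str | None = None
    phenotype_tsv: str | None = None        # columns: sample_id, y, covariates...
    # thresholds
    prevalence_low: float = 0.015
    prevalence_split: float = 0.60
    min_binary_prevalence: float = 0.30
    maf_min: float = 0.05
    max_missing: float = 0.3
    rarefaction_depth: int | None = None
    network_r_threshold: float = 0.6
    network_alpha: float = 0.05
    suggestive: float = 1e-6
    genome_wide: float = 1e-8
    kw_alpha: float = 0.01
    mwas_alpha: float = 0.05
    heritable_alpha: float = 0.05
    n_pcs_h2: int = 5
    n_pcs_gwas: int = 3
    mantel_permutations: int = 9999
    clr_pseudocount: float = 1e-6
    max_mbgwas_features: int | None = None   # cap for desk-scale runs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_recursive_experiment(seed: int, **design_kwargs) -> dict:
    """One designed-truth recursive-detection run.

    Simulates the :func:`recursive_design_config` cohort, runs MWAS ->
    mbGWAS (marker genera) -> GWAS -> scenario labelling, and reports whether
    the designed pleiotropic SNP was labelled recursive and the designed
    taxon-only SNP indirect-only.
    """
    from .features import clr_transform

    cfg = recursive_design_config(seed, **design_kwargs)
    cohort = simulate_cohort(cfg)
    geno = qc_genotypes(cohort["genotypes"])
    grm = compute_grm(geno)
    pcs = genetic_pcs(grm, 3)
    genus_table = filter_genera(cohort["abundance"])
    y_adj = adjust_phenotype(cohort["y"], cohort["covariates"])
    mwas = mwas_two_part(y_adj, genus_table, pcs=pcs)
    X = build_design(cohort["covariates"], pcs)
    clr = clr_transform(genus_table)
    cols = {t: i for i, t in enumerate(genus_table.taxon_ids)}
    mbgwas = {
        g: mlm_gwas(clr[:, cols[g]], X, grm, geno)
        for g in mwas[mwas["p_bonferroni"] < 0.05]["taxon"]
        if g in cols
    }
    gwas = mlm_gwas(cohort["y"], X, grm, geno)
    table, summary = recursive_report(mwas, mbgwas, gwas, cohort["y"], geno)
    pleio_id = cohort["genotypes"].snp_ids[cfg.designed_effects[0].snp_index]
    tonly_id = cohort["genotypes"].snp_ids[cfg.designed_effects[1].snp_index]
    pleio = table[table["snp_id"] == pleio_id]
    tonly = table[table["snp_id"] == tonly_id]
    return {
        "table": table,
        "summary": summary,
        "pleiotropic_recursive": bool(
            len(pleio) and "recursive" in pleio["labels"].iloc[0]
        ),
        "taxon_only_indirect_only": bool(
            len(tonly) and tonly["labels"].iloc[0] == "indirect only"
        ),
    }


def _validate_inputs(config: RunConfig) -> None:
    if config.simulate is not None:
        return
    for name in ("genotype_tsv", "abundance_tsv", "phenotype_tsv"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name} missing: {path}")


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    TSVs plus ``manifest.json`` under ``config.out_dir``."""
    _validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "rumenlink",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.resolved(),
        "stages": {},
    }
    results: dict = {}

    def record(stage, **info):
        manifest["stages"][stage] = info

    try:
        # ----- inputs
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim = SimConfig(**sim_kwargs)
            cohort = simulate_cohort(sim)
            geno = cohort["genotypes"]
            rel = cohort["abundance"]
            counts = to_counts(rel, seed=config.seed)
            y = cohort["y"]
            covariates = cohort["covariates"]
            cohort["truth"].to_json(out / "truth.json")
            rio.write_genotypes_tsv(geno, out / "genotypes.tsv")
            rio.write_abundance_tsv(rel, out / "abundance_relative.tsv")
            pheno_df = covariates.copy()
            pheno_df.insert(0, "y", y)
            pheno_df.to_csv(out / "phenotype.tsv", sep="\t", index_label="sample_id")
            record("inputs", mode="simulated", n_individuals=geno.n_samples,
                   n_snps=geno.n_snps, n_taxa=rel.n_taxa)
        else:
            geno = rio.read_genotypes_tsv(config.genotype_tsv)
            table = rio.read_abundance_tsv(config.abundance_tsv)
            pheno_df = pd.read_csv(config.phenotype_tsv, sep="\t", index_col=0)
            y = pheno_df["y"].to_numpy(dtype=float)
            covariates = pheno_df.drop(columns=["y"])
            if table.kind == "counts":
                counts = table
                rel = table.to_relative()
            else:
                counts, rel = None, table
            record("inputs", mode="files", n_individuals=geno.n_samples,
                   n_snps=geno.n_snps, n_taxa=rel.n_taxa)

        # ----- features
        if counts is not None and config.rarefaction_depth:
            counts = rarefy(counts, config.rarefaction_depth, seed=config.seed)
        genus_table = filter_genera(rel)
        feats = build_feature_set(
            genus_table, counts_table=counts, low=config.prevalence_low,
            split=config.prevalence_split, clr_pseudocount=config.clr_pseudocount,
        )
        feats.community.to_csv(out / "features_community.tsv", sep="\t")
        feats.quantitative.to_csv(out / "features_quantitative_clr.tsv", sep="\t")
        feats.binary.to_csv(out / "features_binary.tsv", sep="\t")
        record("features", n_genera_after_qc=genus_table.n_taxa,
               n_quantitative=feats.quantitative.shape[1],
               n_binary=feats.binary.shape[1],
               n_excluded_rare=len(feats.excluded_taxa),
               n_community=feats.community.shape[1])
        results["features"] = feats

        # ----- network
        core = core_taxa(genus_table)
        net = build_network(
            genus_table, r_threshold=config.network_r_threshold,
            alpha=config.network_alpha, min_prev=config.prevalence_low,
            clr_pseudocount=config.clr_pseudocount,
        )
        if net.graph.number_of_edges() > 0:
            net = detect_modules(net)
            topo = zi_pi(net)
        else:
            topo = pd.DataFrame(
                columns=["taxon", "module", "degree", "Zi", "Pi", "node_class",
                         "keystone"]
            )
        net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        topo.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
        pd.Series(core, name="core_taxon").to_csv(out / "core_taxa.tsv", sep="\t",
                                                  index=False)
        record("network", n_core=len(core), n_nodes=net.graph.number_of_nodes(),
               n_edges=net.graph.number_of_edges(),
               n_keystone=int(topo["keystone"].sum()) if len(topo) else 0,
               modularity=net.modularity)
        results["network"] = (net, topo, core)

        # ----- kinship
        geno_qc = qc_genotypes(geno, maf_min=config.maf_min,
                               max_missing=config.max_missing)
        grm = compute_grm(geno_qc)
        mrm = compute_mrm(rel)
        pcs = genetic_pcs(grm, k=max(config.n_pcs_h2, config.n_pcs_gwas))
        mantel_r, mantel_p = mantel_test(
            grm, mrm, n_perm=config.mantel_permutations, seed=config.seed
        )
        rio.write_relationship_tsv(grm, out / "grm.tsv")
        rio.write_relationship_tsv(mrm, out / "mrm.tsv")
        rio.write_grm_gcta(grm, out / "grm_gcta")
        record("kinship", n_snps_after_qc=geno_qc.n_snps, mantel_r=mantel_r,
               mantel_p=mantel_p)
        results["kinship"] = {"grm": grm, "mrm": mrm, "pcs": pcs,
                              "mantel": (mantel_r, mantel_p)}

        # ----- varcomp
        X_h2 = build_design(covariates, pcs[:, : config.n_pcs_h2])
        scan = feature_h2_scan(feats, X_h2, grm, alpha=config.heritable_alpha)
        scan.to_csv(out / "feature_h2.tsv", sep="\t", index=False)
        fit_h2 = estimate_h2(y, X_h2, grm)
        fit_m2 = estimate_m2(y, X_h2, mrm)
        fit_joint = estimate_joint(y, X_h2, grm, mrm)
        null = reml_null(y, X_h2)
        weight_rows = [
            {"model": "1_grm", "h2": fit_h2.ratios.get("genetic"),
             "m2": None, "logL": fit_h2.logL,
             "lrt_p": lrt(fit_h2, null).p_value},
            {"model": "2_mrm", "h2": None,
             "m2": fit_m2.ratios.get("microbial"), "logL": fit_m2.logL,
             "lrt_p": lrt(fit_m2, null).p_value},
            {"model": "3_joint", "h2": fit_joint.ratios.get("genetic"),
             "m2": fit_joint.ratios.get("microbial"), "logL": fit_joint.logL,
             "lrt_p": None},
        ]
        pd.DataFrame(weight_rows).to_csv(out / "weight_varcomp.tsv", sep="\t",
                                         index=False)
        record("varcomp", n_features_scanned=len(scan),
               n_heritable=int(scan["heritable"].sum()) if len(scan) else 0,
               weight_h2=fit_h2.ratios.get("genetic"),
               weight_m2=fit_m2.ratios.get("microbial"),
               weight_joint_h2=fit_joint.ratios.get("genetic"),
               weight_joint_m2=fit_joint.ratios.get("microbial"))
        results["varcomp"] = {"scan": scan, "h2": fit_h2, "m2": fit_m2,
                              "joint": fit_joint}

        # ----- assoc
        tiers = {"suggestive": config.suggestive, "genome_wide": config.genome_wide}
        X_gwas = build_design(covariates, pcs[:, : config.n_pcs_gwas])
        gwas = mlm_gwas(y, X_gwas, grm, geno_qc, tiers=tiers)
        gwas.to_csv(out / "gwas_weight.tsv", sep="\t", index=False)
        scan_for_mb = scan
        if config.max_mbgwas_features:
            heritable = scan[scan["lrt_p"] < config.heritable_alpha]
            keep = heritable.nsmallest(config.max_mbgwas_features, "lrt_p")
            scan_for_mb = keep
        mb = mbgwas_scan(
            feats, scan_for_mb, X_gwas, grm, geno_qc,
            feature_prevalence=feats.prevalence,
            min_binary_prevalence=config.min_binary_prevalence, tiers=tiers,
        )
        mb["summary"].to_csv(out / "mbgwas_hits.tsv", sep="\t", index=False)
        y_adj = adjust_phenotype(y, covariates)
        mwas = mwas_two_part(
            y_adj, genus_table, pcs=pcs[:, : config.n_pcs_gwas],
            low=config.prevalence_low, split=config.prevalence_split,
            clr_pseudocount=config.clr_pseudocount, alpha=config.mwas_alpha,
        )
        mwas.to_csv(out / "mwas.tsv", sep="\t", index=False)
        record("assoc", n_gwas_hits=int((gwas["tier"] != "none").sum()),
               n_mbgwas_features=len(mb["per_feature"]),
               n_mbgwas_associations=len(mb["summary"]),
               n_mwas_significant=int(mwas["significant"].sum()) if len(mwas) else 0,
               study_wide_threshold=bonferroni(n_tests=geno_qc.n_snps))
        results["assoc"] = {"gwas": gwas, "mbgwas": mb, "mwas": mwas,
                            "y_adj": y_adj}

        # ----- recursive
        mb_by_genus = {
            g: df for g, df in mb["per_feature"].items()
        }
        table, summary = recursive_report(
            mwas, mb_by_genus, gwas, y, geno_qc, kw_alpha=config.kw_alpha,
            mwas_alpha=config.mwas_alpha,
        )
        table.to_csv(out / "recursive_scenarios.tsv", sep="\t", index=False)
        record("recursive", **summary)
        results["recursive"] = (table, summary)
    except Exception as exc:
        manifest["failed_stage"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
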