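"""Integration of GWAS, mbGWAS and MWAS into indirect/recursive scenarios.

A SNP is *indirect* when it associates (mbGWAS, at a chosen tier) with a
marker genus — a genus itself significantly associated with the phenotype by
the Bonferroni-corrected MWAS.  An indirect SNP becomes *recursive* when it
also shows a direct path to the phenotype: either it appears among the
phenotype GWAS hits (locus overlap, exact SNP identity) or the phenotype
differs across its genotype classes by a Kruskal-Wallis test at p < 0.01.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("rumenlink")

TIER_ORDER = {"study_wide": 0, "genome_wide": 1, "suggestive": 2, "none": 3}


def _hits_at_tier(gwas: pd.DataFrame, tier: str) -> pd.DataFrame:
    """Rows at the requested tier or any more stringent one."""
    rank = TIER_ORDER[tier]
    return gwas[gwas["tier"].map(TIER_ORDER).le(rank)]


def indirect_scenario(mwas: pd.DataFrame, mbgwas: dict,
                      tier: str = "suggestive", alpha: float = 0.05) -> dict:
    """Per-marker-genus indirect SNP sets.

    ``mwas`` is the two-part association table (with p_bonferroni);
    ``mbgwas`` maps genus -> its GWAS table.  Returns
    {genus: set of snp ids}; empty when no genus survives Bonferroni.
    """
    if len(mwas) == 0:
        return {}
    markers = mwas[mwas["p_bonferroni"] < alpha]["taxon"].tolist()
    out = {}
    for genus in markers:
        if genus not in mbgwas:
            logger.warning("marker genus %s has no mbGWAS table", genus)
            continue
        hits = _hits_at_tier(mbgwas[genus], tier)
        out[genus] = set(hits["snp_id"].tolist())
    return out


def overlap_loci(indirect_snps: dict, gwas: pd.DataFrame,
                 tier: str = "suggestive") -> set:
    """Exact-identity intersection of the indirect SNP union with the
    phenotype GWAS hit set at the given tier."""
    union = set().union(*indirect_snps.values()) if indirect_snps else set()
    gwas_hits = set(_hits_at_tier(gwas, tier)["snp_id"].tolist())
    return union & gwas_hits


def kruskal_wallis(y: np.ndarray, genotype: np.ndarray):
    """Tie-corrected Kruskal-Wallis H across genotype classes (0/1/2).

    Returns (H, p) with p from chi2 on (groups - 1) df.  Requires at least
    two genotype groups.
    """
    y = np.asarray(y, dtype=float)
    genotype = np.asarray(genotype)
    groups = [y[genotype == g] for g in np.unique(genotype)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 genotype groups")
    if np.ptp(y) == 0:
        return 0.0, 1.0  # identical observations: no signal by convention
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def recursive_report(mwas: pd.DataFrame, mbgwas: dict, gwas: pd.DataFrame,
                     y: np.ndarray, geno, tier: str = "suggestive",
                     kw_alpha: float = 0.01, mwas_alpha: float = 0.05):
    """Label every indirect SNP with its scenario(s).

    Returns (table, summary): the table has one row per (snp, genus) pair
    with the mbGWAS/GWAS/KW p-values and non-exclusive labels
    "recursive (overlap)", "recursive (KW)", "indirect only"; the summary is
    a JSON-serialisable dict of counts.
    """
    indirect = indirect_scenario(mwas, mbgwas, tier=tier, alpha=mwas_alpha)
    overlap = overlap_loci(indirect, gwas, tier=tier)
    snp_col = {s: i for i, s in enumerate(geno.snp_ids)}
    gwas_p = dict(zip(gwas["snp_id"], gwas["p_value"]))
    rows = []
    kw_cache = {}
    for genus, snps in indirect.items():
        mb = mbgwas[genus].set_index("snp_id")
        for snp in sorted(snps):
            if snp not in kw_cache:
                if snp in snp_col:
                    kw_cache[snp] = kruskal_wallis(y, geno.values[:, snp_col[snp]])[1]
                else:
                    kw_cache[snp] = np.nan
            kw_p = kw_cache[snp]
            labels = []
            if snp in overlap:
                labels.append("recursive (overlap)")
            if np.isfinite(kw_p) and kw_p < kw_alpha:
                labels.append("recursive (KW)")
            if not labels:
                labels.append("indirect only")
            rows.append(
                {
                    "snp_id": snp,
                    "genus": genus,
                    "mbgwas_p": float(mb.loc[snp, "p_value"]),
                    "gwas_p": float(gwas_p.get(snp, np.nan)),
                    "kw_p": kw_p,
                    "labels": ";".join(labels),
                }
            )
    table = pd.DataFrame(
        rows, columns=["snp_id", "genus", "mbgwas_p", "gwas_p", "kw_p", "labels"]
    )
    uniq = table.drop_duplicates("snp_id") if len(table) else table
    recursive_snps = set(
        uniq[uniq["labels"].str.contains("recursive")]["snp_id"]
    ) if len(uniq) else set()
    summary = {
        "n_marker_genera": len(indirect),
        "n_indirect_snps": int(uniq["snp_id"].nunique()) if len(uniq) else 0,
        "n_overlap_snps": len(overlap),
        "n_kw_recursive_snps": int(
            (uniq["kw_p"] < kw_alpha).sum()
        ) if len(uniq) else 0,
        "n_recursive_snps": len(recursive_snps),
    }
    return table, summary


def write_report(table: pd.DataFrame, summary: dict, tsv_path, json_path) -> None:
    table.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=1)
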