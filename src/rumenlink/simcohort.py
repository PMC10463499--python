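"""Synthetic genotype–microbiome–phenotype cohorts with known ground truth.

The generator emulates the data structure of a large single-farm ruminant
cohort: biallelic autosomal SNPs in Hardy–Weinberg proportions with MAF above
0.05, a few hundred genera with a long-tailed prevalence spectrum (a small
core at 100% prevalence, many rare genera), per-taxon additive genetic
control, and a weight phenotype combining categorical covariates, a polygenic
breeding value and a microbial value.

Model per taxon t:

    latent_t = sqrt(h2_t) * g_t + designed effects + noise
    abundance_t = exp(mu_t + latent_t), zeroed below a per-taxon quantile
                  chosen to hit the taxon's target prevalence

where ``g_t`` is a standardized sum of causal-SNP genotype scores.  The
exponential link with quantile zero-truncation is a stand-in for the unknown
generative distribution of real taxa: it yields zero-inflated, long-tailed
compositional abundances whose presence/absence pattern is exactly
controlled.

Phenotype:

    y = intercept + covariates + a + m + designed SNP effects + e

with Var(a)/Var(y - covariates) = pheno_h2 and Var(m)/... = pheno_m2 in
expectation; ``m`` is linear in z-scored taxon abundances so the microbial
relationship matrix built downstream spans it exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import AbundanceTable, ConfigurationError, GenotypeMatrix

logger = logging.getLogger("rumenlink")

N_AUTOSOMES = 26  # Ovis aries

_PHYLA = [
    ("Firmicutes", 0.50),
    ("Bacteroidota", 0.27),
    ("Proteobacteria", 0.08),
    ("Spirochaetota", 0.05),
    ("Fibrobacterota", 0.04),
    ("Actinobacteriota", 0.03),
    ("Verrucomicrobiota", 0.03),
]


@dataclass
class DesignedEffect:
    """A SNP given an explicit effect on a taxon and/or the phenotype.

    ``taxon_var`` is the fraction of the taxon's latent variance explained by
    the SNP; ``pheno_var`` the fraction of phenotypic (covariate-free)
    variance from a direct path.  A SNP with both is pleiotropic and is the
    designed truth for recursive-scenario detection.
    """

    snp_index: int
    taxon_index: int | None = None
    taxon_var: float = 0.0
    pheno_var: float = 0.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study's structure at full scale (1150 animals); the
    pipeline and tests pass smaller sizes explicitly.
    """

    n_individuals: int = 1150
    n_snps: int = 5000
    maf_range: tuple = (0.05, 0.5)
    n_taxa: int = 400
    taxon_h2: np.ndarray | None = None          # drawn if None
    prevalence_targets: np.ndarray | None = None  # drawn if None
    pheno_h2: float = 0.39
    pheno_m2: float = 0.20
    n_causal_snps_per_taxon: int = 10
    n_causal_snps_pheno: int = 500
    n_covariate_levels: tuple = (4, 2)          # birthplace, rearing season
    covariate_sd: float = 0.5                   # fixed-effect spread, in SD of y
    frac_unclassified: float = 0.05
    marker_taxa: dict = field(default_factory=dict)   # taxon index -> pheno var frac
    designed_effects: list = field(default_factory=list)
    link_scale: float = 1.0                     # SD of latent on the log scale
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.pheno_h2 < 1 and 0 <= self.pheno_m2 < 1):
            raise ConfigurationError("pheno_h2 and pheno_m2 must lie in [0, 1)")
        if self.pheno_h2 + self.pheno_m2 >= 1:
            raise ConfigurationError("pheno_h2 + pheno_m2 must be < 1")
        for name in ("n_individuals", "n_snps", "n_taxa",
                     "n_causal_snps_per_taxon", "n_causal_snps_pheno"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.taxon_h2 is not None:
            self.taxon_h2 = np.asarray(self.taxon_h2, dtype=float)
            if len(self.taxon_h2) != self.n_taxa:
                raise ConfigurationError("taxon_h2 length must equal n_taxa")
            if ((self.taxon_h2 < 0) | (self.taxon_h2 >= 1)).any():
                raise ConfigurationError("taxon_h2 must lie in [0, 1)")
        if self.prevalence_targets is not None:
            self.prevalence_targets = np.asarray(self.prevalence_targets, dtype=float)
            if len(self.prevalence_targets) != self.n_taxa:
                raise ConfigurationError("prevalence_targets length must equal n_taxa")
            if ((self.prevalence_targets <= 0) | (self.prevalence_targets > 1)).any():
                raise ConfigurationError("prevalence_targets must lie in (0, 1]")

# stable per-stage keys for child seed streams
_STAGE_KEYS = {
    "genotypes": 11,
    "microbiota": 23,
    "phenotype": 37,
    "counts": 41,
}


def _stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STAGE_KEYS[stage]])


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for downstream validation."""

    true_h2_per_taxon: np.ndarray = None
    realized_h2_per_taxon: np.ndarray = None
    causal_snp_ids: dict = field(default_factory=dict)  # taxon id / "phenotype" -> ids
    true_pheno_h2: float = 0.0
    true_pheno_m2: float = 0.0
    breeding_values: np.ndarray = None
    microbial_values: np.ndarray = None
    covariate_effects: dict = field(default_factory=dict)
    designed_effects: list = field(default_factory=list)
    marker_taxa: dict = field(default_factory=dict)

    def realized_pheno_fractions(self, y_resid_var: float | None = None) -> dict:
        va = float(np.var(self.breeding_values))
        vm = float(np.var(self.microbial_values))
        return {"var_breeding": va, "var_microbial": vm}

    def to_json(self, path) -> None:
        def _clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return float(x)
            if isinstance(x, dict):
                return {str(k): _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            return x
        with open(path, "w") as fh:
            json.dump({k: _clean(v) for k, v in asdict(self).items()}, fh, indent=1)


# --------------------------------------------------------------- genotypes

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw HWE genotypes: per SNP, allele freq ~ U(maf_range), g = Bin(2, p).

    Markers are spread cyclically over the autosomes with increasing
    positions; no linkage disequilibrium is simulated.
    """
    if config.n_individuals < 1 or config.n_snps < 1:
        raise ConfigurationError("need at least 1 individual and 1 SNP")
    rng = _stage_rng(config, "genotypes")
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    values = rng.binomial(2, p, size=(config.n_individuals, config.n_snps))
    chrom = np.array([str(1 + j % N_AUTOSOMES) for j in range(config.n_snps)])
    pos = np.array([1000 + 100 * (j // N_AUTOSOMES) for j in range(config.n_snps)])
    return GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(config.n_individuals)],
        snp_ids=[f"snp{j}" for j in range(config.n_snps)],
        chrom=chrom,
        pos=pos,
        values=values.astype(np.int16),
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _snp_scores(geno: GenotypeMatrix, idx: np.ndarray, rng) -> np.ndarray:
    """Standardized polygenic score over the given SNPs with random-sign
    effects of equal per-SNP variance contribution."""
    p = geno.allele_freq()[idx]
    x = geno.values[:, idx].astype(float)
    w = (x - 2 * p) / np.sqrt(np.maximum(2 * p * (1 - p), 1e-12))
    beta = rng.choice([-1.0, 1.0], size=len(idx))
    return _standardize(w @ beta)


def default_taxon_h2(n_taxa: int, rng) -> np.ndarray:
    """Mixture matching the study's spectrum: roughly 40% of taxa heritable,
    with h2 spread over 0.05–0.7, the rest purely environmental."""
    h2 = np.where(rng.random(n_taxa) < 0.6, 0.0, rng.uniform(0.05, 0.7, n_taxa))
    return h2


def default_prevalence_targets(n_taxa: int, rng) -> np.ndarray:
    """Long-tailed prevalence spectrum: a small 100%-prevalence core, a
    high-prevalence block, and a long tail of rare genera."""
    u = rng.random(n_taxa)
    prev = np.empty(n_taxa)
    prev[u < 0.04] = 1.0
    m = (u >= 0.04) & (u < 0.20)
    prev[m] = rng.uniform(0.6, 1.0, m.sum())
    m = (u >= 0.20) & (u < 0.50)
    prev[m] = rng.uniform(0.1, 0.6, m.sum())
    m = (u >= 0.50) & (u < 0.78)
    prev[m] = rng.uniform(0.015, 0.1, m.sum())
    m = u >= 0.78
    prev[m] = rng.uniform(0.003, 0.015, m.sum())
    return prev


# --------------------------------------------------------------- microbiota

def simulate_microbiota(geno: GenotypeMatrix, config: SimConfig):
    """Generate a relative-abundance table plus its TruthSet.

    Returns ``(AbundanceTable(kind="relative"), TruthSet)``.
    """
    rng = _stage_rng(config, "microbiota")
    n, t = geno.n_samples, config.n_taxa
    h2 = config.taxon_h2
    if h2 is None:
        h2 = default_taxon_h2(t, rng)
    prev = config.prevalence_targets
    if prev is None:
        prev = default_prevalence_targets(t, rng)

    designed_by_taxon: dict[int, list[DesignedEffect]] = {}
    for eff in config.designed_effects:
        if eff.taxon_index is not None and eff.taxon_var > 0:
            designed_by_taxon.setdefault(eff.taxon_index, []).append(eff)

    taxon_ids = [f"g{k}" for k in range(t)]
    n_causal = min(config.n_causal_snps_per_taxon, geno.n_snps)
    latents = np.empty((n, t))
    realized = np.empty(t)
    causal_ids: dict[str, list] = {}
    for k in range(t):
        designed = designed_by_taxon.get(k, [])
        v_designed = sum(e.taxon_var for e in designed)
        if h2[k] + v_designed >= 1:
            raise ConfigurationError(
                f"taxon {k}: h2 + designed variance must be < 1"
            )
        parts = np.zeros(n)
        ids = []
        if h2[k] > 0:
            idx = rng.choice(geno.n_snps, size=n_causal, replace=False)
            ids = [geno.snp_ids[j] for j in idx]
            parts = parts + np.sqrt(h2[k]) * _snp_scores(geno, idx, rng)
        for e in designed:
            s = _standardize(geno.values[:, e.snp_index].astype(float))
            parts = parts + np.sqrt(e.taxon_var) * s
            ids.append(geno.snp_ids[e.snp_index])
        noise = rng.standard_normal(n)
        lat = parts + np.sqrt(max(1 - h2[k] - v_designed, 0)) * noise
        latents[:, k] = lat
        vg = np.var(parts)
        realized[k] = vg / np.var(lat) if np.var(lat) > 0 else 0.0
        causal_ids[taxon_ids[k]] = ids

    # long-tailed baseline abundance, correlated with prevalence (core taxa
    # tend to be abundant), then the exponential link
    mu = 2.5 * prev + rng.normal(0, 1.5, size=t)
    raw = np.exp(mu + config.link_scale * latents)

    # zero-truncate below the per-taxon quantile implied by target prevalence
    for k in range(t):
        if prev[k] >= 1.0:
            continue
        thresh = np.quantile(raw[:, k], 1 - prev[k])
        raw[raw[:, k] < thresh, k] = 0.0

    totals = raw.sum(axis=1, keepdims=True)
    rel = raw / np.maximum(totals, 1e-300)

    # marker/designed taxa are known genera by construction: never unclassified
    protected = set(config.marker_taxa) | {
        e.taxon_index for e in config.designed_effects if e.taxon_index is not None
    }
    eligible = np.array([k for k in range(t) if k not in protected])
    n_uncls = min(int(round(config.frac_unclassified * t)), eligible.size)
    uncls = set(rng.choice(eligible, size=n_uncls, replace=False).tolist()) if n_uncls else set()
    phyla_names = [p for p, _ in _PHYLA]
    phyla_probs = np.array([w for _, w in _PHYLA])
    phyla_probs = phyla_probs / phyla_probs.sum()
    phylum = list(rng.choice(phyla_names, size=t, p=phyla_probs))
    genus = [
        f"unclassified_g{k}" if k in uncls else f"Genus_{k}" for k in range(t)
    ]
    is_classified = np.array([k not in uncls for k in range(t)])

    table = AbundanceTable(
        sample_ids=list(geno.sample_ids),
        taxon_ids=taxon_ids,
        values=rel,
        kind="relative",
        phylum=phylum,
        genus=genus,
        is_classified=is_classified,
    )
    truth = TruthSet(
        true_h2_per_taxon=h2,
        realized_h2_per_taxon=realized,
        causal_snp_ids=causal_ids,
        designed_effects=list(config.designed_effects),
        marker_taxa=dict(config.marker_taxa),
    )
    return table, truth


def to_counts(table: AbundanceTable, mean_depth: int = 35000,
              depth_cv: float = 0.1, seed: int = 0) -> AbundanceTable:
    """Multinomial read-count realisation of a relative table.

    Emulates sequencing at ~constant library size; sampling re-introduces
    zeros for very rare taxa, as in real count data.
    """
    rng = np.random.default_rng([seed, _STAGE_KEYS["counts"]])
    depths = np.maximum(
        rng.normal(mean_depth, depth_cv * mean_depth, size=table.n_samples), 1
    ).astype(int)
    counts = np.empty_like(table.values)
    for i in range(table.n_samples):
        p = table.values[i]
        s = p.sum()
        if s <= 0:
            counts[i] = 0
            continue
        counts[i] = rng.multinomial(depths[i], p / s)
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        values=counts,
        kind="counts",
        phylum=table.phylum,
        genus=table.genus,
        is_classified=table.is_classified,
    )


# --------------------------------------------------------------- phenotype

def simulate_phenotype(geno: GenotypeMatrix, micro: AbundanceTable,
                       config: SimConfig, truth: TruthSet | None = None):
    """Simulate the weight phenotype and categorical covariates.

    Returns ``(y, covariates DataFrame, TruthSet)``; if a TruthSet from
    :func:`simulate_microbiota` is passed it is extended in place.
    """
    import pandas as pd

    if list(geno.sample_ids) != list(micro.sample_ids):
        from .containers import AlignmentError

        raise AlignmentError("genotype and abundance tables have different samples")
    rng = _stage_rng(config, "phenotype")
    n = geno.n_samples
    truth = truth or TruthSet()

    # categorical covariates with evenly spaced fixed offsets of +-covariate_sd
    cov = {}
    cov_eff = {}
    for name, levels in zip(("birthplace", "season"), config.n_covariate_levels):
        lv = rng.integers(0, levels, size=n)
        offsets = (
            np.linspace(-config.covariate_sd, config.covariate_sd, levels)
            if levels > 1
            else np.zeros(1)
        )
        cov[name] = lv
        cov_eff[name] = offsets
    covariates = pd.DataFrame(cov, index=list(geno.sample_ids))
    fixed = sum(cov_eff[name][cov[name]] for name in cov)

    # breeding value
    h2, m2 = config.pheno_h2, config.pheno_m2
    v_direct = sum(e.pheno_var for e in config.designed_effects)
    if h2 + m2 + v_direct >= 1:
        raise ConfigurationError("pheno_h2 + pheno_m2 + designed variance must be < 1")
    a = np.zeros(n)
    if h2 > 0:
        n_causal = min(config.n_causal_snps_pheno, geno.n_snps)
        idx = rng.choice(geno.n_snps, size=n_causal, replace=False)
        a = np.sqrt(h2) * _snp_scores(geno, idx, rng)
        truth.causal_snp_ids["phenotype"] = [geno.snp_ids[j] for j in idx]

    # microbial value: explicit marker taxa plus a diffuse background over the
    # remaining z-scored taxa
    m = np.zeros(n)
    v_markers = float(sum(config.marker_taxa.values()))
    if v_markers >= m2 + 1e-12 and m2 > 0:
        raise ConfigurationError("marker taxa variance exceeds pheno_m2")
    sd = micro.values.std(axis=0, ddof=1)
    nonconst = sd > 0
    Z = np.zeros_like(micro.values)
    Z[:, nonconst] = (
        micro.values[:, nonconst] - micro.values[:, nonconst].mean(axis=0)
    ) / sd[nonconst]
    if m2 > 0:
        for k, v in config.marker_taxa.items():
            m = m + np.sqrt(v) * _standardize(Z[:, k])
        v_bg = m2 - v_markers
        if v_bg > 0:
            bg_idx = np.array(
                [k for k in range(micro.n_taxa) if nonconst[k] and k not in config.marker_taxa]
            )
            w = rng.standard_normal(len(bg_idx))
            m = m + np.sqrt(v_bg) * _standardize(Z[:, bg_idx] @ w)

    direct = np.zeros(n)
    for e in config.designed_effects:
        if e.pheno_var > 0:
            s = _standardize(geno.values[:, e.snp_index].astype(float))
            direct = direct + np.sqrt(e.pheno_var) * s

    e_var = 1 - h2 - m2 - v_direct
    resid = np.sqrt(e_var) * rng.standard_normal(n)
    y = 45.0 + fixed + a + m + direct + resid

    truth.true_pheno_h2 = h2
    truth.true_pheno_m2 = m2
    truth.breeding_values = a
    truth.microbial_values = m
    truth.covariate_effects = {k: v.tolist() for k, v in cov_eff.items()}
    truth.marker_taxa = dict(config.marker_taxa)
    truth.designed_effects = list(config.designed_effects)
    return y, covariates, truth


def recursive_design_config(seed: int, n_individuals: int = 800,
                            n_snps: int = 2000, n_taxa: int = 150) -> SimConfig:
    """Cohort design with a known recursive architecture.

    Two full-prevalence marker genera each drive 5% of phenotypic variance.
    One SNP is pleiotropic (10% of marker-genus-1 latent variance plus a 5%
    direct phenotype effect — the designed recursive locus); a second SNP
    affects only marker genus 2 (8% of its latent variance — the designed
    indirect-only locus).
    """
    cfg = SimConfig(
        n_individuals=n_individuals, n_snps=n_snps, n_taxa=n_taxa,
        pheno_h2=0.35, pheno_m2=0.20, seed=seed,
        marker_taxa={0: 0.05, 1: 0.05},
        designed_effects=[
            DesignedEffect(snp_index=min(100, n_snps - 1), taxon_index=0,
                           taxon_var=0.10, pheno_var=0.05),
            DesignedEffect(snp_index=min(200, n_snps - 1), taxon_index=1,
                           taxon_var=0.08, pheno_var=0.0),
        ],
    )
    prev = default_prevalence_targets(n_taxa, _stage_rng(cfg, "microbiota"))
    prev[0] = prev[1] = 1.0
    cfg.prevalence_targets = prev
    return cfg


def simulate_cohort(config: SimConfig) -> dict:
    """Convenience wrapper running all three stages; returns a dict with keys
    ``genotypes``, ``abundance``, ``y``, ``covariates``, ``truth``."""
    geno = simulate_genotypes(config)
    micro, truth = simulate_microbiota(geno, config)
    y, covariates, truth = simulate_phenotype(geno, micro, config, truth)
    return {
        "genotypes": geno,
        "abundance": micro,
        "y": y,
        "covariates": covariates,
        "truth": truth,
    }
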