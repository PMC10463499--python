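"""Association engine: EMMAX GWAS against dense-GLS and OLS oracles,
significance tiers, phenotype adjustment, the two-part MWAS and Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rumenlink as rl
from rumenlink.containers import GenotypeMatrix, RelationshipMatrix
from rumenlink.varcomp import VarCompResult


def make_geno(values):
    values = np.asarray(values)
    n, p = values.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        snp_ids=[f"snp{j}" for j in range(p)],
        chrom=["1"] * p,
        pos=np.arange(p),
        values=values,
    )


def _fixed_null(n, s2a, s2e):
    return VarCompResult(
        sigma2={"genetic": s2a, "residual": s2e}, se={}, ratios={},
        ratio_se={}, logL=0.0, converged=True, n_iter=0, n=n,
    )


# ---------------------------------------------------------------- GWAS core

def test_gwas_reduces_to_ols_when_no_genetic_variance():
    rng = np.random.default_rng(0)
    n, p = 60, 8
    geno = make_geno(rng.binomial(2, 0.3, size=(n, p)))
    G = RelationshipMatrix(sample_ids=geno.sample_ids,
                           values=np.cov(rng.standard_normal((n, 2 * n))))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = rng.standard_normal(n)
    res = rl.mlm_gwas(y, X, G, geno, null_fit=_fixed_null(n, 0.0, 1.0))

    # OLS oracle with a Gaussian (chi2_1) reference
    for j in range(p):
        Xj = np.column_stack([X, geno.values[:, j].astype(float)])
        beta = np.linalg.solve(Xj.T @ Xj, Xj.T @ y)
        r = y - Xj @ beta
        s2 = (r @ r) / (n - Xj.shape[1])
        cov = s2 * np.linalg.inv(Xj.T @ Xj)
        z2 = beta[-1] ** 2 / cov[-1, -1]
        p_ols = stats.chi2.sf(z2, df=1)
        assert res["p_value"][j] == pytest.approx(p_ols, abs=1e-8)
        assert res["beta"][j] == pytest.approx(beta[-1], abs=1e-8)


def test_gwas_matches_dense_gls_oracle():
    rng = np.random.default_rng(5)
    n, p = 50, 5
    geno = make_geno(rng.binomial(2, 0.4, size=(n, p)))
    z = rng.standard_normal((n, 100))
    G = RelationshipMatrix(sample_ids=geno.sample_ids, values=z @ z.T / 100)
    X = np.ones((n, 1))
    y = rng.standard_normal(n)
    s2a, s2e = 0.6, 0.9
    res = rl.mlm_gwas(y, X, G, geno, null_fit=_fixed_null(n, s2a, s2e))

    V = s2a * G.values + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    for j in range(p):
        Xj = np.column_stack([X, geno.values[:, j].astype(float)])
        XtViX = Xj.T @ Vi @ Xj
        beta = np.linalg.solve(XtViX, Xj.T @ Vi @ y)
        r = y - Xj @ beta
        s2 = (r @ Vi @ r) / (n - Xj.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(XtViX)[-1, -1])
        assert res["beta"][j] == pytest.approx(beta[-1], abs=1e-8)
        assert res["se"][j] == pytest.approx(se, abs=1e-8)


def test_gwas_pvalues_invariant_to_affine_phenotype_rescaling():
    rng = np.random.default_rng(2)
    n, p = 40, 6
    geno = make_geno(rng.binomial(2, 0.3, size=(n, p)))
    z = rng.standard_normal((n, 80))
    G = RelationshipMatrix(sample_ids=geno.sample_ids, values=z @ z.T / 80)
    X = np.ones((n, 1))
    y = rng.standard_normal(n)
    nf = _fixed_null(n, 0.3, 0.7)
    nf2 = _fixed_null(n, 0.3 * 4, 0.7 * 4)  # variance scales with y^2
    p1 = rl.mlm_gwas(y, X, G, geno, null_fit=nf)["p_value"]
    p2 = rl.mlm_gwas(2 * y + 5, X, G, geno, null_fit=nf2)["p_value"]
    assert np.allclose(p1, p2, atol=1e-10)


def test_gwas_monomorphic_snp_gets_missing_p():
    rng = np.random.default_rng(3)
    vals = rng.binomial(2, 0.4, size=(30, 3))
    vals[:, 1] = 0
    geno = make_geno(vals)
    z = rng.standard_normal((30, 60))
    G = RelationshipMatrix(sample_ids=geno.sample_ids, values=z @ z.T / 60)
    res = rl.mlm_gwas(rng.standard_normal(30), np.ones((30, 1)), G, geno)
    assert np.isnan(res["p_value"][1])
    assert np.isfinite(res["p_value"][[0, 2]]).all()


# -------------------------------------------------------------------- tiers

def test_tier_assignment_is_nested():
    n_snps = 10**9  # study-wide 5e-11 < genome-wide < suggestive
    p = np.array([1e-12, 5e-9, 5e-7, 1e-3, np.nan])
    tiers = rl.assign_tiers(p, n_snps=n_snps)
    assert tiers == ["study_wide", "genome_wide", "suggestive", "none", "none"]


def test_bonferroni_threshold_and_adjustment():
    # the study-wide threshold printed for 23,112,008 autosomal SNPs
    th = rl.bonferroni(n_tests=23_112_008)
    assert f"{th:.6e}" == "2.163378e-09"
    assert rl.bonferroni(n_tests=1) == 0.05
    assert rl.bonferroni([0.4], n_tests=3)[0] == 1.0
    with pytest.raises(ValueError):
        rl.bonferroni(n_tests=0)


# --------------------------------------------------------------- adjustment

def test_adjust_phenotype_orthogonal_to_covariates():
    rng = np.random.default_rng(11)
    n = 120
    cov = pd.DataFrame({"birthplace": rng.integers(0, 4, n),
                        "season": rng.integers(0, 2, n)})
    y = rng.standard_normal(n) + cov["birthplace"].to_numpy() * 0.5
    adj = rl.adjust_phenotype(y, cov)
    d = pd.get_dummies(cov.astype("category")).to_numpy(dtype=float)
    assert np.allclose(d.T @ adj, 0.0, atol=1e-10)
    assert adj.mean() == pytest.approx(0.0, abs=1e-10)


def test_adjust_phenotype_two_group_closed_form():
    cov = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1]})
    y = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    adj = rl.adjust_phenotype(y, cov)
    assert np.allclose(adj, [-1, 0, 1, -1, 0, 1], atol=1e-10)


# --------------------------------------------------------------------- MWAS

def test_mwas_binary_coding_and_partition(small_cohort):
    tab = rl.filter_genera(small_cohort["abundance"])
    y_adj = rl.adjust_phenotype(small_cohort["y"], small_cohort["covariates"])
    res = rl.mwas_two_part(y_adj, tab)
    prev = pd.Series(tab.prevalence(), index=tab.taxon_ids)
    for _, row in res.iterrows():
        if row["part"] == "binary":
            assert 0.015 <= prev[row["taxon"]] < 0.60
        else:
            assert prev[row["taxon"]] >= 0.60
    assert res["taxon"].is_unique


def test_mwas_presence_coding_rule():
    from tests.conftest import toy_abundance

    # abundance (0, 0.2, 0, 0.5) must be coded (0, 1, 0, 1): with prevalence
    # 0.5 the taxon sits in the binary part and its slope equals the OLS
    # slope on that indicator
    vals = np.array([[0.0, 1.0], [0.2, 0.8], [0.0, 1.0], [0.5, 0.5]])
    tab = toy_abundance(vals, kind="relative")
    y = np.array([1.0, 3.0, 2.0, 4.0])
    res = rl.mwas_two_part(y - y.mean(), tab, low=0.0).set_index("taxon")
    b = np.array([0, 1, 0, 1], dtype=float)
    slope = np.cov(b, y - y.mean(), ddof=1)[0, 1] / np.var(b, ddof=1)
    assert res.loc["t0", "part"] == "binary"
    assert res.loc["t0", "beta"] == pytest.approx(slope, abs=1e-10)


def test_mwas_matches_textbook_simple_regression():
    from tests.conftest import toy_abundance

    x = np.array([0.30, 0.15, 0.45, 0.20, 0.25, 0.40])
    tab = toy_abundance(np.column_stack([x, 1 - x]), kind="relative")
    y = np.array([2.1, 1.4, 3.3, 1.6, 2.0, 2.9])
    res = rl.mwas_two_part(y, tab).set_index("taxon")
    # quantitative part regresses on the CLR value of the taxon
    clr = rl.clr_transform(np.column_stack([x, 1 - x]), pseudocount=1e-6)[:, 0]
    n = 6
    sxx = ((clr - clr.mean()) ** 2).sum()
    beta = ((clr - clr.mean()) * (y - y.mean())).sum() / sxx
    resid = y - y.mean() - beta * (clr - clr.mean())
    s2 = (resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = beta / se
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    assert res.loc["t0", "beta"] == pytest.approx(beta, abs=1e-10)
    assert res.loc["t0", "se"] == pytest.approx(se, abs=1e-10)
    assert res.loc["t0", "p_value"] == pytest.approx(p, abs=1e-10)


def test_mwas_power_for_strong_genus():
    """A genus driving ~10% of phenotypic variance is Bonferroni-significant
    in nearly every replicate at n = 800."""
    hits = 0
    reps = 20
    for seed in range(reps):
        cfg = rl.SimConfig(n_individuals=800, n_snps=50, n_taxa=60,
                           pheno_h2=0.0, pheno_m2=0.10, seed=seed,
                           marker_taxa={0: 0.10})
        prev = rl.simcohort.default_prevalence_targets(
            60, np.random.default_rng(seed))
        prev[0] = 1.0
        cfg.prevalence_targets = prev
        c = rl.simulate_cohort(cfg)
        tab = rl.filter_genera(c["abundance"])
        y_adj = rl.adjust_phenotype(c["y"], c["covariates"])
        res = rl.mwas_two_part(y_adj, tab).set_index("taxon")
        if "g0" in res.index and res.loc["g0", "p_bonferroni"] < 0.05:
            hits += 1
    assert hits / reps >= 0.9


# ------------------------------------------------------------- mbGWAS scan

def test_mbgwas_eligibility_rules(small_cohort, small_kinship):
    feats = rl.build_feature_set(rl.filter_genera(small_cohort["abundance"]))
    scan = pd.DataFrame(
        {
            "feature": ["a", "b", "c"],
            "class": ["quantitative", "binary", "binary"],
            "lrt_p": [0.2, 0.01, 0.01],
        }
    )
    prev = pd.Series({"a": 0.9, "b": 0.25, "c": 0.5})

    class TinyFeatures:
        prevalence = prev

        def trait_columns(self):
            rng = np.random.default_rng(0)
            n = small_kinship["grm"].n_samples
            for name in ["a", "b", "c"]:
                yield name, "binary", rng.binomial(1, 0.5, n).astype(float)

    out = rl.mbgwas_scan(TinyFeatures(), scan, np.ones((300, 1)),
                         small_kinship["grm"], small_kinship["geno"].take_snps(range(20)))
    # "a" fails the heritability gate, "b" fails the 30% prevalence gate
    assert set(out["per_feature"]) == {"c"}


def test_mbgwas_finds_large_effect_causal_snp():
    """A SNP explaining ~5% of a taxon's latent variance is the top mbGWAS
    hit in most replicates."""
    top_hits = 0
    reps = 10
    for seed in range(reps):
        cfg = rl.SimConfig(
            n_individuals=800, n_snps=400, n_taxa=40, seed=seed,
            designed_effects=[rl.DesignedEffect(snp_index=7, taxon_index=0,
                                                taxon_var=0.05)],
        )
        h2 = np.zeros(40)
        prev = np.ones(40)
        cfg.taxon_h2, cfg.prevalence_targets = h2, prev
        geno = rl.simulate_genotypes(cfg)
        micro, _ = rl.simulate_microbiota(geno, cfg)
        grm = rl.compute_grm(geno)
        clr = rl.clr_transform(micro)
        res = rl.mlm_gwas(clr[:, 0], np.ones((800, 1)), grm, geno)
        if res.loc[res["p_value"].idxmin(), "snp_id"] == "snp7":
            top_hits += 1
    assert top_hits / reps >= 0.8
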