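"""Mixed-linear-model GWAS and the two-part microbiota-wide association.

GWAS uses the EMMAX approximation: variance components are estimated once
under the null model y = Xb + a + e (REML against the GRM), then each SNP is
tested by generalised least squares under the fixed covariance
V = sigma2_a G + sigma2_e I, computed efficiently on the eigenbasis of G.
The per-SNP Wald statistic uses a Gaussian reference with the residual scale
re-estimated per SNP, so in the sigma2_a -> 0 limit the test reduces exactly
to ordinary least squares.

Significance tiers follow the printed thresholds: suggestive 1e-6,
genome-wide 1e-8, and the study-wide Bonferroni bound 0.05 / N_SNPs.

The MWAS is a two-part model on the covariate-adjusted phenotype: genera
below 60% prevalence enter as presence/absence indicators (binary part),
genera at or above 60% as CLR-transformed abundances (quantitative part),
each with the top genetic PCs as covariates and a Bonferroni correction over
all genera tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, GenotypeMatrix, RelationshipMatrix
from .features import clr_transform
from .varcomp import estimate_h2

logger = logging.getLogger("rumenlink")

DEFAULT_TIERS = {"suggestive": 1e-6, "genome_wide": 1e-8}


# --------------------------------------------------------------- Bonferroni

def bonferroni(p_values=None, n_tests: int | None = None, alpha: float = 0.05):
    """Bonferroni threshold (when p_values is None) or adjusted p-values.

    Threshold mode returns alpha / n_tests; adjustment mode returns
    min(1, p * n), with n defaulting to the number of p-values given.
    """
    if p_values is None:
        if n_tests is None or n_tests <= 0:
            raise ValueError("n_tests must be a positive integer")
        return alpha / n_tests
    p = np.asarray(p_values, dtype=float)
    n = n_tests if n_tests is not None else p.size
    if n <= 0:
        raise ValueError("n_tests must be a positive integer")
    return np.minimum(1.0, p * n)


def assign_tiers(p: np.ndarray, n_snps: int, alpha: float = 0.05,
                 tiers: dict | None = None) -> list:
    """Label each p-value with the most stringent tier it passes."""
    thresholds = dict(tiers or DEFAULT_TIERS)
    thresholds["study_wide"] = bonferroni(n_tests=n_snps, alpha=alpha)
    ordered = sorted(thresholds.items(), key=lambda kv: kv[1])
    out = []
    for pv in p:
        label = "none"
        if np.isfinite(pv):
            for name, th in ordered:
                if pv < th:
                    label = name
                    break
        out.append(label)
    return out


# --------------------------------------------------------------------- GWAS

def mlm_gwas(y: np.ndarray, X: np.ndarray, G: RelationshipMatrix,
             geno: GenotypeMatrix, tiers: dict | None = None,
             alpha: float = 0.05, null_fit=None) -> pd.DataFrame:
    """EMMAX-style single-trait GWAS.

    Returns a DataFrame with snp_id, chromosome, position, beta, se, p_value
    and tier.  Monomorphic SNPs get missing statistics and are logged.
    """
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("phenotype is constant")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    G_vals = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, float)
    if null_fit is None:
        null_fit = estimate_h2(y, X, G_vals, method="eigen")
    s2a = null_fit.sigma2.get("genetic", 0.0)
    s2e = null_fit.sigma2["residual"]

    evals, evecs = np.linalg.eigh(G_vals)
    w = np.maximum(s2a * evals + s2e, 1e-12)
    sw = np.sqrt(w)
    yt = (evecs.T @ y) / sw
    Xt = (evecs.T @ X) / sw[:, None]
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)

    Gt = (evecs.T @ geno.imputed()) / sw[:, None]
    Rg = Gt - Q @ (Q.T @ Gt)
    gg = (Rg**2).sum(axis=0)
    mono = geno.maf() <= 0
    if mono.any():
        logger.warning("mlm_gwas: %d monomorphic SNP(s) skipped", int(mono.sum()))
    ok = (~mono) & (gg > 1e-12)
    n, q = len(y), X.shape[1] + 1
    beta = np.full(geno.n_snps, np.nan)
    se = np.full(geno.n_snps, np.nan)
    p = np.full(geno.n_snps, np.nan)
    beta[ok] = (Rg[:, ok].T @ ry) / gg[ok]
    rss = (ry @ ry) - beta[ok] ** 2 * gg[ok]
    s2 = np.maximum(rss, 0.0) / (n - q)
    se[ok] = np.sqrt(s2 / gg[ok])
    z2 = (beta[ok] / se[ok]) ** 2
    p[ok] = stats.chi2.sf(z2, df=1)
    return pd.DataFrame(
        {
            "snp_id": geno.snp_ids,
            "chromosome": geno.chrom,
            "position": geno.pos,
            "beta": beta,
            "se": se,
            "p_value": p,
            "tier": assign_tiers(p, n_snps=geno.n_snps, alpha=alpha, tiers=tiers),
        }
    )


def genomic_inflation(p_values) -> float:
    """Genomic-control lambda: median association chi2 over its null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def mbgwas_scan(features, h2_scan: pd.DataFrame, X, G, geno,
                feature_prevalence: pd.Series | None = None,
                min_binary_prevalence: float = 0.30,
                heritable_alpha: float = 0.05, tiers: dict | None = None,
                alpha: float = 0.05) -> dict:
    """mbGWAS over the heritable feature subset.

    Eligibility: LRT p < heritable_alpha; binary genera additionally require
    prevalence >= min_binary_prevalence.  Returns a dict with per-feature
    GWAS tables, a long summary of tiered hits, and the SNPs associated with
    two or more features at the suggestive tier or better.
    """
    heritable = h2_scan[h2_scan["lrt_p"] < heritable_alpha]
    prev = feature_prevalence if feature_prevalence is not None else getattr(
        features, "prevalence", pd.Series(dtype=float)
    )
    results = {}
    null_cache = {}
    for _, row in heritable.iterrows():
        name, cls = row["feature"], row["class"]
        if cls == "binary":
            pr = float(prev.get(name, np.nan))
            if not np.isfinite(pr) or pr < min_binary_prevalence:
                continue
        vec = None
        for fname, fcls, fvec in features.trait_columns():
            if fname == name:
                vec = fvec
                break
        if vec is None:
            continue
        results[name] = mlm_gwas(vec, X, G, geno, tiers=tiers, alpha=alpha)
    hits = []
    for name, df in results.items():
        sig = df[df["tier"] != "none"]
        for _, r in sig.iterrows():
            hits.append({"feature": name, "snp_id": r["snp_id"],
                         "p_value": r["p_value"], "tier": r["tier"]})
    summary = pd.DataFrame(hits, columns=["feature", "snp_id", "p_value", "tier"])
    multi = (
        summary.groupby("snp_id")["feature"].nunique()
        if len(summary)
        else pd.Series(dtype=int)
    )
    return {
        "per_feature": results,
        "summary": summary,
        "shared_snps": sorted(multi[multi >= 2].index.tolist()),
    }


# --------------------------------------------------------------------- MWAS

def adjust_phenotype(y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y regressed on the categorical covariates (+ intercept)."""
    y = np.asarray(y, dtype=float)
    blocks = [np.ones(len(y))]
    for col in covariates.columns:
        counts = covariates[col].value_counts()
        if (counts == 1).any():
            logger.warning("covariate %s has level(s) with a single observation", col)
        d = pd.get_dummies(covariates[col].astype("category"), drop_first=True)
        if d.shape[1]:
            blocks.append(d.to_numpy(dtype=float))
    X = np.column_stack(blocks)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _ols_t(y: np.ndarray, x: np.ndarray, covars: np.ndarray | None):
    """Simple OLS of y on [1, x, covars]; t test on x with residual df."""
    n = len(y)
    cols = [np.ones(n), x]
    if covars is not None and covars.size:
        cols.append(covars)
    X = np.column_stack(cols)
    q = X.shape[1]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - q)
    cov = s2 * np.linalg.inv(XtX)
    b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    t = b / se if se > 0 else np.nan
    p = 2.0 * float(stats.t.sf(abs(t), df=n - q)) if np.isfinite(t) else np.nan
    return b, se, p


def mwas_two_part(y_adj: np.ndarray, table: AbundanceTable,
                  pcs: np.ndarray | None = None, low: float = 0.015,
                  split: float = 0.60, clr_pseudocount: float = 1e-6,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Two-part genus-phenotype association.

    Genera with prevalence in [low, split) are tested through their presence
    indicator (beta1); genera with prevalence >= split through their CLR
    abundance (beta2).  Bonferroni correction is over all genera tested.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    prev = table.prevalence()
    clr = clr_transform(table, pseudocount=clr_pseudocount)
    covars = None
    if pcs is not None:
        covars = np.atleast_2d(np.asarray(pcs, dtype=float))
        if covars.shape[0] != len(y_adj):
            covars = covars.T
    rows = []
    for k, taxon in enumerate(table.taxon_ids):
        if prev[k] < low:
            continue
        if prev[k] < split:
            x = (table.values[:, k] > 0).astype(float)
            part = "binary"
        else:
            x = clr[:, k]
            part = "quantitative"
        if np.std(x) == 0:
            logger.warning("MWAS: %s constant in its coded form; skipped", taxon)
            continue
        b, se, p = _ols_t(y_adj, x, covars)
        rows.append({"taxon": taxon, "part": part, "beta": b, "se": se,
                     "p_value": p})
    out = pd.DataFrame(rows, columns=["taxon", "part", "beta", "se", "p_value"])
    if len(out):
        out["p_bonferroni"] = bonferroni(out["p_value"].to_numpy(), n_tests=len(out))
        out["significant"] = out["p_bonferroni"] < alpha
    else:
        out["p_bonferroni"] = []
        out["significant"] = []
    return out
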