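"""Relationship matrices and the Mantel test between them.

* genotype QC (autosomes, MAF, missingness);
* the Yang et al. SNP-based genetic relationship matrix (GRM), the estimator
  GCTA uses: allele-frequency standardized cross-products off the diagonal
  and an inbreeding-style correction on the diagonal;
* the microbial relationship matrix (MRM) M = ZZ'/m from column z-scored
  taxon abundances, so trace(M) = n - 1 with sample-SD scores;
* genetic principal components from the GRM;
* a one-sided permutation Mantel test on the vectorized off-diagonal upper
  triangles of two relationship matrices (similarity scale, not distances).
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np

from .containers import (AbundanceTable, AlignmentError, GenotypeMatrix,
                         RelationshipMatrix, check_aligned)

logger = logging.getLogger("rumenlink")


def qc_genotypes(geno: GenotypeMatrix, maf_min: float = 0.05,
                 max_missing: float = 0.3,
                 autosomes_only: bool = True) -> GenotypeMatrix:
    """Retain biallelic autosomal SNPs with MAF >= maf_min and missing
    fraction <= max_missing."""
    keep = np.ones(geno.n_snps, dtype=bool)
    if autosomes_only:
        keep &= geno.is_autosomal()
    keep &= geno.missing_rate() <= max_missing
    maf = geno.maf()
    keep &= np.nan_to_num(maf, nan=0.0) >= maf_min
    n_kept = int(keep.sum())
    logger.info("qc_genotypes: %d / %d SNPs retained", n_kept, geno.n_snps)
    if n_kept == 0:
        raise ValueError("no SNPs survive genotype QC")
    return geno.take_snps(np.flatnonzero(keep))


def compute_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Yang et al. GRM.  Off-diagonal

        A_jk = (1/N) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))

    and diagonal

        A_jj = 1 + (1/N) sum_i [x_ij^2 - (1 + 2p_i) x_ij + 2 p_i^2]
                                 / (2 p_i (1 - p_i)).

    Missing genotypes are mean-imputed to 2p per SNP beforehand.
    """
    p = geno.allele_freq()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP reached compute_grm; run qc_genotypes first")
    x = geno.imputed(p)
    het = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p) / np.sqrt(het)
    n_snps = geno.n_snps
    a = (w @ w.T) / n_snps
    diag = 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / het).sum(axis=1) / n_snps
    np.fill_diagonal(a, diag)
    return RelationshipMatrix(
        sample_ids=list(geno.sample_ids), values=a, source="GRM",
        n_markers_used=n_snps,
    )


def compute_mrm(table: AbundanceTable) -> RelationshipMatrix:
    """MRM = ZZ'/m from column z-scored (sample SD) abundances.

    Zero-variance taxa are dropped with a warning; trace(M) = n - 1.
    """
    vals = table.values
    sd = vals.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("compute_mrm: dropped %d zero-variance taxa", n_dropped)
    if keep.sum() < 2:
        raise ValueError("need at least 2 taxa with nonzero variance for the MRM")
    z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    m = int(keep.sum())
    return RelationshipMatrix(
        sample_ids=list(table.sample_ids), values=(z @ z.T) / m, source="MRM",
        n_markers_used=m,
    )


def genetic_pcs(rm: RelationshipMatrix, k: int) -> np.ndarray:
    """Top-k eigenvectors of the relationship matrix scaled by sqrt(lambda).

    Sign convention: the entry of largest magnitude in each axis is positive,
    so scores are deterministic.  A warning is logged when the spectrum is
    (near-)flat and the axes are not identifiable.
    """
    if k >= rm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    evals, evecs = np.linalg.eigh(rm.values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order[:k]], evecs[:, order[:k]]
    if np.ptp(np.linalg.eigvalsh(rm.values)) < 1e-10:
        logger.warning("genetic_pcs: flat eigenvalue spectrum; axes degenerate")
    for a in range(k):
        j = np.argmax(np.abs(evecs[:, a]))
        if evecs[j, a] < 0:
            evecs[:, a] = -evecs[:, a]
    return evecs * np.sqrt(np.maximum(evals, 0.0))


def _offdiag_upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(a: RelationshipMatrix, b: RelationshipMatrix,
                n_perm: int = 9999, seed: int = 0,
                method: str = "permutation"):
    """Mantel correlation between two relationship matrices.

    r is the Pearson correlation of the vectorized off-diagonal upper
    triangles; the one-sided upper-tail p comes from simultaneous row/column
    permutations of ``b``.  ``method="permutation"`` samples ``n_perm``
    permutations and applies the +1 correction, p = (#{r_perm >= r_obs} + 1)
    / (n_perm + 1); ``method="exact"`` enumerates all n! permutations
    (identity included) and divides by n!.
    """
    if not a.aligned_with(b.sample_ids):
        raise AlignmentError("relationship matrices have different samples")
    n = a.n_samples
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    va = _offdiag_upper(a.values)
    if va.std() == 0 or _offdiag_upper(b.values).std() == 0:
        raise ValueError("Mantel r undefined: constant off-diagonal entries")

    va_c = va - va.mean()
    va_norm = np.sqrt((va_c**2).sum())
    iu = np.triu_indices(n, k=1)

    def corr_with(bm: np.ndarray) -> float:
        vb = bm[iu]
        vb_c = vb - vb.mean()
        return float((va_c @ vb_c) / (va_norm * np.sqrt((vb_c**2).sum())))

    r_obs = corr_with(b.values)
    eps = 1e-12
    if method == "exact":
        total = math.factorial(n)
        count = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            if corr_with(b.values[np.ix_(idx, idx)]) >= r_obs - eps:
                count += 1
        return r_obs, count / total
    if method != "permutation":
        raise ValueError(f"unknown Mantel method {method!r}")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr_with(b.values[np.ix_(idx, idx)]) >= r_obs - eps:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)
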