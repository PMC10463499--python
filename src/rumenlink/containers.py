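"""Shared data containers: genotype, abundance and relationship matrices.

These are thin, validated wrappers around numpy arrays plus sample/marker
identifiers.  All downstream modules consume and return these types; pandas
DataFrames are used for tabular *results* (association tables, variance
component scans) rather than for the core matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("rumenlink")

MISSING = -1  # sentinel for missing genotypes in the int-coded matrix

SEX_CHROMOSOMES = {"X", "Y", "Z", "W", "MT", "M", "CHRX", "CHRY"}


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


class AlignmentError(ValueError):
    """Raised when inputs do not share sample identifiers/order."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotype matrix coded 0/1/2 (-1 missing).

    ``values`` counts copies of the alternate allele; ``chrom``/``pos`` give
    marker coordinates (chromosome labels are strings so sex chromosomes can
    be recognised).
    """

    sample_ids: list
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (samples x SNPs)")
        self.chrom = np.asarray(self.chrom, dtype=object).astype(str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError("id lists do not match genotype matrix shape")
        if len(self.chrom) != p or len(self.pos) != p:
            raise ValueError("chrom/pos do not match number of SNPs")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be coded 0/1/2 or -1 (missing)")
        self.values = self.values.astype(np.int16)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.values == MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency among observed calls."""
        obs = self.values != MISSING
        vals = np.where(obs, self.values, 0).astype(float)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = vals.sum(axis=0) / (2.0 * n_obs)
        return np.where(n_obs > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def is_autosomal(self) -> np.ndarray:
        return np.array([c.upper() not in SEX_CHROMOSOMES for c in self.chrom])

    def imputed(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Float matrix with missing genotypes mean-imputed to 2p per SNP."""
        p = self.allele_freq() if freq is None else freq
        out = self.values.astype(float)
        miss = self.values == MISSING
        if miss.any():
            out[miss] = np.broadcast_to(2.0 * p, out.shape)[miss]
        return out

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            values=self.values[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snp_ids=list(self.snp_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            values=self.values[idx, :],
        )


@dataclass
class AbundanceTable:
    """Sample x taxon abundance matrix with optional taxonomy labels.

    ``kind`` is ``"counts"`` (integer reads) or ``"relative"`` (proportions).
    ``phylum``/``genus`` are per-taxon labels; ``is_classified`` marks taxa
    with a resolved genus name (unclassified genera are dropped by the genus
    quality-control filter).
    """

    sample_ids: list
    taxon_ids: list
    values: np.ndarray
    kind: str = "counts"
    phylum: list | None = None
    genus: list | None = None
    is_classified: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("abundance values must be 2-D (samples x taxa)")
        n, t = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != t:
            raise ValueError("id lists do not match abundance matrix shape")
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"unknown table kind {self.kind!r}")
        if (self.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.is_classified is None:
            self.is_classified = np.ones(t, dtype=bool)
        else:
            self.is_classified = np.asarray(self.is_classified, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def prevalence(self) -> np.ndarray:
        """Per-taxon fraction of samples in which the taxon is detected (>0)."""
        return (self.values > 0).mean(axis=0)

    def to_relative(self) -> "AbundanceTable":
        totals = self.values.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            logger.warning("%d sample(s) with zero total abundance", int((totals == 0).sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, self.values / totals, 0.0)
        return replace(self, values=rel, kind="relative")

    def take_taxa(self, idx) -> "AbundanceTable":
        idx = np.asarray(idx)
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=[self.taxon_ids[i] for i in idx],
            values=self.values[:, idx],
            kind=self.kind,
            phylum=None if self.phylum is None else [self.phylum[i] for i in idx],
            genus=None if self.genus is None else [self.genus[i] for i in idx],
            is_classified=self.is_classified[idx],
        )

    def take_samples(self, idx) -> "AbundanceTable":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx, :],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass
class RelationshipMatrix:
    """Symmetric n x n sample relationship matrix (GRM or MRM)."""

    sample_ids: list
    values: np.ndarray
    source: str = "GRM"
    n_markers_used: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square and match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric within 1e-10")
        # enforce exact symmetry so downstream eigendecompositions are stable
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def aligned_with(self, other_ids) -> bool:
        return list(self.sample_ids) == list(other_ids)

    def reorder(self, sample_ids) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in sample_ids])
        except KeyError as e:
            raise AlignmentError(f"sample {e} absent from relationship matrix") from e
        return RelationshipMatrix(
            sample_ids=list(sample_ids),
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
            n_markers_used=self.n_markers_used,
        )


def check_aligned(*id_lists) -> None:
    """Raise AlignmentError unless every id list is identical in order."""
    ref = list(id_lists[0])
    for ids in id_lists[1:]:
        if list(ids) != ref:
            raise AlignmentError("inputs do not share identical sample ids/order")
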