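"""Microbiota feature engineering.

Turns count/relative abundance tables into the trait set used downstream:

* quality-filtered ASV/genus tables (presence and total-count rules);
* rarefaction to a fixed depth (sampling without replacement);
* alpha diversity (richness, Chao1, ACE, Shannon);
* the Firmicutes:Bacteroidetes ratio;
* Bray-Curtis PCoA axis scores;
* a prevalence-based partition of genera into CLR-transformed quantitative
  traits (prevalence >= 60%) and presence/absence binary traits (1.5-60%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import AbundanceTable, ConfigurationError

logger = logging.getLogger("rumenlink")


# ------------------------------------------------------------------ filters

def filter_asvs(table: AbundanceTable, min_samples: int = 3,
                min_total: int = 5) -> AbundanceTable:
    """Keep features detected in >= min_samples samples AND with total count
    strictly greater than min_total."""
    if table.kind != "counts":
        raise TypeError("filter_asvs expects a count table")
    present = (table.values > 0).sum(axis=0)
    totals = table.values.sum(axis=0)
    keep = np.flatnonzero((present >= min_samples) & (totals > min_total))
    if keep.size == 0:
        logger.warning("filter_asvs removed every feature")
    return table.take_taxa(keep)


def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a warning
    (the QIIME dialect of rarefaction).
    """
    if table.kind != "counts":
        raise TypeError("rarefy expects a count table")
    if depth < 1:
        raise ConfigurationError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.values.sum(axis=1)
    keep = np.flatnonzero(totals >= depth)
    dropped = table.n_samples - keep.size
    if dropped:
        logger.warning("rarefy dropped %d sample(s) below depth %d", dropped, depth)
    sub = table.take_samples(keep)
    out = np.empty_like(sub.values)
    for i in range(sub.n_samples):
        counts = sub.values[i].astype(np.int64)
        out[i] = rng.multivariate_hypergeometric(counts, depth)
    return AbundanceTable(
        sample_ids=sub.sample_ids,
        taxon_ids=sub.taxon_ids,
        values=out,
        kind="counts",
        phylum=sub.phylum,
        genus=sub.genus,
        is_classified=sub.is_classified,
    )


def filter_genera(table: AbundanceTable, min_mean_abund: float = 1e-6,
                  min_samples: int = 3) -> AbundanceTable:
    """Genus-level QC on a relative table: drop unclassified genera, then
    require mean relative abundance > min_mean_abund AND occurrence in
    strictly more than min_samples samples."""
    if table.kind != "relative":
        raise TypeError("filter_genera expects a relative-abundance table")
    mean_abund = table.values.mean(axis=0)
    occurrence = (table.values > 0).sum(axis=0)
    keep = (
        table.is_classified
        & (mean_abund > min_mean_abund)
        & (occurrence > min_samples)
    )
    return table.take_taxa(np.flatnonzero(keep))


def prevalence(table: AbundanceTable) -> np.ndarray:
    """Fraction of samples in which each taxon is detected (abundance > 0)."""
    return table.prevalence()


def classify_traits(table: AbundanceTable, low: float = 0.015,
                    split: float = 0.60):
    """Partition taxa by prevalence: < low excluded, [low, split) binary,
    >= split quantitative.  Returns (quantitative_idx, binary_idx,
    excluded_idx) as integer arrays."""
    prev = table.prevalence()
    quant = np.flatnonzero(prev >= split)
    binary = np.flatnonzero((prev >= low) & (prev < split))
    excluded = np.flatnonzero(prev < low)
    return quant, binary, excluded


# --------------------------------------------------------------- transforms

def clr_transform(values: np.ndarray | AbundanceTable,
                  pseudocount: float = 1e-6) -> np.ndarray:
    """Centered log-ratio transform row-wise: log(x+pc) minus its row mean.

    Each output row sums to zero over the included taxa.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    x = values.values if isinstance(values, AbundanceTable) else np.asarray(values, float)
    logx = np.log(x + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


# ----------------------------------------------------------- alpha diversity

@dataclass
class AlphaDiversityResult:
    S_obs: int
    F1: int
    F2: int
    chao1: float
    ace: float
    shannon: float


def alpha_diversity(counts: np.ndarray, chao1_bias_corrected: bool = True,
                    ace_rare_threshold: int = 10) -> AlphaDiversityResult:
    """Alpha diversity of one sample from its taxon counts.

    Chao1 defaults to the bias-corrected form S + F1(F1-1)/(2(F2+1)); the
    classic form S + F1^2/(2 F2) is available via the flag.  ACE uses the
    standard abundance-based coverage estimator with rare/abundant cutoff 10.
    Shannon is in nats over the nonzero proportions.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() == 0:
        raise ValueError("alpha diversity undefined for an all-zero sample")
    nz = counts[counts > 0]
    S = int(nz.size)
    F1 = int((nz == 1).sum())
    F2 = int((nz == 2).sum())
    if chao1_bias_corrected:
        chao1 = S + F1 * (F1 - 1) / (2.0 * (F2 + 1))
    else:
        chao1 = S + (F1 * F1) / (2.0 * F2) if F2 > 0 else S + F1 * (F1 - 1) / 2.0

    rare = nz[nz <= ace_rare_threshold]
    abund = nz[nz > ace_rare_threshold]
    S_rare, S_abund = rare.size, abund.size
    N_rare = int(rare.sum())
    if S_rare == 0:
        ace = float(S_abund)
    else:
        C_ace = 1.0 - F1 / N_rare if N_rare > 0 else 0.0
        if C_ace <= 0:
            # every rare individual is a singleton; coverage undefined, fall
            # back on the Chao1 estimate (vegan behaves comparably)
            ace = float(chao1)
        else:
            i = np.arange(1, ace_rare_threshold + 1)
            Fi = np.array([(rare == k).sum() for k in i])
            gamma2 = max(
                (S_rare / C_ace) * (i * (i - 1) @ Fi) / (N_rare * (N_rare - 1)) - 1
                if N_rare > 1 else 0.0,
                0.0,
            )
            ace = S_abund + S_rare / C_ace + (F1 / C_ace) * gamma2

    p = nz / nz.sum()
    shannon = float(-(p * np.log(p)).sum())
    return AlphaDiversityResult(S_obs=S, F1=F1, F2=F2, chao1=float(chao1),
                                ace=float(ace), shannon=shannon)


def alpha_diversity_table(table: AbundanceTable, **kwargs) -> pd.DataFrame:
    """Per-sample alpha diversity on a (rarefied) count table."""
    if table.kind != "counts":
        raise TypeError("alpha diversity expects a count table")
    rows = [alpha_diversity(table.values[i], **kwargs) for i in range(table.n_samples)]
    return pd.DataFrame(
        {
            "richness": [r.S_obs for r in rows],
            "chao1": [r.chao1 for r in rows],
            "ace": [r.ace for r in rows],
            "shannon": [r.shannon for r in rows],
        },
        index=table.sample_ids,
    )


# ------------------------------------------------------------------- ratios

def fb_ratio(table: AbundanceTable) -> np.ndarray:
    """Per-sample Firmicutes:Bacteroidetes ratio of summed relative
    abundances; NaN when the Bacteroidetes sum is zero."""
    if table.phylum is None:
        raise ValueError("fb_ratio requires phylum labels")
    phyla = np.array([str(p) for p in table.phylum])
    firm = np.isin(phyla, ["Firmicutes"])
    bact = np.isin(phyla, ["Bacteroidetes", "Bacteroidota"])
    if not firm.any() and not bact.any():
        raise ValueError("no taxa labelled Firmicutes or Bacteroidetes")
    f = table.values[:, firm].sum(axis=1)
    b = table.values[:, bact].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(b > 0, f / np.where(b > 0, b, 1.0), np.nan)
    return r


# --------------------------------------------------------------------- PCoA

def bray_curtis_pcoa(table: AbundanceTable, k: int = 5):
    """Classical metric MDS of Bray-Curtis distances.

    Returns ``(scores, frac_explained)`` where scores is n x k (axes scaled
    by sqrt of eigenvalue) and frac_explained is the proportion of
    positive-eigenvalue variance carried by each axis.  Negative eigenvalues
    are ignored (no Cailliez correction).
    """
    n = table.n_samples
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    d = squareform(pdist(table.values, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    # Gower double-centring of -D^2/2
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-12
    top = np.arange(k)
    scores = evecs[:, top] * np.sqrt(np.maximum(evals[top], 0.0))
    frac = np.where(evals[top] > 0, evals[top] / evals[pos].sum(), 0.0)
    return scores, frac


# -------------------------------------------------------------- feature set

@dataclass
class MicrobialFeatureSet:
    """The downstream trait set: community traits, CLR quantitative traits,
    and binary presence traits, with the per-taxon prevalence used to build
    the partition."""

    community: pd.DataFrame
    quantitative: pd.DataFrame
    binary: pd.DataFrame
    prevalence: pd.Series
    excluded_taxa: list

    def trait_columns(self):
        """Yield (name, class, vector) over every feature."""
        for c in self.community.columns:
            yield c, "community", self.community[c].to_numpy()
        for c in self.quantitative.columns:
            yield c, "quantitative", self.quantitative[c].to_numpy()
        for c in self.binary.columns:
            yield c, "binary", self.binary[c].to_numpy()


def build_feature_set(rel_table: AbundanceTable,
                      counts_table: AbundanceTable | None = None,
                      low: float = 0.015, split: float = 0.60,
                      n_pcoa: int = 5, clr_pseudocount: float = 1e-6,
                      clr_on_full_table: bool = True) -> MicrobialFeatureSet:
    """Assemble the full microbial trait set from a filtered genus table.

    ``counts_table`` (rarefied counts, any feature level) supplies alpha
    diversity; when absent the alpha columns are omitted.  The CLR transform
    for quantitative traits is computed over the whole filtered genus table
    (all prevalence-retained taxa) so the geometry is shared, then the
    quantitative columns are extracted.
    """
    prev = rel_table.prevalence()
    quant_idx, bin_idx, excl_idx = classify_traits(rel_table, low=low, split=split)

    community = {}
    if counts_table is not None:
        community.update(alpha_diversity_table(counts_table).to_dict("series"))
    if rel_table.phylum is not None:
        try:
            community["fb_ratio"] = pd.Series(fb_ratio(rel_table), index=rel_table.sample_ids)
        except ValueError:
            logger.warning("F:B ratio unavailable: missing phylum labels")
    scores, _ = bray_curtis_pcoa(rel_table, k=n_pcoa)
    for a in range(n_pcoa):
        community[f"pcoa{a + 1}"] = pd.Series(scores[:, a], index=rel_table.sample_ids)
    community_df = pd.DataFrame(community, index=rel_table.sample_ids)

    included = np.concatenate([quant_idx, bin_idx])
    clr_source = rel_table.take_taxa(np.sort(included)) if not clr_on_full_table else rel_table
    clr = clr_transform(clr_source, pseudocount=clr_pseudocount)
    clr_cols = {t: i for i, t in enumerate(clr_source.taxon_ids)}
    quant_df = pd.DataFrame(
        {rel_table.taxon_ids[i]: clr[:, clr_cols[rel_table.taxon_ids[i]]] for i in quant_idx},
        index=rel_table.sample_ids,
    )
    bin_df = pd.DataFrame(
        {rel_table.taxon_ids[i]: (rel_table.values[:, i] > 0).astype(float) for i in bin_idx},
        index=rel_table.sample_ids,
    )
    return MicrobialFeatureSet(
        community=community_df,
        quantitative=quant_df,
        binary=bin_df,
        prevalence=pd.Series(prev, index=rel_table.taxon_ids),
        excluded_taxa=[rel_table.taxon_ids[i] for i in excl_idx],
    )
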