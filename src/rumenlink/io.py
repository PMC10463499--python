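"""Readers and writers for the package's plain-text interchange formats.

Formats:

* genotype TSV — SNP-major table (snp_id, chrom, pos, then one column per
  sample holding 0/1/2 or ``NA``);
* minimal VCF (GT-only) for genotype export;
* abundance TSV — sample x taxon with an optional ``#taxonomy`` comment line
  carrying ``phylum|genus`` labels and a ``#kind`` line;
* relationship matrices as square TSV or as the GCTA text triplet
  (``.grm.gz`` + ``.grm.id``).
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, AbundanceTable, GenotypeMatrix, RelationshipMatrix

logger = logging.getLogger("rumenlink")


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.values.T, columns=geno.sample_ids)
    df.insert(0, "pos", geno.pos)
    df.insert(0, "chrom", geno.chrom)
    df.insert(0, "snp_id", geno.snp_ids)
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["snp_id", "chrom", "pos"]]
    vals = df.drop(columns=["snp_id", "chrom", "pos"])
    values = vals.to_numpy(dtype=float).T
    values = np.where(np.isnan(values), MISSING, values).astype(np.int16)
    return GenotypeMatrix(
        sample_ids=list(vals.columns),
        snp_ids=meta["snp_id"].tolist(),
        chrom=meta["chrom"].to_numpy(),
        pos=meta["pos"].to_numpy(),
        values=values,
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 export carrying only the GT field (unphased)."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in geno.sample_ids) + "\n")
        for j in range(geno.n_snps):
            calls = "\t".join(gt_code[int(v)] for v in geno.values[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a (possibly bgzipped) VCF, keeping GT only, coded as ALT dosage."""
    try:
        from cyvcf2 import VCF  # fast C parser when available
    except ImportError:  # pragma: no cover - fallback for minimal environments
        return _read_vcf_text(path)
    sample_ids = None
    snp_ids, chrom, pos, rows = [], [], [], []
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}-{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        dosage = []
        for g in var.genotypes:
            alleles = [a for a in g[:-1] if a >= 0]
            dosage.append(sum(alleles) if len(alleles) == 2 else MISSING)
        rows.append(dosage)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chrom=np.array(chrom),
        pos=np.array(pos),
        values=np.array(rows, dtype=np.int16).T,
    )


def _read_vcf_text(path) -> GenotypeMatrix:
    gt_map = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
              "1/1": 2, "1|1": 2}
    opener = gzip.open if str(path).endswith(".gz") else open
    sample_ids, snp_ids, chrom, pos, rows = [], [], [], [], []
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                sample_ids = parts[9:]
                continue
            chrom.append(parts[0])
            pos.append(int(parts[1]))
            snp_ids.append(parts[2] if parts[2] != "." else f"{parts[0]}-{parts[1]}")
            fmt = parts[8].split(":")
            gi = fmt.index("GT")
            rows.append([gt_map.get(f.split(":")[gi], MISSING) for f in parts[9:]])
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        chrom=np.array(chrom),
        pos=np.array(pos),
        values=np.array(rows, dtype=np.int16).T,
    )


# ---------------------------------------------------------------- abundance

def write_abundance_tsv(table: AbundanceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#kind\t{table.kind}\n")
        if table.phylum is not None or table.genus is not None:
            phyla = table.phylum or [""] * table.n_taxa
            genera = table.genus or [""] * table.n_taxa
            labels = "\t".join(f"{p}|{g}" for p, g in zip(phyla, genera))
            fh.write(f"#taxonomy\t{labels}\n")
        fh.write("sample_id\t" + "\t".join(str(t) for t in table.taxon_ids) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = "\t".join(repr(float(v)) for v in table.values[i])
            fh.write(f"{sid}\t{row}\n")


def read_abundance_tsv(path) -> AbundanceTable:
    kind = "counts"
    taxonomy = None
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#kind"):
                kind = line.rstrip("\n").split("\t")[1]
                header_rows += 1
            elif line.startswith("#taxonomy"):
                taxonomy = line.rstrip("\n").split("\t")[1:]
                header_rows += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=header_rows, index_col=0)
    phylum = genus = None
    is_classified = None
    if taxonomy is not None:
        phylum = [t.split("|")[0] for t in taxonomy]
        genus = [t.split("|")[1] if "|" in t else "" for t in taxonomy]
        is_classified = np.array(
            [bool(g) and not g.lower().startswith("unclassified") for g in genus]
        )
    return AbundanceTable(
        sample_ids=list(df.index.astype(str)),
        taxon_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        kind=kind,
        phylum=phylum,
        genus=genus,
        is_classified=is_classified,
    )


# ------------------------------------------------------------- relationship

def write_relationship_tsv(rm: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(rm.values, index=rm.sample_ids, columns=rm.sample_ids)
    df.to_csv(path, sep="\t", index_label=rm.source)


def read_relationship_tsv(path, source: str | None = None) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    src = source or str(df.index.name or "GRM")
    return RelationshipMatrix(
        sample_ids=list(df.index.astype(str)), values=df.to_numpy(dtype=float), source=src
    )


def write_grm_gcta(rm: RelationshipMatrix, prefix) -> None:
    """GCTA text format: gzipped lower-triangle triplets plus an id file."""
    prefix = Path(prefix)
    with gzip.open(str(prefix) + ".grm.gz", "wt") as fh:
        for j in range(rm.n_samples):
            for k in range(j + 1):
                fh.write(
                    f"{j + 1}\t{k + 1}\t{rm.n_markers_used}\t{float(rm.values[j, k])!r}\n"
                )
    with open(str(prefix) + ".grm.id", "w") as fh:
        for sid in rm.sample_ids:
            fh.write(f"{sid}\t{sid}\n")


def read_grm_gcta(prefix, source: str = "GRM") -> RelationshipMatrix:
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(str(prefix) + ".grm.id")]
    n = len(ids)
    vals = np.zeros((n, n))
    n_markers = 0
    with gzip.open(str(prefix) + ".grm.gz", "rt") as fh:
        for line in fh:
            j, k, m, v = line.split()
            j, k = int(j) - 1, int(k) - 1
            vals[j, k] = vals[k, j] = float(v)
            n_markers = int(m)
    return RelationshipMatrix(sample_ids=ids, values=vals, source=source, n_markers_used=n_markers)
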