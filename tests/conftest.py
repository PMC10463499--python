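import numpy as np
import pytest

import rumenlink as rl


@pytest.fixture(scope="session")
def small_cohort():
    """A modest shared cohort for cross-module tests (n=300, 1500 SNPs)."""
    cfg = rl.SimConfig(n_individuals=300, n_snps=1500, n_taxa=80,
                       pheno_h2=0.4, pheno_m2=0.2, seed=42)
    return rl.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_kinship(small_cohort):
    geno = rl.qc_genotypes(small_cohort["genotypes"])
    grm = rl.compute_grm(geno)
    mrm = rl.compute_mrm(small_cohort["abundance"])
    return {"geno": geno, "grm": grm, "mrm": mrm}


def toy_abundance(values, kind="counts", phylum=None, genus=None,
                  is_classified=None):
    """Build a small AbundanceTable from a nested list."""
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    return rl.AbundanceTable(
        sample_ids=[f"s{i}" for i in range(n)],
        taxon_ids=[f"t{j}" for j in range(t)],
        values=values,
        kind=kind,
        phylum=phylum,
        genus=genus,
        is_classified=is_classified,
    )
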