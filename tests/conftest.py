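import numpy as np
import pytest

from tepopgen import SimulationConfig, simulate_fixture
from tepopgen.io_formats import GenotypeTable, TECatalog


@pytest.fixture(scope="session")
def small_fixture():
    """A small mixed-inbreeding fixture shared by read-only tests."""
    cfg = SimulationConfig(seed=42, n_snps=600, n_pops=6, n_samples_per_pop=8,
                           f_pop=[0.8, 0.8, 0.8, 0.0, 0.0, -0.2])
    table, catalog, truth = simulate_fixture(cfg)
    return cfg, table, catalog, truth


def make_table(genotypes, populations, lineages=None, pos0=None, chrom=None):
    """Small hand-constructed genotype tables for arithmetic tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_snps = genotypes.shape
    return GenotypeTable(
        snp_ids=[f"s{j}" for j in range(n_snps)],
        chrom=chrom if chrom is not None else ["chr1"] * n_snps,
        pos0=pos0 if pos0 is not None else np.arange(n_snps) * 10 + 100,
        samples=[f"ind{i}" for i in range(n_samples)],
        population=populations,
        lineage=lineages if lineages is not None else ["L"] * n_samples,
        genotypes=genotypes,
    )


def make_catalog(rows):
    """rows: (te_id, chrom, start1, end1, strand, superfamily) 1-based incl."""
    te_ids, chroms, s0, e0, strands, sfs = zip(*[
        (r[0], r[1], r[2] - 1, r[3], r[4], r[5]) for r in rows])
    return TECatalog(list(te_ids), list(chroms), list(s0), list(e0),
                     list(strands), list(sfs))
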