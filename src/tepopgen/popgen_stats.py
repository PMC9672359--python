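"""Inbreeding coefficients, per-locus statistics and relatedness clusters.

The per-sample inbreeding coefficient is F_IS = 1 - Ho_i / He_i where Ho_i is
the fraction of loci at which sample i is heterozygous and He_i is the mean
over loci of the unbiased expected heterozygosity 2*p*q*m/(m-1), with p the
allele frequency in the sample's own population and m = 2n the number of
allele copies sampled there (the standard Nei small-sample correction).  Per-locus differentiation uses the Weir & Cockerham (1984) theta
estimator across populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io_formats import GenotypeTable


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------

def _pop_allele_freqs(genotable: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population alt-allele frequencies (pops x snps) and sizes."""
    pops, pop_idx = np.unique(genotable.population, return_inverse=True)
    n_pops = len(pops)
    counts = np.zeros((n_pops, genotable.n_snps))
    sizes = np.bincount(pop_idx, minlength=n_pops).astype(float)
    for j in range(n_pops):
        counts[j] = genotable.genotypes[pop_idx == j].sum(axis=0)
    freqs = counts / (2.0 * sizes[:, None])
    return pops, freqs, sizes


def sample_fis(genotable: GenotypeTable) -> pd.DataFrame:
    """Genome-wide F_IS per sample (columns: sample, population, lineage,
    ho, he, fis).  Samples from populations of size 1 get NaN — expected
    heterozygosity is undefined there."""
    pops, freqs, sizes = _pop_allele_freqs(genotable)
    pop_of = {p: j for j, p in enumerate(pops)}

    rows = []
    for i, s in enumerate(genotable.samples):
        j = pop_of[genotable.population[i]]
        n = sizes[j]
        if n < 2:
            rows.append((s, genotable.population[i], genotable.lineage[i],
                         np.nan, np.nan, np.nan))
            continue
        p = freqs[j]
        m = 2.0 * n  # allele copies
        he = (2.0 * p * (1.0 - p) * m / (m - 1.0)).mean()
        ho = float((genotable.genotypes[i] == 1).mean())
        fis = 1.0 - ho / he if he > 0 else np.nan
        rows.append((s, genotable.population[i], genotable.lineage[i], ho, he, fis))
    return pd.DataFrame(rows, columns=["sample", "population", "lineage",
                                       "ho", "he", "fis"])


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def wc_fst(genotable: GenotypeTable) -> np.ndarray:
    """Per-SNP Weir & Cockerham (1984) theta across populations.

    Variance components a (among populations), b (among individuals within
    populations) and c (within individuals) are computed from per-population
    allele frequencies and observed heterozygote frequencies; theta = a/(a+b+c).
    May be slightly negative at undifferentiated loci.
    """
    pops, p_jm, sizes = _pop_allele_freqs(genotable)
    r = len(pops)
    if r < 2:
        raise ValueError("theta requires at least two populations")
    n_j = sizes[:, None]                      # samples per population
    nbar = sizes.mean()
    nc = (sizes.sum() - (sizes ** 2).sum() / sizes.sum()) / (r - 1)

    # observed heterozygote frequency per population x snp
    pop_idx = np.searchsorted(pops, genotable.population)
    h_jm = np.zeros_like(p_jm)
    for j in range(r):
        h_jm[j] = (genotable.genotypes[pop_idx == j] == 1).mean(axis=0)

    pbar = (n_j * p_jm).sum(axis=0) / (r * nbar)
    s2 = (n_j * (p_jm - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_j * h_jm).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2

    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, a / denom, 0.0)
    return theta


def allele_counts_by_population(genotable: GenotypeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alt-allele counts and chromosome totals per SNP x population —
    the input of the Bayesian F_ST decomposition."""
    pops, pop_idx = np.unique(genotable.population, return_inverse=True)
    alt = np.zeros((genotable.n_snps, len(pops)), dtype=np.int64)
    tot = np.zeros_like(alt)
    for j in range(len(pops)):
        sub = genotable.genotypes[pop_idx == j]
        alt[:, j] = sub.sum(axis=0)
        tot[:, j] = 2 * sub.shape[0]
    return pops, alt, tot


# ---------------------------------------------------------------------------
# relatedness clusters and per-locus stats
# ---------------------------------------------------------------------------

def pc_scores(genotable: GenotypeTable, k: int) -> np.ndarray:
    """Sample scores on the first k PCs of the standardized genotype matrix."""
    g = genotable.genotypes.astype(float)
    p = g.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    x = (g - 2.0 * p) / np.where(scale > 0, scale, 1.0)
    k = min(k, min(x.shape) - 1)
    return PCA(n_components=k, svd_solver="full").fit_transform(x)


def relatedness_clusters(genotable: GenotypeTable, k_pcs: int = 3,
                         n_clusters: int = 7, seed: int = 0) -> np.ndarray:
    """K-means clustering of samples on the leading PC scores.

    This categorical grouping stands in for genetic relatedness in the
    heterozygosity models.  Labels are renumbered by order of first
    appearance so a fixed seed gives identical labels across runs.
    """
    if n_clusters == 1:
        return np.zeros(genotable.n_samples, dtype=int)
    scores = pc_scores(genotable, k_pcs)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    raw = km.fit_predict(scores)
    return pd.factorize(raw)[0]


def locus_stats(genotable: GenotypeTable, clusters: np.ndarray) -> pd.DataFrame:
    """Long-format per-SNP statistics: one row per SNP x relatedness cluster
    with heterozygote and sample counts, plus global MAF and W&C theta."""
    maf = genotable.maf()
    theta = wc_fst(genotable)
    het = (genotable.genotypes == 1)
    frames = []
    for c in np.unique(clusters):
        members = clusters == c
        frames.append(pd.DataFrame({
            "snp_id": genotable.snp_ids,
            "cluster": c,
            "het_count": het[members].sum(axis=0),
            "n_samples": int(members.sum()),
            "maf": maf,
            "fst": theta,
        }))
    return pd.concat(frames, ignore_index=True)
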