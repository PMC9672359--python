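"""Synthetic genotype / TE-annotation fixtures with planted ground truth.

The generator draws genotypes directly from inbreeding-adjusted
Hardy-Weinberg proportions instead of simulating generations of selfing: for
a SNP with population allele frequency q and effective inbreeding level F,

    P(het)     = 2 q (1 - q) (1 - F)
    P(hom alt) = q^2 + q (1 - q) F

F is the only quantity the downstream analysis consumes, so direct draws make
the planted truth exact.  SNPs downstream of a "TE-effect" superfamily and
within ``te_effect_reach_bp`` (default 3,500 bp, the distance out to which TEs
are reported to elevate mutation and methylation rates) have their effective
inbreeding reduced to ``max(0, F - delta_te)`` — an excess-heterozygosity
effect without a mechanistic mutation model.

Planted locus classes shape the across-population allele-frequency structure:

* ``neutral``    — ancestral q from the baseline distribution, populations
  diverged with a Balding-Nichols F_ST of ``neutral_fst``;
* ``balancing``  — intermediate q (0.4-0.6) with very low across-population
  variance (low F_ST, high MAF);
* ``divergent``  — per-population frequencies scattered with SD
  ``divergent_sd`` around the ancestral value (high F_ST);
* ``purifying``  — rare global MAF (<= 0.10), low variance, site tagged 0-fold.

Default scale follows the study conditions being emulated: 13 populations in
a selfing gradient, 13 TE superfamilies, class mix 80% neutral / 5% balancing
/ 12% divergent / 3% purifying (the balancing and divergent rates match the
reported genome-wide outlier shares of 4.86% and 12.17%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (AnnotationTables, GenotypeTable, TECatalog,
                         write_metadata, write_table, write_te_gff, write_vcf)
from .te_proximity import DOWNSTREAM, UPSTREAM, annotate_all_positions

SUPERFAMILIES = ("CACTA", "Copia", "Gypsy", "Harbinger", "Helitron", "LINE",
                 "MITE", "MuDR", "SINE", "Tase", "TRIM", "LARD", "Unknown")

CLASSES = ("neutral", "balancing", "divergent", "purifying")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_pops: int = 13
    n_samples_per_pop: int = 4
    f_pop: np.ndarray | None = None          # default: gradient -0.4 .. 0.9
    n_snps: int = 2000
    chromosome_length: int = 8_000_000
    chrom_name: str = "chr1"
    lineage: str = "NorthAmerica"
    #: 80 TEs per superfamily on 8 Mb puts a random SNP ~3.5 kb from its
    #: nearest TE, the scale reported for the emulated genome
    te_counts: dict = field(default_factory=lambda: {sf: 80 for sf in SUPERFAMILIES})
    te_length_log_mean: float = 6.7          # ~800 bp median
    te_length_log_sd: float = 0.6
    class_proportions: dict = field(default_factory=lambda: {
        "neutral": 0.80, "balancing": 0.05, "divergent": 0.12, "purifying": 0.03})
    te_effect_superfamilies: tuple = ("Copia", "Harbinger")
    delta_te: float = 0.6
    te_effect_reach_bp: int = 3500
    baseline_q_range: tuple = (0.25, 0.75)
    neutral_fst: float = 0.05
    balancing_fst: float = 0.005
    divergent_sd: float = 0.35
    purifying_q_range: tuple = (0.02, 0.10)
    fold_4fold_rate: float = 0.15            # share of non-purifying SNPs tagged 4-fold
    fold_0fold_rate: float = 0.05
    #: optional per-superfamily probability that a nearby (upstream/downstream)
    #: SNP is planted divergent — a reproducible "signature profile" shared
    #: across lineages; overrides class_proportions for divergent/neutral
    superfamily_divergent_rates: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.delta_te < 0:
            raise ValueError("delta_te must be >= 0")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.f_pop is None:
            self.f_pop = np.linspace(-0.4, 0.9, self.n_pops)
        self.f_pop = np.asarray(self.f_pop, dtype=float)
        if len(self.f_pop) != self.n_pops:
            raise ValueError("f_pop must have one entry per population")
        if np.any(self.f_pop < -1) or np.any(self.f_pop > 1):
            raise ValueError("f_pop entries must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests.

    ``snp_frame`` has one row per SNP: planted class, true nearest-TE
    distance/sense/superfamily, whether the excess-heterozygosity effect was
    applied, the codon-fold tag, the mean planted allele frequency, and a
    flag for SNPs whose realized MAF fell below the 0.05 analysis filter.
    """

    snp_frame: pd.DataFrame
    pop_f: pd.DataFrame
    te_effect_superfamilies: tuple
    annotations: AnnotationTables


# ---------------------------------------------------------------------------

def simulate_te_landscape(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> TECatalog:
    """Random TE catalog: per-superfamily counts honored exactly, lognormal
    lengths, uniform starts and strands.  Intervals may overlap."""
    rng = rng or np.random.default_rng(config.seed)
    te_ids, chroms, s0, e0, strands, sfs = [], [], [], [], [], []
    total_len = 0
    for sf in sorted(config.te_counts):
        count = config.te_counts[sf]
        lengths = np.exp(rng.normal(config.te_length_log_mean,
                                    config.te_length_log_sd, size=count))
        lengths = np.clip(lengths, 100, 30_000).astype(np.int64)
        total_len += int(lengths.sum())
        if total_len >= config.chromosome_length:
            raise ValueError("infeasible packing: TE footprint exceeds chromosome")
        starts = rng.integers(0, config.chromosome_length - lengths)
        for i in range(count):
            te_ids.append(f"{sf}_{i}")
            chroms.append(config.chrom_name)
            s0.append(int(starts[i]))
            e0.append(int(starts[i] + lengths[i]))
            strands.append("+" if rng.random() < 0.5 else "-")
            sfs.append(sf)
    if not te_ids:
        return TECatalog(np.empty(0, object), np.empty(0, object),
                         np.empty(0, np.int64) , np.empty(0, np.int64) + 1,
                         np.empty(0, object), np.empty(0, object))
    return TECatalog(te_ids, chroms, s0, e0, strands, sfs)


def _planted_classes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_snps
    counts = {c: int(round(config.class_proportions.get(c, 0.0) * n)) for c in CLASSES}
    counts["neutral"] += n - sum(counts.values())  # rounding remainder
    labels = np.concatenate([np.full(counts[c], c, dtype=object) for c in CLASSES])
    rng.shuffle(labels)
    return labels


def _planted_frequencies(config: SimulationConfig, classes: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-population allele frequencies (pops x snps) by planted class."""
    n = len(classes)
    q = np.empty((config.n_pops, n))
    lo, hi = config.baseline_q_range

    def balding_nichols(anc: np.ndarray, fst: float) -> np.ndarray:
        shape = ((1 - fst) / fst) if fst > 0 else None
        if shape is None:
            return np.tile(anc, (config.n_pops, 1))
        a = np.maximum(anc * shape, 1e-3)
        b = np.maximum((1 - anc) * shape, 1e-3)
        return rng.beta(a, b, size=(config.n_pops, len(anc)))

    for cls in CLASSES:
        idx = np.flatnonzero(classes == cls)
        if idx.size == 0:
            continue
        if cls == "neutral":
            anc = rng.uniform(lo, hi, idx.size)
            q[:, idx] = balding_nichols(anc, config.neutral_fst)
        elif cls == "balancing":
            anc = rng.uniform(0.40, 0.60, idx.size)
            q[:, idx] = balding_nichols(anc, config.balancing_fst)
        elif cls == "divergent":
            # deviations standardized per locus so the planted across-pop
            # frequency SD equals divergent_sd exactly (up to boundary clips)
            anc = rng.uniform(0.35, 0.65, idx.size)
            dev = rng.normal(size=(config.n_pops, idx.size))
            dev = (dev - dev.mean(axis=0)) / dev.std(axis=0, ddof=1)
            q[:, idx] = anc + config.divergent_sd * dev
        else:  # purifying: rare minor allele, low variance
            anc = rng.uniform(*config.purifying_q_range, idx.size)
            q[:, idx] = balding_nichols(anc, config.balancing_fst)
    q = np.clip(q, 0.001, 0.999)
    # outbreeding feasibility: a population at F < 0 can only display that
    # heterozygote excess at loci with q in [-F/(1-F), 1/(1-F)]; truncate the
    # drawn frequencies there so the planted F is exact at every locus.
    # Purifying loci keep their rare alleles (their F is clamped instead).
    free = classes != "purifying"
    for j, f in enumerate(config.f_pop):
        if f < 0:
            b = -f / (1.0 - f)
            q[j, free] = np.clip(q[j, free], b, 1.0 - b)
    return q


def genotype_probabilities(q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Stacked (3, ...) probabilities of hom-ref / het / hom-alt genotypes
    under inbreeding-adjusted Hardy-Weinberg.

    A negative F is only representable down to -min(q/(1-q), (1-q)/q) — below
    that a homozygote probability would be negative — so F is clamped at the
    per-locus feasibility bound before the probabilities are formed.
    """
    with np.errstate(divide="ignore"):
        bound = -np.minimum(q / (1 - q), (1 - q) / q)
    f = np.maximum(f, bound)
    het = 2 * q * (1 - q) * (1 - f)
    hom_alt = q ** 2 + q * (1 - q) * f
    hom_ref = (1 - q) ** 2 + q * (1 - q) * f
    probs = np.clip(np.stack([hom_ref, het, hom_alt]), 0.0, None)
    return probs / probs.sum(axis=0, keepdims=True)


def simulate_genotypes(config: SimulationConfig, te_catalog: TECatalog,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeTable, GroundTruth]:
    """Draw the genotype table and record the planted ground truth."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_snps

    pos0 = np.sort(rng.choice(config.chromosome_length, size=n, replace=False))
    snp_ids = np.array([f"snp{i:06d}" for i in range(n)], dtype=object)
    chrom = np.full(n, config.chrom_name, dtype=object)

    ctx = annotate_all_positions(chrom, pos0, snp_ids, te_catalog, "strand")
    if config.superfamily_divergent_rates is not None:
        rates = config.superfamily_divergent_rates
        p_div = np.array([rates.get(sf, 0.0) if sense in (UPSTREAM, DOWNSTREAM)
                          else 0.0
                          for sf, sense in zip(ctx["superfamily"], ctx["sense"])])
        classes = np.where(rng.random(n) < p_div, "divergent", "neutral").astype(object)
    else:
        classes = _planted_classes(config, rng)
    q = _planted_frequencies(config, classes, rng)
    te_effect = (ctx["superfamily"].isin(config.te_effect_superfamilies)
                 & (ctx["sense"] == DOWNSTREAM)
                 & (ctx["distance_bp"] > 0)
                 & (ctx["distance_bp"] <= config.te_effect_reach_bp)).to_numpy()

    # excess heterozygosity near TE-effect superfamilies: the effective
    # inbreeding drops by delta_te, floored at 0, and never increases (an
    # already-outbred population keeps its F)
    f_eff = np.tile(config.f_pop[:, None], (1, n))
    f_eff[:, te_effect] = np.minimum(
        f_eff[:, te_effect],
        np.maximum(0.0, f_eff[:, te_effect] - config.delta_te))

    n_samples = config.n_pops * config.n_samples_per_pop
    populations = np.repeat([f"pop{j:02d}" for j in range(config.n_pops)],
                            config.n_samples_per_pop)
    samples = np.array([f"{config.lineage}_s{i:03d}" for i in range(n_samples)],
                       dtype=object)
    pop_idx = np.repeat(np.arange(config.n_pops), config.n_samples_per_pop)

    probs = genotype_probabilities(q, f_eff)          # (3, pops, snps)
    cum = np.cumsum(probs, axis=0)
    u = rng.random((n_samples, n))
    thresholds = cum[:, pop_idx, :]                   # (3, samples, snps)
    geno = ((u > thresholds[0]).astype(np.int8) + (u > thresholds[1]))

    table = GenotypeTable(snp_ids, chrom, pos0, samples,
                          populations.astype(object),
                          np.full(n_samples, config.lineage, dtype=object), geno)

    fold = _fold_tags(config, classes, rng)
    realized_maf = table.maf()
    snp_frame = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos0": pos0,
        "planted_class": classes,
        "distance_bp": ctx["distance_bp"].to_numpy(),
        "sense": ctx["sense"].to_numpy(),
        "superfamily": ctx["superfamily"].to_numpy(),
        "te_effect_applied": te_effect,
        "fold": fold,
        "mean_q": q.mean(axis=0),
        "below_maf_filter": realized_maf < 0.05,
    })
    pop_f = pd.DataFrame({"population": [f"pop{j:02d}" for j in range(config.n_pops)],
                          "f_pop": config.f_pop})
    annotations = _annotation_tables(config, snp_frame, rng)
    truth = GroundTruth(snp_frame, pop_f, tuple(config.te_effect_superfamilies),
                        annotations)
    return table, truth


def _fold_tags(config: SimulationConfig, classes: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    fold = np.full(len(classes), "none", dtype=object)
    u = rng.random(len(classes))
    fold[u < config.fold_4fold_rate] = "4-fold"
    fold[(u >= config.fold_4fold_rate)
         & (u < config.fold_4fold_rate + config.fold_0fold_rate)] = "0-fold"
    fold[classes == "purifying"] = "0-fold"
    return fold


def _annotation_tables(config: SimulationConfig, snp_frame: pd.DataFrame,
                       rng: np.random.Generator) -> AnnotationTables:
    """Codon-fold, SNP->gene, gene->GO and essentiality fixture tables.

    Genes tile consecutive SNP pairs; GO terms and essentiality values are
    structureless (no planted enrichment) unless tests construct their own.
    """
    tagged = snp_frame[snp_frame["fold"] != "none"]
    codon_fold = pd.DataFrame({"chrom": tagged["chrom"].to_numpy(),
                               "pos0": tagged["pos0"].to_numpy(),
                               "fold": tagged["fold"].to_numpy()})
    genes = np.array([f"g{i // 2:05d}" for i in range(len(snp_frame))], dtype=object)
    snp_gene = pd.DataFrame({"snp_id": snp_frame["snp_id"], "gene": genes})
    uniq = pd.unique(genes)
    vocab = [f"GO:{i:07d}" for i in range(30)]
    rows = []
    for g in uniq:
        for t in rng.choice(vocab, size=rng.integers(1, 4), replace=False):
            rows.append((g, t))
    gene_go = pd.DataFrame(rows, columns=["gene", "go_term"])
    ess = pd.DataFrame({
        "gene": uniq,
        "family_copy_number": 1 + rng.poisson(1.5, size=len(uniq)),
        "ka_ks": np.exp(rng.normal(-1.5, 0.5, size=len(uniq))),
    })
    return AnnotationTables(codon_fold=codon_fold, snp_gene=snp_gene,
                            gene_go=gene_go, gene_essentiality=ess)


# ---------------------------------------------------------------------------

def emit_fixture(out_dir: str | Path, genotable: GenotypeTable,
                 catalog: TECatalog, truth: GroundTruth) -> dict[str, Path]:
    """Write the full fixture (VCF, GFF3, metadata, annotation and truth
    TSVs) so the pipeline can be exercised purely from disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "gff": out / "te_annotation.gff3",
        "metadata": out / "metadata.tsv",
        "codon_fold": out / "codon_fold.tsv",
        "snp_gene": out / "snp_gene.tsv",
        "gene_go": out / "gene_go.tsv",
        "essentiality": out / "gene_essentiality.tsv",
        "truth_snps": out / "truth_snps.tsv",
        "truth_pops": out / "truth_pops.tsv",
    }
    write_vcf(genotable, paths["vcf"])
    write_te_gff(catalog, paths["gff"])
    write_metadata(genotable, paths["metadata"])
    ann = truth.annotations
    fold = ann.codon_fold.copy()
    fold["pos"] = fold.pop("pos0") + 1
    write_table(fold[["chrom", "pos", "fold"]], paths["codon_fold"])
    write_table(ann.snp_gene, paths["snp_gene"])
    write_table(ann.gene_go, paths["gene_go"])
    write_table(ann.gene_essentiality, paths["essentiality"])
    write_table(truth.snp_frame, paths["truth_snps"])
    write_table(truth.pop_f, paths["truth_pops"])
    return paths


def simulate_fixture(config: SimulationConfig
                     ) -> tuple[GenotypeTable, TECatalog, GroundTruth]:
    """One-call convenience: landscape + genotypes from a single seed."""
    rng = np.random.default_rng(config.seed)
    catalog = simulate_te_landscape(config, rng)
    table, truth = simulate_genotypes(config, catalog, rng)
    return table, catalog, truth
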