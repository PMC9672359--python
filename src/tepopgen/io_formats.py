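"""Readers, writers and configuration for the pipeline's on-disk formats.

Coordinate conventions
----------------------
VCF and GFF3 are 1-based inclusive on disk.  Internally every coordinate is
0-based half-open: a SNP position ``pos0`` satisfies ``0 <= pos0 < L`` and a
TE interval is ``[start0, end0)``.  All conversions happen in this module and
nowhere else.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tepopgen")

#: sentinel superfamily label for SNPs on chromosomes without any TE
NO_TE = "no_te"

MISSING = -1  # internal missing-genotype code (pre-filter only)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Biallelic SNP genotypes for a set of samples with population labels.

    ``genotypes`` is an ``(n_samples, n_snps)`` int8 array counting copies of
    the alternate allele (0/1/2).  After :func:`read_genotypes` filtering the
    table is complete-case (no missing entries).  ``pos0`` is 0-based.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos0: np.ndarray
    samples: np.ndarray
    population: np.ndarray
    lineage: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos0 = np.asarray(self.pos0, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=object)
        self.population = np.asarray(self.population, dtype=object)
        self.lineage = np.asarray(self.lineage, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.snp_ids)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_ids)} SNPs"
            )
        if np.any(self.pos0 < 0):
            raise ValueError("positions must be non-negative (0-based)")
        if len(self.population) != len(self.samples) or len(self.lineage) != len(self.samples):
            raise ValueError("every sample needs a population and lineage label")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_samples(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.snp_ids, self.chrom, self.pos0,
            self.samples[mask], self.population[mask], self.lineage[mask],
            self.genotypes[mask],
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.snp_ids[mask], self.chrom[mask], self.pos0[mask],
            self.samples, self.population, self.lineage,
            self.genotypes[:, mask],
        )

    def alt_allele_freq(self) -> np.ndarray:
        """Global alternate-allele frequency per SNP (all samples pooled)."""
        return self.genotypes.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class TECatalog:
    """Annotated transposable elements; intervals are 0-based half-open.

    Overlapping intervals are permitted (TE islands).  ``strand`` is one of
    ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    te_ids: np.ndarray
    chrom: np.ndarray
    start0: np.ndarray
    end0: np.ndarray
    strand: np.ndarray
    superfamily: np.ndarray

    def __post_init__(self) -> None:
        self.te_ids = np.asarray(self.te_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start0 = np.asarray(self.start0, dtype=np.int64)
        self.end0 = np.asarray(self.end0, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        self.superfamily = np.asarray(self.superfamily, dtype=object)
        if np.any(self.end0 <= self.start0):
            raise ValueError("TE intervals must be non-empty (start0 < end0)")
        if any(not s for s in self.superfamily):
            raise ValueError("superfamily labels must be non-empty")

    @property
    def n_tes(self) -> int:
        return len(self.te_ids)

    def to_frame(self) -> pd.DataFrame:
        """1-based inclusive coordinates, as read from / written to GFF3."""
        return pd.DataFrame({
            "te_id": self.te_ids, "chrom": self.chrom,
            "start": self.start0 + 1, "end": self.end0,
            "strand": self.strand, "superfamily": self.superfamily,
        })


@dataclass
class AnnotationTables:
    """Optional per-site and per-gene annotations consumed downstream.

    ``codon_fold`` maps (chrom, pos0) -> {'0-fold', '4-fold'}; sites absent
    from the table are unannotated.  ``gene_essentiality`` carries the gene
    family copy number (>=1) and the Ka/Ks ratio (>=0).
    """

    codon_fold: pd.DataFrame | None = None     # chrom, pos0, fold
    snp_gene: pd.DataFrame | None = None       # snp_id, gene
    gene_go: pd.DataFrame | None = None        # gene, go_term
    gene_essentiality: pd.DataFrame | None = None  # gene, family_copy_number, ka_ks

    def __post_init__(self) -> None:
        ess = self.gene_essentiality
        if ess is not None and (ess["ka_ks"] < 0).any():
            raise ValueError("Ka/Ks must be non-negative")

    def fold_for_snps(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Fold label per SNP ('0-fold', '4-fold' or 'none')."""
        out = np.full(len(pos0), "none", dtype=object)
        if self.codon_fold is None or self.codon_fold.empty:
            return out
        key = pd.MultiIndex.from_arrays([chrom, pos0])
        tab = self.codon_fold.set_index(["chrom", "pos0"])["fold"]
        tab = tab[~tab.index.duplicated()]
        hit = tab.reindex(key)
        out[hit.notna().to_numpy()] = hit.dropna().to_numpy()
        return out


@dataclass
class FilterReport:
    """Bookkeeping of SNPs dropped while loading genotypes."""

    n_input: int = 0
    n_retained: int = 0
    dropped_multiallelic: int = 0
    dropped_missing: int = 0
    dropped_maf: int = 0

    @property
    def n_dropped(self) -> int:
        return self.dropped_multiallelic + self.dropped_missing + self.dropped_maf

    def check(self) -> None:
        if self.n_retained + self.n_dropped != self.n_input:
            raise AssertionError("filter report does not sum to input SNP count")


@dataclass
class PipelineConfig:
    """All thresholds and settings of the pipeline, with the printed defaults.

    The selfing/outcrossing F_IS split (0.6), the European demographic split
    (-0.3), the PCA-scan q-value cutoff (0.01), the log10 posterior-odds
    cutoff (0.5) and the Bayesian FDR (0.05) are the study constants; change
    them only to explore sensitivity.
    """

    fis_split_high: float = 0.6
    fis_split_europe: float = -0.3
    q_cutoff: float = 0.01
    log10_po_cutoff: float = 0.5
    fdr: float = 0.05
    n_pcs: int = 3
    maf_min: float = 0.05
    n_clusters: int = 7          # European panel; North American default 6
    sense_mode: str = "strand"   # or "genomic"
    classify_mode: str = "combined"  # or "bayescan-only"
    superfamily_key: str = "superfamily"
    reference_superfamily: str = "CACTA"
    seed: int = 0
    mcmc: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.q_cutoff < 1) or not (0 < self.fdr < 1):
            raise ValueError("q_cutoff and fdr must lie in (0, 1)")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if self.sense_mode not in ("strand", "genomic"):
            raise ValueError("sense_mode must be 'strand' or 'genomic'")
        if self.classify_mode not in ("combined", "bayescan-only"):
            raise ValueError("classify_mode must be 'combined' or 'bayescan-only'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# genotype input
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "lineage"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta


def _filter_and_build(snp_ids, chrom, pos0, geno, samples, meta,
                      maf_min: float, n_multi: int) -> tuple[GenotypeTable, FilterReport]:
    geno = np.asarray(geno, dtype=np.int16)
    report = FilterReport(n_input=len(snp_ids) + n_multi,
                          dropped_multiallelic=n_multi)

    missing = (geno == MISSING).any(axis=0)
    report.dropped_missing = int(missing.sum())
    keep = ~missing

    with np.errstate(invalid="ignore"):
        p = np.where(keep, geno.clip(min=0).mean(axis=0) / 2.0, np.nan)
    maf = np.minimum(p, 1 - p)
    low = keep & (maf < maf_min)
    report.dropped_maf = int(low.sum())
    keep &= ~low

    report.n_retained = int(keep.sum())
    report.check()

    meta = meta.set_index("sample")
    missing_samples = [s for s in samples if s not in meta.index]
    if missing_samples:
        raise ValueError(f"samples absent from metadata: {missing_samples}")
    meta = meta.loc[list(samples)]

    table = GenotypeTable(
        snp_ids=np.asarray(snp_ids, dtype=object)[keep],
        chrom=np.asarray(chrom, dtype=object)[keep],
        pos0=np.asarray(pos0)[keep],
        samples=np.asarray(samples, dtype=object),
        population=meta["population"].to_numpy(dtype=object),
        lineage=meta["lineage"].to_numpy(dtype=object),
        genotypes=geno[:, keep].astype(np.int8),
    )
    return table, report


def read_genotypes(vcf_or_table: str | Path, metadata_table: str | Path,
                   maf_min: float = 0.05) -> tuple[GenotypeTable, FilterReport]:
    """Load genotypes from a VCF or a TSV genotype matrix and filter them.

    Multi-allelic records are skipped with a warning; SNPs with any missing
    genotype, then SNPs with pooled MAF < ``maf_min``, are dropped and counted
    in the returned :class:`FilterReport`.
    """
    path = Path(vcf_or_table)
    meta = read_metadata(metadata_table)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, meta, maf_min)
    return _read_genotype_tsv(path, meta, maf_min)


def _read_vcf(path: Path, meta: pd.DataFrame, maf_min: float):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, pos0, rows = [], [], [], []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multi += 1
            warnings.warn(f"skipping multi-allelic record {rec.CHROM}:{rec.POS}")
            continue
        g = rec.gt_types.astype(np.int16)  # 0/1/2, 3 = unknown under gts012
        g[g == 3] = MISSING
        rows.append(g)
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        pos0.append(rec.POS - 1)
    geno = np.array(rows, dtype=np.int16).T if rows else np.empty((len(samples), 0), np.int16)
    return _filter_and_build(snp_ids, chroms, np.array(pos0, dtype=np.int64),
                             geno, samples, meta, maf_min, n_multi)


def _read_genotype_tsv(path: Path, meta: pd.DataFrame, maf_min: float):
    """TSV matrix: columns snp_id, chrom, pos (1-based), then one per sample."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["snp_id", "chrom", "pos"]
    if df.columns[:3].tolist() != fixed:
        raise ValueError(f"genotype TSV must start with columns {fixed}")
    samples = df.columns[3:].tolist()
    geno = df[samples].to_numpy(dtype=float).T
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int16)
    return _filter_and_build(df["snp_id"].astype(str).tolist(),
                             df["chrom"].astype(str).tolist(),
                             df["pos"].to_numpy(np.int64) - 1,
                             geno, samples, meta, maf_min, n_multi=0)


def filter_genotypes(table: GenotypeTable, maf_min: float = 0.05
                     ) -> tuple[GenotypeTable, FilterReport]:
    """Apply the MAF filter to an in-memory complete-case table.

    Mirrors the filtering of :func:`read_genotypes` for tables that never
    touch disk (e.g. simulated ones).
    """
    report = FilterReport(n_input=table.n_snps)
    keep = table.maf() >= maf_min
    report.dropped_maf = int((~keep).sum())
    report.n_retained = int(keep.sum())
    report.check()
    return table.subset_snps(keep), report


# ---------------------------------------------------------------------------
# TE annotation input / output
# ---------------------------------------------------------------------------

_STRAND_MAP = {"+": "+", "-": "-"}


def read_te_gff(gff3_path: str | Path, superfamily_key: str = "superfamily") -> TECatalog:
    """Read a TE annotation GFF3 into a :class:`TECatalog`.

    Records lacking the superfamily attribute get the label ``'Unknown'``;
    strands other than + or - map to unknown ('.').  Malformed lines raise
    with their line number.
    """
    te_ids, chroms, s0, e0, strands, sfs = [], [], [], [], [], []
    n_anon = 0
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 tab-separated fields, got {len(parts)}")
            chrom, _source, _type, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{gff3_path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{gff3_path}:{lineno}: invalid interval [{start}, {end}]")
            attr = _parse_gff_attributes(attrs)
            te_id = attr.get("ID")
            if te_id is None:
                n_anon += 1
                te_id = f"te_{lineno}"
            chroms.append(chrom)
            te_ids.append(te_id)
            s0.append(start_i - 1)
            e0.append(end_i)
            strands.append(_STRAND_MAP.get(strand, "."))
            sfs.append(attr.get(superfamily_key, "Unknown"))
    return TECatalog(te_ids, chroms, s0, e0, strands, sfs)


def _parse_gff_attributes(attrs: str) -> dict:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_te_gff(catalog: TECatalog, path: str | Path,
                 superfamily_key: str = "superfamily") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(catalog.n_tes):
            fh.write("\t".join([
                str(catalog.chrom[i]), "tepopgen", "transposable_element",
                str(catalog.start0[i] + 1), str(catalog.end0[i]), ".",
                str(catalog.strand[i]), ".",
                f"ID={catalog.te_ids[i]};{superfamily_key}={catalog.superfamily[i]}",
            ]) + "\n")


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a minimal biallelic VCF 4.2 (REF=A, ALT=T placeholders)."""
    gt_strings = np.array(["0/0", "0/1", "1/1"], dtype=object)
    order = np.lexsort((table.pos0, table.chrom.astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(table.chrom[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, table.samples)) + "\n")
        for j in order:
            gts = gt_strings[table.genotypes[:, j]]
            fh.write(f"{table.chrom[j]}\t{table.pos0[j] + 1}\t{table.snp_ids[j]}"
                     f"\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_metadata(table: GenotypeTable, path: str | Path) -> None:
    pd.DataFrame({
        "sample": table.samples,
        "population": table.population,
        "lineage": table.lineage,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic TSV round-trip helpers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV (float columns at full precision)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_annotations(codon_fold: str | Path | None = None,
                     snp_gene: str | Path | None = None,
                     gene_go: str | Path | None = None,
                     gene_essentiality: str | Path | None = None) -> AnnotationTables:
    """Load the optional annotation TSVs (codon fold is 1-based on disk)."""
    def _load(p):
        return pd.read_csv(p, sep="\t") if p is not None else None

    fold = _load(codon_fold)
    if fold is not None:
        fold = fold.rename(columns={"pos": "pos0"})
        fold["pos0"] = fold["pos0"].astype(np.int64) - 1
    return AnnotationTables(
        codon_fold=fold,
        snp_gene=_load(snp_gene),
        gene_go=_load(gene_go),
        gene_essentiality=_load(gene_essentiality),
    )
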