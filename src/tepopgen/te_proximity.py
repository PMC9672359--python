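"""Nearest-TE context for every SNP: distance, orientation, superfamily.

Distance is edge-to-position in bp, exclusive of the TE itself: a SNP on the
base adjacent to a TE edge is at distance 1 and a SNP inside the TE is at
distance 0 ("within").  Orientation ("sense") is TE-strand-aware by default:
for a + strand TE, positions past its end are downstream; for a - strand TE,
positions before its start are downstream.  TEs of unknown strand — and every
TE when ``sense_mode='genomic'`` — use genomic forward orientation (past the
end = downstream).  Ties in distance are broken by lowest TE start, then by
TE identifier, so the assignment is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import NO_TE, GenotypeTable, TECatalog

WITHIN, UPSTREAM, DOWNSTREAM = "within", "upstream", "downstream"
SENSE_NONE = "none"


@dataclass
class SNPTEContext:
    snp_id: str
    nearest_te_id: str
    superfamily: str
    distance_bp: int
    sense: str


def _sense_for(pos0: np.ndarray, start0: np.ndarray, end0: np.ndarray,
               strand: np.ndarray, within: np.ndarray, mode: str) -> np.ndarray:
    """Vectorised orientation rule for SNP/TE pairs."""
    beyond_end = pos0 >= end0  # past the TE in genomic forward orientation
    if mode == "genomic":
        down = beyond_end
    elif mode == "strand":
        minus = strand == "-"
        down = np.where(minus, ~beyond_end, beyond_end)
    else:
        raise ValueError(f"unknown sense mode {mode!r}")
    out = np.where(down, DOWNSTREAM, UPSTREAM).astype(object)
    out[within] = WITHIN
    return out


def _annotate_chrom(pos0: np.ndarray, cat_idx: np.ndarray, catalog: TECatalog,
                    mode: str, chunk: int = 256) -> tuple[np.ndarray, ...]:
    """Nearest-TE assignment for all SNPs of one chromosome.

    ``cat_idx`` indexes the catalog rows on this chromosome.  TEs are
    pre-sorted by (start, te_id) so that np.argmin's first-occurrence rule
    implements the tie-break.
    """
    start0 = catalog.start0[cat_idx]
    end0 = catalog.end0[cat_idx]
    ids = catalog.te_ids[cat_idx]
    order = np.lexsort((ids.astype(str), start0))
    cat_idx = cat_idx[order]
    start0, end0 = start0[order], end0[order]

    best = np.empty(len(pos0), dtype=np.int64)
    dist = np.empty(len(pos0), dtype=np.int64)
    for lo in range(0, len(pos0), chunk):
        p = pos0[lo:lo + chunk, None]
        # gap to the nearer edge; 0 inside the interval
        d = np.maximum(np.maximum(start0[None, :] - p, p - end0[None, :] + 1), 0)
        k = np.argmin(d, axis=1)
        best[lo:lo + chunk] = cat_idx[k]
        dist[lo:lo + chunk] = d[np.arange(len(k)), k]
    within = dist == 0
    sense = _sense_for(pos0, catalog.start0[best], catalog.end0[best],
                       catalog.strand[best], within, mode)
    return best, dist, sense


def nearest_te(chrom: str, pos0: int, catalog: TECatalog,
               sense_mode: str = "strand") -> SNPTEContext:
    """Nearest-TE context for a single SNP (0-based position)."""
    df = annotate_all_positions(np.array([chrom], dtype=object),
                                np.array([pos0]), np.array(["snp"], dtype=object),
                                catalog, sense_mode)
    r = df.iloc[0]
    return SNPTEContext(r["snp_id"], r["te_id"], r["superfamily"],
                        int(r["distance_bp"]), r["sense"])


def annotate_all_positions(chrom: np.ndarray, pos0: np.ndarray, snp_ids: np.ndarray,
                           catalog: TECatalog, sense_mode: str = "strand") -> pd.DataFrame:
    """Nearest-TE context per position; sentinel rows where the chromosome
    carries no TE (superfamily ``no_te``, distance -1, sense ``none``)."""
    n = len(pos0)
    te_id = np.full(n, "", dtype=object)
    superfamily = np.full(n, NO_TE, dtype=object)
    distance = np.full(n, -1, dtype=np.int64)
    sense = np.full(n, SENSE_NONE, dtype=object)

    cat_by_chrom: dict = {}
    for i, c in enumerate(catalog.chrom):
        cat_by_chrom.setdefault(c, []).append(i)

    for c, rows in pd.Series(range(n)).groupby(pd.Series(chrom, dtype=object)):
        idx = rows.to_numpy()
        if c not in cat_by_chrom:
            continue
        cat_idx = np.asarray(cat_by_chrom[c])
        best, dist, sns = _annotate_chrom(pos0[idx], cat_idx, catalog, sense_mode)
        te_id[idx] = catalog.te_ids[best]
        superfamily[idx] = catalog.superfamily[best]
        distance[idx] = dist
        sense[idx] = sns

    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos0": pos0,
        "te_id": te_id, "superfamily": superfamily,
        "distance_bp": distance, "sense": sense,
    })


def annotate_all(genotable: GenotypeTable, catalog: TECatalog,
                 sense_mode: str = "strand") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Context for every SNP of the table plus a per-superfamily summary.

    The summary counts SNPs per nearest superfamily and reports mean, min and
    max distance; its counts sum to the number of SNPs with a TE on their
    chromosome.
    """
    ctx = annotate_all_positions(genotable.chrom, genotable.pos0,
                                 genotable.snp_ids, catalog, sense_mode)
    annotated = ctx[ctx["superfamily"] != NO_TE]
    if annotated.empty:
        summary = pd.DataFrame(columns=["superfamily", "n_snps", "mean_distance",
                                        "min_distance", "max_distance"])
    else:
        summary = (annotated.groupby("superfamily")["distance_bp"]
                   .agg(n_snps="size", mean_distance="mean",
                        min_distance="min", max_distance="max")
                   .reset_index())
    return ctx, summary


def nearest_te_brute_force(chrom: str, pos0: int, catalog: TECatalog,
                           sense_mode: str = "strand") -> tuple[str, int, str]:
    """O(m) reference scan over every catalog entry; used as a test oracle."""
    best = None
    for i in range(catalog.n_tes):
        if catalog.chrom[i] != chrom:
            continue
        if catalog.start0[i] <= pos0 < catalog.end0[i]:
            d = 0
        elif pos0 < catalog.start0[i]:
            d = int(catalog.start0[i] - pos0)
        else:
            d = int(pos0 - catalog.end0[i] + 1)
        key = (d, int(catalog.start0[i]), str(catalog.te_ids[i]))
        if best is None or key < best[0]:
            best = (key, i)
    if best is None:
        return "", -1, SENSE_NONE
    i = best[1]
    d = best[0][0]
    if d == 0:
        sense = WITHIN
    else:
        beyond = pos0 >= catalog.end0[i]
        if sense_mode == "strand" and catalog.strand[i] == "-":
            beyond = not beyond
        sense = DOWNSTREAM if beyond else UPSTREAM
    return str(catalog.te_ids[i]), d, sense
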