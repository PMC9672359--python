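"""Cross-lineage outlier reproducibility, GO enrichment, essentiality ANOVA.

Per TE superfamily and orientation stratum (upstream / downstream) the
proportion of SNPs called balancing and divergent is computed; the Pearson
correlation of these proportions across two independently analysed lineages
measures whether superfamily-specific selection signatures reproduce.  GO
overrepresentation uses one-sided Fisher exact tests at the gene level
(classic per-term tests, no GO-graph decorrelation), and gene essentiality
(family copy number, Ka/Ks) is compared across selection class and
orientation by two-way type-II ANOVA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import hypergeom, pearsonr

from .selection_scan import BALANCING, DIVERGENT, bh_qvalues
from .te_proximity import DOWNSTREAM, UPSTREAM


# ---------------------------------------------------------------------------
# superfamily outlier profiles and cross-lineage correlation
# ---------------------------------------------------------------------------

def outlier_profiles(contexts: pd.DataFrame, calls: pd.DataFrame,
                     min_n: int = 5) -> pd.DataFrame:
    """Per superfamily x sense stratum: SNP count and the proportion of
    balancing and divergent calls.  Strata with no SNPs are omitted; strata
    with fewer than ``min_n`` SNPs are flagged low-confidence."""
    merged = contexts.merge(calls[["snp_id", "class"]], on="snp_id")
    merged = merged[merged["sense"].isin([UPSTREAM, DOWNSTREAM])]
    rows = []
    for (sf, sense), grp in merged.groupby(["superfamily", "sense"]):
        n = len(grp)
        rows.append({
            "superfamily": sf, "sense": sense, "n_snps": n,
            "prop_balancing": float((grp["class"] == BALANCING).mean()),
            "prop_divergent": float((grp["class"] == DIVERGENT).mean()),
            "low_confidence": n < min_n,
        })
    return pd.DataFrame(rows)


def cross_lineage_correlation(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
                              ) -> pd.DataFrame:
    """Pearson r of per-superfamily outlier proportions between two lineages,
    per sense stratum and selection type, over superfamilies present in both."""
    rows = []
    for sense in (UPSTREAM, DOWNSTREAM):
        a = profiles_a[profiles_a["sense"] == sense].set_index("superfamily")
        b = profiles_b[profiles_b["sense"] == sense].set_index("superfamily")
        shared = sorted(a.index.intersection(b.index))
        for sel, col in ((BALANCING, "prop_balancing"), (DIVERGENT, "prop_divergent")):
            if len(shared) < 3:
                rows.append((sense, sel, len(shared), np.nan, np.nan))
                continue
            x = a.loc[shared, col].to_numpy()
            y = b.loc[shared, col].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((sense, sel, len(shared), np.nan, np.nan))
                continue
            r, p = pearsonr(x, y)
            rows.append((sense, sel, len(shared), r, p))
    return pd.DataFrame(rows, columns=["sense", "selection", "n_superfamilies",
                                       "pearson_r", "p_value"])


def shared_outliers(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                    contexts_a: pd.DataFrame, contexts_b: pd.DataFrame
                    ) -> pd.DataFrame:
    """SNPs (matched by chrom+position) called non-neutral in both lineages."""
    def keyed(calls, ctx):
        df = calls.merge(ctx[["snp_id", "chrom", "pos0"]], on="snp_id")
        return df[df["class"] != "neutral"].set_index(["chrom", "pos0"])

    a, b = keyed(calls_a, contexts_a), keyed(calls_b, contexts_b)
    common = a.index.intersection(b.index)
    out = pd.DataFrame(index=common)
    out["class_a"] = a.loc[common, "class"]
    out["class_b"] = b.loc[common, "class"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def fisher_exact_pvalue(k: int, big_k: int, n: int, big_n: int) -> float:
    """One-sided overrepresentation p: P(X >= k) with X ~ Hypergeom(N, n, K),
    for k foreground genes carrying the term, K foreground genes, n universe
    genes carrying the term, N universe genes."""
    return float(hypergeom.sf(k - 1, big_n, n, big_k))


def fisher_enrichment(foreground_snps, background_snps, snp_gene: pd.DataFrame,
                      gene_go: pd.DataFrame, unit: str = "gene",
                      min_fg_genes: int = 2) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of the foreground SNP set.

    SNPs are deduplicated to genes before testing (``unit='snp'`` keeps
    SNP-level counting).  The universe is the background set; foreground
    members absent from it are added so the margins stay consistent.  Terms
    with fewer than ``min_fg_genes`` foreground genes are skipped.
    """
    if unit not in ("gene", "snp"):
        raise ValueError("unit must be 'gene' or 'snp'")
    mapping = snp_gene.set_index("snp_id")["gene"]

    def units(snps):
        snps = pd.Index(pd.unique(pd.Series(list(snps), dtype=object)))
        genes = mapping.reindex(snps).dropna()
        if unit == "gene":
            return set(genes.unique())
        return set(zip(genes.index, genes.to_numpy()))

    fg = units(foreground_snps)
    bg = units(background_snps) | fg
    if unit == "gene":
        term_members = gene_go.groupby("go_term")["gene"].agg(set)
    else:
        gg = gene_go.merge(snp_gene, on="gene")
        term_members = (gg.assign(u=list(zip(gg["snp_id"], gg["gene"])))
                        .groupby("go_term")["u"].agg(set))

    rows = []
    for term, members in term_members.items():
        in_fg = len(fg & members)
        in_bg = len(bg & members)
        if in_fg < min_fg_genes:
            continue
        p = fisher_exact_pvalue(in_fg, len(fg), in_bg, len(bg))
        odds = _odds_ratio(in_fg, len(fg), in_bg, len(bg))
        rows.append((term, in_fg, len(fg), in_bg, len(bg), odds, p))
    out = pd.DataFrame(rows, columns=["term", "fg_with_term", "fg_size",
                                      "bg_with_term", "bg_size",
                                      "odds_ratio", "p_value"])
    if not out.empty:
        out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out.sort_values("p_value").reset_index(drop=True)


def _odds_ratio(k: int, big_k: int, n: int, big_n: int) -> float:
    a, b = k, big_k - k
    c, d = n - k, (big_n - big_k) - (n - k)
    if b == 0 or c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# essentiality ANOVA
# ---------------------------------------------------------------------------

def essentiality_anova(gene_essentiality: pd.DataFrame, calls: pd.DataFrame,
                       contexts: pd.DataFrame, snp_gene: pd.DataFrame,
                       log_transform: bool = True) -> dict[str, pd.DataFrame]:
    """Two-way type-II ANOVA of gene essentiality on selection class x sense.

    Genes are deduplicated (first SNP mapping wins after sorting by snp_id);
    copy number and Ka/Ks are log1p-transformed by default for variance
    stabilization.  Returns one ANOVA table per essentiality measure.
    """
    df = (calls[["snp_id", "class"]]
          .merge(contexts[["snp_id", "sense"]], on="snp_id")
          .merge(snp_gene, on="snp_id"))
    df = df[df["sense"].isin([UPSTREAM, DOWNSTREAM])]
    df = df.sort_values("snp_id").drop_duplicates("gene")
    df = df.merge(gene_essentiality, on="gene")
    if df.empty:
        raise ValueError("no genes with essentiality measures after merging")

    tables = {}
    for measure in ("family_copy_number", "ka_ks"):
        y = df[measure].astype(float)
        df["_y"] = np.log1p(y) if log_transform else y
        ols = smf.ols("_y ~ C(sense) * C(selection)",
                      data=df.rename(columns={"class": "selection"})).fit()
        tables[measure] = sm.stats.anova_lm(ols, typ=2).reset_index(names="term")
    return tables
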