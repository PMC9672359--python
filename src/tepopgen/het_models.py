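"""The ladder of binomial cloglog heterozygosity models and the TE-Effect set.

The response is the per-SNP, per-relatedness-cluster heterozygote count out
of the cluster's sample count, modeled with a binomial likelihood and the
complementary log-log link log(-log(1 - p)).  The ladder:

* Model 0a (samples with F_IS > 0.6) and 0b (F_IS < 0.6):
  ``H ~ superfamily:sense + distance`` — exploratory, with the CACTA
  superfamily as reference level.  Superfamilies whose downstream coefficient
  is significantly positive under inbreeding (0a) but not in the outcrossed
  subset (0b) form the binary "TE Effect" grouping (H_TE vs H_0).
* Model 1: ``H ~ distance x TE-effect + TE-effect x sense + distance x sense``.
* Models 2a / 2b: ``H ~ F_IS x selection + sense x selection`` on the H_TE
  and H_0 subsets respectively.
* Model 3: ``H ~ TE-effect + sense`` on the independent outcrossing lineage,
  split at F_IS = -0.3.

Relatedness enters as fixed cluster intercepts by default; a single-variance
Laplace-approximated random intercept is available via
``cluster_handling='random'``.  Distance enters in kb, linear plus quadratic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .io_formats import NO_TE, GenotypeTable

logger = logging.getLogger("tepopgen")

H_TE, H_0 = "H_TE", "H_0"


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------

def build_observations(genotable: GenotypeTable, contexts: pd.DataFrame,
                       clusters: np.ndarray, fis: pd.DataFrame,
                       sample_mask: np.ndarray | None = None,
                       calls: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per SNP x relatedness cluster with the binomial response.

    ``sample_mask`` restricts to a sample subset (e.g. F_IS > 0.6); cells
    left without samples are dropped.  SNPs on chromosomes without TEs are
    excluded — they carry no proximity covariates.  ``mean_fis`` is the mean
    per-sample F_IS of the cell's samples.
    """
    if sample_mask is None:
        sample_mask = np.ones(genotable.n_samples, dtype=bool)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if not sample_mask.any():
        raise ValueError("sample subset is empty; no observations can be built")

    clusters = np.asarray(clusters)
    fis_values = fis.set_index("sample").loc[list(genotable.samples), "fis"].to_numpy()
    het = genotable.genotypes == 1

    frames = []
    for c in np.unique(clusters[sample_mask]):
        members = sample_mask & (clusters == c)
        n = int(members.sum())
        if n == 0:
            continue
        frames.append(pd.DataFrame({
            "snp_id": genotable.snp_ids,
            "cluster": c,
            "het_count": het[members].sum(axis=0),
            "n_samples": n,
            "mean_fis": float(np.nanmean(fis_values[members])),
        }))
    obs = pd.concat(frames, ignore_index=True)

    ctx_cols = contexts[["snp_id", "superfamily", "sense", "distance_bp"]]
    obs = obs.merge(ctx_cols, on="snp_id", how="left")
    obs = obs[obs["superfamily"] != NO_TE].reset_index(drop=True)
    obs["dist_kb"] = obs["distance_bp"] / 1000.0
    if calls is not None:
        obs = obs.merge(calls[["snp_id", "class"]].rename(columns={"class": "selection"}),
                        on="snp_id", how="left")
        obs["selection"] = obs["selection"].fillna("neutral")
    if obs.empty:
        raise ValueError("no observations remain after filtering")
    return obs


def assign_te_effect_group(obs: pd.DataFrame, te_effect_set: set[str]) -> pd.DataFrame:
    obs = obs.copy()
    obs["te_effect"] = np.where(obs["superfamily"].isin(te_effect_set), H_TE, H_0)
    return obs


# ---------------------------------------------------------------------------
# cloglog GLM
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted cloglog binomial model with its analysis of deviance."""

    model_id: str
    formula: str
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    deviance: float
    null_deviance: float
    n_obs: int
    converged: bool
    aliased: list[str] = field(default_factory=list)
    anova: pd.DataFrame | None = None
    cluster_handling: str = "fixed"
    random_intercept_var: float | None = None
    subset_rule: str = ""

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.params.index, "estimate": self.params.values,
                             "std_error": self.bse.values, "z": self.zvalues.values,
                             "p": self.pvalues.values})


def _binomial_family() -> sm.families.Binomial:
    return sm.families.Binomial(link=sm.families.links.CLogLog())


def _drop_aliased(design: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Keep a full-rank column subset (QR with pivoting); report the rest."""
    q, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    aliased = [names[i] for i in sorted(set(range(design.shape[1])) - set(keep))]
    return design[:, keep], [names[i] for i in keep], aliased


def fit_cloglog_binomial(obs: pd.DataFrame, formula_terms: list[str],
                         model_id: str = "", cluster_handling: str = "fixed",
                         anova_terms: list[str] | None = None,
                         subset_rule: str = "") -> ModelFit:
    """Fit the binomial cloglog GLM for an observation table.

    ``formula_terms`` are the right-hand-side terms (the cluster term is
    prepended automatically: fixed intercepts by default, a Laplace random
    intercept with ``cluster_handling='random'``).  Aliased design columns
    are dropped with a report.  Separation (|coef| > 15) triggers a
    Firth-style ridge-penalized refit.  A type-II analysis of deviance is
    computed for ``anova_terms`` (default: all non-cluster terms).
    """
    if cluster_handling not in ("fixed", "random"):
        raise ValueError("cluster_handling must be 'fixed' or 'random'")
    terms = list(formula_terms)
    fixed_cluster = cluster_handling == "fixed" and obs["cluster"].nunique() > 1
    rhs_terms = (["C(cluster)"] if fixed_cluster else []) + terms
    formula = "1 + " + " + ".join(rhs_terms) if rhs_terms else "1"

    design = patsy.dmatrix(formula, obs, return_type="dataframe")
    x, names, aliased = _drop_aliased(design.to_numpy(), list(design.columns))
    if aliased:
        logger.info("model %s: dropping aliased columns %s", model_id, aliased)
    endog = np.column_stack([obs["het_count"], obs["n_samples"] - obs["het_count"]])

    if cluster_handling == "random" and obs["cluster"].nunique() > 1:
        return _fit_random_intercept(obs, x, names, endog, formula, model_id,
                                     aliased, terms, anova_terms, subset_rule)

    res = sm.GLM(endog, x, family=_binomial_family()).fit(tol=1e-10, maxiter=200)
    params, bse = res.params, res.bse
    if np.max(np.abs(params)) > 15:
        logger.warning("model %s: separation suspected (|coef| > 15); "
                       "refitting with Firth-style ridge penalty", model_id)
        params, bse = _penalized_irls(x, endog)
        res_dev = _binomial_deviance(x @ params, endog)
    else:
        res_dev = res.deviance

    z = params / bse
    pvals = 2 * norm.sf(np.abs(z))
    fit = ModelFit(
        model_id=model_id, formula=formula,
        params=pd.Series(params, index=names), bse=pd.Series(bse, index=names),
        zvalues=pd.Series(z, index=names), pvalues=pd.Series(pvals, index=names),
        deviance=float(res_dev), null_deviance=float(res.null_deviance),
        n_obs=len(obs), converged=bool(getattr(res, "converged", True)),
        aliased=aliased, cluster_handling=cluster_handling,
        subset_rule=subset_rule,
    )
    fit.anova = _anova_type2(obs, endog, terms, anova_terms, fixed_cluster)
    return fit


def _binomial_deviance(eta: np.ndarray, endog: np.ndarray) -> float:
    p = np.clip(1 - np.exp(-np.exp(eta)), 1e-12, 1 - 1e-12)
    y, nf = endog[:, 0], endog.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y > 0, y * np.log(y / (nf * p)), 0.0) \
            + np.where(nf - y > 0, (nf - y) * np.log((nf - y) / (nf * (1 - p))), 0.0)
    return float(2 * ll.sum())


def _penalized_irls(x: np.ndarray, endog: np.ndarray, lam: float = 1e-3,
                    max_iter: int = 200, tol: float = 1e-10
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized IRLS for the cloglog binomial (separation fallback)."""
    y, nf = endog[:, 0], endog.sum(axis=1)
    beta = np.zeros(x.shape[1])
    pbar = np.clip(y.sum() / nf.sum(), 1e-6, 1 - 1e-6)
    beta[0] = np.log(-np.log(1 - pbar))
    for _ in range(max_iter):
        eta = x @ beta
        p = np.clip(1 - np.exp(-np.exp(eta)), 1e-10, 1 - 1e-10)
        dp_deta = np.exp(eta - np.exp(eta))            # dp/deta for cloglog
        w = nf * dp_deta ** 2 / (p * (1 - p))
        score = x.T @ ((y - nf * p) * dp_deta / (p * (1 - p))) - lam * beta
        info = x.T @ (w[:, None] * x) + lam * np.eye(x.shape[1])
        step = np.linalg.solve(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    p = np.clip(1 - np.exp(-np.exp(eta)), 1e-10, 1 - 1e-10)
    dp_deta = np.exp(eta - np.exp(eta))
    w = nf * dp_deta ** 2 / (p * (1 - p))
    cov = np.linalg.inv(x.T @ (w[:, None] * x) + lam * np.eye(x.shape[1]))
    return beta, np.sqrt(np.diag(cov))


def _term_factors(term: str) -> frozenset:
    return frozenset(f.strip() for f in term.split(":"))


def _anova_type2(obs: pd.DataFrame, endog: np.ndarray, terms: list[str],
                 anova_terms: list[str] | None,
                 fixed_cluster: bool) -> pd.DataFrame:
    """Type-II analysis of deviance: each term is tested against the model
    containing all terms that do not contain it, by likelihood ratio.
    The statistic is the deviance drop per degree of freedom (F-like)."""
    test_terms = anova_terms if anova_terms is not None else terms
    cluster_term = ["C(cluster)"] if fixed_cluster else []
    rows = []
    for term in test_terms:
        fac = _term_factors(term)
        others = [t for t in terms if not (fac <= _term_factors(t))]
        base_terms = cluster_term + others
        with_terms = base_terms + [term]
        dev_with, df_with = _fit_deviance(obs, endog, with_terms)
        dev_base, df_base = _fit_deviance(obs, endog, base_terms)
        df_term = max(df_with - df_base, 0)
        drop = max(dev_base - dev_with, 0.0)
        stat = drop / df_term if df_term else np.nan
        p = chi2.sf(drop, df_term) if df_term else np.nan
        rows.append((term, df_term, drop, stat, p))
    return pd.DataFrame(rows, columns=["term", "df", "deviance_drop",
                                       "statistic", "p"])


def _fit_deviance(obs: pd.DataFrame, endog: np.ndarray,
                  terms: list[str]) -> tuple[float, int]:
    formula = "1 + " + " + ".join(terms) if terms else "1"
    design = patsy.dmatrix(formula, obs, return_type="dataframe")
    x, _, _ = _drop_aliased(design.to_numpy(), list(design.columns))
    res = sm.GLM(endog, x, family=_binomial_family()).fit()
    return float(res.deviance), x.shape[1]


# ---------------------------------------------------------------------------
# Laplace random intercept (one variance component)
# ---------------------------------------------------------------------------

def _fit_random_intercept(obs, x, names, endog, formula, model_id, aliased,
                          terms, anova_terms, subset_rule) -> ModelFit:
    """Laplace-approximate ML for a cluster random intercept.

    Inner step: joint penalized IRLS over (beta, u) with u ~ N(0, s2 I);
    outer step: 1-D maximization of the Laplace log-likelihood over log s2.
    """
    codes, _ = pd.factorize(obs["cluster"])
    q = codes.max() + 1
    z = np.zeros((len(obs), q))
    z[np.arange(len(obs)), codes] = 1.0
    y, nf = endog[:, 0], endog.sum(axis=1)

    def inner(s2: float):
        xz = np.hstack([x, z])
        pen = np.zeros(xz.shape[1])
        pen[x.shape[1]:] = 1.0 / s2
        coef = np.zeros(xz.shape[1])
        pbar = np.clip(y.sum() / nf.sum(), 1e-6, 1 - 1e-6)
        coef[0] = np.log(-np.log(1 - pbar))
        for _ in range(200):
            eta = xz @ coef
            p = np.clip(1 - np.exp(-np.exp(eta)), 1e-10, 1 - 1e-10)
            dp = np.exp(eta - np.exp(eta))
            w = nf * dp ** 2 / (p * (1 - p))
            score = xz.T @ ((y - nf * p) * dp / (p * (1 - p))) - pen * coef
            info = xz.T @ (w[:, None] * xz) + np.diag(pen)
            step = np.linalg.solve(info, score)
            coef = coef + step
            if np.max(np.abs(step)) < 1e-9:
                break
        eta = xz @ coef
        p = np.clip(1 - np.exp(-np.exp(eta)), 1e-10, 1 - 1e-10)
        ll = float((y * np.log(p) + (nf - y) * np.log(1 - p)).sum())
        u = coef[x.shape[1]:]
        dp = np.exp(eta - np.exp(eta))
        w = nf * dp ** 2 / (p * (1 - p))
        h_uu = z.T @ (w[:, None] * z) + np.eye(q) / s2
        laplace = (ll - (u ** 2).sum() / (2 * s2) - 0.5 * q * np.log(s2)
                   - 0.5 * np.linalg.slogdet(h_uu)[1])
        return laplace, coef, info

    res = minimize_scalar(lambda t: -inner(np.exp(t))[0], bounds=(-8, 4),
                          method="bounded", options={"xatol": 1e-4})
    s2_hat = float(np.exp(res.x))
    _, coef, info = inner(s2_hat)
    cov = np.linalg.inv(info)[:x.shape[1], :x.shape[1]]
    params = coef[:x.shape[1]]
    bse = np.sqrt(np.diag(cov))
    zval = params / bse
    dev = _binomial_deviance(np.hstack([x, z]) @ coef, endog)
    fit = ModelFit(
        model_id=model_id, formula=formula + " + (1 | cluster)",
        params=pd.Series(params, index=names), bse=pd.Series(bse, index=names),
        zvalues=pd.Series(zval, index=names),
        pvalues=pd.Series(2 * norm.sf(np.abs(zval)), index=names),
        deviance=dev, null_deviance=np.nan, n_obs=len(obs), converged=True,
        aliased=aliased, cluster_handling="random",
        random_intercept_var=s2_hat, subset_rule=subset_rule,
    )
    fit.anova = _anova_type2(obs, endog, terms, anova_terms, True)
    return fit


# ---------------------------------------------------------------------------
# the ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderInputs:
    """Observation tables for each subset the ladder uses."""

    obs_high: pd.DataFrame                  # inbred samples, F_IS > 0.6
    obs_low: pd.DataFrame                   # outcrossed samples, F_IS < 0.6
    obs_all: pd.DataFrame                   # all samples (models 1, 2a, 2b)
    obs_europe_above: pd.DataFrame | None = None   # Europe, F_IS > -0.3
    obs_europe_below: pd.DataFrame | None = None   # Europe, F_IS < -0.3


@dataclass
class LadderResult:
    fits: dict
    te_effect_set: set
    skipped: list
    observations: pd.DataFrame              # obs_all with te_effect labels


def superfamily_sense_coefs(fit: ModelFit) -> pd.DataFrame:
    """Extract the superfamily-by-sense contrasts from a Model-0 fit."""
    pat = re.compile(r"\[T\.(?P<sf>[^\]]+)\]:C\(sense\)\[(?:T\.)?(?P<sense>[^\]]+)\]")
    rows = []
    for name in fit.params.index:
        m_ = pat.search(name)
        if m_ and "superfamily" in name:
            rows.append((m_["sf"], m_["sense"], fit.params[name], fit.pvalues[name]))
    return pd.DataFrame(rows, columns=["superfamily", "sense", "estimate", "p"])


def model0_terms(reference: str = "CACTA") -> list[str]:
    sf = f"C(superfamily, Treatment({reference!r}))"
    return ["C(sense)", f"{sf}:C(sense)", "dist_kb", "I(dist_kb**2)"]


def te_effect_membership(fit_high: ModelFit, fit_low: ModelFit,
                         senses: tuple = ("downstream",),
                         alpha: float = 0.05) -> set:
    """Superfamilies significantly positive under inbreeding (Model 0a) for
    any of the given sense strata and not significantly positive in the
    outcrossed subset (Model 0b)."""
    hi = superfamily_sense_coefs(fit_high)
    lo = superfamily_sense_coefs(fit_low)
    members = set()
    for sf in hi["superfamily"].unique():
        hi_rows = hi[(hi["superfamily"] == sf) & hi["sense"].isin(senses)]
        sig_high = ((hi_rows["estimate"] > 0) & (hi_rows["p"] < alpha)).any()
        lo_rows = lo[(lo["superfamily"] == sf) & lo["sense"].isin(senses)]
        sig_low = ((lo_rows["estimate"] > 0) & (lo_rows["p"] < alpha)).any()
        if sig_high and not sig_low:
            members.add(sf)
    return members


def model_ladder(inputs: LadderInputs, reference: str = "CACTA",
                 membership_senses: tuple = ("downstream",),
                 alpha: float = 0.05, cluster_handling: str = "fixed"
                 ) -> LadderResult:
    """Fit Models 0a/0b, derive the TE-Effect grouping, then Models 1-3."""
    fits: dict = {}
    skipped: list = []
    terms0 = model0_terms(reference)
    fits["0a"] = fit_cloglog_binomial(inputs.obs_high, terms0, "0a",
                                      cluster_handling, subset_rule="F_IS > 0.6")
    fits["0b"] = fit_cloglog_binomial(inputs.obs_low, terms0, "0b",
                                      cluster_handling, subset_rule="F_IS < 0.6")
    te_set = te_effect_membership(fits["0a"], fits["0b"], membership_senses, alpha)

    obs_all = assign_te_effect_group(inputs.obs_all, te_set)
    base1 = ["dist_kb", "I(dist_kb**2)", "C(sense)",
             "dist_kb:C(sense)", "I(dist_kb**2):C(sense)"]
    if len(te_set) > 0:
        terms1 = base1 + ["C(te_effect)", "dist_kb:C(te_effect)",
                          "I(dist_kb**2):C(te_effect)", "C(te_effect):C(sense)"]
    else:
        skipped.append(("1", "TE-Effect set empty; fitting distance/sense only"))
        terms1 = base1
    fits["1"] = fit_cloglog_binomial(obs_all, terms1, "1", cluster_handling)

    terms2 = ["mean_fis", "C(selection)", "C(sense)",
              "mean_fis:C(selection)", "C(sense):C(selection)"]
    if te_set and "selection" in obs_all.columns:
        fits["2a"] = fit_cloglog_binomial(obs_all[obs_all["te_effect"] == H_TE],
                                          terms2, "2a", cluster_handling,
                                          subset_rule="te_effect == H_TE")
    else:
        skipped.append(("2a", "TE-Effect set empty or no selection calls"))
    if "selection" in obs_all.columns:
        obs_2b = obs_all[obs_all["te_effect"] == H_0]
        if not obs_2b.empty:
            fits["2b"] = fit_cloglog_binomial(obs_2b, terms2, "2b",
                                              cluster_handling,
                                              subset_rule="te_effect == H_0")

    for key, obs_eu, rule in (("3_above", inputs.obs_europe_above, "Europe F_IS > -0.3"),
                              ("3_below", inputs.obs_europe_below, "Europe F_IS < -0.3")):
        if obs_eu is None:
            continue
        if not te_set:
            skipped.append((key, "TE-Effect set empty"))
            continue
        obs_eu = assign_te_effect_group(obs_eu, te_set)
        fits[key] = fit_cloglog_binomial(obs_eu, ["C(te_effect)", "C(sense)"],
                                         key, cluster_handling, subset_rule=rule)
    return LadderResult(fits, te_set, skipped, obs_all)
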