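"""Dual genome scan for selection signatures and the outlier classifier.

Two arms:

* **PCA-Mahalanobis scan** — genotypes are standardized per SNP by
  sqrt(2p(1-p)), samples are projected on the first K principal components,
  each SNP is regressed on the K score vectors, and the K regression z-scores
  are combined into a squared Mahalanobis distance under a robustly estimated
  z-score covariance.  Distances are rescaled by a genomic inflation factor
  (median d2 over the chi-square_K median) and converted to p-values via the
  chi-square_K tail; q-values are Benjamini-Hochberg.

* **Bayesian F_ST decomposition** — the logistic model
  F_ST(i,j) = 1 / (1 + exp(-(alpha_i + beta_j))) with locus effects alpha and
  population effects beta; alt-allele counts at locus i in population j are
  beta-binomial around an ancestral frequency mu_i with overdispersion set by
  F_ST(i,j).  A reversible-jump MCMC toggles inclusion of each alpha with
  prior odds for neutrality (default 10); the posterior inclusion frequency
  gives the posterior odds, and negative posterior-mean alphas point to
  balancing (or purifying) selection.

The classifier combines both arms: a significant locus effect with alpha < 0
is balancing; a significant locus effect with alpha > 0 — or, in 'combined'
mode, a PCA outlier (q < 0.01) whose W&C theta lies above the SNP-set
median — is divergent; everything else is neutral.  Negative-alpha SNPs are
further screened by the purifying-selection discrimination rule on minor
allele frequency and 0-fold/4-fold codon usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit
from scipy.stats import chi2
from sklearn.covariance import EmpiricalCovariance, MinCovDet

from .io_formats import GenotypeTable
from .popgen_stats import pc_scores

logger = logging.getLogger("tepopgen")

BALANCING, DIVERGENT, NEUTRAL = "balancing", "divergent", "neutral"


# ---------------------------------------------------------------------------
# PCA-Mahalanobis arm
# ---------------------------------------------------------------------------

def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(q, 0.0, 1.0)


def mahalanobis_d2(z: np.ndarray, robust: bool = True, seed: int = 0) -> np.ndarray:
    """Squared Mahalanobis distance of each row of ``z`` from the centre,
    under a minimum-covariance-determinant estimate of the covariance
    (empirical covariance for small inputs or with ``robust=False``).
    With identity covariance this reduces to the squared Euclidean norm of
    the centred rows."""
    k = z.shape[1]
    if robust and len(z) > 5 * k:
        cov = MinCovDet(random_state=seed).fit(z)
    else:
        cov = EmpiricalCovariance().fit(z)
    return cov.mahalanobis(z)  # distances from the fitted location


def pca_scan(genotable: GenotypeTable, k: int = 3, robust: bool = True,
             seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP Mahalanobis distance, genomic-inflation-corrected p and BH q.

    Returns the per-SNP frame and the (n_samples, k) PC score matrix used as
    the background-structure / relatedness representation.
    """
    g = genotable.genotypes.astype(float)
    p_hat = g.mean(axis=0) / 2.0
    if np.any((p_hat <= 0) | (p_hat >= 1)) or np.any(g.var(axis=0) == 0):
        raise ValueError("constant SNP column; filter monomorphic SNPs first")
    x = (g - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))

    scores = pc_scores(genotable, k)
    k = scores.shape[1]
    n = x.shape[0]

    # per-SNP least squares on the K score vectors (columns are centered,
    # so no intercept), z = beta / se
    sts_inv = np.linalg.inv(scores.T @ scores)
    betas = sts_inv @ scores.T @ x                      # (k, m)
    resid = x - scores @ betas
    dof = max(n - k, 1)
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(sts_inv), sigma2))
    z = (betas / se).T                                  # (m, k)

    d2 = mahalanobis_d2(z, robust=robust, seed=seed)

    gif = np.median(d2) / chi2.ppf(0.5, df=k)
    pvals = chi2.sf(d2 / gif, df=k)
    frame = pd.DataFrame({
        "snp_id": genotable.snp_ids,
        "mahalanobis_d2": d2,
        "p_value": pvals,
        "q_value": bh_qvalues(pvals),
    })
    frame.attrs["gif"] = float(gif)
    return frame, scores


# ---------------------------------------------------------------------------
# Bayesian F_ST decomposition (RJ-MCMC)
# ---------------------------------------------------------------------------

@dataclass
class MCMCSettings:
    """Chain settings; defaults are the desk-scale analysis configuration."""

    n_pilot: int = 10
    pilot_length: int = 1000
    burn_in: int = 5000
    n_iter: int = 25000
    thin: int = 10
    prior_odds: float = 10.0      # prior odds for neutrality (alpha excluded)
    alpha_prior_sd: float = 1.8
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    seed: int = 0

    def scaled(self, factor: float) -> "MCMCSettings":
        """Proportionally shorter chains, e.g. for tests."""
        return MCMCSettings(
            n_pilot=max(2, int(self.n_pilot * factor)),
            pilot_length=max(100, int(self.pilot_length * factor)),
            burn_in=max(200, int(self.burn_in * factor)),
            n_iter=max(500, int(self.n_iter * factor)),
            thin=self.thin, prior_odds=self.prior_odds,
            alpha_prior_sd=self.alpha_prior_sd,
            beta_prior_mean=self.beta_prior_mean,
            beta_prior_sd=self.beta_prior_sd, seed=self.seed)


def beta_binomial_loglik(alt: np.ndarray, tot: np.ndarray, mu: np.ndarray,
                         fst: np.ndarray) -> np.ndarray:
    """Elementwise beta-binomial log-likelihood of alt counts out of tot
    chromosomes, mean ``mu`` and overdispersion set by ``fst``."""
    fst = np.clip(fst, 1e-10, 1 - 1e-10)
    theta = (1.0 - fst) / fst
    a_par = mu * theta
    b_par = (1.0 - mu) * theta
    return (gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)
            + gammaln(alt + a_par) + gammaln(tot - alt + b_par)
            - gammaln(tot + a_par + b_par)
            + gammaln(a_par + b_par) - gammaln(a_par) - gammaln(b_par))


class _FstModel:
    """Cached-likelihood state for the RJ-MCMC sampler."""

    def __init__(self, alt: np.ndarray, tot: np.ndarray):
        self.alt = np.asarray(alt, dtype=float)
        self.tot = np.asarray(tot, dtype=float)
        self.m, self.j = alt.shape

    def loglik(self, mu: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
        fst = expit(alpha[:, None] + beta[None, :])
        return beta_binomial_loglik(self.alt, self.tot, mu[:, None], fst)

    def loglik_col(self, mu: np.ndarray, alpha: np.ndarray, beta_j: float,
                   j: int) -> np.ndarray:
        fst = expit(alpha + beta_j)
        return beta_binomial_loglik(self.alt[:, j], self.tot[:, j], mu, fst)


def fst_decomposition_mcmc(alt: np.ndarray, tot: np.ndarray,
                           settings: MCMCSettings | None = None,
                           snp_ids: np.ndarray | None = None,
                           fdr: float = 0.05
                           ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the reversible-jump MCMC over the locus/population decomposition.

    Parameters
    ----------
    alt, tot
        (n_snps, n_pops) alt-allele counts and chromosome totals.
    settings
        Chain lengths, priors and seed; see :class:`MCMCSettings`.
    fdr
        Bayesian false-discovery-rate bound for the selected outlier set
        (mean posterior probability of neutrality among selected loci).

    Returns
    -------
    per-locus frame (alpha_mean, post_inclusion, log10_PO, bayes_q,
    significant), per-population beta frame, diagnostics dict.
    """
    settings = settings or MCMCSettings()
    alt = np.asarray(alt)
    tot = np.asarray(tot)
    if alt.ndim != 2 or alt.shape != tot.shape:
        raise ValueError("alt and tot must be matching 2-D count arrays")
    if alt.shape[1] < 2:
        raise ValueError("at least two populations are required")
    model = _FstModel(alt, tot)
    m, j = model.m, model.j
    rng = np.random.default_rng(settings.seed)
    pi_incl = 1.0 / (1.0 + settings.prior_odds)

    # initial state: empirical mu, no locus effects, mildly negative betas
    mu = np.clip(alt.sum(axis=1) / tot.sum(axis=1), 0.01, 0.99)
    alpha = np.zeros(m)
    included = np.zeros(m, dtype=bool)
    beta = np.full(j, settings.beta_prior_mean)
    ll = model.loglik(mu, alpha, beta)

    s_mu = np.full(m, 0.5)
    s_alpha = np.full(m, 0.8)
    s_beta = np.full(j, 0.3)
    acc = {"mu": np.zeros(m), "alpha": np.zeros(m), "beta": np.zeros(j)}
    tries = {"mu": 0, "alpha": np.zeros(m), "beta": 0}

    def sweep(adapt: bool) -> None:
        nonlocal mu, alpha, included, beta, ll
        # --- ancestral frequencies (random walk on the logit scale; uniform
        # prior on mu => Jacobian term mu(1-mu))
        prop_mu = expit(logit(mu) + rng.normal(0, s_mu))
        ll_prop = model.loglik(prop_mu, alpha, beta)
        log_r = (ll_prop.sum(axis=1) - ll.sum(axis=1)
                 + np.log(prop_mu * (1 - prop_mu)) - np.log(mu * (1 - mu)))
        take = np.log(rng.random(m)) < log_r
        mu = np.where(take, prop_mu, mu)
        ll[take] = ll_prop[take]
        acc["mu"] += take
        tries["mu"] += 1

        # --- random-walk update of included alphas
        if included.any():
            prop_a = np.where(included, alpha + rng.normal(0, s_alpha), alpha)
            ll_prop = model.loglik(mu, prop_a, beta)
            log_r = (ll_prop.sum(axis=1) - ll.sum(axis=1)
                     + (alpha ** 2 - prop_a ** 2) / (2 * settings.alpha_prior_sd ** 2))
            take = included & (np.log(rng.random(m)) < log_r)
            alpha = np.where(take, prop_a, alpha)
            ll[take] = ll_prop[take]
            acc["alpha"] += take
            tries["alpha"] += included

        # --- reversible-jump toggle; the proposal for a new alpha is its
        # prior, so proposal density and prior cancel in the ratio
        prop_a = np.where(included, 0.0,
                          rng.normal(0, settings.alpha_prior_sd, m))
        ll_prop = model.loglik(mu, prop_a, beta)
        log_prior_odds = np.where(included,
                                  np.log((1 - pi_incl) / pi_incl),
                                  np.log(pi_incl / (1 - pi_incl)))
        log_r = ll_prop.sum(axis=1) - ll.sum(axis=1) + log_prior_odds
        take = np.log(rng.random(m)) < log_r
        alpha = np.where(take, prop_a, alpha)
        included = np.where(take, ~included, included)
        ll[take] = ll_prop[take]

        # --- population effects, one at a time
        for col in range(j):
            b_new = beta[col] + rng.normal(0, s_beta[col])
            ll_col = model.loglik_col(mu, alpha, b_new, col)
            log_r = (ll_col.sum() - ll[:, col].sum()
                     + ((beta[col] - settings.beta_prior_mean) ** 2
                        - (b_new - settings.beta_prior_mean) ** 2)
                     / (2 * settings.beta_prior_sd ** 2))
            if np.log(rng.random()) < log_r:
                beta[col] = b_new
                ll[:, col] = ll_col
                acc["beta"][col] += 1
        tries["beta"] += 1

        if adapt:
            pass  # adaptation is applied blockwise by the caller

    def adapt_scales() -> None:
        r_mu = acc["mu"] / max(tries["mu"], 1)
        s_mu[:] = np.clip(s_mu * np.exp(r_mu - 0.3), 0.05, 3.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r_a = np.where(tries["alpha"] > 0, acc["alpha"] / tries["alpha"], 0.3)
        s_alpha[:] = np.clip(s_alpha * np.exp(r_a - 0.3), 0.05, 3.0)
        r_b = acc["beta"] / max(tries["beta"], 1)
        s_beta[:] = np.clip(s_beta * np.exp(r_b - 0.3), 0.02, 2.0)
        acc["mu"][:] = 0
        acc["alpha"][:] = 0
        acc["beta"][:] = 0
        tries["mu"] = 0
        tries["alpha"] = np.zeros(m)
        tries["beta"] = 0

    # pilot blocks with proposal adaptation, then burn-in with frozen scales
    for _ in range(settings.n_pilot):
        for _ in range(settings.pilot_length):
            sweep(adapt=True)
        adapt_scales()
    for _ in range(settings.burn_in):
        sweep(adapt=False)

    n_kept = settings.n_iter // settings.thin
    alpha_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    beta_samples = np.empty((n_kept, j))
    kept = 0
    for it in range(settings.n_iter):
        sweep(adapt=False)
        if (it + 1) % settings.thin == 0:
            alpha_sum += alpha
            incl_sum += included
            beta_samples[kept] = beta
            kept += 1

    post_incl = incl_sum / kept
    p_clip = np.clip(post_incl, 1.0 / (2 * kept), 1 - 1.0 / (2 * kept))
    log10_po = np.log10(p_clip / (1 - p_clip))
    alpha_mean = alpha_sum / kept

    # Bayesian FDR: mean posterior neutrality probability of the selected set
    order = np.argsort(-post_incl)
    cum_fdr = np.cumsum(1 - post_incl[order]) / np.arange(1, m + 1)
    bayes_q = np.empty(m)
    bayes_q[order] = np.minimum.accumulate(cum_fdr[::-1])[::-1]
    significant = (log10_po > 0.5) & (bayes_q <= fdr)

    psrf = _split_psrf(beta_samples)
    diagnostics = {
        "psrf_beta": psrf,
        "max_psrf_beta": float(np.max(psrf)),
        "converged": bool(np.max(psrf) <= 1.1),
        "n_kept": kept,
        "proposal_scales": {"mu": s_mu.mean(), "alpha": s_alpha.mean(),
                            "beta": s_beta.mean()},
    }
    if not diagnostics["converged"]:
        logger.warning("MCMC convergence diagnostic: split-chain PSRF %.3f > 1.1",
                       diagnostics["max_psrf_beta"])
    ids = snp_ids if snp_ids is not None else np.arange(m)
    locus = pd.DataFrame({
        "snp_id": ids, "alpha_mean": alpha_mean, "post_inclusion": post_incl,
        "log10_PO": log10_po, "bayes_q": bayes_q, "significant": significant,
    })
    pops = pd.DataFrame({"population_index": np.arange(j),
                         "beta_mean": beta_samples.mean(axis=0),
                         "psrf": psrf})
    return locus, pops, diagnostics


def _split_psrf(samples: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per column."""
    n = (len(samples) // 2) * 2
    halves = samples[:n].reshape(2, n // 2, -1)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    b = (n // 2) * halves.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n // 2 - 1) / (n // 2) * w + b / (n // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(w > 0, np.sqrt(var_plus / w), 1.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ScanThresholds:
    q_cutoff: float = 0.01
    log10_po_cutoff: float = 0.5
    fdr: float = 0.05


def classify_selection(pca_frame: pd.DataFrame, mcmc_frame: pd.DataFrame,
                       theta: np.ndarray,
                       thresholds: ScanThresholds | None = None,
                       mode: str = "combined") -> pd.DataFrame:
    """Merge the two scan arms into per-SNP selection calls.

    Precedence: a significant locus effect decides first (negative alpha =>
    balancing, positive => divergent); in 'combined' mode a PCA outlier
    (q below cutoff) with theta above the SNP-set median is also divergent.
    """
    if mode not in ("combined", "bayescan-only"):
        raise ValueError("mode must be 'combined' or 'bayescan-only'")
    t = thresholds or ScanThresholds()
    frame = pca_frame.merge(mcmc_frame, on="snp_id", validate="1:1")
    frame["fst"] = np.asarray(theta)

    sig = frame["significant"] & (frame["log10_PO"] > t.log10_po_cutoff)
    balancing = sig & (frame["alpha_mean"] < 0)
    divergent = sig & (frame["alpha_mean"] > 0)
    if mode == "combined":
        pca_out = (frame["q_value"] < t.q_cutoff) & (frame["fst"] > frame["fst"].median())
        divergent |= pca_out & ~balancing

    frame["class"] = NEUTRAL
    frame.loc[divergent, "class"] = DIVERGENT
    frame.loc[balancing, "class"] = BALANCING
    frame["purifying_candidate"] = False
    return frame


def purifying_rule(calls: pd.DataFrame, maf: np.ndarray, fold: np.ndarray,
                   group_level: bool = True) -> pd.DataFrame:
    """Flag purifying-selection candidates among negative-alpha SNPs.

    Condition (i): the SNP's MAF is below the median MAF of neutral-class
    SNPs.  Condition (ii), group level: among negative-alpha SNPs with codon
    fold annotation, the median MAF of 0-fold (non-synonymous) SNPs is below
    the median of 4-fold (synonymous) ones.  A SNP is flagged iff (i) holds
    and ((ii) holds, or the SNP itself is 0-fold with MAF below the 4-fold
    median).  With ``group_level=False`` condition (ii) is evaluated per SNP:
    a negative-alpha SNP must itself be 0-fold with MAF below the 4-fold
    median.  Without any fold annotation the decision falls back to (i) alone
    with a logged warning.  Positive-alpha and neutral SNPs are never flagged;
    flagged SNPs otherwise classed balancing keep ``class='balancing'``.
    """
    calls = calls.copy()
    maf = np.asarray(maf, dtype=float)
    fold = np.asarray(fold, dtype=object)
    neg = (calls["alpha_mean"] < 0).to_numpy()
    neutral_maf = maf[(calls["class"] == NEUTRAL).to_numpy()]
    if len(neutral_maf) == 0:
        calls["purifying_candidate"] = False
        return calls
    cond_i = neg & (maf < np.median(neutral_maf))

    has_fold = fold != "none"
    zero_maf = maf[neg & (fold == "0-fold")]
    four_maf = maf[neg & (fold == "4-fold")]
    if not has_fold[neg].any() or len(four_maf) == 0:
        logger.warning("no codon-fold annotation among negative-alpha SNPs; "
                       "purifying rule decided on MAF condition alone")
        calls["purifying_candidate"] = cond_i
        return calls

    four_median = np.median(four_maf)
    cond_ii_group = len(zero_maf) > 0 and np.median(zero_maf) < four_median
    snp_is_low_zero = (fold == "0-fold") & (maf < four_median)
    if group_level:
        flag = cond_i & (cond_ii_group | snp_is_low_zero)
    else:
        flag = cond_i & snp_is_low_zero
    calls["purifying_candidate"] = flag
    return calls
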