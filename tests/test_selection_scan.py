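import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from tepopgen.io_formats import filter_genotypes
from tepopgen.popgen_stats import allele_counts_by_population
from tepopgen.selection_scan import (MCMCSettings, ScanThresholds, bh_qvalues,
                                     beta_binomial_loglik, classify_selection,
                                     fst_decomposition_mcmc, mahalanobis_d2,
                                     pca_scan, purifying_rule)
from tepopgen.synthetic_data import SimulationConfig, simulate_fixture
from tepopgen.validation import (_expected_purifying, purifying_rule_cases,
                                 purifying_rule_truth_table)

TINY = dict(n_pilot=2, pilot_length=60, burn_in=150, n_iter=600, thin=3)


def test_bh_qvalues_match_reference_procedure():
    rng = np.random.default_rng(0)
    p = rng.random(200) ** 2
    from statsmodels.stats.multitest import multipletests
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_qvalues(p), q_ref, atol=1e-12)


def test_mahalanobis_reduces_to_euclidean_under_identity_covariance():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(400, 3))
    z -= z.mean(axis=0)
    # whiten exactly so the empirical covariance is the identity
    cov = z.T @ z / len(z)
    w = np.linalg.cholesky(np.linalg.inv(cov))
    zw = z @ w
    d2 = mahalanobis_d2(zw, robust=False)
    np.testing.assert_allclose(d2, (zw ** 2).sum(axis=1), atol=1e-8)


class TestPcaScan:
    def test_constant_snp_column_rejected(self):
        from conftest import make_table
        table = make_table([[1, 0], [1, 2], [1, 1], [1, 0]], ["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="constant"):
            pca_scan(table, 1)

    def test_divergent_loci_get_smaller_q_values(self):
        cfg = SimulationConfig(seed=4, n_snps=1200, n_pops=6,
                               n_samples_per_pop=10, f_pop=[0.1] * 6,
                               class_proportions={"neutral": 0.9, "balancing": 0,
                                                  "divergent": 0.1, "purifying": 0})
        table, _, truth = simulate_fixture(cfg)
        table, _ = filter_genotypes(table)
        kept = truth.snp_frame.set_index("snp_id").loc[list(table.snp_ids)]
        frame, scores = pca_scan(table, 5, seed=0)
        div = (kept["planted_class"] == "divergent").to_numpy()
        assert frame.loc[div, "q_value"].median() < 0.01
        assert frame.loc[~div, "q_value"].median() > 0.5
        assert scores.shape == (table.n_samples, 5)
        assert 0.7 < frame.attrs["gif"] < 1.4


def test_beta_binomial_loglik_matches_numerical_integration():
    """The closed-form beta-binomial likelihood equals direct integration of
    binomial pmf times the beta mixing density."""
    cases = [(7, 20, 0.3, 0.08), (0, 14, 0.5, 0.25), (19, 20, 0.7, 0.02),
             (5, 36, 0.12, 0.6)]
    for alt, tot, mu, fst in cases:
        theta = (1 - fst) / fst
        a_par, b_par = mu * theta, (1 - mu) * theta
        val, err = integrate.quad(
            lambda p: binom.pmf(alt, tot, p) * beta_dist.pdf(p, a_par, b_par),
            0, 1, limit=200)
        got = beta_binomial_loglik(np.array([alt]), np.array([tot]),
                                   np.array([mu]), np.array([fst]))[0]
        assert got == pytest.approx(np.log(val), abs=1e-8)


@pytest.fixture(scope="module")
def counts():
    cfg = SimulationConfig(seed=6, n_snps=150, n_pops=3,
                           n_samples_per_pop=10, f_pop=[0.1] * 3,
                           class_proportions={"neutral": 0.9, "balancing": 0,
                                              "divergent": 0.1, "purifying": 0})
    table, _, _ = simulate_fixture(cfg)
    table, _ = filter_genotypes(table)
    _, alt, tot = allele_counts_by_population(table)
    return alt, tot


class TestMcmc:
    def test_identical_seed_gives_identical_chains(self, counts):
        alt, tot = counts
        s = MCMCSettings(seed=9, **TINY)
        a = fst_decomposition_mcmc(alt, tot, s)[0]
        b = fst_decomposition_mcmc(alt, tot, s)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_input_validation(self, counts):
        alt, tot = counts
        with pytest.raises(ValueError, match="two populations"):
            fst_decomposition_mcmc(alt[:, :1], tot[:, :1])
        with pytest.raises(ValueError, match="2-D"):
            fst_decomposition_mcmc(alt[:, 0], tot[:, 0])

    def test_alpha_increases_with_across_population_variance(self):
        """Posterior-mean locus effect is (weakly) monotone in planted
        differentiation along a 1-D sweep."""
        rng = np.random.default_rng(3)
        n_chrom = 60
        base = rng.binomial(n_chrom, 0.5, size=(160, 4))
        sweep = np.array([0.0, 0.12, 0.24, 0.36, 0.46])
        rows = []
        for d in sweep:
            freqs = np.array([0.5 - d, 0.5 + d, 0.5 - d, 0.5 + d])
            rows.append(np.round(freqs * n_chrom).astype(int))
        alt = np.vstack([base, np.array(rows)])
        tot = np.full_like(alt, n_chrom)
        settings = MCMCSettings(seed=2, n_pilot=2, pilot_length=150,
                                burn_in=400, n_iter=2500, thin=5)
        locus, _, _ = fst_decomposition_mcmc(alt, tot, settings)
        a = locus["alpha_mean"].to_numpy()[-len(sweep):]
        assert np.all(np.diff(a) > -0.25)       # weak monotonicity, MCMC noise
        assert a[-1] > a[0] + 1.0
        assert locus["log10_PO"].iloc[-1] > 0.5

    def test_diagnostics_reported(self, counts):
        alt, tot = counts
        _, pops, diag = fst_decomposition_mcmc(alt, tot,
                                               MCMCSettings(seed=1, **TINY))
        assert set(diag) >= {"psrf_beta", "converged", "n_kept"}
        assert len(pops) == alt.shape[1]


class TestClassify:
    def _frames(self, rows):
        pca = pd.DataFrame([{"snp_id": r["snp_id"], "mahalanobis_d2": 1.0,
                             "p_value": r.get("p", 0.5),
                             "q_value": r.get("q", 0.5)} for r in rows])
        mcmc = pd.DataFrame([{"snp_id": r["snp_id"],
                              "alpha_mean": r.get("alpha", 0.0),
                              "post_inclusion": 0.5,
                              "log10_PO": r.get("po", -1.0),
                              "bayes_q": r.get("bq", 1.0),
                              "significant": r.get("sig", False)}
                             for r in rows])
        return pca, mcmc

    def test_negative_alpha_with_strong_odds_is_balancing(self):
        pca, mcmc = self._frames([
            {"snp_id": "a", "po": 1.2, "alpha": -0.8, "sig": True, "bq": 0.01},
            {"snp_id": "b"}])
        calls = classify_selection(pca, mcmc, np.array([0.05, 0.30]))
        assert calls.set_index("snp_id")["class"].to_dict() == {
            "a": "balancing", "b": "neutral"}

    def test_below_all_thresholds_is_neutral(self):
        pca, mcmc = self._frames([{"snp_id": "a", "q": 0.5, "po": -0.3},
                                  {"snp_id": "b", "q": 0.5, "po": -0.3}])
        calls = classify_selection(pca, mcmc, np.array([0.1, 0.2]))
        assert (calls["class"] == "neutral").all()

    def test_pca_arm_calls_divergent_when_theta_high(self):
        rows = [{"snp_id": f"n{i}", "q": 0.8} for i in range(8)]
        rows.append({"snp_id": "hit", "q": 0.001, "po": 0.2, "alpha": 0.5})
        pca, mcmc = self._frames(rows)
        theta = np.array([0.02] * 8 + [0.45])   # top decile
        calls = classify_selection(pca, mcmc, theta)
        assert calls.set_index("snp_id").loc["hit", "class"] == "divergent"
        # bayescan-only mode ignores the PCA arm
        calls2 = classify_selection(pca, mcmc, theta, mode="bayescan-only")
        assert calls2.set_index("snp_id").loc["hit", "class"] == "neutral"

    def test_significant_positive_alpha_is_divergent(self):
        pca, mcmc = self._frames([
            {"snp_id": "a", "po": 0.9, "alpha": 1.4, "sig": True, "bq": 0.01},
            {"snp_id": "b"}])
        calls = classify_selection(pca, mcmc, np.array([0.4, 0.1]))
        assert calls.set_index("snp_id").loc["a", "class"] == "divergent"

    def test_unknown_mode_rejected(self):
        pca, mcmc = self._frames([{"snp_id": "a"}])
        with pytest.raises(ValueError):
            classify_selection(pca, mcmc, np.array([0.1]), mode="union")


class TestPurifyingRule:
    def test_truth_table_agreement(self):
        assert purifying_rule_truth_table()["agreement"] == 1.0

    def test_positive_alpha_and_neutral_never_flagged(self):
        cases = purifying_rule_cases()
        df = cases[cases["scenario"] == "A"].reset_index(drop=True)
        calls = purifying_rule(df[["snp_id", "alpha_mean", "class"]],
                               df["maf"].to_numpy(), df["fold"].to_numpy())
        flagged = calls[calls["purifying_candidate"]]
        assert (flagged["alpha_mean"] < 0).all()
        assert not flagged["class"].eq("neutral").any()

    def test_high_maf_negative_alpha_stays_balancing(self):
        df = pd.DataFrame({"snp_id": ["n1", "n2", "b"],
                           "alpha_mean": [0.0, 0.0, -0.9],
                           "class": ["neutral", "neutral", "balancing"]})
        maf = np.array([0.20, 0.24, 0.45])
        calls = purifying_rule(df, maf, np.array(["none"] * 3))
        assert not calls["purifying_candidate"].any()
        assert calls.loc[2, "class"] == "balancing"

    def test_missing_fold_annotation_falls_back_to_maf_condition(self, caplog):
        df = pd.DataFrame({"snp_id": ["n1", "n2", "b"],
                           "alpha_mean": [0.0, 0.0, -0.9],
                           "class": ["neutral", "neutral", "balancing"]})
        maf = np.array([0.20, 0.24, 0.05])
        with caplog.at_level("WARNING", logger="tepopgen"):
            calls = purifying_rule(df, maf, np.array(["none"] * 3))
        assert calls.loc[2, "purifying_candidate"]
        assert any("fold" in r.message for r in caplog.records)

    def test_per_snp_variant_requires_own_zero_fold(self):
        df = pd.DataFrame({"snp_id": ["n1", "n2", "z", "f"],
                           "alpha_mean": [0.0, 0.0, -0.5, -0.5],
                           "class": ["neutral", "neutral", "balancing",
                                     "balancing"]})
        maf = np.array([0.20, 0.24, 0.05, 0.06])
        fold = np.array(["none", "none", "0-fold", "4-fold"])
        calls = purifying_rule(df, maf, fold, group_level=False)
        got = calls.set_index("snp_id")["purifying_candidate"]
        assert got["z"] and not got["f"]


def test_scalar_expected_rule_covers_both_scenarios():
    # the oracle itself flags at least one SNP in A and exactly one in B
    cases = purifying_rule_cases()
    a = _expected_purifying(cases[cases["scenario"] == "A"].reset_index(drop=True))
    b = _expected_purifying(cases[cases["scenario"] == "B"].reset_index(drop=True))
    assert a.sum() >= 3 and b.sum() == 1
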