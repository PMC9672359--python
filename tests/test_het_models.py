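import math

import numpy as np
import pandas as pd
import pytest

from tepopgen.het_models import (H_0, H_TE, LadderInputs, assign_te_effect_group,
                                 build_observations, fit_cloglog_binomial,
                                 model_ladder, model0_terms,
                                 superfamily_sense_coefs)
from tepopgen.io_formats import filter_genotypes
from tepopgen.popgen_stats import relatedness_clusters, sample_fis
from tepopgen.synthetic_data import SimulationConfig, simulate_fixture
from tepopgen.te_proximity import annotate_all
from tepopgen.validation import glm_oracle
from conftest import make_table


# ---------------------------------------------------------------------------
# observation construction
# ---------------------------------------------------------------------------

def _toy_inputs():
    table = make_table([[1, 0], [0, 1], [1, 2], [2, 1]], ["p1", "p1", "p2", "p2"])
    contexts = pd.DataFrame({
        "snp_id": ["s0", "s1"], "superfamily": ["Copia", "CACTA"],
        "sense": ["downstream", "upstream"], "distance_bp": [1200, 300]})
    clusters = np.array([0, 0, 1, 1])
    fis = sample_fis(table)
    return table, contexts, clusters, fis


class TestBuildObservations:
    def test_toy_two_by_two_hand_assembled(self):
        table, contexts, clusters, fis = _toy_inputs()
        obs = build_observations(table, contexts, clusters, fis)
        assert len(obs) == 4  # 2 SNPs x 2 clusters
        cell = obs.set_index(["snp_id", "cluster"])
        # cluster 0 = samples 0,1 -> s0 genotypes (1, 0): one heterozygote
        assert cell.loc[("s0", 0), "het_count"] == 1
        assert cell.loc[("s1", 1), "het_count"] == 1  # genotypes (2, 1)
        assert (cell["n_samples"] == 2).all()
        assert cell.loc[("s0", 0), "dist_kb"] == pytest.approx(1.2)

    def test_empty_sample_subset_raises(self):
        table, contexts, clusters, fis = _toy_inputs()
        with pytest.raises(ValueError, match="empty"):
            build_observations(table, contexts, clusters, fis,
                               sample_mask=np.zeros(4, dtype=bool))

    def test_row_count_matches_snps_times_clusters(self):
        """1734 SNPs across 7 fully populated clusters give 12,138 rows."""
        rng = np.random.default_rng(0)
        n_snps, n_clusters = 1734, 7
        g = rng.integers(0, 3, size=(14, n_snps))
        table = make_table(g, [f"p{i}" for i in range(14)])
        contexts = pd.DataFrame({
            "snp_id": table.snp_ids, "superfamily": "Copia",
            "sense": "downstream", "distance_bp": 1000})
        clusters = np.repeat(np.arange(n_clusters), 2)
        fis = pd.DataFrame({"sample": table.samples, "fis": 0.0})
        obs = build_observations(table, contexts, clusters, fis)
        assert len(obs) == 12_138

    def test_no_te_sentinel_snps_excluded(self):
        table, contexts, clusters, fis = _toy_inputs()
        contexts.loc[1, "superfamily"] = "no_te"
        obs = build_observations(table, contexts, clusters, fis)
        assert set(obs["snp_id"]) == {"s0"}


# ---------------------------------------------------------------------------
# the GLM itself
# ---------------------------------------------------------------------------

class TestCloglogFit:
    def test_intercept_only_closed_form(self):
        df = pd.DataFrame({"het_count": [3, 5, 2, 7], "n_samples": [10] * 4,
                           "cluster": 0})
        fit = fit_cloglog_binomial(df, [])
        pbar = 17 / 40
        assert float(fit.params.iloc[0]) == pytest.approx(
            math.log(-math.log(1 - pbar)), abs=1e-10)

    def test_matches_independent_likelihood_maximization(self):
        assert glm_oracle(11)["max_coef_diff"] < 1e-6

    def test_irls_deviance_decreases_monotonically(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        x = np.column_stack([np.ones(200), rng.normal(size=200)])
        p = 1 - np.exp(-np.exp(-0.4 + 0.8 * x[:, 1]))
        y = rng.binomial(8, p)
        endog = np.column_stack([y, 8 - y])
        fam = sm.families.Binomial(link=sm.families.links.CLogLog())
        res = sm.GLM(endog, x, family=fam).fit()
        # history[0] is +inf and history[1] is evaluated at the data-based
        # starting values; the IRLS iterates proper begin at history[2]
        dev = res.fit_history["deviance"][2:]
        assert all(d2 <= d1 + 1e-8 for d1, d2 in zip(dev, dev[1:]))
        assert res.converged

    def test_aliased_columns_dropped_and_reported(self):
        df = pd.DataFrame({"het_count": [3, 5, 2, 7, 1, 4],
                           "n_samples": [10] * 6,
                           "x": [0.1, 0.4, -0.3, 0.8, 0.2, -0.5],
                           "cluster": 0})
        df["x_copy"] = df["x"]
        fit = fit_cloglog_binomial(df, ["x", "x_copy"])
        assert len(fit.aliased) == 1
        assert "x" in fit.params.index

    def test_separation_triggers_penalized_fallback(self, caplog):
        # one factor level has zero heterozygotes everywhere -> separation
        df = pd.DataFrame({"het_count": [0, 0, 0, 6, 7, 5],
                           "n_samples": [8] * 6,
                           "g": ["a", "a", "a", "b", "b", "b"],
                           "cluster": 0})
        with caplog.at_level("WARNING", logger="tepopgen"):
            fit = fit_cloglog_binomial(df, ["C(g)"])
        assert np.isfinite(fit.params).all()
        assert np.max(np.abs(fit.params)) < 15
        assert any("separation" in r.message for r in caplog.records)

    def test_wald_interval_coverage_on_simulated_fits(self):
        """95% Wald CIs cover the generating coefficients in most replicates
        (true downstream effect 0.5, zero distance effect)."""
        rng = np.random.default_rng(7)
        n_rows, n_bin = 400, 12
        cover_sense = cover_dist = reps = 0
        for _ in range(120):
            sense = rng.choice(["upstream", "downstream"], n_rows)
            dist = rng.uniform(0, 5, n_rows)
            eta = -1.0 + 0.5 * (sense == "downstream") + 0.0 * dist
            y = rng.binomial(n_bin, 1 - np.exp(-np.exp(eta)))
            df = pd.DataFrame({"het_count": y, "n_samples": n_bin,
                               "sense": sense, "dist_kb": dist, "cluster": 0})
            fit = fit_cloglog_binomial(df, ["C(sense)", "dist_kb"])
            for name, truth_val, which in [
                    ("C(sense)[T.upstream]", -0.5, "sense"),
                    ("dist_kb", 0.0, "dist")]:
                lo = fit.params[name] - 1.96 * fit.bse[name]
                hi = fit.params[name] + 1.96 * fit.bse[name]
                hitit = lo <= truth_val <= hi
                if which == "sense":
                    cover_sense += hitit
                else:
                    cover_dist += hitit
            reps += 1
        assert cover_sense / reps >= 0.90
        assert cover_dist / reps >= 0.90

    def test_anova_tests_the_informative_term(self):
        rng = np.random.default_rng(9)
        n = 600
        g = rng.choice(["u", "d"], n)
        noise = rng.normal(size=n)
        eta = -1.0 + 0.8 * (g == "d")
        y = rng.binomial(10, 1 - np.exp(-np.exp(eta)))
        df = pd.DataFrame({"het_count": y, "n_samples": 10, "g": g,
                           "x": noise, "cluster": 0})
        fit = fit_cloglog_binomial(df, ["C(g)", "x"])
        an = fit.anova.set_index("term")
        assert an.loc["C(g)", "p"] < 1e-6
        assert an.loc["x", "p"] > 0.01
        assert (an["df"] == 1).all()

    def test_random_intercept_agrees_in_sign_with_fixed(self):
        rng = np.random.default_rng(4)
        n = 900
        cluster = rng.integers(0, 3, n)
        sense = rng.choice(["upstream", "downstream"], n)
        u = np.array([-0.4, 0.1, 0.5])[cluster]
        eta = -1.0 + 0.7 * (sense == "downstream") + u
        y = rng.binomial(10, 1 - np.exp(-np.exp(eta)))
        df = pd.DataFrame({"het_count": y, "n_samples": 10, "sense": sense,
                           "cluster": cluster})
        fixed = fit_cloglog_binomial(df, ["C(sense)"], cluster_handling="fixed")
        rand = fit_cloglog_binomial(df, ["C(sense)"], cluster_handling="random")
        name = "C(sense)[T.upstream]"
        assert np.sign(fixed.params[name]) == np.sign(rand.params[name])
        assert rand.random_intercept_var > 0
        assert abs(fixed.params[name] - rand.params[name]) < 0.15


# ---------------------------------------------------------------------------
# the ladder
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_ladder():
    cfg = SimulationConfig(seed=1, n_snps=1500, n_pops=6, n_samples_per_pop=8,
                           f_pop=[0.8] * 3 + [0.0] * 3,
                           class_proportions={"neutral": 0.9, "balancing": 0.02,
                                              "divergent": 0.05, "purifying": 0.03})
    table, catalog, truth = simulate_fixture(cfg)
    table, _ = filter_genotypes(table)
    ctx, _ = annotate_all(table, catalog)
    fis = sample_fis(table)
    fv = fis.set_index("sample").loc[list(table.samples), "fis"].to_numpy()
    clusters = relatedness_clusters(table, 3, 2, seed=0)
    calls = pd.DataFrame({"snp_id": table.snp_ids, "class": "neutral"})
    obs = lambda mask: build_observations(table, ctx, clusters, fis,
                                          sample_mask=mask, calls=calls)
    inputs = LadderInputs(obs_hi := obs(fv > 0.6), obs(fv < 0.6), obs(None),
                          obs_europe_above=obs(fv < 0.6))
    return model_ladder(inputs)


class TestModelLadder:
    def test_planted_superfamilies_recovered(self, planted_ladder):
        assert {"Copia", "Harbinger"} <= planted_ladder.te_effect_set
        assert "CACTA" not in planted_ladder.te_effect_set

    def test_ladder_fits_all_models(self, planted_ladder):
        assert {"0a", "0b", "1", "2a", "2b", "3_above"} <= set(planted_ladder.fits)
        fit1 = planted_ladder.fits["1"]
        assert any("te_effect" in t for t in fit1.params.index)
        assert any("dist_kb" in t for t in fit1.params.index)

    def test_te_effect_groups_assigned(self, planted_ladder):
        obs = planted_ladder.observations
        grouped = obs.groupby("te_effect")["superfamily"].unique()
        assert set(grouped[H_TE]) == planted_ladder.te_effect_set
        assert "CACTA" in set(grouped[H_0])

    def test_model0_reference_level_is_cacta(self, planted_ladder):
        coefs = superfamily_sense_coefs(planted_ladder.fits["0a"])
        assert "CACTA" not in set(coefs["superfamily"])
        assert set(coefs["sense"]) <= {"within", "upstream", "downstream"}

    def test_deviance_of_nested_model_not_smaller(self, planted_ladder):
        # Model 1 nests its distance/sense submodel: the anova deviance drops
        # are all non-negative by construction
        an = planted_ladder.fits["1"].anova
        assert (an["deviance_drop"] >= 0).all()


def test_empty_te_effect_set_skips_dependent_models():
    rng = np.random.default_rng(0)
    n_snps = 300
    g = rng.integers(0, 3, size=(12, n_snps))
    table = make_table(g, [f"p{i // 2}" for i in range(12)])
    sfs = rng.choice(["CACTA", "Copia", "Gypsy"], n_snps)
    contexts = pd.DataFrame({"snp_id": table.snp_ids, "superfamily": sfs,
                             "sense": rng.choice(["upstream", "downstream"], n_snps),
                             "distance_bp": rng.integers(1, 5000, n_snps)})
    clusters = np.repeat([0, 1], 6)
    fis = pd.DataFrame({"sample": table.samples, "fis": 0.0})
    obs = build_observations(table, contexts, clusters, fis)
    result = model_ladder(LadderInputs(obs, obs, obs,
                                       obs_europe_above=obs))
    if not result.te_effect_set:
        skipped_ids = {s[0] for s in result.skipped}
        assert "2a" in skipped_ids and "3_above" in skipped_ids
        assert (result.observations["te_effect"] == H_0).all()


def test_model0_term_list_uses_reference():
    terms = model0_terms("CACTA")
    assert any("Treatment('CACTA')" in t for t in terms)
    assert "dist_kb" in terms and "I(dist_kb**2)" in terms
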