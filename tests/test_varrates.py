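"""Variable-rates rjMCMC, stepping-stone marginal likelihoods, shift
detection, ESS diagnostics, and group tests on branch rates."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from skelevol.phylo import bm_covariance, tree_arrays
from skelevol.synthdata import SimConfig, sim_bm_traits, sim_tree
from skelevol.varrates import (
    Chain,
    ChainSettings,
    bayes_factor,
    bm_profile_loglik,
    branch_rate_table,
    detect_shifts,
    effective_sample_size,
    rate_level_test,
    rate_variance_test,
    rjmcmc_rates,
    stepping_stone,
)
from skelevol.varrates import _prune

from conftest import random_tree


def _dense_profile_loglik(phy, Y, sigma2):
    """Oracle: dense-matrix GLS likelihood at the profiled root."""
    Y = np.atleast_2d(Y)
    cov = bm_covariance(phy)
    C = cov.C
    n = C.shape[0]
    sign, logdet = np.linalg.slogdet(C)
    a = cov.gls_mean(Y)
    R = Y - a
    out = 0.0
    for j, s2 in enumerate(np.broadcast_to(sigma2, (Y.shape[1],))):
        ss = R[:, j] @ np.linalg.solve(C, R[:, j])
        out += -0.5 * (n * math.log(2 * math.pi * s2) + logdet + ss / s2)
    return out


class TestLikelihood:
    def test_pruning_matches_dense_gls_oracle(self, rng):
        phy = random_tree(12, rng, crown_age=3.0)
        Y = sim_bm_traits(phy, np.eye(3), seed=4).to_numpy()
        for s2 in ([1.0, 1.0, 1.0], [0.5, 2.0, 7.0]):
            got = bm_profile_loglik(phy, Y, sigma2=np.array(s2))
            want = _dense_profile_loglik(phy, Y, np.array(s2))
            assert got == pytest.approx(want, abs=1e-6)

    def test_equal_rate_mode_at_ml_sigma(self, rng):
        # analytic ML rate: sigma2_hat = SS / N; likelihood there must
        # agree with the dense oracle to 1e-6
        phy = random_tree(15, rng)
        Y = sim_bm_traits(phy, np.eye(1), seed=2).to_numpy()
        ta = tree_arrays(phy)
        _, ss, _ = _prune(ta, ta.length, Y)
        s2_hat = ss[0] / ta.n_tips
        got = bm_profile_loglik(phy, Y, sigma2=s2_hat)
        want = _dense_profile_loglik(phy, Y, np.array([s2_hat]))
        assert got == pytest.approx(want, abs=1e-6)

    def test_unit_scalars_equal_no_scalars(self, rng):
        phy = random_tree(10, rng)
        Y = sim_bm_traits(phy, np.eye(2), seed=3).to_numpy()
        ta = tree_arrays(phy)
        base = bm_profile_loglik(phy, Y, sigma2=1.0)
        withones = bm_profile_loglik(phy, Y, sigma2=1.0,
                                     edge_rates=np.ones(ta.n_nodes))
        assert withones == pytest.approx(base, abs=1e-12)


def _chain_with(scalars_list, ta):
    n = len(scalars_list)
    return Chain(
        ta=ta,
        settings=ChainSettings(),
        seed=0,
        loglik=np.zeros(n),
        n_scalars=np.array([len(s) for s in scalars_list]),
        scalars=scalars_list,
        base_rates=np.ones((n, 1)),
        edge_log_rates=np.zeros((n, ta.n_nodes)),
        acceptance={},
    )


class TestShiftDetection:
    def test_empty_chain_gives_empty_list(self, rng):
        ta = tree_arrays(random_tree(6, rng))
        out = detect_shifts(_chain_with([{} for _ in range(10)], ta))
        assert len(out) == 0

    def test_threshold_arithmetic(self, rng):
        ta = tree_arrays(random_tree(6, rng))
        loc = ("branch", 2)
        scalars = [{loc: 4.0} if i < 6 else {} for i in range(10)]
        out = detect_shifts(_chain_with(scalars, ta), threshold=0.5)
        assert len(out) == 1
        assert out.iloc[0]["frequency"] == pytest.approx(0.6)
        assert out.iloc[0]["kind"] == "branch"
        assert out.iloc[0]["magnitude"] == pytest.approx(4.0)

    def test_monotone_in_threshold(self, rng):
        ta = tree_arrays(random_tree(8, rng))
        rs = np.random.default_rng(5)
        scalars = []
        for _ in range(50):
            s = {}
            for v in range(1, 6):
                if rs.random() < v / 6:
                    s[("branch", v)] = 2.0
            scalars.append(s)
        ch = _chain_with(scalars, ta)
        low = set(detect_shifts(ch, 0.5)["location"])
        high = set(detect_shifts(ch, 0.7)["location"])
        assert high <= low


class TestRjmcmc:
    def test_single_rate_data_recovers_null(self, rng):
        phy = random_tree(20, rng, crown_age=5.0)
        Y = sim_bm_traits(phy, np.eye(2), seed=6).to_numpy()
        ch = rjmcmc_rates(
            Y, phy, ChainSettings(iterations=60_000, thinning=30), seed=2
        )
        k_mode = np.bincount(ch.n_scalars).argmax()
        assert k_mode == 0
        mean_logr = ch.edge_log_rates.mean(axis=0)
        assert np.abs(mean_logr).max() < 0.5
        assert np.abs(mean_logr).mean() < 0.3

    def test_planted_clade_scalar_detected(self, rng):
        cfg = SimConfig(
            seed=99,
            n_species={"GreaterAntilles": 12, "PrimaryMainland": 14,
                       "SecondaryMainland": 14},
            rate_scalars={"GreaterAntilles": 10.0},
        )
        phy, groups = sim_tree(cfg)
        Y = sim_bm_traits(phy, np.eye(3), rate_scalars=cfg.rate_scalars,
                          groups=groups, seed=100).to_numpy()
        ch = rjmcmc_rates(
            Y, phy, ChainSettings(iterations=100_000, thinning=50), seed=3
        )
        shifts = detect_shifts(ch, threshold=0.5)
        # the GA crown/stem region must carry a supported shift whose
        # scope covers the GA clade
        ga_tips = {t for t, g in groups.items() if g == "GreaterAntilles"}
        ta = ch.ta
        found = False
        for row in shifts.itertuples():
            if row.kind != "node":
                continue
            v = int(row.location.replace("node", ""))
            clade_tips = {
                ta.tip_labels[e] for e in ta.clade_edges(v) if e < ta.n_tips
            }
            if clade_tips == ga_tips and row.magnitude > 3:
                found = True
        assert found

    def test_reproducible_given_seed(self, rng):
        phy = random_tree(10, rng)
        Y = sim_bm_traits(phy, np.eye(2), seed=1).to_numpy()
        c1 = rjmcmc_rates(Y, phy, ChainSettings(iterations=5000, thinning=10),
                          seed=7)
        c2 = rjmcmc_rates(Y, phy, ChainSettings(iterations=5000, thinning=10),
                          seed=7)
        assert np.array_equal(c1.loglik, c2.loglik)
        assert np.array_equal(c1.edge_log_rates, c2.edge_log_rates)


class TestSteppingStone:
    @staticmethod
    def _conjugate_log_ml(phy, Y, a0, b0):
        ta = tree_arrays(phy)
        logdet, ss, _ = _prune(ta, ta.length, Y)
        n = ta.n_tips
        out = 0.0
        for j in range(Y.shape[1]):
            out += (
                -(n / 2) * math.log(2 * math.pi)
                - 0.5 * logdet
                + a0 * math.log(b0)
                - gammaln(a0)
                + gammaln(a0 + n / 2)
                - (a0 + n / 2) * math.log(b0 + ss[j] / 2)
            )
        return out

    def test_matches_conjugate_closed_form(self, rng):
        phy = random_tree(15, rng, crown_age=2.0)
        Y = sim_bm_traits(phy, np.eye(2), seed=9).to_numpy()
        want = self._conjugate_log_ml(phy, Y, a0=2.0, b0=1.0)
        got = stepping_stone(
            Y, phy, model="equal", n_stones=16, iterations_per_stone=6000,
            settings=ChainSettings(iterations=6000, burnin=0.3, thinning=5,
                                   ig_alpha=2.0, ig_beta=1.0),
            seed=4,
        )
        assert abs(got - want) < 0.2

    def test_equal_rate_data_small_bayes_factor(self, rng):
        phy = random_tree(12, rng, crown_age=3.0)
        Y = sim_bm_traits(phy, np.eye(2), seed=21).to_numpy()
        common = dict(n_stones=12, iterations_per_stone=6000,
                      settings=ChainSettings(iterations=6000, burnin=0.3,
                                             thinning=5))
        ml_var = stepping_stone(Y, phy, model="variable", seed=5, **common)
        ml_eq = stepping_stone(Y, phy, model="equal", seed=5, **common)
        assert bayes_factor(ml_var, ml_eq) < 2.0

    def test_planted_heterogeneity_strong_bayes_factor(self, rng):
        cfg = SimConfig(
            seed=31,
            n_species={"GreaterAntilles": 10, "PrimaryMainland": 5,
                       "SecondaryMainland": 10},
            rate_scalars={"GreaterAntilles": 30.0},
        )
        phy, groups = sim_tree(cfg)
        Y = sim_bm_traits(phy, np.eye(2), rate_scalars=cfg.rate_scalars,
                          groups=groups, seed=32).to_numpy()
        common = dict(n_stones=12, iterations_per_stone=6000,
                      settings=ChainSettings(iterations=6000, burnin=0.3,
                                             thinning=5))
        ml_var = stepping_stone(Y, phy, model="variable", seed=6, **common)
        ml_eq = stepping_stone(Y, phy, model="equal", seed=6, **common)
        assert bayes_factor(ml_var, ml_eq) > 4.0

    def test_too_few_stones_rejected(self, rng):
        phy = random_tree(6, rng)
        Y = sim_bm_traits(phy, np.eye(1), seed=0).to_numpy()
        with pytest.raises(ValueError, match="10 stones"):
            stepping_stone(Y, phy, n_stones=5)


class TestEss:
    def test_white_noise_ess_near_n(self, rng):
        x = rng.standard_normal(4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.1)

    def test_ar1_matches_analytic_formula(self, rng):
        phi = 0.9
        n = 60_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        want = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(want, rel=0.2)

    def test_identical_runs_average_to_either(self, rng):
        phy = random_tree(8, rng)
        Y = sim_bm_traits(phy, np.eye(1), seed=1).to_numpy()
        ch = rjmcmc_rates(Y, phy, ChainSettings(iterations=4000, thinning=10),
                          seed=5)
        t1 = branch_rate_table(ch)
        t2 = branch_rate_table([ch, ch])
        assert np.allclose(t1["mean_log_rate"], t2["mean_log_rate"])

    def test_mismatched_trees_rejected(self, rng):
        phy1 = random_tree(8, rng)
        phy2 = random_tree(9, rng)
        Y1 = sim_bm_traits(phy1, np.eye(1), seed=1).to_numpy()
        Y2 = sim_bm_traits(phy2, np.eye(1), seed=1).to_numpy()
        c1 = rjmcmc_rates(Y1, phy1, ChainSettings(iterations=2000, thinning=10),
                          seed=0)
        c2 = rjmcmc_rates(Y2, phy2, ChainSettings(iterations=2000, thinning=10),
                          seed=0)
        with pytest.raises(ValueError, match="different trees"):
            branch_rate_table([c1, c2])


def _btab(groups_rates):
    rows = []
    for g, rates in groups_rates.items():
        for i, r in enumerate(rates):
            rows.append({"branch": f"{g}{i}", "mean_log_rate": r, "group": g})
    return pd.DataFrame(rows)


class TestGroupTests:
    def test_identical_rate_multisets_f_zero(self):
        tab = _btab({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = rate_variance_test(tab)
        assert res.F == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_levene_median_oracle(self):
        g1, g2 = [1.0, 2.0, 3.0], [1.0, 2.0, 10.0]
        tab = _btab({"a": g1, "b": g2})
        res = rate_variance_test(tab)
        # independent route: scipy's Brown-Forsythe (median-centered Levene)
        W, p = stats.levene(g1, g2, center="median")
        assert res.F == pytest.approx(W, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        # and the fully explicit ANOVA on |x - median| deviations
        F, p2 = stats.f_oneway([1.0, 0.0, 1.0], [1.0, 0.0, 8.0])
        assert res.F == pytest.approx(F, rel=1e-10)

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            tab = _btab({"a": rng.standard_normal(20),
                         "b": rng.standard_normal(20)})
            if rate_variance_test(tab).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08

    def test_kruskal_identical_groups(self):
        tab = _btab({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = rate_level_test(tab)
        assert res["p_value"] > 0.5

    def test_kruskal_known_h(self):
        tab = _btab({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
                     "c": [7.0, 8.0, 9.0]})
        res = rate_level_test(tab)
        assert res["H"] == pytest.approx(7.2)

    def test_kruskal_power_on_shifted_groups(self, rng):
        hits = 0
        for _ in range(50):
            tab = _btab({"a": rng.standard_normal(50),
                         "b": rng.standard_normal(50) + 1.0})
            if rate_level_test(tab)["p_value"] < 0.05:
                hits += 1
        assert hits >= 46

    def test_all_tied_data(self):
        tab = _btab({"a": [1.0] * 4, "b": [1.0] * 4})
        res = rate_level_test(tab)
        assert res["H"] == 0.0 and res["p_value"] == 1.0
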