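import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ncflow import bh_adjust, build_design, de_table, ebayes, fit_linear, nb_glm_de
from ncflow.diffexpr import (
    _fit_f_dist,
    _nb_irls,
    _profile_dispersion,
    trigamma_inverse,
)
from ncflow.errors import ValidationError


def make_meta(groups, **covs):
    meta = pd.DataFrame({"group": groups},
                        index=[f"S{i}" for i in range(len(groups))])
    for name, values in covs.items():
        meta[name] = values
    return meta


class TestBuildDesign:
    def test_three_group_design_columns(self):
        design = build_design(make_meta(["TA", "TA", "SSL", "TV"]), "TA")
        assert list(design.matrix.columns) == ["intercept", "group_SSL", "group_TV"]
        assert design.matrix.shape == (4, 3)
        assert design.matrix["group_SSL"].tolist() == [0, 0, 1, 0]

    def test_constant_covariate_raises_rank_error(self):
        meta = make_meta(["TA", "TA", "SSL", "SSL"], batch=[1, 1, 1, 1])
        with pytest.raises(ValidationError, match="batch"):
            build_design(meta, "TA", covariates=["batch"])

    def test_w_adds_one_column(self):
        meta = make_meta(["TA", "TA", "SSL", "SSL"])
        W = pd.DataFrame({"W1": [0.1, -0.2, 0.3, 0.05]}, index=meta.index)
        design = build_design(meta, "TA", W=W)
        assert design.w_columns == ["W1"]
        assert design.matrix.shape[1] == 3

    def test_binary_covariate_encoded(self):
        meta = make_meta(["TA", "SSL", "TA", "SSL"], sex=["F", "M", "M", "F"])
        design = build_design(meta, "TA", covariates=["sex"])
        assert set(design.matrix["sex"]) == {0.0, 1.0}


class TestFitLinear:
    def test_exact_fit_recovers_coefficients(self):
        meta = make_meta(["TA", "TA", "SSL", "SSL", "TV", "TV"])
        design = build_design(meta, "TA")
        base = 5.0 + design.matrix["group_SSL"].to_numpy() * 1.0
        expr = pd.DataFrame([base], index=["g1"], columns=meta.index)
        fit = fit_linear(expr, design)
        assert fit.coef.at["g1", "group_SSL"] == pytest.approx(1.0)
        assert fit.s2["g1"] == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        meta = make_meta(["TA", "TA", "TA", "SSL", "SSL", "SSL", "TV", "TV"])
        design = build_design(meta, "TA")
        Y = rng.normal(6, 1, (40, 8))
        expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(40)],
                            columns=meta.index)
        fit = fit_linear(expr, design)
        X = design.matrix.to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ Y.T)
        assert np.abs(fit.coef.to_numpy() - beta_oracle.T).max() < 1e-10
        resid = Y.T - X @ beta_oracle
        s2_oracle = (resid**2).sum(axis=0) / (8 - 3)
        assert np.abs(fit.s2.to_numpy() - s2_oracle).max() < 1e-10

    def test_consistent_permutation_leaves_fit_unchanged(self):
        rng = np.random.default_rng(0)
        meta = make_meta(["TA", "SSL", "TA", "SSL", "TV", "TV"])
        design = build_design(meta, "TA")
        expr = pd.DataFrame(rng.normal(5, 1, (10, 6)),
                            index=[f"g{i}" for i in range(10)],
                            columns=meta.index)
        perm = ["S3", "S0", "S5", "S1", "S4", "S2"]
        design_p = build_design(meta.loc[perm], "TA")
        fit_a = fit_linear(expr, design)
        fit_b = fit_linear(expr[perm], design_p)
        assert np.allclose(fit_a.coef, fit_b.coef)
        assert np.allclose(fit_a.s2, fit_b.s2)

    def test_n_not_greater_than_p_raises(self):
        meta = make_meta(["TA", "SSL", "TV"])
        design = build_design(meta, "TA")
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=meta.index)
        with pytest.raises(ValidationError):
            fit_linear(expr, design)


class TestEbayes:
    def simulated_fit(self, seed=0, n_genes=200):
        rng = np.random.default_rng(seed)
        meta = make_meta(["TA"] * 6 + ["SSL"] * 6)
        design = build_design(meta, "TA")
        expr = pd.DataFrame(rng.normal(7, 0.6, (n_genes, 12)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=meta.index)
        return fit_linear(expr, design)

    def test_infinite_prior_df_shrinks_all_variances_to_prior(self):
        fit = self.simulated_fit()
        mod = ebayes(fit, prior_df=np.inf)
        assert np.allclose(mod.s2_post, mod.s02)

    def test_zero_prior_df_reproduces_ordinary_t(self):
        fit = self.simulated_fit()
        mod = ebayes(fit, prior_df=0.0)
        X = fit.design.matrix.to_numpy()
        v = np.linalg.inv(X.T @ X)[1, 1]
        t_ord = fit.coef["group_SSL"] / np.sqrt(fit.s2 * v)
        assert np.allclose(mod.t["group_SSL"], t_ord)
        p_ord = 2 * sps.t.sf(np.abs(t_ord), fit.df_residual)
        assert np.allclose(mod.p["group_SSL"], p_ord)

    def test_moderated_variance_between_prior_and_sample(self):
        fit = self.simulated_fit(seed=1)
        mod = ebayes(fit)
        lo = np.minimum(fit.s2, mod.s02)
        hi = np.maximum(fit.s2, mod.s02)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_identical_variances_fall_back_to_infinite_prior(self):
        meta = make_meta(["TA"] * 4 + ["SSL"] * 4)
        design = build_design(meta, "TA")
        # identical residual patterns -> identical s2 across genes
        base = np.array([1.0, -1.0, 0.5, -0.5, 1.0, -1.0, 0.5, -0.5])
        expr = pd.DataFrame([5 + base, 9 + base], index=["g1", "g2"],
                            columns=meta.index)
        mod = ebayes(fit_linear(expr, design))
        assert np.isinf(mod.d0)

    def test_prior_parameter_recovery_from_hierarchy(self):
        # s2 ~ s0^2 * d0 / chi2_d0 * chi2_d / d with d0 = 4, s0^2 = 0.25
        rng = np.random.default_rng(7)
        d0, s02, d = 4.0, 0.25, 10
        sigma2 = s02 * d0 / rng.chisquare(d0, 500)
        s2 = sigma2 * rng.chisquare(d, 500) / d
        d0_hat, s02_hat = _fit_f_dist(s2, d)
        assert 2.0 <= d0_hat <= 8.0
        assert abs(s02_hat - s02) / s02 <= 0.30

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in [0.1, 0.5, 2.0, 17.0, 400.0]:
            x = float(polygamma(1, y))
            assert trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestNbGlm:
    def test_poisson_limit_matches_poisson_glm_oracle(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        n = 60
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = rng.normal(0, 0.2, n)
        for _ in range(10):
            beta_true = np.array([np.log(150), rng.normal(0, 0.5)])
            y = rng.poisson(np.exp(X @ beta_true + offset)).astype(float)
            beta, ok = _nb_irls(y, X, offset, phi=1e-8)
            assert ok
            oracle = statsmodels.GLM(
                y, X, family=statsmodels.families.Poisson(), offset=offset
            ).fit()
            assert np.abs(beta - oracle.params).max() < 1e-3

    def test_poisson_null_data_yields_small_shrunk_dispersions(self):
        # Poisson-simulated counts: phi -> 0, so shrunk dispersions stay small
        rng = np.random.default_rng(3)
        n, m = 40, 60
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        offset = np.zeros(n)
        phis = []
        for g in range(m):
            y = rng.poisson(200, n).astype(float)
            beta, _ = _nb_irls(y, X, offset, phi=0.05)
            phis.append(_profile_dispersion(y, X, offset, beta))
        phis = np.array(phis)
        log_bar = np.mean(np.log(phis))
        w = 10 / (10 + n)
        shrunk = np.exp(w * log_bar + (1 - w) * np.log(phis))
        assert np.mean(shrunk <= 0.05) >= 0.95

    def test_planted_log2fc_recovery(self):
        rng = np.random.default_rng(11)
        n = 80
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 40)])
        offset = np.zeros(n)
        lfcs = []
        for g in range(60):
            mu = 200 * 2 ** X[:, 1]
            r = 1 / 0.1
            y = rng.negative_binomial(r, r / (r + mu)).astype(float)
            beta, _ = _nb_irls(y, X, offset, phi=0.1)
            phi = _profile_dispersion(y, X, offset, beta)
            beta, _ = _nb_irls(y, X, offset, phi, beta0=beta)
            lfcs.append(beta[1] / np.log(2))
        assert abs(np.mean(lfcs) - 1.0) <= 0.15

    def test_equal_groups_give_null_statistics(self, tiny_experiment):
        from ncflow.normalize import nb_size_factors

        exp = tiny_experiment
        # identical counts in both groups for GENE1
        exp.counts.loc["GENE1"] = [100, 100, 100, 100]
        design = build_design(exp.samples, "TA")
        fit = nb_glm_de(exp, design, nb_size_factors(exp))
        assert abs(fit.log2fc_table.at["GENE1", "group_SSL"]) < 0.2
        assert fit.lrt.at["GENE1", "group_SSL"] < 1.5


class TestBhAdjust:
    def bh_oracle(self, p):
        """Literal step-up definition with explicit loops."""
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [
                m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
            ]
            q[idx] = min(min(candidates), 1.0)
        return q

    def test_hand_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_brute_force_oracle_on_1000_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 51))
            assert np.allclose(bh_adjust(p), self.bh_oracle(p))

    def test_matches_statsmodels_reference(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest"
        ).multipletests
        rng = np.random.default_rng(5)
        p = rng.random(200)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone_in_rank(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        # ties in p receive equal q
        for value in np.unique(p):
            assert np.allclose(q[p == value], q[p == value][0])


class TestDeTable:
    def fitted_stats(self, seed=0, null=True):
        rng = np.random.default_rng(seed)
        meta = make_meta(["TA"] * 10 + ["SSL"] * 10)
        design = build_design(meta, "TA")
        expr = pd.DataFrame(rng.normal(6, 0.5, (100, 20)),
                            index=[f"g{i}" for i in range(100)],
                            columns=meta.index)
        return ebayes(fit_linear(expr, design))

    def test_all_p_one_gives_zero_significant(self):
        stats = self.fitted_stats()
        stats.p["group_SSL"] = 1.0
        res = de_table(stats, "group_SSL")
        assert res.n_significant == 0

    def test_referent_flip_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(1)
        meta = make_meta(["TA"] * 8 + ["SSL"] * 8)
        expr = pd.DataFrame(rng.normal(6, 0.5, (50, 16)),
                            index=[f"g{i}" for i in range(50)],
                            columns=meta.index)
        res_ta = de_table(ebayes(fit_linear(expr, build_design(meta, "TA"))),
                          "group_SSL")
        res_ssl = de_table(ebayes(fit_linear(expr, build_design(meta, "SSL"))),
                           "group_TA")
        merged = res_ta.table.join(res_ssl.table, lsuffix="_a", rsuffix="_b")
        assert np.allclose(merged["log2fc_a"], -merged["log2fc_b"])
        assert np.allclose(merged["p_a"], merged["p_b"])

    def test_unknown_contrast_raises(self):
        with pytest.raises(ValidationError, match="unknown contrast"):
            de_table(self.fitted_stats(), "group_NOPE")

    def test_sorted_by_q_then_effect_size(self):
        res = de_table(self.fitted_stats(seed=2), "group_SSL")
        q = res.table["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_fdr_controlled_under_global_null_over_replicates(self):
        # under a global null BH makes any discovery with prob <= alpha;
        # check the mean realized FDP over 200 replicates with MC slack
        rng = np.random.default_rng(99)
        meta = make_meta(["TA"] * 10 + ["SSL"] * 10)
        design = build_design(meta, "TA")
        fdp = []
        for _ in range(200):
            expr = pd.DataFrame(rng.normal(6, 0.5, (277, 20)),
                                columns=meta.index)
            res = de_table(ebayes(fit_linear(expr, design)), "group_SSL")
            fdp.append(1.0 if res.n_significant > 0 else 0.0)
        limit = 0.05 + 3 * np.sqrt(0.05 * 0.95 / 200)
        assert np.mean(fdp) <= limit
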