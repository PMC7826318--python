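"""FIML likelihood, optimization, restarts, and the likelihood-ratio test."""

import math

import numpy as np
import pytest

import ldefit as lf
from ldefit.embedding import TDEMatrix

from conftest import random_theta


def dense_mvn_loglik(w, mu, sigma):
    """Independent oracle: textbook multivariate-normal log-density."""
    k = len(w)
    sign, logdet = np.linalg.slogdet(sigma)
    assert sign > 0
    resid = w - mu
    return -0.5 * (k * math.log(2 * math.pi) + logdet
                   + resid @ np.linalg.solve(sigma, resid))


def make_tde(values, persons, d, p, names=None):
    return TDEMatrix(values=np.asarray(values, dtype=float),
                     row_person=np.asarray(persons), D=d, tau=1,
                     delta_t=1.0,
                     series_names=names or [f"series_{i+1}"
                                            for i in range(p)])


def identity_sigma_theta(spec):
    """Parameters under which Sigma = I and all means are 0."""
    vals = np.zeros(lf.count_free_parameters(spec))
    vals[0] = -0.01
    i = 2 + spec.P - 1 + 3 + spec.n_resid
    vals[i:i + spec.P] = 1.0
    return lf.ParamVector(spec, vals)


class TestTotalLoglik:
    def test_standard_normal_row(self):
        spec = lf.LDESpec(order=2, D=5, P=3, delta_t=1.0, person_ids=(1,))
        theta = identity_sigma_theta(spec)
        data = make_tde(np.zeros((1, 15)), [1], 5, 3)
        assert lf.total_loglik(spec, theta, data) == pytest.approx(
            -7.5 * math.log(2 * math.pi), abs=1e-12)

    def test_matches_dense_mvn_oracle_on_complete_rows(self):
        spec = lf.LDESpec(order=2, D=5, P=2, delta_t=1.0,
                          person_ids=(1, 2))
        rng = np.random.default_rng(14)
        theta = random_theta(spec, rng)
        sigma = lf.implied_covariance(spec, theta)
        w = rng.normal(size=(6, 10))
        persons = [1, 1, 1, 2, 2, 2]
        data = make_tde(w, persons, 5, 2)
        expected = sum(
            dense_mvn_loglik(w[i], lf.implied_row_mean(spec, theta, persons[i]),
                             sigma)
            for i in range(6))
        got = lf.total_loglik(spec, theta, data)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_cells_use_analytic_marginal(self):
        """A row's contribution equals the marginal normal density of its
        observed cells, and other rows are unaffected by the deletion."""
        spec = lf.LDESpec(order=2, D=5, P=1, delta_t=1.0, person_ids=(1,))
        rng = np.random.default_rng(15)
        theta = random_theta(spec, rng)
        sigma = lf.implied_covariance(spec, theta)
        mu = lf.implied_row_mean(spec, theta, 1)
        w = rng.normal(size=(3, 5))
        full = lf.total_loglik(spec, theta, make_tde(w, [1, 1, 1], 5, 1))
        w_miss = w.copy()
        obs = [0, 2, 3]
        w_miss[1, [1, 4]] = np.nan
        got = lf.total_loglik(spec, theta, make_tde(w_miss, [1, 1, 1], 5, 1))
        marg = dense_mvn_loglik(w[1, obs], mu[obs],
                                sigma[np.ix_(obs, obs)])
        row_full = dense_mvn_loglik(w[1], mu, sigma)
        assert got == pytest.approx(full - row_full + marg, abs=1e-10)

    def test_fully_missing_rows_contribute_zero(self):
        spec = lf.LDESpec(order=2, D=5, P=1, delta_t=1.0, person_ids=(1,))
        theta = random_theta(spec, np.random.default_rng(16))
        w = np.random.default_rng(17).normal(size=(2, 5))
        base = lf.total_loglik(spec, theta, make_tde(w, [1, 1], 5, 1))
        w_ext = np.vstack([w, np.full((1, 5), np.nan)])
        ext = lf.total_loglik(spec, theta, make_tde(w_ext, [1, 1, 1], 5, 1))
        assert ext == pytest.approx(base, abs=1e-12)

    def test_complete_data_bypasses_pattern_machinery(self):
        """With no missing cells the FIML sum equals the one-pattern
        complete-data log-likelihood computed directly."""
        spec = lf.LDESpec(order=4, D=6, P=2, delta_t=1.0, person_ids=(1,))
        rng = np.random.default_rng(18)
        theta = random_theta(spec, rng)
        sigma = lf.implied_covariance(spec, theta)
        mu = lf.implied_row_mean(spec, theta, 1)
        w = rng.multivariate_normal(mu, sigma, size=50)
        data = make_tde(w, [1] * 50, 6, 2)
        model = lf.LDEModel(data, order=4, spec=spec)
        assert len(model.patterns) == 1
        resid = w - mu
        sign, logdet = np.linalg.slogdet(sigma)
        direct = -0.5 * (50 * (12 * math.log(2 * math.pi) + logdet)
                         + np.einsum("ij,ij->", resid,
                                     np.linalg.solve(sigma, resid.T).T))
        assert model.loglike(theta) == pytest.approx(direct, rel=1e-12)


class TestFit:
    def test_low_noise_recovery_within_5_percent(self):
        cfg = lf.SimConfig(
            params=lf.DLOParams(eta=-0.01, zeta=-0.02),
            n_persons=50, n_occasions=100, noise_sd=(1e-4,) * 3,
            missing_rate=0.0, seed=10,
        )
        tde = lf.embed_panel(lf.simulate_panel(cfg), 6)
        res = lf.LDEModel(tde, order=2).fit(
            lf.FitOptions(seed=1, compute_se=False))
        assert res.converged
        assert res.eta == pytest.approx(-0.01, rel=0.05)
        assert res.zeta == pytest.approx(-0.02, rel=0.05)

    def test_minus2ll_reproducible_from_estimates(self, small_fits):
        for res in small_fits:
            ll = lf.total_loglik(res.spec, res.params, res.model.data)
            assert -2 * ll == pytest.approx(res.minus2ll, rel=1e-6)

    def test_refit_from_estimates_reproduces_optimum(self, small_fits):
        solde, _ = small_fits
        refit = solde.model.fit(lf.FitOptions(seed=2, compute_se=False),
                                start=solde.params)
        assert refit.minus2ll == pytest.approx(solde.minus2ll, abs=1e-4)

    def test_fit_is_deterministic(self, small_p2_panel):
        panel, _ = small_p2_panel
        tde = lf.embed_panel(panel, 5)
        opts = lf.FitOptions(seed=3, compute_se=False)
        r1 = lf.LDEModel(tde, order=2).fit(opts)
        r2 = lf.LDEModel(tde, order=2).fit(opts)
        np.testing.assert_array_equal(r1.params.values, r2.params.values)
        assert r1.llf == r2.llf and r1.n_attempts == r2.n_attempts

    def test_gradient_vanishes_at_optimum(self, small_fits):
        for res in small_fits:
            # per-row scaled objective; interior optimum, small gradient
            assert res.grad_norm < 1e-3

    def test_analytic_gradient_matches_finite_differences(self,
                                                          small_p2_panel):
        panel, _ = small_p2_panel
        tde = lf.embed_panel(panel, 5)
        model = lf.LDEModel(tde, order=4)
        rng = np.random.default_rng(4)
        x = model.start_params() + rng.uniform(-0.2, 0.2,
                                               model.spec.n_structural)
        _, g = model._profiled_nll_grad(x)
        from scipy.optimize._numdiff import approx_derivative
        gfd = approx_derivative(model._profiled_negloglik, x,
                                method="3-point")
        np.testing.assert_allclose(g, gfd, rtol=5e-4, atol=1e-4)

    def test_standard_errors_available(self, small_p2_panel):
        panel, _ = small_p2_panel
        tde = lf.embed_panel(panel, 5)
        res = lf.LDEModel(tde, order=2).fit(lf.FitOptions(seed=1))
        tbl = res.param_table
        assert np.isfinite(tbl.loc["eta", "se"]) and tbl.loc["eta", "se"] > 0
        # every person mean has a positive GLS standard error
        means_se = tbl.loc[[n for n in tbl.index if n.startswith("m_")], "se"]
        assert (means_se > 0).all()

    def test_too_few_rows_rejected(self):
        spec = lf.LDESpec(order=2, D=5, P=1, delta_t=1.0, person_ids=(1,))
        data = make_tde(np.zeros((2, 5)), [1, 1], 5, 1)
        with pytest.raises(ValueError, match="informative rows"):
            lf.LDEModel(data, order=2, spec=spec).fit(
                lf.FitOptions(compute_se=False))

    def test_summary_mentions_key_quantities(self, small_fits):
        solde, _ = small_fits
        text = solde.summary()
        assert "SOLDE" in text and "eta" in text and "wavelength" in text
        assert "naive" in text

    def test_two_stage_local_linear_oracle_agreement(self):
        """Window-wise quadratic fits + OLS of f'' on (f, f') agree with
        FIML in sign and within 15% at low noise."""
        cfg = lf.SimConfig(
            params=lf.DLOParams(eta=-0.05, zeta=-0.04),
            n_persons=30, n_occasions=80, n_series=1,
            series_loadings=(1.0,), noise_sd=(0.01,),
            equilibrium_mean=0.0, equilibrium_sd=1.0,
            init_pos_sd=2.0, init_vel_sd=0.4, missing_rate=0.0, seed=12,
        )
        panel = lf.simulate_panel(cfg)
        d = 7
        tde = lf.embed_panel(panel, d)
        # stage 1: per-window least-squares derivative estimates
        basis = lf.build_loading_matrix(d, 2, 1.0, [1.0])
        person_mean = {p: panel.values_for(p)["series_1"].mean()
                       for p in panel.persons}
        centered = tde.values - np.array(
            [person_mean[p] for p in tde.row_person])[:, None]
        derivs = np.linalg.lstsq(basis, centered.T, rcond=None)[0].T
        # stage 2: OLS of f'' on (f, f')
        x = derivs[:, :2]
        coef = np.linalg.lstsq(x, derivs[:, 2], rcond=None)[0]
        res = lf.LDEModel(tde, order=2).fit(
            lf.FitOptions(seed=1, compute_se=False))
        assert np.sign(coef[0]) == np.sign(res.eta) == -1
        assert coef[0] == pytest.approx(res.eta, rel=0.15)
        assert coef[1] == pytest.approx(res.zeta, rel=0.15)


class TestLikelihoodRatio:
    def test_df_is_two_for_solde_vs_folde(self, small_fits):
        solde, folde = small_fits
        lrt = lf.likelihood_ratio_test(solde, folde)
        assert lrt.df == 2
        assert lrt.statistic >= 0 and 0 <= lrt.pvalue <= 1
        assert solde.lrt(folde) == folde.lrt(solde)

    def test_identical_loglik_gives_zero_statistic(self, small_fits):
        solde, folde = small_fits
        import copy
        fake = copy.copy(folde)
        fake.llf = solde.llf
        lrt = lf.likelihood_ratio_test(solde, fake)
        assert lrt.statistic == 0.0 and lrt.pvalue == 1.0

    def test_negative_statistic_clipped_with_warning(self, small_fits):
        solde, folde = small_fits
        import copy
        fake = copy.copy(folde)
        fake.llf = solde.llf - 1.0  # "full" model fits worse
        with pytest.warns(RuntimeWarning, match="clipped"):
            lrt = lf.likelihood_ratio_test(solde, fake)
        assert lrt.statistic == 0.0 and lrt.pvalue == 1.0

    def test_non_nested_specs_rejected(self, small_fits, tiny_p1_panel):
        solde, _ = small_fits
        panel, _ = tiny_p1_panel
        other = lf.LDEModel(lf.embed_panel(panel, 5), order=4).fit(
            lf.FitOptions(seed=1, compute_se=False))
        with pytest.raises(ValueError, match="not nested"):
            lf.likelihood_ratio_test(solde, other)

    def test_null_rejection_rate_not_inflated(self):
        """Under true second-order dynamics the SOLDE-vs-FOLDE test should
        not reject much above its nominal level (boundary effects on the
        added variance parameters make it conservative)."""
        rejections = 0
        n_rep = 40
        opts = lf.FitOptions(seed=1, compute_se=False,
                             max_extra_attempts=10)
        for rep in range(n_rep):
            cfg = lf.SimConfig(
                params=lf.DLOParams(eta=-0.03, zeta=-0.05),
                n_persons=10, n_occasions=45, n_series=1,
                series_loadings=(1.0,), noise_sd=(0.4,),
                equilibrium_mean=0.0, equilibrium_sd=1.0,
                init_pos_sd=2.0, init_vel_sd=0.3,
                missing_rate=0.0, seed=500 + rep,
            )
            tde = lf.embed_panel(lf.simulate_panel(cfg), 5)
            solde = lf.LDEModel(tde, order=2).fit(opts)
            folde = lf.LDEModel(tde, order=4).fit(opts)
            if not (solde.converged and folde.converged):
                continue
            if lf.likelihood_ratio_test(solde, folde).pvalue < 0.05:
                rejections += 1
        assert rejections / n_rep <= 0.12
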