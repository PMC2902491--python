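"""Estimation: gradients, fitting, inference helpers, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import snhurdle as sh
from snhurdle import (
    FitResult,
    ParameterSet,
    QuadratureRule,
    fit_mle,
    information_criteria,
    likelihood_ratio_test,
    lrt_delta_zero,
    predict,
    total_loglik,
    wald_tests,
)
from snhurdle._likelihood import find_modes
from snhurdle.estimation import _pack, _theta_objective, _unpack

from conftest import RECOVERY_TRUTH


@pytest.fixture(scope="module")
def grad_data():
    return sh.simulate_probit_logsn(RECOVERY_TRUTH, 30, 8, p_x=0.2, seed=3)


THETA_POINT = ParameterSet(
    beta1=[-0.8, 2.0], beta2=[0.1, 0.5], sigma=0.7, delta=-0.3, s11=0.5, s22=0.4, s12=0.1
)


class TestGradient:
    @pytest.mark.parametrize("link", ["probit", "logit"])
    @pytest.mark.parametrize("fix_delta", [None, 0.0])
    @pytest.mark.parametrize("adaptive", [False, True])
    def test_analytic_matches_finite_differences(self, grad_data, link, fix_delta, adaptive):
        theta = _pack(THETA_POINT, fix_delta)
        centers = None
        if adaptive:
            b1, b2, sig, dl, *_, L, _rho = _unpack(theta, 2, 2, fix_delta)
            centers = find_modes(grad_data, b1, b2, sig, dl, L, link=link)
        fun = _theta_objective(
            grad_data, QuadratureRule(7), link, 2, 2, fix_delta, centers
        )
        _, g = fun(theta)
        gfd = np.zeros_like(theta)
        for j in range(len(theta)):
            h = 1e-6 * (1 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            gfd[j] = (fun(tp)[0] - fun(tm)[0]) / (2 * h)
        assert np.max(np.abs(g - gfd) / (1 + np.abs(gfd))) < 1e-6


class TestFit:
    def test_fit_diagnostics_and_criteria(self, small_fit_pair):
        fit_sn, fit_ln = small_fit_pair
        assert fit_sn.converged and fit_ln.converged
        assert fit_sn.aic == fit_sn.neg2ll + 2 * fit_sn.n_params
        assert fit_sn.bic == pytest.approx(
            fit_sn.neg2ll + fit_sn.n_params * np.log(fit_sn.n_subjects)
        )
        assert fit_ln.n_params == fit_sn.n_params - 1
        # covariance is symmetric with positive diagonals where defined
        assert np.allclose(fit_sn.vcov, fit_sn.vcov.T)
        ok = ~np.isnan(fit_sn.se)
        assert np.all(fit_sn.se[ok] > 0)

    def test_nested_model_never_beats_full(self, small_fit_pair):
        fit_sn, fit_ln = small_fit_pair
        assert fit_sn.neg2ll <= fit_ln.neg2ll + 1e-6

    def test_delta_frozen_fit_matches_direct_lognormal_loglik(self, small_data):
        """The delta=0 fit must equal an independently coded normal-severity
        marginal likelihood evaluated at the same parameter values."""
        rule = QuadratureRule(41)
        fit = fit_mle(small_data, rule=rule, fix_delta=0.0, compute_se=False)
        p = fit.params

        # independent oracle: meshgrid of nodes, scipy normal pieces, loop
        # over observations per subject
        z, w = np.polynomial.hermite_e.hermegauss(41)
        w = w / w.sum()
        L = np.linalg.cholesky(p.cov)
        za, zb = np.meshgrid(z, z, indexing="ij")
        t0 = L[0, 0] * za
        t1 = L[1, 0] * za + L[1, 1] * zb
        w2 = np.outer(w, w)
        ll = 0.0
        for s in range(small_data.n_subjects):
            i0 = small_data.starts[s]
            i1 = (
                small_data.starts[s + 1]
                if s + 1 < small_data.n_subjects
                else small_data.n_obs
            )
            cl = np.zeros_like(t0)
            for k in range(i0, i1):
                eta = small_data.X1[k] @ p.beta1 + t0
                if small_data.y[k] == 0:
                    cl += stats.norm.logcdf(-eta)
                else:
                    cl += stats.norm.logcdf(eta)
                    cl += stats.norm.logpdf(
                        np.log(small_data.y[k]),
                        small_data.X2[k] @ p.beta2 + t1,
                        p.sigma,
                    )
            m = cl.max()
            ll += m + np.log((w2 * np.exp(cl - m)).sum())
        assert fit.neg2ll == pytest.approx(-2 * ll, abs=1e-6)

    def test_start_point_invariance(self, small_data):
        rule = QuadratureRule(7, adaptive=True)
        default = fit_mle(small_data, rule=rule, compute_se=False)
        perturbed = ParameterSet(
            beta1=RECOVERY_TRUTH.beta1 * 1.3 + 0.2,
            beta2=RECOVERY_TRUTH.beta2 * 0.7 - 0.1,
            sigma=0.9,
            delta=-0.2,
            s11=0.7,
            s22=0.35,
            s12=0.05,
        )
        other = fit_mle(small_data, rule=rule, init=perturbed, compute_se=False)
        assert default.neg2ll == pytest.approx(other.neg2ll, abs=1e-4)

    def test_logit_link_fits(self, small_data):
        fit = fit_mle(small_data, link="logit", compute_se=False, rule=QuadratureRule(5, adaptive=True))
        assert fit.converged


class TestWald:
    def _result_with(self, names, est, se):
        k = len(est)
        return FitResult(
            params=ParameterSet([0.0], [0.0], 1.0, 0.0, 1.0, 1.0, 0.0),
            param_names=names,
            estimates=np.asarray(est, float),
            se=np.asarray(se, float),
            vcov=np.diag(np.asarray(se, float)) ** 2,
            neg2ll=0.0, aic=0.0, bic=0.0, n_subjects=10, n_obs=10, n_params=k,
            converged=True, n_iter=1, grad_norm=0.0,
        )

    def test_highly_significant_coefficient(self):
        tab = wald_tests(self._result_with(["b"], [2.459], [0.126]))
        assert tab["z"][0] == pytest.approx(19.52, abs=0.01)
        assert tab["p_value"][0] < 1e-4
        assert tab["stars"][0] == "***"

    def test_null_estimate(self):
        tab = wald_tests(self._result_with(["b"], [0.0], [0.3]))
        assert tab["p_value"][0] == 1.0

    def test_marginal_coefficient(self):
        tab = wald_tests(self._result_with(["b"], [-0.1286], [0.076]))
        assert tab["p_value"][0] == pytest.approx(0.0906, abs=5e-4)
        assert tab["stars"][0] == "*"

    def test_missing_se_flagged(self):
        tab = wald_tests(self._result_with(["a", "b"], [1.0, 2.0], [0.5, np.nan]))
        assert np.isnan(tab["p_value"][1]) and tab["stars"][1] == ""


class TestInformationCriteria:
    def test_zero_parameters(self):
        aic, bic = information_criteria(123.4, 0, 50)
        assert aic == 123.4 and bic == 123.4

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            information_criteria(1.0, 2, 0)


class TestLRT:
    def test_identical_models(self):
        stat, df, p = likelihood_ratio_test(100.0, 100.0)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_fit_pair(self, small_fit_pair):
        fit_sn, fit_ln = small_fit_pair
        stat, df, p = lrt_delta_zero(fit_sn, fit_ln)
        assert stat >= -1e-6 and df == 1 and 0 <= p <= 1

    def test_mismatched_data_rejected(self, small_fit_pair):
        fit_sn, fit_ln = small_fit_pair
        other = sh.simulate_probit_logsn(RECOVERY_TRUTH, 10, 4, p_x=0.3, seed=99)
        fit_other = fit_mle(other, rule=QuadratureRule(5, adaptive=True),
                            fix_delta=0.0, compute_se=False)
        with pytest.raises(ValueError):
            lrt_delta_zero(fit_sn, fit_other)


class TestPredict:
    def _fit(self, small_fit_pair):
        return small_fit_pair[0]

    def test_conditional_reference_point(self, small_fit_pair):
        fit = self._fit(small_fit_pair)
        # force parameters to a clean reference: intercept-only, eta=0
        ref = FitResult(**{**fit.__dict__})
        ref.params = ParameterSet([0.0, 0.0], [0.0, 0.0], 1.0, 0.0, 1.0, 0.2, 0.0)
        new = pd.DataFrame({"x": [0.0]})
        out = predict(ref, new, mode="conditional-at-zero-effects")
        assert out["p_symptom_free"][0] == pytest.approx(0.5)

    def test_marginal_closed_form(self, small_fit_pair):
        fit = self._fit(small_fit_pair)
        ref = FitResult(**{**fit.__dict__})
        ref.params = ParameterSet([-1.0, 0.0], [0.0, 0.0], 1.0, 0.0, 1.0, 0.2, 0.0)
        new = pd.DataFrame({"x": [0.0]})
        out = predict(ref, new, mode="population-marginal")
        assert out["p_positive"][0] == pytest.approx(
            stats.norm.cdf(-1 / np.sqrt(2)), abs=1e-6
        )

    def test_marginal_shrinks_toward_half(self, small_fit_pair):
        fit = self._fit(small_fit_pair)
        ref = FitResult(**{**fit.__dict__})
        for eta in (-2.0, -0.5, 0.5, 2.0):
            ref.params = ParameterSet([eta, 0.0], [0.0, 0.0], 1.0, 0.0, 1.5, 0.2, 0.0)
            new = pd.DataFrame({"x": [0.0]})
            cond = predict(ref, new, mode="conditional-at-zero-effects")["p_positive"][0]
            marg = predict(ref, new, mode="population-marginal")["p_positive"][0]
            assert abs(marg - 0.5) < abs(cond - 0.5)

    def test_unknown_covariate(self, small_fit_pair):
        fit = self._fit(small_fit_pair)
        with pytest.raises(KeyError):
            predict(fit, pd.DataFrame({"nope": [1.0]}))

    def test_unknown_mode(self, small_fit_pair):
        with pytest.raises(ValueError):
            predict(self._fit(small_fit_pair), pd.DataFrame({"x": [0.0]}), mode="nope")


class TestSerialization:
    def test_json_round_trip(self, small_fit_pair, tmp_path):
        fit, _ = small_fit_pair
        path = tmp_path / "fit.json"
        fit.save(path)
        back = FitResult.load(path)
        assert back.param_names == fit.param_names
        assert np.allclose(back.estimates, fit.estimates)
        assert np.allclose(back.vcov, fit.vcov, equal_nan=True)
        assert back.neg2ll == fit.neg2ll
        assert back.data_fingerprint == fit.data_fingerprint

    def test_summary_mentions_criteria(self, small_fit_pair):
        fit, _ = small_fit_pair
        text = fit.summary()
        assert "AIC" in text and "BIC" in text and "-2 Log Likelihood" in text
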