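"""Gauss-Hermite marginal likelihood against brute-force oracles."""

import numpy as np
import pytest

import snhurdle as sh
from snhurdle import LongDataset, ParameterSet, QuadratureRule, subject_loglik, total_loglik
from snhurdle.quadrature import subject_logliks

from conftest import RECOVERY_TRUTH


def toy_dataset():
    """Two subjects, three observations each, mixed zeros and positives."""
    subj = [1, 1, 1, 2, 2, 2]
    y = [0.0, 1.2, 0.0, 0.4, 0.0, 2.5]
    X = np.column_stack([np.ones(6), [0, 1, 0, 0, 1, 1]])
    return LongDataset(subj, y, X, X, x1_names=["intercept", "x"], x2_names=["intercept", "x"])


TOY_PARAMS = ParameterSet(
    beta1=[-0.3, 1.0], beta2=[0.1, 0.5], sigma=0.8, delta=-0.6, s11=1.0, s22=0.2, s12=0.2
)


def mc_subject_logliks(data, params, n_draws=1_000_000, seed=0):
    """Brute-force Monte-Carlo integration oracle (antithetic BVN draws).

    Written independently of the package kernel: plain loops over
    observations, scipy for the normal pieces.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    half = n_draws // 2
    z = rng.standard_normal((half, 2))
    z = np.vstack([z, -z])
    L = np.linalg.cholesky(params.cov)
    tau = z @ L.T
    out = []
    for s in range(data.n_subjects):
        i0 = data.starts[s]
        i1 = data.starts[s + 1] if s + 1 < data.n_subjects else data.n_obs
        cl = np.zeros(tau.shape[0])
        for k in range(i0, i1):
            eta = data.X1[k] @ params.beta1 + tau[:, 0]
            if data.y[k] == 0:
                cl += norm.logcdf(-eta)
            else:
                cl += norm.logcdf(eta)
                t = np.log(data.y[k])
                mu = data.X2[k] @ params.beta2 + tau[:, 1]
                ss = np.hypot(params.sigma, params.delta)
                r = (t - mu) / ss
                cl += (
                    np.log(2)
                    - 0.5 * np.log(2 * np.pi)
                    - np.log(ss)
                    - 0.5 * r * r
                    + norm.logcdf(params.delta * r / params.sigma)
                )
        m = cl.max()
        out.append(m + np.log(np.exp(cl - m).mean()))
    return np.array(out)


class TestRule:
    def test_weights_sum_to_one(self):
        for n in (1, 5, 21, 50):
            assert QuadratureRule(n).weights.sum() == pytest.approx(1.0, abs=1e-14)

    def test_polynomial_exactness(self):
        # n-point rule is exact for normal moments up to degree 2n-1
        rule = QuadratureRule(5)
        z, w = rule.nodes, rule.weights
        # normal moments: odd vanish, even are double factorials (k-1)!!
        expected = {0: 1, 1: 0, 2: 1, 3: 0, 4: 3, 5: 0, 6: 15, 7: 0, 8: 105, 9: 0}
        for k, ref in expected.items():
            assert np.sum(w * z**k) == pytest.approx(ref, rel=1e-12, abs=1e-10)

    def test_invalid_points(self):
        with pytest.raises(ValueError):
            QuadratureRule(0)


class TestSubjectLoglik:
    def test_degenerate_random_effects(self):
        # S ~ 0 recovers the fixed-effects density: one zero observation at
        # binary intercept 0 gives log(1/2)
        data = LongDataset([1], [0.0], np.ones((1, 1)), np.ones((1, 1)))
        params = ParameterSet(
            beta1=[0.0], beta2=[0.0], sigma=1.0, delta=0.0, s11=1e-12, s22=1e-12, s12=0.0
        )
        assert subject_loglik(data, params) == pytest.approx(np.log(0.5), abs=1e-6)

    def test_matches_monte_carlo_oracle(self):
        data = toy_dataset()
        mc = mc_subject_logliks(data, TOY_PARAMS)
        gh = subject_logliks(data, TOY_PARAMS, QuadratureRule(21))
        assert np.max(np.abs(gh - mc)) <= 1e-3

    def test_self_convergence(self):
        data = toy_dataset()
        a = subject_logliks(data, TOY_PARAMS, QuadratureRule(25))
        b = subject_logliks(data, TOY_PARAMS, QuadratureRule(50))
        assert np.max(np.abs(a - b)) <= 1e-6

    def test_adaptive_agrees_with_dense_rule(self):
        data = toy_dataset()
        dense = subject_logliks(data, TOY_PARAMS, QuadratureRule(51))
        agq = subject_logliks(data, TOY_PARAMS, QuadratureRule(7, adaptive=True))
        assert np.max(np.abs(dense - agq)) < 1e-5

    def test_adaptive_accuracy_at_many_occasions(self):
        # with 50 occasions the prior-scaled rule needs far more points than
        # the recentered one; AGQ at 7 points should match AGQ at 15
        data = sh.simulate_probit_logsn(RECOVERY_TRUTH, 5, 50, p_x=0.1, seed=2)
        a = subject_logliks(data, RECOVERY_TRUTH, QuadratureRule(7, adaptive=True))
        b = subject_logliks(data, RECOVERY_TRUTH, QuadratureRule(15, adaptive=True))
        assert np.max(np.abs(a - b)) < 1e-6

    def test_requires_single_subject(self):
        with pytest.raises(ValueError):
            subject_loglik(toy_dataset(), TOY_PARAMS)


class TestTotalLoglik:
    def test_subject_order_invariance(self):
        subj = [1, 1, 1, 2, 2, 2]
        y = [0.0, 1.2, 0.0, 0.4, 0.0, 2.5]
        X = np.column_stack([np.ones(6), [0, 1, 0, 0, 1, 1]])
        a = total_loglik(LongDataset(subj, y, X, X), TOY_PARAMS)
        perm = [3, 4, 5, 0, 1, 2]
        b = total_loglik(
            LongDataset(np.array(subj)[perm], np.array(y)[perm], X[perm], X[perm]),
            TOY_PARAMS,
        )
        assert a == pytest.approx(b, abs=1e-12)

    def test_duplicating_subjects_doubles_loglik(self):
        data = toy_dataset()
        subj2 = np.r_[data.subj, data.subj + 10]
        y2 = np.r_[data.y, data.y]
        X2 = np.vstack([data.X1, data.X1])
        doubled = total_loglik(LongDataset(subj2, y2, X2, X2), TOY_PARAMS)
        assert doubled == pytest.approx(2 * total_loglik(data, TOY_PARAMS), rel=1e-12)

    def test_total_is_sum_of_subject_values(self):
        data = toy_dataset()
        per = [subject_loglik(data, TOY_PARAMS, subject=lab) for lab in (1, 2)]
        assert total_loglik(data, TOY_PARAMS) == pytest.approx(sum(per), abs=1e-10)

    def test_vanishing_random_effects_limit(self):
        from snhurdle import RandomEffects, obs_logdensity

        data = toy_dataset()
        params0 = ParameterSet(
            beta1=TOY_PARAMS.beta1, beta2=TOY_PARAMS.beta2, sigma=TOY_PARAMS.sigma,
            delta=TOY_PARAMS.delta, s11=1e-10, s22=1e-10, s12=0.0,
        )
        fixed = sum(
            obs_logdensity(
                data.y[k], data.X1[k], data.X2[k], params0, RandomEffects(0.0, 0.0)
            )
            for k in range(data.n_obs)
        )
        assert abs(total_loglik(data, params0) - fixed) < 1e-4

    def test_allzero_subject_ignores_severity_variance(self):
        # a subject with only zeros integrates over tau0 alone when s12=0
        data = LongDataset([1, 1, 1], [0.0, 0.0, 0.0], np.ones((3, 1)), np.ones((3, 1)))
        base = dict(beta1=[0.2], beta2=[0.0], sigma=1.0, delta=0.3, s11=0.8, s12=0.0)
        a = total_loglik(data, ParameterSet(s22=0.1, **base))
        b = total_loglik(data, ParameterSet(s22=5.0, **base))
        assert abs(a - b) < 1e-10

    def test_error_decreases_with_points(self):
        data = toy_dataset()
        ref = total_loglik(data, TOY_PARAMS, QuadratureRule(60))
        errs = [
            abs(total_loglik(data, TOY_PARAMS, QuadratureRule(n)) - ref)
            for n in (5, 10, 15, 20)
        ]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi + 1e-9
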