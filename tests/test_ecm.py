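import numpy as np
import pytest
from scipy import optimize, stats
from scipy.integrate import quad

from thresholdgp import (CoefficientState, OrdinalDataset, PriorSpec,
                         ThresholdState, elicit_scale, fit_mapt,
                         mean_sq_design, observed_log_posterior,
                         truncated_moments)
from thresholdgp.ecm import (cm_step_beta, cm_step_delta1, cm_step_delta_k,
                             cm_step_sigma2, e_step, q_function)

from conftest import random_instance


def quad_trunc_moments(mu, sd, a, b):
    """Numerical-quadrature oracle for truncated-normal mean and variance.

    Infinite bounds are clipped 14 standard deviations out (density < 1e-40)
    so adaptive quadrature keeps full relative accuracy on tail intervals.
    """
    lo = max(a, mu - 14 * sd)
    hi = min(b, mu + 14 * sd)
    kw = dict(epsabs=1e-15, epsrel=1e-12, limit=300)
    Z, _ = quad(lambda x: stats.norm.pdf(x, mu, sd), lo, hi, **kw)
    m, _ = quad(lambda x: x * stats.norm.pdf(x, mu, sd), lo, hi, **kw)
    m /= Z
    v, _ = quad(lambda x: (x - m) ** 2 * stats.norm.pdf(x, mu, sd), lo, hi,
                **kw)
    return m, v / Z


class TestTruncatedMoments:
    def test_half_normal_closed_form(self):
        m, v = truncated_moments(0.0, 1.0, -np.inf, 0.0)
        assert m == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-10)
        assert v == pytest.approx(1 - 2 / np.pi, abs=1e-10)

    def test_symmetry(self):
        m_neg, v_neg = truncated_moments(0.0, 1.0, -np.inf, 0.0)
        m_pos, v_pos = truncated_moments(0.0, 1.0, 0.0, np.inf)
        assert m_pos == pytest.approx(-m_neg, abs=1e-12)
        assert v_pos == pytest.approx(v_neg, abs=1e-12)

    def test_unit_interval_against_quadrature(self):
        m, v = truncated_moments(0.0, 1.0, 0.0, 1.0)
        m_q, v_q = quad_trunc_moments(0.0, 1.0, 0.0, 1.0)
        assert m == pytest.approx(0.45986, abs=1e-5)
        assert m == pytest.approx(m_q, abs=1e-8)
        assert v == pytest.approx(v_q, abs=1e-8)

    @pytest.mark.parametrize("mu,sd,a,b", [
        (0.3, 0.7, -1.0, 2.0),
        (-2.0, 1.5, 0.0, 1.0),
        (0.0, 1.0, 5.0, 7.0),        # upper-tail interval
        (1.0, 0.5, -np.inf, -2.0),   # lower tail, one-sided
        (0.0, 2.0, 7.9, np.inf),
    ])
    def test_against_quadrature(self, mu, sd, a, b):
        m, v = truncated_moments(mu, sd, a, b)
        m_q, v_q = quad_trunc_moments(mu, sd, a, b)
        assert m == pytest.approx(m_q, abs=1e-8)
        assert v == pytest.approx(v_q, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            truncated_moments(0.0, 0.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            truncated_moments(0.0, 1.0, 1.0, 0.0)


class TestEStep:
    def _one_record(self, y, C, eta, delta):
        data = OrdinalDataset(y=[y], X=[[1.0]], C=C)
        thr = ThresholdState(delta=np.asarray(delta, dtype=float), C=C)
        coef = CoefficientState(beta=np.array([eta]), sigma_beta2=None)
        coef.refresh_eta(data.X)
        return e_step(data, thr, coef)

    def test_lowest_category_half_normal(self):
        mom = self._one_record(1, 3, 0.0, [0.0, 1.0])
        assert mom.l_star[0] == pytest.approx(-np.sqrt(2 / np.pi), abs=1e-8)

    def test_highest_category_symmetric(self):
        # gamma_{C-1} = 0 requires delta summing to zero
        mom = self._one_record(3, 3, 0.0, [-1.0, 1.0])
        assert mom.l_star[0] == pytest.approx(np.sqrt(2 / np.pi), abs=1e-8)

    def test_interior_category_matches_quadrature(self):
        # y=2 with C=4, eta=0.3, delta=(0, 1.5, 1.0):
        # working latent ~ N(-0.2, (1/1.5)^2) truncated to (0, 1)
        mom = self._one_record(2, 4, 0.3, [0.0, 1.5, 1.0])
        m_q, v_q = quad_trunc_moments(-0.2, 1 / 1.5, 0.0, 1.0)
        assert mom.l_star[0] == pytest.approx(m_q, abs=1e-8)
        assert mom.l_star2[0] == pytest.approx(v_q, abs=1e-8)


class TestQFunction:
    def test_perfect_square_vanishes(self):
        from thresholdgp.ecm import LatentMoments
        data = OrdinalDataset(y=[1], X=[[0.0]], C=2)
        thr = ThresholdState(delta=np.array([1.0]), C=2)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=None)
        coef.refresh_eta(data.X)
        mom = LatentMoments(l_star=np.array([-1.0]), l_star2=np.array([0.0]))
        assert q_function(data, thr, coef, mom, PriorSpec(flat=True)) == 0.0

    def test_interior_category_hand_value(self):
        from thresholdgp.ecm import LatentMoments
        data = OrdinalDataset(y=[2], X=[[0.0]], C=3)
        thr = ThresholdState(delta=np.array([0.0, 2.0]), C=3)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=None)
        coef.refresh_eta(data.X)
        mom = LatentMoments(l_star=np.array([0.0]), l_star2=np.array([1.0]))
        q = q_function(data, thr, coef, mom, PriorSpec(flat=True))
        assert q == pytest.approx(np.log(2) - 2, abs=1e-12)

    def test_rejects_nonpositive_increments(self):
        data, thr, coef, prior, mom = random_instance(seed=1)
        bad = ThresholdState.__new__(ThresholdState)
        bad.delta = thr.delta.copy()
        bad.delta[1] = -0.5
        bad.C = thr.C
        with pytest.raises(ValueError):
            q_function(data, bad, coef, mom, prior)


def _numeric_argmax(fun, x0, lo, hi):
    res = optimize.minimize_scalar(lambda x: -fun(x), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    assert res.success
    return res.x


class TestCMStepsAgainstNumericMaximiser:
    """Each conditional-maximisation update must coincide with a 1-D numeric
    maximiser of the Q-function in that coordinate."""

    @pytest.mark.parametrize("seed", range(5))
    def test_delta1(self, seed):
        data, thr, coef, prior, mom = random_instance(seed, n=50, C=4)
        upd = cm_step_delta1(data, mom, thr, coef)

        def q_of(d1):
            t = ThresholdState(np.concatenate(([d1], thr.delta[1:])), thr.C)
            return q_function(data, t, coef, mom, prior)

        assert upd == pytest.approx(
            _numeric_argmax(q_of, upd, upd - 5, upd + 5), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [2, 3])
    def test_delta_k(self, seed, k):
        data, thr, coef, prior, mom = random_instance(seed + 10, n=80, C=5)
        upd = cm_step_delta_k(k, data, mom, thr, coef)

        def q_of(dk):
            d = thr.delta.copy()
            d[k - 1] = dk
            return q_function(data, ThresholdState(d, thr.C), coef, mom, prior)

        assert upd == pytest.approx(
            _numeric_argmax(q_of, upd, 1e-8, upd * 4 + 2), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("flat", [False, True])
    def test_beta(self, seed, flat):
        data, thr, coef, prior, mom = random_instance(
            seed + 20, n=60, p=4, C=3, flat=flat)
        for j in range(data.p):
            upd = cm_step_beta(j, data, mom, thr, coef, prior)

            def q_of(bj):
                c = CoefficientState(beta=coef.beta.copy(),
                                     sigma_beta2=coef.sigma_beta2)
                c.beta[j] = bj
                c.refresh_eta(data.X)
                return q_function(data, thr, c, mom, prior)

            assert upd == pytest.approx(
                _numeric_argmax(q_of, upd, upd - 3, upd + 3), abs=1e-6)

    @pytest.mark.parametrize("S,bsq,v,p,expected", [
        (2.0, 2.0, 2.0, 2, 2 / 3),
        (4.0, 0.0, 4.0, 2, 0.5),
    ])
    def test_sigma2_closed_forms(self, S, bsq, v, p, expected):
        beta = np.zeros(p)
        beta[0] = np.sqrt(bsq)
        coef = CoefficientState(beta=beta, sigma_beta2=1.0)
        prior = PriorSpec(v_beta=v, S_beta=S)
        assert cm_step_sigma2(coef, prior) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_sigma2_matches_numeric_maximiser(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 8))
        beta = rng.normal(size=p)
        prior = PriorSpec(v_beta=float(rng.uniform(5, 50)),
                          S_beta=float(rng.uniform(0.5, 5)))
        coef = CoefficientState(beta=beta, sigma_beta2=1.0)
        upd = cm_step_sigma2(coef, prior)
        bsq = float(beta @ beta)

        def obj(s2):  # sigma^2-dependent terms of the log posterior
            return (-(p / 2) * np.log(s2) - bsq / (2 * s2)
                    - (1 + prior.v_beta / 2) * np.log(s2)
                    - prior.S_beta / (2 * s2))

        num = _numeric_argmax(obj, upd, upd / 20, upd * 20)
        assert upd == pytest.approx(num, rel=1e-6)

    def test_sigma2_flat_is_error(self):
        coef = CoefficientState(beta=np.ones(2), sigma_beta2=1.0)
        with pytest.raises(ValueError):
            cm_step_sigma2(coef, PriorSpec(flat=True))

    def test_empty_category_is_error(self):
        data, thr, coef, prior, mom = random_instance(seed=3, n=30, C=4)
        data.y[data.y == 2] = 3
        with pytest.raises(ValueError, match="merge categories"):
            cm_step_delta_k(2, data, mom, thr, coef)


class TestDelta1ClosedForms:
    def test_two_lowest_records(self):
        from thresholdgp.ecm import LatentMoments
        data = OrdinalDataset(y=[1, 1], X=[[0.0], [0.0]], C=2)
        thr = ThresholdState(delta=np.array([0.3]), C=2)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=None)
        coef.refresh_eta(data.X)
        mom = LatentMoments(l_star=np.array([-0.5, -1.5]),
                            l_star2=np.zeros(2))
        assert cm_step_delta1(data, mom, thr, coef) == pytest.approx(1.0)

    def test_single_interior_record(self):
        from thresholdgp.ecm import LatentMoments
        data = OrdinalDataset(y=[2], X=[[1.0]], C=3)
        thr = ThresholdState(delta=np.array([0.0, 2.0]), C=3)
        coef = CoefficientState(beta=np.array([0.3]), sigma_beta2=None)
        coef.refresh_eta(data.X)
        mom = LatentMoments(l_star=np.array([0.1]), l_star2=np.zeros(1))
        assert cm_step_delta1(data, mom, thr, coef) == pytest.approx(-0.5)


class TestBetaClosedForms:
    def _setup(self, sigma2):
        from thresholdgp.ecm import LatentMoments
        data = OrdinalDataset(y=[1, 1], X=[[1.0], [1.0]], C=2,
                              penalized=[True])
        thr = ThresholdState(delta=np.array([0.0]), C=2)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=sigma2)
        coef.refresh_eta(data.X)
        mom = LatentMoments(l_star=np.array([-1.0, -3.0]), l_star2=np.zeros(2))
        return data, thr, coef, mom

    def test_flat_is_negative_mean(self):
        data, thr, coef, mom = self._setup(None)
        assert cm_step_beta(0, data, mom, thr, coef,
                            PriorSpec(flat=True)) == pytest.approx(2.0)

    def test_ridge_denominator(self):
        data, thr, coef, mom = self._setup(1.0)
        prior = PriorSpec(v_beta=10.0, S_beta=1.0)
        assert cm_step_beta(0, data, mom, thr, coef,
                            prior) == pytest.approx(4.0 / 3.0)


class TestObservedLogPosterior:
    def test_binary_midpoint(self):
        data = OrdinalDataset(y=[1], X=[[0.0]], C=2)
        thr = ThresholdState(delta=np.array([0.0]), C=2)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=None)
        lp = observed_log_posterior(data, thr, coef, PriorSpec(flat=True))
        assert lp == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("y", [1, 2, 3, 4, 5])
    def test_equal_slices(self, y):
        gamma = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])
        data = OrdinalDataset(y=[y], X=[[0.0]], C=5)
        thr = ThresholdState.from_gamma(gamma, C=5)
        coef = CoefficientState(beta=np.array([0.0]), sigma_beta2=None)
        lp = observed_log_posterior(data, thr, coef, PriorSpec(flat=True))
        assert lp == pytest.approx(np.log(0.2), abs=1e-10)

    def test_matches_quadrature_of_complete_likelihood(self):
        # P(y_i) integrates the working latent variable's base density over
        # its truncation region
        data, thr, coef, prior, _ = random_instance(seed=5, n=20, C=4,
                                                    flat=True)
        eta = data.X @ coef.beta
        gamma = thr.gamma
        total = 0.0
        for i in range(data.n):
            y = data.y[i]
            if y == 1:
                f = lambda l: stats.norm.pdf(l, -(eta[i] + thr.delta[0]), 1.0)
                Z, _ = quad(f, -np.inf, 0.0)
            elif y == data.C:
                f = lambda l: stats.norm.pdf(l, -(eta[i] + gamma[-1]), 1.0)
                Z, _ = quad(f, 0.0, np.inf)
            else:
                d = thr.delta[y - 1]
                f = lambda l: stats.norm.pdf(
                    l, -(eta[i] + gamma[y - 2]) / d, 1.0 / d)
                Z, _ = quad(f, 0.0, 1.0)
            total += np.log(Z)
        lp = observed_log_posterior(data, thr, coef, PriorSpec(flat=True))
        assert lp == pytest.approx(total, abs=1e-6)


def _simulate_marginal(seed, n, C, probs, p=2):
    rng = np.random.default_rng(seed)
    gamma = stats.norm.ppf(np.cumsum(probs)[:-1])
    liab = rng.normal(size=n)
    y = 1 + np.searchsorted(gamma, liab)
    X = rng.normal(size=(n, p)) * 0.5
    return OrdinalDataset(y=y, X=X, C=C), gamma


class TestFit:
    def test_null_signal_recovers_marginal_cutpoints(self):
        data, _ = _simulate_marginal(21, n=2000, C=5, probs=[0.2] * 5)
        prior = elicit_scale(mean_sq_design=mean_sq_design(data.X))
        fit = fit_mapt(data, prior)
        cum = np.cumsum(data.category_counts())[:-1] / data.n
        expected = stats.norm.ppf(cum)
        assert np.max(np.abs(fit.thresholds.gamma - expected)) < 0.08
        assert np.linalg.norm(fit.coefficients.beta) < 0.25

    @pytest.mark.parametrize("flat", [False, True])
    def test_trace_is_monotone(self, flat):
        data, _ = _simulate_marginal(22, n=300, C=3, probs=[0.3, 0.4, 0.3])
        prior = (PriorSpec(flat=True) if flat
                 else elicit_scale(mean_sq_design=mean_sq_design(data.X)))
        fit = fit_mapt(data, prior, max_iter=200)
        tr = np.asarray(fit.log_posterior_trace)
        assert np.all(np.diff(tr) >= -1e-10)

    def test_flat_prior_matches_direct_ml(self):
        data, _ = _simulate_marginal(23, n=300, C=3, probs=[0.3, 0.4, 0.3],
                                     p=3)
        fit = fit_mapt(data, PriorSpec(flat=True), tol=1e-12, max_iter=5000)

        def negll(theta):
            thr = ThresholdState(np.array([theta[0], np.exp(theta[1])]), 3)
            coef = CoefficientState(beta=theta[2:], sigma_beta2=None)
            coef.refresh_eta(data.X)
            return -observed_log_posterior(data, thr, coef,
                                           PriorSpec(flat=True))

        cum = np.cumsum(data.category_counts())[:-1] / data.n
        g0 = stats.norm.ppf(cum)
        x0 = np.concatenate([[g0[0], np.log(g0[1] - g0[0])], np.zeros(3)])
        res = optimize.minimize(negll, x0, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 2000})
        gamma_ml = np.cumsum([res.x[0], np.exp(res.x[1])])
        assert np.max(np.abs(fit.thresholds.gamma - gamma_ml)) < 1e-3
        assert np.max(np.abs(fit.coefficients.beta - res.x[2:])) < 1e-3

    def test_flat_prior_matches_statsmodels_ordered_probit(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        data, _ = _simulate_marginal(24, n=400, C=3, probs=[0.3, 0.4, 0.3],
                                     p=2)
        fit = fit_mapt(data, PriorSpec(flat=True), tol=1e-12, max_iter=5000)
        sm = OrderedModel(data.y, data.X, distr="probit").fit(
            method="bfgs", disp=False, gtol=1e-9)
        cut = sm.model.transform_threshold_params(sm.params)[1:-1]
        beta_sm = sm.params[:data.p]
        np.testing.assert_allclose(fit.thresholds.gamma, cut, atol=2e-3)
        np.testing.assert_allclose(fit.coefficients.beta, -beta_sm, atol=2e-3)

    def test_empty_category_raises(self):
        data, _ = _simulate_marginal(25, n=100, C=3, probs=[0.4, 0.3, 0.3])
        data.y[data.y == 2] = 3
        with pytest.raises(ValueError, match="merge categories"):
            fit_mapt(data, PriorSpec(flat=True))

    def test_serialisation_round_trip(self):
        data, _ = _simulate_marginal(26, n=150, C=3, probs=[0.3, 0.4, 0.3])
        prior = elicit_scale(mean_sq_design=mean_sq_design(data.X))
        fit = fit_mapt(data, prior, max_iter=50)
        d = fit.to_dict()
        assert "sigma_beta2" in d
        np.testing.assert_allclose(np.cumsum(d["delta"]), d["gamma"])
        flat_fit = fit_mapt(data, PriorSpec(flat=True), max_iter=50)
        assert "sigma_beta2" not in flat_fit.to_dict()
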