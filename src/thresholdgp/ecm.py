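"""Maximum a posteriori fitting of the ordinal threshold (probit) model by ECM.

Model
-----
An observed ordinal response ``y_i in {1..C}`` arises from a latent liability
``l_i = -x_i' beta + eps_i`` with ``eps_i ~ N(0, 1)`` and ordered cut-points
``-inf = gamma_0 < gamma_1 < ... < gamma_C = +inf``; ``y_i = c`` iff
``gamma_{c-1} < l_i < gamma_c``, so that

    P(y_i = c) = Phi(gamma_c + eta_i) - Phi(gamma_{c-1} + eta_i),

with linear predictor ``eta_i = x_i' beta``.  Priors: flat on the cut-points,
``beta_j ~ N(0, sigma_beta^2)`` on penalised columns, and a scaled inverse
chi-squared prior on sigma_beta^2 (see :mod:`thresholdgp.priors`).

Estimation
----------
The posterior mode is found by expectation--conditional-maximisation after the
increment reparameterisation ``delta_1 = gamma_1``, ``delta_c = gamma_c -
gamma_{c-1}`` (c = 2..C-1), ``delta_C = 1`` (a notational constant, never
estimated), which turns the ordering constraint into positivity of the
interior increments.  Each interior category's latent variable is rescaled to
the unit interval: for ``y_i = c`` with ``2 <= c <= C-1`` the working latent
variable is normal with mean ``-(eta_i + gamma_{c-1}) / delta_c`` and standard
deviation ``1 / delta_c`` truncated to (0, 1); for the extreme categories it
is a unit-variance normal truncated to a half line.  The E-step computes the
truncated-normal mean ``l*`` and variance ``l**`` of each record's working
latent variable; the CM-steps maximise the expected complete-data log
posterior (the Q-function) one parameter at a time in the order delta_1,
delta_2..delta_{C-1}, beta_1..beta_p, sigma_beta^2, each step using the
freshest values from the preceding steps.  Every update is available in
closed form; the observed log posterior is guaranteed non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import erfcx, gammaln

from .priors import PriorSpec

__all__ = [
    "OrdinalDataset",
    "ThresholdState",
    "CoefficientState",
    "LatentMoments",
    "FitResult",
    "truncated_moments",
    "e_step",
    "q_function",
    "cm_step_delta1",
    "cm_step_delta_k",
    "cm_step_beta",
    "cm_step_sigma2",
    "observed_log_posterior",
    "fit_mapt",
]

# Standardised truncation bounds are clipped here; beyond this the truncated
# distribution is numerically a point mass at the boundary.
_BOUND_CLIP = 30.0


@dataclass
class OrdinalDataset:
    """Ordinal responses with their design matrix.

    ``penalized`` flags, per design column, whether the coefficient receives
    the normal (ridge) prior; unflagged columns get the flat-prior update.
    """

    y: np.ndarray
    X: np.ndarray
    C: int
    penalized: np.ndarray | None = None
    column_ids: list[str] | None = None
    record_map: Any = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be records x p, matching y")
        if self.y.min() < 1 or self.y.max() > self.C:
            raise ValueError("responses must lie in 1..C")
        if self.penalized is None:
            self.penalized = np.ones(self.X.shape[1], dtype=bool)
        else:
            self.penalized = np.asarray(self.penalized, dtype=bool)
            if self.penalized.shape[0] != self.X.shape[1]:
                raise ValueError("penalized mask must have one flag per column")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def category_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.C + 1)[1:]


@dataclass
class ThresholdState:
    """Cut-point increments delta and the derived cut-points gamma.

    ``delta[0]`` (= gamma_1) is unrestricted in sign; the interior increments
    ``delta[1:]`` must be positive so the cut-points are strictly increasing.
    """

    delta: np.ndarray
    C: int

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape[0] != self.C - 1:
            raise ValueError("delta must have C-1 entries")
        if self.C > 2 and np.any(self.delta[1:] <= 0):
            raise ValueError("interior increments must be positive")

    @property
    def gamma(self) -> np.ndarray:
        """Cut-points gamma_1..gamma_{C-1} (cumulative sums of delta)."""
        return np.cumsum(self.delta)

    @classmethod
    def from_gamma(cls, gamma: np.ndarray, C: int) -> "ThresholdState":
        gamma = np.asarray(gamma, dtype=float)
        return cls(delta=np.diff(gamma, prepend=0.0), C=C)


@dataclass
class CoefficientState:
    """Coefficients, their common prior variance, and the eta cache."""

    beta: np.ndarray
    sigma_beta2: float | None
    eta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma_beta2 is not None and self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")

    def refresh_eta(self, X: np.ndarray) -> None:
        self.eta = X @ self.beta


@dataclass
class LatentMoments:
    """Conditional mean and variance of each record's working latent variable."""

    l_star: np.ndarray
    l_star2: np.ndarray


@dataclass
class FitResult:
    thresholds: ThresholdState
    coefficients: CoefficientState
    log_posterior_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    column_ids: list[str] | None = None

    def to_dict(self) -> dict:
        out = {
            "delta": self.thresholds.delta.tolist(),
            "gamma": self.thresholds.gamma.tolist(),
            "beta": self.coefficients.beta.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
            "log_posterior_trace": list(self.log_posterior_trace),
        }
        if self.column_ids is not None:
            out["column_ids"] = list(self.column_ids)
        if self.coefficients.sigma_beta2 is not None:
            out["sigma_beta2"] = self.coefficients.sigma_beta2
        return out


_SQRT_2OPI = np.sqrt(2.0 / np.pi)


def _std_trunc_moments(a: np.ndarray, b: np.ndarray):
    """Mean and variance of a standard normal truncated to (a, b), vectorised.

    Intervals are first reflected so their midpoint is non-negative.  Deep in
    the upper tail (a >= 6) differences of Phi underflow, so the moment
    ratios are rewritten with the scaled complementary error function:
    with d = exp((a^2 - b^2)/2),

        (phi(a) - phi(b)) / Z = sqrt(2/pi) (1 - d)     / (erfcx(a/r2) - d erfcx(b/r2))
        (a phi(a) - b phi(b)) / Z = sqrt(2/pi) (a - b d) / (erfcx(a/r2) - d erfcx(b/r2))
    """
    a = np.array(a, dtype=float, copy=True)
    b = np.array(b, dtype=float, copy=True)
    flip = (a + b) < 0  # -inf + inf never occurs together after clipping
    a[flip], b[flip] = -b[flip], -a[flip]

    tail = a >= 6.0
    mean0 = np.empty_like(a)
    r2 = np.empty_like(a)
    if np.any(~tail):
        an, bn = a[~tail], b[~tail]
        pa, pb = stats.norm.pdf(an), stats.norm.pdf(bn)
        # when the whole interval sits above 0, survival functions keep the
        # mass difference accurate; otherwise plain CDFs are safe
        Z = np.where(an > 0,
                     stats.norm.sf(an) - stats.norm.sf(bn),
                     stats.norm.cdf(bn) - stats.norm.cdf(an))
        with np.errstate(invalid="ignore"):
            apa = np.where(np.isinf(an), 0.0, an * pa)
            bpb = np.where(np.isinf(bn), 0.0, bn * pb)
        mean0[~tail] = (pa - pb) / Z
        r2[~tail] = (apa - bpb) / Z
    if np.any(tail):
        at, bt = a[tail], b[tail]
        with np.errstate(over="ignore"):
            d = np.exp((at * at - bt * bt) / 2.0)  # in [0, 1]
        ea = erfcx(at / np.sqrt(2.0))
        eb = np.where(np.isinf(bt), 0.0, erfcx(np.minimum(bt, 1e30) / np.sqrt(2.0)))
        den = ea - d * eb
        mean0[tail] = _SQRT_2OPI * (1.0 - d) / den
        r2[tail] = _SQRT_2OPI * (at - bt * d) / den
    var = np.maximum(1.0 + r2 - mean0 * mean0, 0.0)
    mean0[flip] = -mean0[flip]
    return mean0, var


def truncated_moments(mu, sd, a, b):
    """Mean and variance of ``N(mu, sd^2)`` truncated to the interval (a, b).

    Vectorised over all arguments; bounds may be infinite.  Standardised
    bounds are clipped at +/-30, beyond which the distribution is numerically
    degenerate at the nearer boundary.
    """
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    if np.any(a >= b):
        raise ValueError("lower bound must be below upper bound")
    alpha = np.clip((a - mu) / sd, -_BOUND_CLIP, _BOUND_CLIP)
    beta = np.clip((b - mu) / sd, -_BOUND_CLIP, _BOUND_CLIP)
    beta = np.maximum(beta, alpha + 1e-12)
    mean0, var0 = _std_trunc_moments(alpha, beta)
    return mu + sd * mean0, sd * sd * var0


def _lstar_scale_offset(data: OrdinalDataset, thr: ThresholdState):
    """Per-record (s_i, o_i): the Q-function term is
    ``-2 log s_i + l** s_i^2 + (l* s_i + eta_i + o_i)^2`` with s_i = 1 and the
    log term absent for the extreme categories."""
    gamma = thr.gamma
    y = data.y
    s = np.ones(data.n)
    o = np.empty(data.n)
    first = y == 1
    o[first] = thr.delta[0]
    mid = (y >= 2) & (y <= data.C - 1)
    s[mid] = thr.delta[y[mid] - 1]
    o[~first] = gamma[y[~first] - 2]
    return s, o


def e_step(data: OrdinalDataset, thr: ThresholdState,
           coef: CoefficientState) -> LatentMoments:
    """Truncated-normal moments of the working latent variable per record.

    * ``y = 1``: ``N(-(eta + delta_1), 1)`` truncated to (-inf, 0);
    * ``y = c``, 2 <= c <= C-1: ``N(-(eta + gamma_{c-1}) / delta_c,
      (1/delta_c)^2)`` truncated to (0, 1);
    * ``y = C``: ``N(-(eta + gamma_{C-1}), 1)`` truncated to (0, +inf).
    """
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    y = data.y
    gamma = thr.gamma
    mu = np.empty(data.n)
    sd = np.ones(data.n)
    lo = np.zeros(data.n)
    hi = np.full(data.n, np.inf)

    first = y == 1
    mu[first] = -(eta[first] + thr.delta[0])
    lo[first] = -np.inf
    hi[first] = 0.0

    last = y == data.C
    mu[last] = -(eta[last] + gamma[-1])

    mid = ~first & ~last
    if mid.any():
        d = thr.delta[y[mid] - 1]
        mu[mid] = -(eta[mid] + gamma[y[mid] - 2]) / d
        sd[mid] = 1.0 / d
        hi[mid] = 1.0

    mean, var = truncated_moments(mu, sd, lo, hi)
    return LatentMoments(l_star=mean, l_star2=var)


def q_function(data: OrdinalDataset, thr: ThresholdState, coef: CoefficientState,
               moments: LatentMoments, prior: PriorSpec) -> float:
    """Expected complete-data log posterior (additive constants omitted)."""
    if data.C > 2 and np.any(thr.delta[1:] <= 0):
        raise ValueError("interior increments must be positive")
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    s, o = _lstar_scale_offset(data, thr)
    term = (-2.0 * np.log(s) + moments.l_star2 * s**2
            + (moments.l_star * s + eta + o) ** 2)
    q = -0.5 * float(np.sum(term))
    if not prior.flat:
        sig2 = coef.sigma_beta2
        bsq = float(np.sum(coef.beta[data.penalized] ** 2))
        p_pen = int(np.sum(data.penalized))
        q += (-bsq / (2.0 * sig2) - 0.5 * p_pen * np.log(sig2)
              - (1.0 + prior.v_beta / 2.0) * np.log(sig2)
              - prior.S_beta / (2.0 * sig2))
    return q


def cm_step_delta1(data: OrdinalDataset, moments: LatentMoments,
                   thr: ThresholdState, coef: CoefficientState) -> float:
    """Closed-form update of the first cut-point gamma_1 = delta_1."""
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    s, o = _lstar_scale_offset(data, thr)
    # contribution per record: l* s + eta, plus gamma_{c-1} - delta_1 for c >= 2
    extra = np.where(data.y >= 2, o - thr.delta[0], 0.0)
    return float(-np.mean(moments.l_star * s + eta + extra))


def cm_step_delta_k(k: int, data: OrdinalDataset, moments: LatentMoments,
                    thr: ThresholdState, coef: CoefficientState) -> float:
    """Update of the interior increment delta_k (2 <= k <= C-1).

    The stationarity condition is the quadratic
    ``a delta_k^2 + b delta_k - n_k = 0``; the positive root
    ``(-b + sqrt(b^2 + 4 a n_k)) / (2 a)`` is the conditional maximiser.
    """
    if not 2 <= k <= data.C - 1:
        raise ValueError("k must index an interior category (2..C-1)")
    y = data.y
    in_k = y == k
    n_k = int(np.sum(in_k))
    if n_k == 0:
        raise ValueError(f"empty category {k}; merge categories before fitting")
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    gamma = thr.gamma
    ls, lv = moments.l_star, moments.l_star2

    above = y > k
    a = float(np.sum(lv[in_k] + ls[in_k] ** 2)) + int(np.sum(above))
    # delta_C == 1 by convention; gamma_{c-1} - delta_k drops the k-th increment
    s_above = np.where(y[above] == data.C, 1.0, thr.delta[np.minimum(y[above] - 1, data.C - 2)])
    gsum_above = gamma[y[above] - 2] - thr.delta[k - 1]
    b = (float(np.sum(ls[in_k] * eta[in_k]))
         + float(np.sum(ls[in_k])) * gamma[k - 2]
         + float(np.sum(ls[above] * s_above + eta[above] + gsum_above)))
    if a <= 0:
        raise ValueError("non-positive quadratic coefficient in delta update")
    return float((-b + np.sqrt(b * b + 4.0 * a * n_k)) / (2.0 * a))


def cm_step_beta(j: int, data: OrdinalDataset, moments: LatentMoments,
                 thr: ThresholdState, coef: CoefficientState,
                 prior: PriorSpec) -> float:
    """Ridge (or unpenalised) coordinate update of beta_j.

    ``beta_j = -sum_i x_ij (l*_i s_i + eta_{i,-j} + o_i) /
    (sum_i x_ij^2 + 1/sigma_beta^2)``, where ``eta_{i,-j}`` excludes column j
    and the prior term is dropped for flat/unpenalised columns.
    """
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    s, o = _lstar_scale_offset(data, thr)
    x = data.X[:, j]
    r = moments.l_star * s + eta + o
    num = -float(x @ (r - x * coef.beta[j]))
    pen = 0.0
    if not prior.flat and data.penalized[j]:
        pen = 1.0 / coef.sigma_beta2
    den = float(x @ x) + pen
    if den == 0:
        raise ValueError("degenerate column: zero denominator in beta update")
    return num / den


def cm_step_sigma2(coef: CoefficientState, prior: PriorSpec,
                   penalized: np.ndarray | None = None) -> float:
    """Conditional-mode update of the common coefficient variance.

    ``sigma_beta^2 = (S_beta + beta' beta) / (2 + v_beta + p)`` over the
    penalised coefficients.  Removed entirely under the flat prior.
    """
    if prior.flat:
        raise ValueError("variance update does not exist under the flat prior")
    beta = coef.beta if penalized is None else coef.beta[penalized]
    p = beta.shape[0]
    if p < 1:
        raise ValueError("no penalised coefficients")
    return float((prior.S_beta + beta @ beta) / (2.0 + prior.v_beta + p))


def _interval_log_probs(gamma: np.ndarray, eta: np.ndarray,
                        y: np.ndarray, C: int) -> np.ndarray:
    """log[Phi(gamma_y + eta) - Phi(gamma_{y-1} + eta)], tail-stable."""
    upper = np.where(y == C, np.inf, gamma[np.minimum(y - 1, C - 2)] + eta)
    lower = np.where(y == 1, -np.inf, gamma[np.maximum(y - 2, 0)] + eta)
    # use the survival function when the interval sits in the upper tail
    use_sf = (np.where(np.isinf(lower), upper, lower) > 0)
    prob = np.where(use_sf,
                    stats.norm.sf(lower) - stats.norm.sf(upper),
                    stats.norm.cdf(upper) - stats.norm.cdf(lower))
    with np.errstate(divide="ignore"):
        return np.where(prob > 0, np.log(np.maximum(prob, 1e-300)), -np.inf)


def observed_log_posterior(data: OrdinalDataset, thr: ThresholdState,
                           coef: CoefficientState, prior: PriorSpec) -> float:
    """Log posterior of (beta, gamma, sigma_beta^2) with the latent integrated out.

    Returns ``-inf`` (rather than raising) when some record's category
    probability underflows to zero; used for convergence monitoring and for
    the ascent guarantee check.
    """
    gamma = thr.gamma
    if np.any(np.diff(gamma) <= 0):
        raise ValueError("cut-points must be strictly increasing")
    eta = coef.eta if coef.eta is not None else data.X @ coef.beta
    ll = float(np.sum(_interval_log_probs(gamma, eta, data.y, data.C)))
    if not np.isfinite(ll):
        return -np.inf
    if not prior.flat:
        sig2 = coef.sigma_beta2
        b = coef.beta[data.penalized]
        p_pen = b.shape[0]
        ll += float(-0.5 * p_pen * np.log(2.0 * np.pi * sig2)
                    - (b @ b) / (2.0 * sig2))
        # scaled inverse chi-squared log density at sig2
        half_v = prior.v_beta / 2.0
        ll += float(half_v * np.log(prior.S_beta / 2.0) - gammaln(half_v)
                    - (1.0 + half_v) * np.log(sig2)
                    - prior.S_beta / (2.0 * sig2))
    return ll


def _initial_state(data: OrdinalDataset, prior: PriorSpec
                   ) -> tuple[ThresholdState, CoefficientState]:
    """beta = 0; cut-points at probit quantiles of the empirical cumulative
    category proportions; sigma_beta^2 at its prior mean."""
    counts = data.category_counts()
    cum = np.cumsum(counts)[:-1] / data.n
    gamma0 = stats.norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6))
    thr = ThresholdState.from_gamma(gamma0, data.C)
    sig2 = None if prior.flat else prior.prior_mean
    coef = CoefficientState(beta=np.zeros(data.p), sigma_beta2=sig2)
    coef.refresh_eta(data.X)
    return thr, coef


def fit_mapt(data: OrdinalDataset, prior: PriorSpec,
             init: tuple[ThresholdState, CoefficientState] | None = None,
             tol: float = 1e-8, max_iter: int = 1000) -> FitResult:
    """Fit the threshold model to its posterior mode by ECM.

    Iterates the E-step and the closed-form CM-steps until the relative change
    of the observed log posterior falls below ``tol`` or ``max_iter`` is
    reached.  Requires every category 1..C to be observed (an empty interior
    category makes its increment update degenerate).
    """
    counts = data.category_counts()
    if np.any(counts == 0):
        missing = [c + 1 for c in range(data.C) if counts[c] == 0]
        raise ValueError(f"empty category {missing}; merge categories before fitting")
    if data.p < 1:
        raise ValueError("design matrix must have at least one column")

    thr, coef = init if init is not None else _initial_state(data, prior)
    coef.refresh_eta(data.X)
    xsq = np.einsum("ij,ij->j", data.X, data.X)

    trace: list[float] = []
    last = observed_log_posterior(data, thr, coef, prior)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moments = e_step(data, thr, coef)

        thr = ThresholdState(
            np.concatenate(([cm_step_delta1(data, moments, thr, coef)],
                            thr.delta[1:])), data.C)
        for k in range(2, data.C):
            d = thr.delta.copy()
            d[k - 1] = cm_step_delta_k(k, data, moments, thr, coef)
            thr = ThresholdState(d, data.C)

        # coordinate sweep over beta with an incrementally maintained
        # residual r_i = l*_i s_i + eta_i + o_i
        s, o = _lstar_scale_offset(data, thr)
        r = moments.l_star * s + coef.eta + o
        inv_sig = 0.0 if prior.flat else 1.0 / coef.sigma_beta2
        for j in range(data.p):
            x = data.X[:, j]
            pen = inv_sig if data.penalized[j] else 0.0
            den = xsq[j] + pen
            if den == 0.0:
                raise ValueError(
                    "degenerate column: zero denominator in beta update")
            new_bj = -float(x @ r - xsq[j] * coef.beta[j]) / den
            step = new_bj - coef.beta[j]
            if step != 0.0:
                coef.beta[j] = new_bj
                coef.eta += step * x
                r += step * x

        if not prior.flat:
            coef.sigma_beta2 = cm_step_sigma2(coef, prior, data.penalized)

        lp = observed_log_posterior(data, thr, coef, prior)
        trace.append(lp)
        if np.isfinite(lp) and np.isfinite(last):
            if abs(lp - last) / (1.0 + abs(lp)) < tol:
                converged = True
                last = lp
                break
        last = lp

    return FitResult(thresholds=thr, coefficients=coef,
                     log_posterior_trace=trace, iterations=it,
                     converged=converged, column_ids=data.column_ids)
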