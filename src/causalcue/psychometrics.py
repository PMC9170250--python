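"""Descriptive psychometric analyses.

Three estimator families, all sklearn-style (``fit`` / fitted attributes
with trailing underscores / ``get_params``):

* :class:`PsychometricFunction` - maximum-likelihood cumulative-Gaussian
  fit of binary localization responses, with optional lapse parameters.
  The bias (PSE) ``mu`` and threshold ``sigma`` summarize accuracy and
  precision; goodness of fit is R^2 on per-level proportions, and the
  screening convention flags observers with R^2 < 0.5 as flat.
* :class:`GaussianCurve` - least-squares Gaussian fit to the proportion of
  common-cause (or synchrony) reports over disparity, parameterized by
  amplitude, mean and width, optionally with an additive baseline held to a
  reference shape (the functional-form alternative to causal inference).
* :class:`DisparityPolynomial` - nested OLS (null/linear/quadratic/cubic)
  of localization bias against disparity; the partial R^2 of the cubic term
  indexes saturation of the bias at large disparity, the signature of
  causal inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares, minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

__all__ = [
    "PsychometricFunction",
    "GaussianCurve",
    "DisparityPolynomial",
    "fit_cumulative_gaussian",
    "goodness_of_fit",
    "fit_gaussian_curve",
    "fit_gaussian_plus_bias",
    "fit_cubic_regression",
    "proportions",
    "FLAT_R2_THRESHOLD",
]

#: Observers whose descriptive fit explains less than this fraction of
#: variance are flagged as flat (no stimulus-driven modulation).
FLAT_R2_THRESHOLD = 0.50

_EPS = 1e-12


def proportions(x, y):
    """Aggregate per-trial binary outcomes into (levels, successes, totals)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    levels = np.unique(x)
    k = np.array([y[x == v].sum() for v in levels], float)
    n = np.array([(x == v).sum() for v in levels], float)
    return levels, k, n


def _r_squared(observed, predicted):
    """1 - RSS/TSS on per-condition proportions."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    rss = np.sum((observed - predicted) ** 2)
    tss = np.sum((observed - observed.mean()) ** 2)
    if tss == 0:
        return 1.0 if rss == 0 else -np.inf
    return float(1.0 - rss / tss)


class PsychometricFunction(BaseEstimator):
    """Cumulative-Gaussian psychometric function with lapses.

    P(positive | x) = lapse_rate * lapse_bias
                      + (1 - lapse_rate) * Phi((x - mu) / sigma)

    Parameters
    ----------
    lapse_mode : {"none", "rate_only", "rate_and_bias"}
        Which lapse parameters are free.  ``rate_only`` fixes the lapse
        bias at 1/2; ``none`` fixes the rate at 0.
    n_starts : int
        Seeded multi-starts of the bounded quasi-Newton optimizer.
    tol : float
        Convergence tolerance on the negative log-likelihood.

    Attributes
    ----------
    mu_, sigma_, lapse_rate_, lapse_bias_ : float
    r_squared_ : float
        R^2 of predicted vs observed per-level proportions.
    degenerate_ : bool
        True when the data carry no slope information (all responses
        identical); parameters are then not interpretable.
    n_trials_ : int
    """

    def __init__(self, lapse_mode="rate_only", n_starts=10, tol=1e-8, random_state=0):
        self.lapse_mode = lapse_mode
        self.n_starts = n_starts
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _unpack(self, theta):
        mu, log_sigma = theta[0], theta[1]
        lam = theta[2] if self.lapse_mode != "none" else 0.0
        bias = theta[3] if self.lapse_mode == "rate_and_bias" else 0.5
        return mu, np.exp(log_sigma), lam, bias

    def _nll(self, theta, x, k, n):
        mu, sigma, lam, bias = self._unpack(theta)
        p = lam * bias + (1 - lam) * norm.cdf((x - mu) / sigma)
        p = np.clip(p, _EPS, 1 - _EPS)
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    def fit(self, x, y=None, counts=None):
        """Fit by maximum likelihood.

        Either per-trial: ``x`` stimulus per trial, ``y`` binary outcome
        (1 = positive response); or aggregated: ``x`` levels, ``y``
        successes, ``counts`` totals per level.
        """
        if self.lapse_mode not in ("none", "rate_only", "rate_and_bias"):
            raise ValueError(f"unknown lapse_mode {self.lapse_mode!r}")
        if counts is None:
            x, k, n = proportions(x, np.asarray(y))
        else:
            x = np.asarray(x, float)
            k = np.asarray(y, float)
            n = np.asarray(counts, float)
        if len(x) < 3:
            raise ValueError("need responses at >= 3 distinct stimulus levels")
        if np.any(n < 1):
            raise ValueError("every stimulus level needs at least one trial")
        self.n_trials_ = int(n.sum())
        self.degenerate_ = bool(k.sum() == 0 or k.sum() == n.sum())

        span = max(x.max() - x.min(), 1e-3)
        rng = np.random.default_rng(self.random_state)
        lo, hi = x.min() - 2 * span, x.max() + 2 * span
        bounds = [(lo, hi), (np.log(1e-3), np.log(20 * span)), (0.0, 0.5), (0.0, 1.0)]
        ndim = {"none": 2, "rate_only": 3, "rate_and_bias": 4}[self.lapse_mode]
        bounds = bounds[:ndim]

        p_obs = k / n
        # moment start: PSE near the 50% crossing, slope from the spread
        mu0 = float(np.interp(0.5, np.clip(p_obs, 0.01, 0.99), x)) if np.any(np.diff(p_obs)) else 0.0
        starts = [np.array([mu0, np.log(span / 4), 0.02, 0.5][:ndim])]
        for _ in range(max(self.n_starts - 1, 0)):
            starts.append(
                np.array(
                    [
                        rng.uniform(x.min(), x.max()),
                        rng.uniform(np.log(span / 20), np.log(2 * span)),
                        rng.uniform(0, 0.3),
                        rng.uniform(0.2, 0.8),
                    ][:ndim]
                )
            )
        best = None
        for s in starts:
            res = minimize(
                self._nll, s, args=(x, k, n), method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "maxiter": 500},
            )
            key = (res.fun, float(np.linalg.norm(res.x)))
            if best is None or key < best[0]:
                best = (key, res)
        res = best[1]
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"psychometric fit did not converge: {res.message}")
        self.mu_, self.sigma_, self.lapse_rate_, self.lapse_bias_ = self._unpack(res.x)
        self.nll_ = float(res.fun)
        self.r_squared_ = _r_squared(p_obs, self.predict_proba(x))
        self.flat_ = self.degenerate_ or self.r_squared_ < FLAT_R2_THRESHOLD
        return self

    def predict_proba(self, x):
        """Probability of the positive response at stimulus value(s) x."""
        p = self.lapse_rate_ * self.lapse_bias_ + (1 - self.lapse_rate_) * norm.cdf(
            (np.asarray(x, float) - self.mu_) / self.sigma_
        )
        return p

    def predict(self, x):
        return (self.predict_proba(x) >= 0.5).astype(int)

    def score(self, x, y=None, counts=None):
        """R^2 of predicted vs observed proportions on held data."""
        if counts is None:
            x, k, n = proportions(x, np.asarray(y))
        else:
            k, n = np.asarray(y, float), np.asarray(counts, float)
        return _r_squared(k / n, self.predict_proba(np.asarray(x, float)))


class GaussianCurve(BaseEstimator):
    """Gaussian curve for common-cause report proportions over disparity.

    p(delta) = amplitude * exp(-(delta - mean)^2 / (2 width^2)) + baseline

    With ``reference`` set, the Gaussian shape (amplitude, mean, width) is
    frozen to the reference fit and only the additive baseline is free -
    the functional-form alternative used to contrast against causal
    inference.  Otherwise baseline is fixed at 0 and the three shape
    parameters are fit by least squares on proportions.
    """

    def __init__(self, reference=None, n_starts=10, random_state=0):
        self.reference = reference
        self.n_starts = n_starts
        self.random_state = random_state

    @staticmethod
    def _curve(delta, amplitude, mean, width, baseline=0.0):
        return amplitude * np.exp(-((delta - mean) ** 2) / (2.0 * width**2)) + baseline

    def fit(self, delta, prop, counts=None):
        delta = np.asarray(delta, float)
        prop = np.asarray(prop, float)
        if len(np.unique(delta)) < 5:
            raise ValueError("need proportions at >= 5 disparity levels")

        if self.reference is not None:
            ref = self.reference
            shape = self._curve(delta, ref.amplitude_, ref.mean_, ref.width_)
            b = float(np.clip(np.mean(prop - shape), -1.0, 1.0))
            self.amplitude_, self.mean_, self.width_ = ref.amplitude_, ref.mean_, ref.width_
            self.baseline_ = b
        else:
            span = max(np.abs(delta).max(), 1.0)
            rng = np.random.default_rng(self.random_state)

            def resid(theta):
                a, m, lw = theta
                return prop - self._curve(delta, a, m, np.exp(lw))

            starts = [np.array([np.clip(prop.max(), 0.05, 1.0), delta[np.argmax(prop)],
                                np.log(span / 2)])]
            for _ in range(self.n_starts - 1):
                starts.append(
                    np.array(
                        [rng.uniform(0.1, 1.0), rng.uniform(delta.min(), delta.max()),
                         rng.uniform(np.log(span / 10), np.log(2 * span))]
                    )
                )
            lo = [0.0, delta.min() - span, np.log(1e-3)]
            hi = [1.0, delta.max() + span, np.log(20 * span)]
            best = None
            for s in starts:
                res = least_squares(resid, np.clip(s, lo, hi), bounds=(lo, hi),
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15)
                key = (res.cost, float(np.linalg.norm(res.x)))
                if best is None or key < best[0]:
                    best = (key, res)
            a, m, lw = best[1].x
            self.amplitude_, self.mean_, self.width_ = float(a), float(m), float(np.exp(lw))
            self.baseline_ = 0.0
        self.r_squared_ = _r_squared(prop, self.predict(delta))
        self.flat_ = self.r_squared_ < FLAT_R2_THRESHOLD
        return self

    def predict(self, delta):
        return self._curve(
            np.asarray(delta, float), self.amplitude_, self.mean_, self.width_, self.baseline_
        )

    def score(self, delta, prop):
        return _r_squared(np.asarray(prop, float), self.predict(delta))


class DisparityPolynomial(BaseEstimator):
    """Nested polynomial regression of localization bias on disparity.

    Fits null/linear/quadratic/cubic OLS models
    ``y = a0 + a1 d + a2 d^2 + a3 d^3`` and reports per-order R^2 and the
    partial R^2 of the cubic term,
    ``(RSS_quadratic - RSS_cubic) / RSS_quadratic``.
    """

    ORDERS = ("null", "linear", "quadratic", "cubic")

    def fit(self, delta, bias):
        delta = np.asarray(delta, float)
        bias = np.asarray(bias, float)
        if len(np.unique(delta)) < 5:
            raise ValueError("need bias estimates at >= 5 distinct disparities")
        X_full = np.column_stack([delta**p for p in range(4)])
        rss = {}
        r2 = {}
        for order, name in enumerate(self.ORDERS):
            X = X_full[:, : order + 1]
            model = sm.OLS(bias, X).fit()
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise np.linalg.LinAlgError("rank-deficient disparity design")
            rss[name] = float(np.sum(model.resid**2))
            tss = float(np.sum((bias - bias.mean()) ** 2))
            r2[name] = 1.0 - rss[name] / tss if tss > 0 else 1.0
            if name == "cubic":
                self.coef_ = np.asarray(model.params, float)
        self.r_squared_by_order_ = r2
        self.rss_by_order_ = rss
        tss = float(np.sum((bias - bias.mean()) ** 2))
        if rss["quadratic"] <= max(1e-12 * tss, 1e-20):
            # the quadratic model is already exact; the cubic adds nothing
            self.partial_r2_cubic_ = 0.0
        else:
            self.partial_r2_cubic_ = float(
                np.clip((rss["quadratic"] - rss["cubic"]) / rss["quadratic"], 0.0, 1.0)
            )
        return self

    def predict(self, delta, order="cubic"):
        delta = np.asarray(delta, float)
        p = self.ORDERS.index(order)
        return np.column_stack([delta**i for i in range(p + 1)]) @ self.coef_[: p + 1]


# --------------------------------------------------------------------------
# Thin functional wrappers (the operation surface)
# --------------------------------------------------------------------------

def fit_cumulative_gaussian(x, k, n, lapse_mode="rate_only", **kwargs) -> PsychometricFunction:
    """MLE cumulative-Gaussian fit to per-level response counts."""
    return PsychometricFunction(lapse_mode=lapse_mode, **kwargs).fit(x, k, counts=n)


def goodness_of_fit(fit: PsychometricFunction, x, k, n) -> float:
    """R^2 of a psychometric fit against per-level proportions."""
    return fit.score(x, k, counts=n)


def fit_gaussian_curve(delta, prop, **kwargs) -> GaussianCurve:
    """Least-squares Gaussian fit to report proportions over disparity."""
    return GaussianCurve(**kwargs).fit(delta, prop)


def fit_gaussian_plus_bias(delta, prop, reference_fit: GaussianCurve) -> GaussianCurve:
    """Hold the reference Gaussian shape; fit only an additive baseline."""
    return GaussianCurve(reference=reference_fit).fit(delta, prop)


def fit_cubic_regression(delta, bias) -> DisparityPolynomial:
    """Nested null/linear/quadratic/cubic OLS of bias against disparity."""
    return DisparityPolynomial().fit(delta, bias)


def psychometric_table(data, experiment="exp2"):
    """Per-(reliability, delta) psychometric fits of an implicit dataset.

    Returns a DataFrame with bias/threshold/R^2 per cell, fitting the
    proportion of rightward responses against the auditory location.
    """
    trials = data.trials if hasattr(data, "trials") else data
    sub = trials[(trials["experiment"] == experiment) & (trials["condition"] == "audio_visual")]
    rows = []
    for (rel, delta), cell in sub.groupby(["reliability", "delta"]):
        x = cell["eps_a"].to_numpy(dtype=float)
        y = (cell["response"].to_numpy() == 1).astype(float)
        fit = PsychometricFunction(lapse_mode="rate_only").fit(x, y)
        rows.append(
            {
                "reliability": rel,
                "delta": float(delta),
                "mu": fit.mu_,
                "sigma": fit.sigma_,
                "r_squared": fit.r_squared_,
                "n_trials": fit.n_trials_,
                "degenerate": fit.degenerate_,
            }
        )
    return pd.DataFrame(rows)
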