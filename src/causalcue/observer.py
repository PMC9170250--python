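"""Ideal-observer core for audio-visual causal inference.

The generative model: on each trial the true auditory and visual locations
``eps_a, eps_v`` are corrupted by Gaussian sensory noise into measurements
``Xa ~ N(eps_a, sigma_a^2)``, ``Xv ~ N(eps_v, sigma_v^2)``.  The observer
entertains two causal structures - one shared source (C = 1, probability
``p_common``) or two independent sources (C = 2) - with Gaussian natural
priors over the source locations.  Localization ("implicit") responses
report the side of the inferred auditory source; common-cause ("explicit")
responses compare the two structure likelihoods at a criterion set by
``p_combined``.

Everything here is a pure function of (measurement, parameters); all
densities are evaluated in log space, and all functions broadcast over
NumPy arrays of measurements.  Marginalization over measurement noise is
done with a 1-D Gauss-Hermite rule over the visual measurement while the
auditory dimension is integrated exactly: the implicit decision is monotone
in ``Xa`` so its region is a half-line found by bisection, and the explicit
decision's log-likelihood ratio is an exact quadratic in ``Xa`` so its
region is an interval (or complement) with closed-form Gaussian mass.
A discontinuous-indicator product quadrature would converge far too slowly
for fitting; this hybrid scheme is validated against Monte-Carlo and dense
grid oracles in the test suite.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import expit, log_ndtr, roots_hermitenorm
from scipy.stats import norm

from .conventions import COMMON, LEFT, RIGHT, SEPARATE
from .params import ObserverParams, QuadratureSpec

__all__ = [
    "likelihood_common",
    "likelihood_separate",
    "log_likelihood_common",
    "log_likelihood_separate",
    "posterior_common",
    "implicit_decision",
    "explicit_decision",
    "implicit_rightward_belief",
    "response_prob_implicit",
    "response_prob_explicit",
    "response_prob_unisensory",
    "p_combined_from_components",
    "p_combined_from_criterion",
]

_BRACKET = 1e4  # degrees; decision thresholds beyond this give probability 0/1


def _log_normpdf(x, mean, var):
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mean) ** 2 / (2.0 * var)


class _Consts:
    """Derived constants for one (params, reliability) pair."""

    def __init__(self, params: ObserverParams, reliability: str):
        self.sa = float(params.sigma_a)
        self.sv = float(params.sigma_v[reliability])
        self.va, self.vv = self.sa**2, self.sv**2
        self.mua, self.muv = params.mu_a_prior, params.mu_v_prior
        self.vap = params.sigma_a_prior**2
        self.vvp = params.sigma_v_prior**2
        # fused natural prior over the shared source (C = 1)
        self.vp = 1.0 / (1.0 / self.vap + 1.0 / self.vvp)
        self.mup = self.vp * (self.mua / self.vap + self.muv / self.vvp)
        self.p_common = params.p_common
        self.p_choice = params.p_choice_implicit


def _consts(params, reliability):
    params.validate()
    return _Consts(params, reliability)


# --------------------------------------------------------------------------
# Structure likelihoods and the cause posterior
# --------------------------------------------------------------------------

def _log_L1(xa, xv, c: _Consts):
    # integral over the shared source S of N(Xa;S,va) N(Xv;S,vv) N(S;mup,vp)
    s2 = 1.0 / (1.0 / c.va + 1.0 / c.vv)
    m = s2 * (xa / c.va + xv / c.vv)
    return _log_normpdf(xa, xv, c.va + c.vv) + _log_normpdf(m, c.mup, s2 + c.vp)


def _log_L2(xa, xv, c: _Consts):
    return _log_normpdf(xa, c.mua, c.va + c.vap) + _log_normpdf(xv, c.muv, c.vv + c.vvp)


def log_likelihood_common(x_a, x_v, params, reliability="high"):
    """log p(Xa, Xv | C = 1): single-source marginal with the fused prior."""
    xa, xv = np.broadcast_arrays(np.asarray(x_a, float), np.asarray(x_v, float))
    return _log_L1(xa, xv, _consts(params, reliability))


def log_likelihood_separate(x_a, x_v, params, reliability="high"):
    """log p(Xa, Xv | C = 2): product of the two per-modality convolutions."""
    xa, xv = np.broadcast_arrays(np.asarray(x_a, float), np.asarray(x_v, float))
    return _log_L2(xa, xv, _consts(params, reliability))


def likelihood_common(x_a, x_v, params, reliability="high"):
    return np.exp(log_likelihood_common(x_a, x_v, params, reliability))


def likelihood_separate(x_a, x_v, params, reliability="high"):
    return np.exp(log_likelihood_separate(x_a, x_v, params, reliability))


def posterior_common(x_a, x_v, params, reliability="high"):
    """p(C = 1 | Xa, Xv) under the causal prior p_common."""
    c = _consts(params, reliability)
    xa, xv = np.broadcast_arrays(np.asarray(x_a, float), np.asarray(x_v, float))
    if c.p_common <= 0.0:
        return np.zeros_like(xa)
    if c.p_common >= 1.0:
        return np.ones_like(xa)
    la = np.log(c.p_common) + _log_L1(xa, xv, c)
    lb = np.log1p(-c.p_common) + _log_L2(xa, xv, c)
    return expit(la - lb)


# --------------------------------------------------------------------------
# Implicit (localization) rule
# --------------------------------------------------------------------------

def _half_line_posterior(mean, sd, prior_mean, prior_sd, p_choice):
    """p(D = 1) given a Gaussian source posterior truncated by the task prior.

    The task prior restricts the source to a half-line per category; the
    truncated-prior normalizers P(S > 0), P(S < 0) under the natural prior
    enter the category posterior together with the Bernoulli choice prior.
    """
    lq_pos, lq_neg = log_ndtr(mean / sd), log_ndtr(-mean / sd)
    lpi_pos = log_ndtr(prior_mean / prior_sd)
    lpi_neg = log_ndtr(-prior_mean / prior_sd)
    if p_choice <= 0.0:
        return np.zeros_like(np.asarray(mean, float))
    if p_choice >= 1.0:
        return np.ones_like(np.asarray(mean, float))
    num = np.log(p_choice) + lq_pos + lpi_neg
    alt = np.log1p(-p_choice) + lq_neg + lpi_pos
    return np.exp(num - np.logaddexp(num, alt))


def _rightward_belief(xa, xv, c: _Consts):
    """p(D_imp = 1 | Xa, Xv): posterior of 'auditory source is rightward'."""
    # mixture weight: cause posterior
    if c.p_common <= 0.0:
        w1 = np.zeros_like(xa)
    elif c.p_common >= 1.0:
        w1 = np.ones_like(xa)
    else:
        w1 = expit(
            np.log(c.p_common)
            - np.log1p(-c.p_common)
            + _log_L1(xa, xv, c)
            - _log_L2(xa, xv, c)
        )
    # C = 1: shared-source posterior fuses both measurements and the prior
    tau1 = 1.0 / c.va + 1.0 / c.vv + 1.0 / c.vp
    m1 = (xa / c.va + xv / c.vv + c.mup / c.vp) / tau1
    p1 = _half_line_posterior(m1, tau1**-0.5, c.mup, np.sqrt(c.vp), c.p_choice)
    # C = 2: only the auditory measurement informs the auditory source
    tau2 = 1.0 / c.va + 1.0 / c.vap
    m2 = (xa / c.va + c.mua / c.vap) / tau2
    p2 = _half_line_posterior(m2, tau2**-0.5, c.mua, np.sqrt(c.vap), c.p_choice)
    return w1 * p1 + (1.0 - w1) * p2


def implicit_rightward_belief(x_a, x_v, params, reliability="high"):
    """Posterior probability that the auditory source is rightward."""
    c = _consts(params, reliability)
    xa, xv = np.broadcast_arrays(np.asarray(x_a, float), np.asarray(x_v, float))
    return _rightward_belief(xa, xv, c)


def implicit_decision(x_a, x_v, params, reliability="high"):
    """Localization response: +1 (right) / -1 (left); ties go rightward."""
    belief = implicit_rightward_belief(x_a, x_v, params, reliability)
    return np.where(belief >= 0.5, RIGHT, LEFT)


def _implicit_threshold(xv, c: _Consts, n_iter: int):
    """Bisection for the Xa value where the rightward belief crosses 1/2.

    The belief is monotone non-decreasing in Xa (verified by grid-scan
    property tests), so the rightward decision region is a half-line.
    """
    xv = np.asarray(xv, float)
    lo = np.full(xv.shape, -_BRACKET)
    hi = np.full(xv.shape, _BRACKET)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        above = _rightward_belief(mid, xv, c) >= 0.5
        hi = np.where(above, mid, hi)
        lo = np.where(above, lo, mid)
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Explicit (common-cause) rule
# --------------------------------------------------------------------------

def _explicit_logodds(xa, xv, c: _Consts, p_combined):
    return (
        np.log(p_combined)
        - np.log1p(-p_combined)
        + _log_L1(xa, xv, c)
        - _log_L2(xa, xv, c)
    )


def explicit_decision(x_a, x_v, params, reliability="high"):
    """Common-cause report: 1 (common) / 2 (separate); ties go to common."""
    c = _consts(params, reliability)
    pcb = params.p_combined
    xa, xv = np.broadcast_arrays(np.asarray(x_a, float), np.asarray(x_v, float))
    if pcb >= 1.0:
        return np.full(xa.shape, COMMON)
    if pcb <= 0.0:
        return np.full(xa.shape, SEPARATE)
    return np.where(_explicit_logodds(xa, xv, c, pcb) >= 0.0, COMMON, SEPARATE)


def _explicit_common_mass(xv, eps_a, c: _Consts, p_combined):
    """P(report common | Xv) integrated exactly over Xa ~ N(eps_a, sigma_a^2).

    The explicit log-odds is an exact quadratic in Xa; its coefficients are
    read off by evaluating at three points, the 'common' region is then an
    interval (or its complement, or everything/nothing) with closed-form
    Gaussian mass.
    """
    xv = np.asarray(xv, float)
    g0 = _explicit_logodds(np.zeros_like(xv), xv, c, p_combined)
    g1 = _explicit_logodds(np.ones_like(xv), xv, c, p_combined)
    gm1 = _explicit_logodds(-np.ones_like(xv), xv, c, p_combined)
    a = 0.5 * (g1 + gm1) - g0
    b = 0.5 * (g1 - gm1)
    eps_a = np.asarray(eps_a, float)

    mass = np.empty(np.broadcast(xv, eps_a).shape)
    a, b, g0, eps_b = np.broadcast_arrays(a, b, g0, eps_a)

    lin = np.abs(a) < 1e-12
    disc = b**2 - 4.0 * a * g0

    def _cdf(x):
        return norm.cdf((x - eps_b) / c.sa)

    # linear case: region is a half-line (or all/none if b ~ 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x0 = -g0 / b
        r_lo = (-b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
        r_hi = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    lo = np.minimum(r_lo, r_hi)
    hi = np.maximum(r_lo, r_hi)

    # quadratic opening down (a < 0): common between the roots
    mass_down = _cdf(hi) - _cdf(lo)
    # quadratic opening up (a > 0): common outside the roots
    mass_up = 1.0 - (_cdf(hi) - _cdf(lo))

    quad_mass = np.where(a < 0, mass_down, mass_up)
    # no real roots: sign of the quadratic is the sign of a everywhere
    quad_mass = np.where(disc <= 0, np.where(a < 0, 0.0, 1.0), quad_mass)

    lin_mass = np.where(
        np.abs(b) < 1e-12,
        np.where(g0 >= 0, 1.0, 0.0),
        np.where(b > 0, 1.0 - _cdf(x0), _cdf(x0)),
    )
    mass = np.where(lin, lin_mass, quad_mass)
    return mass


# --------------------------------------------------------------------------
# Response probabilities (marginalized over measurement noise)
# --------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _gh_nodes(order):
    x, w = roots_hermitenorm(order)
    return x, w / w.sum()


def _lapse_mix(p, lapse_rate, lapse_bias):
    return lapse_rate * lapse_bias + (1.0 - lapse_rate) * p


#: Grid size for the threshold-in-Xv interpolant used by the implicit rule.
_THRESHOLD_GRID = 65


def _cells_prob_implicit(eps_a, eps_v, params, reliability, quad):
    """Vectorized P(rightward) for arrays of cells at one reliability.

    The decision threshold c(Xv) is smooth, so it is solved by bisection on
    a compact Xv grid spanning all quadrature nodes and evaluated at the
    nodes by monotone cubic interpolation; the auditory mass is then the
    exact Gaussian tail beyond the threshold.
    """
    c = _consts(params, reliability)
    x, w = _gh_nodes(quad.order)
    eps_a = np.atleast_1d(np.asarray(eps_a, float))
    eps_v = np.atleast_1d(np.asarray(eps_v, float))
    xv = eps_v[:, None] + c.sv * x[None, :]
    lo, hi = float(xv.min()), float(xv.max())
    if hi - lo < 1e-9 or xv.size <= _THRESHOLD_GRID:
        thr = _implicit_threshold(xv, c, quad.bisect_iters)
    else:
        grid = np.linspace(lo, hi, _THRESHOLD_GRID)
        cg = _implicit_threshold(grid, c, quad.bisect_iters)
        thr = PchipInterpolator(grid, cg)(xv)
    p_cells = (w[None, :] * norm.sf((thr - eps_a[:, None]) / c.sa)).sum(axis=1)
    return _lapse_mix(p_cells, params.lapse_rate, params.lapse_bias)


def _cells_prob_explicit(eps_a, eps_v, params, reliability, quad):
    """Vectorized P(report common) for arrays of cells at one reliability."""
    c = _consts(params, reliability)
    pcb = params.p_combined
    eps_a = np.atleast_1d(np.asarray(eps_a, float))
    eps_v = np.atleast_1d(np.asarray(eps_v, float))
    if pcb >= 1.0:
        p_cells = np.ones_like(eps_a)
    elif pcb <= 0.0:
        p_cells = np.zeros_like(eps_a)
    else:
        x, w = _gh_nodes(quad.order)
        xv = eps_v[:, None] + c.sv * x[None, :]
        mass = _explicit_common_mass(xv, eps_a[:, None], c, pcb)
        p_cells = (w[None, :] * mass).sum(axis=1)
    return _lapse_mix(p_cells, params.lapse_rate, params.lapse_bias)


def response_prob_implicit(eps_a, eps_v, params, reliability="high", quad=None):
    """P(rightward response) on an audio-visual localization trial."""
    quad = (quad or QuadratureSpec()).validate()
    p = _cells_prob_implicit(eps_a, eps_v, params, reliability, quad)
    return float(p[0]) if np.isscalar(eps_a) and np.isscalar(eps_v) else p


def response_prob_explicit(eps_a, eps_v, params, reliability="high", quad=None):
    """P('common source' report) on an explicit common-cause trial."""
    quad = (quad or QuadratureSpec()).validate()
    p = _cells_prob_explicit(eps_a, eps_v, params, reliability, quad)
    return float(p[0]) if np.isscalar(eps_a) and np.isscalar(eps_v) else p


def _unisensory_threshold(params, modality, reliability, n_iter=60):
    """Measurement threshold of the single-cue localization rule."""
    params.validate()
    if modality == "auditory":
        sig, mu_p, sd_p = params.sigma_a, params.mu_a_prior, params.sigma_a_prior
    else:
        sig = params.sigma_v[reliability]
        mu_p, sd_p = params.mu_v_prior, params.sigma_v_prior
    tau = 1.0 / sig**2 + 1.0 / sd_p**2
    pch = params.p_choice_implicit
    if pch >= 1.0:
        return -np.inf, sig
    if pch <= 0.0:
        return np.inf, sig

    def belief(x):
        m = (x / sig**2 + mu_p / sd_p**2) / tau
        return _half_line_posterior(m, tau**-0.5, mu_p, sd_p, pch)

    lo, hi = -_BRACKET, _BRACKET
    if belief(lo) >= 0.5:
        return -np.inf, sig
    if belief(hi) < 0.5:
        return np.inf, sig
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if belief(mid) >= 0.5:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), sig


def response_prob_unisensory(eps, params, modality="auditory", reliability="high"):
    """P(rightward response) on a single-cue localization trial.

    With a centered natural prior and an unbiased choice prior this is the
    lapse-adjusted cumulative Gaussian ``Phi(eps / sigma)``.
    """
    thr, sig = _unisensory_threshold(params, modality, reliability)
    p = norm.sf((thr - np.asarray(eps, float)) / sig)
    out = _lapse_mix(p, params.lapse_rate, params.lapse_bias)
    return float(out) if np.isscalar(eps) else out


# --------------------------------------------------------------------------
# The explicit task's estimable mixture parameter
# --------------------------------------------------------------------------

def p_combined_from_components(p_common, p_choice_explicit, alpha_task):
    """Collapse (p_common, explicit choice prior, task learning) into the
    single criterion parameter governing explicit reports.

    Derived by collecting the structure-likelihood coefficients of the
    explicit decision inequality: with ``k = pch (1 - pc) + pc (1 - pch)``,

        p_combined = [pc (2 pch - 1) + a k] / [(2 pc - 1)(2 pch - 1) + 2 a k]

    clipped to [0, 1].  At full task learning (alpha = 1) with an unbiased
    choice prior this is 1/2: the category prior then follows the choice
    prior, not the environmental p_common.  These parameters trade off and
    are not individually estimable; only p_combined is fitted.
    """
    pc = np.asarray(p_common, float)
    pch = np.asarray(p_choice_explicit, float)
    a = np.asarray(alpha_task, float)
    if np.any((pc < 0) | (pc > 1) | (pch < 0) | (pch > 1) | (a < 0) | (a > 1)):
        raise ValueError("all arguments must lie in [0, 1]")
    k = pch * (1.0 - pc) + pc * (1.0 - pch)
    num = pc * (2.0 * pch - 1.0) + a * k
    den = (2.0 * pc - 1.0) * (2.0 * pch - 1.0) + 2.0 * a * k
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, 0.5, num / np.where(den == 0.0, 1.0, den))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def p_combined_from_criterion(t, p_common):
    """p_combined equivalent to thresholding the cause posterior at ``t``."""
    t = np.asarray(t, float)
    pc = np.asarray(p_common, float)
    if np.any((t <= 0) | (t >= 1) | (pc <= 0) | (pc >= 1)):
        raise ValueError("t and p_common must lie strictly inside (0, 1)")
    out = (1.0 - t) * pc / ((1.0 - t) * pc + t * (1.0 - pc))
    return float(out) if out.ndim == 0 else out
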