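"""Oracle and property tests for the ideal-observer core.

Every closed-form quantity is checked against an independent brute-force
numerical integration on a dense grid, and the marginalized response
probabilities against Monte-Carlo simulation of the decision rule.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from causalcue import (
    ObserverParams,
    QuadratureSpec,
    explicit_decision,
    implicit_rightward_belief,
    likelihood_common,
    likelihood_separate,
    p_combined_from_components,
    p_combined_from_criterion,
    posterior_common,
    predict_visual_weight,
    response_prob_explicit,
    response_prob_implicit,
)

from conftest import random_observer_params

# --------------------------------------------------------------------------
# Brute-force oracles (trapezoid integration on dense grids)
# --------------------------------------------------------------------------

_GRID = np.linspace(-250.0, 250.0, 20001)


def _npdf(x, m, s):
    return np.exp(-((x - m) ** 2) / (2 * s**2)) / (s * np.sqrt(2 * np.pi))


def oracle_L1(xa, xv, p, rel):
    """Single-source marginal: integrate over the shared source location."""
    s = _GRID
    prior = _npdf(s, p.mu_a_prior, p.sigma_a_prior) * _npdf(s, p.mu_v_prior, p.sigma_v_prior)
    prior = prior / np.trapezoid(prior, s)
    integrand = _npdf(xa, s, p.sigma_a) * _npdf(xv, s, p.sigma_v[rel]) * prior
    return np.trapezoid(integrand, s)


def oracle_L2(xa, xv, p, rel):
    """Independent-sources marginal: two 1-D convolutions."""
    s = _GRID
    fa = np.trapezoid(_npdf(xa, s, p.sigma_a) * _npdf(s, p.mu_a_prior, p.sigma_a_prior), s)
    fv = np.trapezoid(_npdf(xv, s, p.sigma_v[rel]) * _npdf(s, p.mu_v_prior, p.sigma_v_prior), s)
    return fa * fv


def _halves(f):
    """Trapezoid masses of f over S > 0 and S < 0 (grid contains 0 exactly)."""
    s = _GRID
    pos, neg = s >= 0, s <= 0
    return np.trapezoid(f[pos], s[pos]), np.trapezoid(f[neg], s[neg])


def oracle_rightward_belief(xa, xv, p, rel):
    """p(D_imp = 1 | Xa, Xv) by direct numerical posterior computation."""
    s = _GRID
    pch = p.p_choice_implicit
    # C = 1: posterior over the shared source
    prior1 = _npdf(s, p.mu_a_prior, p.sigma_a_prior) * _npdf(s, p.mu_v_prior, p.sigma_v_prior)
    prior1 = prior1 / np.trapezoid(prior1, s)
    post1 = _npdf(xa, s, p.sigma_a) * _npdf(xv, s, p.sigma_v[rel]) * prior1
    (m1p, m1n), (pi1p, pi1n) = _halves(post1), _halves(prior1)
    mass1_pos, mass1_neg = m1p / pi1p, m1n / pi1n
    pd1_c1 = pch * mass1_pos / (pch * mass1_pos + (1 - pch) * mass1_neg)
    # C = 2: only the auditory measurement informs the auditory source
    prior2 = _npdf(s, p.mu_a_prior, p.sigma_a_prior)
    post2 = _npdf(xa, s, p.sigma_a) * prior2
    (m2p, m2n), (pi2p, pi2n) = _halves(post2), _halves(prior2)
    mass2_pos, mass2_neg = m2p / pi2p, m2n / pi2n
    pd1_c2 = pch * mass2_pos / (pch * mass2_pos + (1 - pch) * mass2_neg)
    # cause posterior from the structure likelihoods
    l1, l2 = oracle_L1(xa, xv, p, rel), oracle_L2(xa, xv, p, rel)
    w1 = p.p_common * l1 / (p.p_common * l1 + (1 - p.p_common) * l2)
    return w1 * pd1_c1 + (1 - w1) * pd1_c2


def _random_draws(n, seed, tight=False):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p = random_observer_params(rng, tight=tight)
        rel = rng.choice(["high", "medium", "low"])
        xa, xv = rng.normal(0, 10), rng.normal(0, 10)
        out.append((xa, xv, p, rel))
    return out


# --------------------------------------------------------------------------
# Structure likelihoods
# --------------------------------------------------------------------------

def test_likelihoods_match_numerical_integration():
    for xa, xv, p, rel in _random_draws(50, seed=1):
        l1 = likelihood_common(xa, xv, p, rel)
        l2 = likelihood_separate(xa, xv, p, rel)
        o1, o2 = oracle_L1(xa, xv, p, rel), oracle_L2(xa, xv, p, rel)
        assert l1 == pytest.approx(o1, rel=1e-4)
        assert l2 == pytest.approx(o2, rel=1e-4)


def test_likelihood_common_symmetric_under_modality_swap():
    rng = np.random.default_rng(2)
    for _ in range(20):
        p = random_observer_params(rng)
        xa, xv = rng.normal(0, 10, 2)
        swapped = p.replace(
            sigma_a=p.sigma_v["medium"],
            sigma_v={**p.sigma_v, "medium": p.sigma_a},
            mu_a_prior=p.mu_v_prior,
            mu_v_prior=p.mu_a_prior,
            sigma_a_prior=p.sigma_v_prior,
            sigma_v_prior=p.sigma_a_prior,
        )
        assert likelihood_common(xa, xv, p, "medium") == pytest.approx(
            likelihood_common(xv, xa, swapped, "medium"), rel=1e-12
        )


def test_likelihood_separate_factorizes_and_translates():
    rng = np.random.default_rng(3)
    p = random_observer_params(rng)
    xa, xv, c = 4.0, -2.0, 7.5
    # factorization: the value splits into auditory x visual factors
    base = likelihood_separate(xa, xv, p, "high")
    other_v = likelihood_separate(xa, 11.0, p, "high")
    other_a = likelihood_separate(-3.0, xv, p, "high")
    cross = likelihood_separate(-3.0, 11.0, p, "high")
    assert base * cross == pytest.approx(other_v * other_a, rel=1e-10)
    # translation equivariance: shift measurements and prior means together
    shifted = p.replace(mu_a_prior=p.mu_a_prior + c, mu_v_prior=p.mu_v_prior + c)
    assert likelihood_separate(xa + c, xv + c, shifted, "high") == pytest.approx(base, rel=1e-10)


def test_tight_coincident_measurements_favor_common_cause():
    p = ObserverParams(sigma_a=1.0, sigma_v={"high": 1.0, "medium": 5.0, "low": 14.0},
                       sigma_a_prior=50.0, sigma_v_prior=50.0)
    assert likelihood_common(0.0, 0.0, p, "high") > likelihood_separate(0.0, 0.0, p, "high")


# --------------------------------------------------------------------------
# Cause posterior
# --------------------------------------------------------------------------

def test_posterior_common_limits_and_normalization():
    rng = np.random.default_rng(4)
    p = random_observer_params(rng)
    xa, xv = 3.0, -5.0
    assert posterior_common(xa, xv, p.replace(p_common=1.0), "high") == 1.0
    assert posterior_common(xa, xv, p.replace(p_common=0.0), "high") == 0.0
    q = posterior_common(xa, xv, p, "medium")
    assert 0.0 <= q <= 1.0  # the C=2 posterior is 1 - q by construction


def test_posterior_common_decreases_with_conflict():
    """At fixed midpoint, the cause posterior falls as |Xa - Xv| grows."""
    p = ObserverParams(p_common=0.5, mu_a_prior=0.0, mu_v_prior=0.0)
    half = np.linspace(0.0, 30.0, 61)
    q = posterior_common(half, -half, p, "medium")
    assert np.all(np.diff(q) <= 1e-12)


# --------------------------------------------------------------------------
# Implicit rule
# --------------------------------------------------------------------------

def test_rightward_belief_matches_numerical_integration():
    for xa, xv, p, rel in _random_draws(50, seed=5):
        got = float(implicit_rightward_belief(xa, xv, p, rel))
        want = oracle_rightward_belief(xa, xv, p, rel)
        assert got == pytest.approx(want, rel=1e-4, abs=1e-6)


def test_rightward_belief_monotone_in_auditory_measurement():
    rng = np.random.default_rng(6)
    xa = np.linspace(-60, 60, 601)
    for _ in range(25):
        p = random_observer_params(rng)
        xv = rng.normal(0, 15)
        belief = implicit_rightward_belief(xa, np.full_like(xa, xv), p, "medium")
        assert np.all(np.diff(belief) >= -1e-10)


def test_coincident_rightward_evidence_gives_rightward_decision():
    p = ObserverParams(mu_a_prior=0.0, mu_v_prior=0.0, p_choice_implicit=0.5)
    assert implicit_rightward_belief(4.0, 4.0, p, "high") > 0.5


def test_degenerate_choice_prior_dominates():
    p = ObserverParams(p_choice_implicit=1.0)
    assert implicit_rightward_belief(-30.0, -30.0, p, "high") == 1.0


# --------------------------------------------------------------------------
# Explicit rule
# --------------------------------------------------------------------------

def test_explicit_decision_limits():
    xa = np.array([-20.0, 0.0, 15.0])
    p1 = ObserverParams(p_combined=1.0)
    p0 = ObserverParams(p_combined=0.0)
    assert np.all(explicit_decision(xa, xa, p1, "low") == 1)
    assert np.all(explicit_decision(xa, xa, p0, "low") == 2)


def test_explicit_decision_equals_criterion_on_cause_posterior():
    """Comparing structure likelihoods at p_combined is the same rule as
    thresholding the cause posterior at the matching criterion t."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = random_observer_params(rng)
        t = rng.uniform(0.05, 0.95)
        pcb = p_combined_from_criterion(t, p.p_common)
        p_use = p.replace(p_combined=pcb)
        xa, xv = rng.normal(0, 15, 2)
        via_rule = explicit_decision(xa, xv, p_use, "medium")
        via_posterior = 1 if posterior_common(xa, xv, p, "medium") >= t else 2
        assert via_rule == via_posterior


# --------------------------------------------------------------------------
# Response probabilities
# --------------------------------------------------------------------------

def _mc_prob(decide, eps_a, eps_v, p, rel, n, seed, positive):
    rng = np.random.default_rng(seed)
    xa = rng.normal(eps_a, p.sigma_a, n)
    xv = rng.normal(eps_v, p.sigma_v[rel], n)
    hits = np.mean(decide(xa, xv, p, rel) == positive)
    se = np.sqrt(max(hits * (1 - hits), 1e-12) / n)
    return hits, se


def _assert_mc_agreement(decide, positive, quad_prob, seed_base, quad):
    """Quadrature vs Monte-Carlo on 20 random cells at 1e5 draws each.

    A derandomized 3-SE criterion fails by chance ~5% of the time across 20
    cells, so one 3-SE excursion is tolerated but every cell must stay
    within 4 SE.
    """
    excursions = 0
    for i, (xa, xv, p, rel) in enumerate(_random_draws(20, seed=seed_base)):
        eps_a, eps_v = np.clip(xa, -25, 25), np.clip(xv, -25, 25)
        want = quad_prob(eps_a, eps_v, p, rel, quad)
        got, se = _mc_prob(decide, eps_a, eps_v, p, rel, 10**5, 100 * seed_base + i, positive)
        err = abs(want - got)
        assert err <= max(4 * se, 1e-6)
        if err > max(3 * se, 1e-6):
            excursions += 1
    assert excursions <= 1


def test_response_prob_implicit_matches_monte_carlo(quad):
    from causalcue import implicit_decision

    _assert_mc_agreement(implicit_decision, 1, response_prob_implicit, 8, quad)


def test_response_prob_explicit_matches_monte_carlo(quad):
    _assert_mc_agreement(explicit_decision, 1, response_prob_explicit, 9, quad)


def test_full_lapse_returns_lapse_bias(quad):
    p = ObserverParams(lapse_rate=0.5, lapse_bias=0.9)
    # lapse_rate is capped at 0.5; with rate r the mixture is r*b + (1-r)*p
    pr = response_prob_implicit(0.0, 0.0, p.replace(p_choice_implicit=0.5), "medium", quad)
    assert pr == pytest.approx(0.5 * 0.9 + 0.5 * 0.5, abs=1e-6)


def test_response_prob_implicit_monotone_in_auditory_location(quad):
    p = ObserverParams(p_common=0.5)
    eps = np.linspace(-20, 20, 21)
    pr = response_prob_implicit(eps, np.full_like(eps, 5.0), p, "medium", quad)
    assert np.all(np.diff(pr) >= -1e-9)


def test_response_prob_explicit_symmetric_and_peaked(quad):
    p = ObserverParams(
        sigma_a=6.0, sigma_v={"high": 2.0, "medium": 5.0, "low": 12.0},
        mu_a_prior=0.0, mu_v_prior=0.0, p_combined=0.5, lapse_rate=0.0,
    )
    for d in (6.0, 12.0, 24.0):
        plus = response_prob_explicit(d / 2, -d / 2, p, "high", quad)
        minus = response_prob_explicit(-d / 2, d / 2, p, "high", quad)
        assert plus == pytest.approx(minus, abs=1e-9)
    at0 = response_prob_explicit(0.0, 0.0, p, "high", quad)
    at24 = response_prob_explicit(12.0, -12.0, p, "high", quad)
    assert at0 > at24


def test_quadrature_order_validation():
    with pytest.raises(ValueError):
        response_prob_implicit(0, 0, ObserverParams(), "high", QuadratureSpec(order=2))


# --------------------------------------------------------------------------
# Forced-fusion limit and the causal-inference signature
# --------------------------------------------------------------------------

def _implicit_pse(p, rel, delta, quad):
    """Mean stimulus location where P(rightward) = 1/2 under conflict."""

    def f(m):
        return response_prob_implicit(m + delta / 2, m - delta / 2, p, rel, quad) - 0.5

    return brentq(f, -20, 20, xtol=1e-6)


def test_forced_fusion_pse_shift_matches_weight_formula(quad):
    """With p_common = 1 and flat priors the implicit observer's PSE under a
    delta-conflict sits at (2 w_v - 1) delta / 2."""
    p = ObserverParams(
        sigma_a=2.0, sigma_v={"high": 1.0, "medium": 5.0, "low": 12.0},
        mu_a_prior=0.0, mu_v_prior=0.0, sigma_a_prior=1e4, sigma_v_prior=1e4,
        p_common=1.0, lapse_rate=0.0,
    )
    w_v = predict_visual_weight(2.0, 1.0)
    for delta in (6.0, -6.0):
        pse = _implicit_pse(p, "high", delta, quad)
        assert pse == pytest.approx((2 * w_v - 1) * delta / 2, abs=1e-3)


def test_bias_saturates_under_causal_inference_but_not_fusion(quad):
    """Predicted auditory bias grows sublinearly in disparity for
    0 < p_common < 1 but near-linearly for p_common = 1."""

    def bias(p, delta):
        # auditory localization PSE against the true auditory location
        def f(loc):
            return response_prob_implicit(loc, loc - delta, p, "high", quad) - 0.5

        return -brentq(f, -40, 40, xtol=1e-6)

    ci = ObserverParams(p_common=0.5, lapse_rate=0.0)
    ff = ci.replace(p_common=1.0)
    assert abs(bias(ci, 24.0)) < 2 * abs(bias(ci, 12.0))
    assert abs(bias(ff, 24.0)) == pytest.approx(2 * abs(bias(ff, 12.0)), rel=0.08)


# --------------------------------------------------------------------------
# The estimable explicit mixture parameter
# --------------------------------------------------------------------------

def test_p_combined_equivalent_to_component_decision_rule():
    """The collapsed parameter reproduces the full component-wise decision:
    summing the structure likelihoods against the (p_common, p_choice,
    alpha_task) priors gives the same choice as the single p_combined."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        pc, pch, a = rng.uniform(0.05, 0.95, 3)
        p = random_observer_params(rng)
        xa, xv = rng.normal(0, 15, 2)
        l1 = likelihood_common(xa, xv, p, "medium")
        l2 = likelihood_separate(xa, xv, p, "medium")
        lhs = (
            pch * l1 * (pc + a * (1 - pc)) + pch * l2 * (1 - pc - a * (1 - pc))
        )
        rhs = (
            (1 - pch) * l1 * (pc - a * pc) + (1 - pch) * l2 * (1 - pc + a * pc)
        )
        pcb = p_combined_from_components(pc, pch, a)
        if 0.0 < pcb < 1.0:
            want = lhs > rhs
            got = l1 * pcb > l2 * (1 - pcb)
            denom = (2 * pc - 1) * (2 * pch - 1) + 2 * a * (
                pch * (1 - pc) + pc * (1 - pch)
            )
            if denom > 0:  # the inequality flips with the denominator's sign
                assert got == want


def test_p_combined_component_limits():
    # complete task learning with an unbiased choice prior: criterion 1/2
    assert p_combined_from_components(0.3, 0.5, 1.0) == pytest.approx(0.5)
    # clipping keeps the value a probability on a dense grid
    g = np.linspace(0.01, 0.99, 20)
    vals = p_combined_from_components(
        g[:, None, None], g[None, :, None], g[None, None, :]
    )
    assert np.all((vals >= 0) & (vals <= 1))


def test_p_combined_from_criterion_values_and_monotonicity():
    assert p_combined_from_criterion(0.5, 0.37) == pytest.approx(0.37)
    assert p_combined_from_criterion(0.25, 0.5) == pytest.approx(0.75)
    t = np.linspace(0.05, 0.95, 50)
    vals = p_combined_from_criterion(t, 0.4)
    assert np.all(np.diff(vals) < 0)
    with pytest.raises(ValueError):
        p_combined_from_criterion(0.0, 0.5)
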