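import math

import numpy as np
import pytest
from scipy import stats

from seamsel import (
    Design,
    base_draws,
    calibrate,
    make_scenario,
    optimal_rule,
    realize,
    simulate_batch,
    tse_rule,
)
from seamsel.design import stage1_covariance
from seamsel.optimal import (
    lambda_coefficients,
    optimal_family_statistic,
    optimal_single_statistic,
)


def test_lambda_coefficient_signs_across_gamma():
    # off-selected coefficients scale with (2*gamma - 1): negative below
    # one half, zero at one half, positive above
    design = Design(n_arms=5, m1=28.0, m2=140.0, sigma=5.0)
    for gamma, sign in [(0.0, -1), (0.25, -1), (0.5, 0), (0.75, 1)]:
        shape = np.full(5, gamma)
        shape[2] = 1.0
        lam = lambda_coefficients(shape, design)[0]
        off = np.delete(lam, 2)
        np.testing.assert_allclose(off, off[0], atol=1e-12)  # equal across arms
        if sign == 0:
            np.testing.assert_allclose(off, 0.0, atol=1e-12)
        else:
            assert np.all(np.sign(off) == sign)


def test_gamma_half_statistic_is_pooled_estimate():
    # at gamma = 1/2 and m1 = m2 the statistic collapses to a positive
    # multiple of theta_hat1[i*] + theta_hat2
    design = Design(n_arms=5, m1=20.0, m2=20.0, sigma=2.0)
    batch = simulate_batch(design, np.zeros(5), 2_000, seed=6)
    cont = batch.continued
    stat = optimal_single_statistic(batch, 0.5, design)[cont]
    pooled = batch.selected_estimate[cont] + batch.theta_hat2[cont]
    scale = design.m1 / (2.0 * design.sigma**2)
    np.testing.assert_allclose(stat, scale * pooled, atol=1e-10)


def test_gamma_half_decisions_identical_to_tse(design5, null_draws5):
    """The pooled-data (TSE) rule is the Bayes rule for the family with
    all non-best effects at half the best effect."""
    tse = tse_rule(design5)
    calibrate(tse, draws=null_draws5)
    opt = optimal_rule(design5, make_scenario(5, 0.5, 2.0, kind="single"))
    calibrate(opt, draws=null_draws5)
    sc = make_scenario(5, 0.5, 2.0, kind="single")
    batch = simulate_batch(design5, sc, 50_000, seed=31)
    np.testing.assert_array_equal(tse.rejects(batch), opt.rejects(batch))


@pytest.mark.parametrize("n_arms,gammas", [(3, (0.25, 0.5)), (4, (0.2, 0.5, 0.8))])
def test_permutation_statistic_matches_density_ratio_oracle(n_arms, gammas):
    """The log-sum-exp evaluation must equal a direct evaluation of the
    multivariate-normal likelihood ratios from V itself."""
    design = Design(n_arms=n_arms, m1=6.0, m2=14.0, sigma=1.5)
    sc = make_scenario(n_arms, gammas, 1.0, kind="permutation")
    batch = simulate_batch(design, sc, 500, seed=12)
    stat = optimal_family_statistic(batch, sc, design)

    V, _ = stage1_covariance(design)
    f1 = lambda x, mean: stats.multivariate_normal.pdf(x, mean=mean, cov=V)
    sd2 = np.sqrt(2.0 * design.sigma**2 / design.m2)
    for r in range(batch.replications):
        if not batch.continued[r]:
            assert stat[r] == -np.inf
            continue
        i_star = batch.selected[r]
        shapes, log_w = sc.support_shapes(i_star)
        ratio = 0.0
        for shape, lw in zip(shapes, log_w):
            theta = shape * sc.delta
            lr1 = f1(batch.theta_hat1[r], theta) / f1(batch.theta_hat1[r], np.zeros(n_arms))
            lr2 = stats.norm.pdf(batch.theta_hat2[r], theta[i_star], sd2) / stats.norm.pdf(
                batch.theta_hat2[r], 0.0, sd2
            )
            ratio += math.exp(lw) * lr1 * lr2
        np.testing.assert_allclose(stat[r], math.log(ratio), atol=1e-10)


def test_equal_gammas_collapse_keeps_single_rule_decisions(design5, null_draws5):
    # a "permutation" family with identical gammas is the single-shape
    # family: the (K-1)! identical terms only shift the statistic by a
    # constant, which calibration absorbs
    sc = make_scenario(5, (0.4, 0.4, 0.4, 0.4), 2.0, kind="permutation")
    assert sc.kind == "single"
    rule = optimal_rule(design5, sc)
    calibrate(rule, draws=null_draws5)
    batch = simulate_batch(design5, sc, 20_000, seed=13)
    single = optimal_rule(design5, make_scenario(5, 0.4, 2.0, kind="single"))
    calibrate(single, draws=null_draws5)
    np.testing.assert_array_equal(rule.rejects(batch), single.rejects(batch))


def test_ordered_statistic_blocks():
    """Below the top dose the ordered and permutation statistics agree;
    at the top dose the ordered rule collapses to the single dose-ordered
    term with a log((K-1)!) prior-mass offset."""
    design = Design(n_arms=3, m1=8.0, m2=16.0, sigma=1.0)
    perm = make_scenario(3, (0.25, 0.5), 1.0, kind="permutation")
    ordered = make_scenario(3, (0.25, 0.5), 1.0, kind="ordered")
    batch = simulate_batch(design, perm, 2_000, seed=14)
    s_perm = optimal_family_statistic(batch, perm, design)
    s_ord = optimal_family_statistic(batch, ordered, design)
    cont = batch.continued
    low = cont & (batch.selected < 2)
    np.testing.assert_allclose(s_ord[low], s_perm[low], atol=1e-12)

    top = cont & (batch.selected == 2)
    _, V_inv = stage1_covariance(design)
    theta = ordered.theta_ord
    lam = V_inv @ theta
    s2 = (design.m2 * ordered.delta / (4.0 * design.sigma**2)) * (
        2.0 * batch.theta_hat2[top] - ordered.delta
    )
    closed_form = (
        batch.theta_hat1[top] @ lam - 0.5 * theta @ lam + s2 + math.log(2.0)
    )
    np.testing.assert_allclose(s_ord[top], closed_form, atol=1e-10)


def test_statistic_strictly_increasing_in_stage2():
    design = Design(n_arms=3, m1=8.0, m2=16.0, sigma=1.0)
    sc = make_scenario(3, (0.25, 0.5), 1.0, kind="permutation")
    batch = simulate_batch(design, sc, 1_000, seed=15)
    base_stat = optimal_family_statistic(batch, sc, design)
    batch.theta_hat2 = batch.theta_hat2 + 0.5
    bumped = optimal_family_statistic(batch, sc, design)
    cont = batch.continued
    assert np.all(bumped[cont] > base_stat[cont])


def test_permutation_critical_depends_on_delta(design5, null_draws5):
    # there is no uniformly most powerful rule for these families: the
    # calibrated threshold moves with the effect scale
    crits = []
    for delta in (1.0, 2.0):
        sc = make_scenario(5, (0.3, 0.475, 0.65, 0.825), delta, "permutation")
        rule = optimal_rule(design5, sc)
        calibrate(rule, draws=null_draws5)
        crits.append(rule.critical)
    assert abs(crits[0] - crits[1]) > 0.5


def test_single_shape_rule_is_delta_free(design5, null_draws5):
    stats_by_delta = []
    batch = realize(design5, null_draws5, np.zeros(5))
    for delta in (0.5, 1.0, 2.0):
        sc = make_scenario(5, 0.3, delta, kind="single")
        rule = optimal_rule(design5, sc)
        stats_by_delta.append(rule.statistic(batch))
    np.testing.assert_allclose(stats_by_delta[0], stats_by_delta[1], atol=1e-12)
    np.testing.assert_allclose(stats_by_delta[0], stats_by_delta[2], atol=1e-12)


def test_pseudo_optimal_labelling(design5):
    spread = make_scenario(5, (0.3, 0.475, 0.65, 0.825), 2.0, "permutation")
    tight = make_scenario(5, (0.75, 0.8125, 0.875, 0.9375), 2.0, "permutation")
    assert optimal_rule(design5, spread).pseudo_optimal
    assert not optimal_rule(design5, tight).pseudo_optimal


def test_optimal_rule_dominates_at_design_point(design5):
    """At the configuration it is derived for, the calibrated optimal
    rule's power is at least that of the general-purpose rules (up to
    coupled Monte-Carlo error)."""
    from seamsel import conventional_rule, estimate_power

    sc = make_scenario(5, (0.75, 0.8125, 0.875, 0.9375), 2.0, "permutation")
    n = 100_000
    null_draws = base_draws(5, n, seed=41)
    power_draws = base_draws(5, n, seed=42, permuted=True)
    opt = optimal_rule(design5, sc)
    calibrate(opt, draws=null_draws)
    tse = tse_rule(design5)
    calibrate(tse, draws=null_draws)
    conv = conventional_rule(design5)
    p_opt = estimate_power(opt, sc, draws=power_draws).power
    p_tse = estimate_power(tse, sc, draws=power_draws).power
    p_conv = estimate_power(conv, sc, draws=power_draws).power
    margin = 3 * np.sqrt(0.25 / n)  # conservative bound on the coupled SE
    assert p_opt >= p_tse - margin
    assert p_opt >= p_conv - margin
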