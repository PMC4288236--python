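"""Bayes-optimal decision statistics for specific effect-configuration
families.

Each rule arises from a Bayes decision problem: a discrete prior over
effect vectors (mass 1/(K+1) on ``theta = 0`` and 1/(K+1) on each
best-arm block), a reward for correctly rejecting the selected arm's
hypothesis, and a cost for a false rejection under ``theta = 0``.  The
Bayes rule rejects when a likelihood-ratio statistic exceeds a constant
``c``; only the cost *ratio* matters, so rules are parameterized by
``c`` directly and ``c`` is found by calibrating the null rejection rate
to alpha.  A rule calibrated this way maximizes the (block-averaged)
power among all rules with null type-I error rate at most alpha.

Stage-1 estimates have density ``N(theta, V)`` with
``V^{-1} = (m1/sigma^2)(I - J/(K+1))``, so each prior atom ``phi``
contributes a linear form ``lambda(phi)' theta_hat1`` with
``lambda(phi) = (m1/sigma^2)(phi - 1 * sum(phi)/(K+1))``.  When any
component of ``lambda(phi)`` is negative, null calibration does not
guarantee strong familywise-error control and the rule is labelled
*pseudo-optimal*; for permutation families with equally spaced gammas
all components are positive exactly when ``gamma_1 > K/(K+2)``.

Three families are implemented:

* ``single`` (one common gamma): all atoms in a block coincide, the
  statistic is a single linear form, and — divided through by delta —
  it is free of delta, so one calibrated ``c`` serves every effect
  scale.  At ``gamma = 0.5`` the statistic is proportional to
  ``m1 * theta_hat1[i*] + m2 * theta_hat2``, i.e. the TSE pooled rule.
* ``permutation``: the statistic is a log-sum of ``(K-1)!``
  exponential terms (one per permutation with the peak at ``i*``),
  evaluated with a max-subtracted log-sum-exp; ``c`` depends on delta.
* ``ordered``: as ``permutation`` except the block with the peak at the
  top dose collapses to the single dose-ordered vector carrying the
  whole block mass, entering the log-sum-exp as a ``log (K-1)!`` offset.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .design import Design, ScenarioFamily, stage1_covariance
from .simulate import TrialBatch

__all__ = [
    "lambda_coefficients",
    "optimal_single_statistic",
    "optimal_family_statistic",
]


def lambda_coefficients(shapes: np.ndarray, design: Design) -> np.ndarray:
    """Stage-1 coefficient vectors ``lambda(phi) = V^{-1} phi`` for unit
    (delta-free) shape vectors ``phi``, shape (n_terms, K)."""
    shapes = np.atleast_2d(np.asarray(shapes, dtype=float))
    K = design.n_arms
    unit = design.m1 / design.sigma**2
    return unit * (shapes - shapes.sum(axis=1, keepdims=True) / (K + 1))


def optimal_single_statistic(
    batch: TrialBatch, gamma: float, design: Design | None = None
) -> np.ndarray:
    """Delta-free log-likelihood-ratio statistic for the single-shape
    family ``theta = permutation of (gamma*delta, ..., gamma*delta, delta)``.

    Equals ``lambda(shape_{i*})' theta_hat1 + (m2 / (2 sigma^2)) *
    theta_hat2`` where ``shape_{i*}`` has 1 at the selected arm and
    gamma elsewhere; normalizing constants are absorbed into the
    calibrated threshold.  Stopped trials map to ``-inf``.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    design = design or batch.design
    K = design.n_arms
    unit = design.m1 / design.sigma**2
    shape_sum = 1.0 + gamma * (K - 1)
    coef_sel = unit * (1.0 - shape_sum / (K + 1))
    coef_off = unit * (gamma - shape_sum / (K + 1))
    total1 = batch.theta_hat1.sum(axis=1)
    sel_est = batch.selected_estimate
    stat = coef_sel * sel_est + coef_off * (total1 - sel_est)
    stat = stat + (design.m2 / (2.0 * design.sigma**2)) * np.where(
        batch.continued, batch.theta_hat2, 0.0
    )
    return np.where(batch.continued, stat, -np.inf)


def optimal_family_statistic(
    batch: TrialBatch, scenario: ScenarioFamily, design: Design | None = None
) -> np.ndarray:
    """Log of the prior-weighted likelihood-ratio sum for permutation and
    ordered families:

    ``log sum_{phi in block(i*)} w(phi) *
    f(theta_hat1; phi*delta, V) / f(theta_hat1; 0, V) *
    f2(theta_hat2; delta) / f2(theta_hat2; 0)``

    with weights on the scale where one permutation atom has weight 1.
    Rejection at threshold ``c`` reproduces the Bayes rule; ``c``
    depends on delta, so each delta is calibrated separately.
    """
    design = design or batch.design
    if scenario.kind == "single":
        return optimal_single_statistic(batch, scenario.gammas[0], design)
    delta = scenario.delta
    if not delta > 0:
        raise ValueError("permutation/ordered statistics need delta > 0")
    K = design.n_arms
    _, V_inv = stage1_covariance(design)

    # stage-2 log likelihood ratio: theta_hat2 ~ N(theta_sel, 2 sigma^2 / m2)
    s2 = (design.m2 * delta / (4.0 * design.sigma**2)) * (
        2.0 * np.where(batch.continued, batch.theta_hat2, 0.0) - delta
    )

    out = np.full(batch.replications, -np.inf)
    for i_best in range(K):
        rows = np.flatnonzero(batch.continued & (batch.selected == i_best))
        if rows.size == 0:
            continue
        shapes, log_w = scenario.support_shapes(i_best)
        thetas = shapes * delta  # (T, K)
        lam = thetas @ V_inv  # (T, K): lambda(phi) row-wise
        quad = 0.5 * np.einsum("tk,tk->t", lam, thetas)  # 0.5 phi' Vinv phi
        terms = batch.theta_hat1[rows] @ lam.T - quad + log_w  # (R_i, T)
        out[rows] = logsumexp(terms, axis=1) + s2[rows]
    return out
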