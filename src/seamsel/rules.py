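"""The final decision rules as calibrated classifiers of trial batches.

Every rule shares one contract: a statistic that is a deterministic
function of ``(Z_{1,1..K}, i*, Z_{2,i*})`` — stopped trials map to
``-inf`` — and a critical value such that the rule rejects
``H_{0,i*}`` iff ``statistic >= critical``.  Selection and the futility
gate are identical across rules (they live upstream in the simulator),
so power differences isolate the data-combination step.

Rules
-----
``conventional``
    Stage-2 data only: statistic ``Z_{2,i*}``; the critical value
    ``qnorm(1 - alpha / p_cont)`` (with ``p_cont`` the null continuation
    probability) is analytic, exact and independent of ``m2``.
``tse``
    Thall-Simon-Ellenberg pooled statistic ``w1 Z_{1,i*} + w2 Z_{2,i*}``
    with ``w_i = sqrt(m_i / (m1 + m2))``.
``bk_invchisq_simes`` / ``bk_invchisq_dunnett`` /
``bk_invnormal_simes`` / ``bk_invnormal_dunnett``
    Closed testing with the inverse chi-square or inverse normal
    combination and Simes or Dunnett stage-1 intersection p-values.
``optimal_single`` / ``optimal_permutation`` / ``optimal_ordered``
    Bayes(-pseudo)-optimal likelihood-ratio rules for a scenario family.

All simulated criticals come from :mod:`seamsel.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .closed_testing import closed_test_statistic
from .design import Design, ScenarioFamily, min_fwer_coefficient
from .optimal import optimal_family_statistic, optimal_single_statistic
from .simulate import TrialBatch, continuation_probability

__all__ = [
    "Rule",
    "Decision",
    "RULE_IDS",
    "conventional_critical",
    "conventional_rule",
    "tse_statistic",
    "tse_rule",
    "bk_rule",
    "optimal_rule",
    "build_rule",
    "evaluate_rule",
]

RULE_IDS = (
    "conventional",
    "tse",
    "bk_invchisq_simes",
    "bk_invchisq_dunnett",
    "bk_invnormal_simes",
    "bk_invnormal_dunnett",
)


@dataclass
class Rule:
    """A decision rule: identity, statistic and (possibly pending)
    calibrated critical value for a specific design."""

    rule_id: str
    design: Design
    statistic_fn: Callable[[TrialBatch], np.ndarray] = field(repr=False)
    critical: float | None = None
    analytic: bool = False
    pseudo_optimal: bool = False
    scenario: ScenarioFamily | None = None

    def statistic(self, batch: TrialBatch) -> np.ndarray:
        self._check_design(batch.design)
        stat = self.statistic_fn(batch)
        return np.where(batch.continued, stat, -np.inf)

    def rejects(self, batch: TrialBatch) -> np.ndarray:
        """Boolean rejection indicator per replicate."""
        if self.critical is None:
            raise ValueError(f"rule {self.rule_id!r} is not calibrated")
        return self.statistic(batch) >= self.critical

    def decide(self, batch: TrialBatch) -> "Decision":
        return Decision(
            rule_id=self.rule_id,
            selected=batch.selected.copy(),
            rejected=self.rejects(batch),
        )

    def _check_design(self, design: Design) -> None:
        mine = self.design
        if (design.n_arms, design.m1, design.m2, design.sigma) != (
            mine.n_arms,
            mine.m1,
            mine.m2,
            mine.sigma,
        ):
            raise ValueError(
                "batch design does not match the design this rule was built for"
            )


@dataclass
class Decision:
    """Outcome per replicate: action A_0 (no rejection) or A_{i*}."""

    rule_id: str
    selected: np.ndarray
    rejected: np.ndarray

    @property
    def actions(self) -> np.ndarray:
        """0 for A_0, i+1 for rejecting arm i's hypothesis."""
        return np.where(self.rejected, self.selected + 1, 0)


def conventional_critical(design: Design) -> float:
    """Critical value of the stage-2-only test, adjusted for the chance
    of stopping at the futility gate: ``qnorm(1 - alpha / p_cont)``.
    Exact (no simulation) and independent of ``m2``."""
    p_cont = continuation_probability(design)
    if design.alpha >= p_cont:
        raise ValueError("alpha is not attainable: exceeds continuation probability")
    return float(stats.norm.isf(design.alpha / p_cont))


def conventional_rule(design: Design) -> Rule:
    return Rule(
        rule_id="conventional",
        design=design,
        statistic_fn=lambda b: b.z2,
        critical=conventional_critical(design),
        analytic=True,
    )


def tse_statistic(batch: TrialBatch) -> np.ndarray:
    """Pooled statistic ``w1 Z_{1,i*} + w2 Z_{2,i*}``; proportional to
    the information-weighted estimate ``m1 theta_hat1[i*] + m2
    theta_hat2`` up to a positive constant."""
    w1, w2 = batch.design.stage_weights
    return w1 * batch.z1_selected + w2 * np.where(batch.continued, batch.z2, 0.0)


def tse_rule(design: Design) -> Rule:
    return Rule(rule_id="tse", design=design, statistic_fn=tse_statistic)


_BK = {
    "bk_invchisq_simes": ("inverse_chisq", "simes"),
    "bk_invchisq_dunnett": ("inverse_chisq", "dunnett"),
    "bk_invnormal_simes": ("inverse_normal", "simes"),
    "bk_invnormal_dunnett": ("inverse_normal", "dunnett"),
}


def bk_rule(design: Design, rule_id: str) -> Rule:
    method, intersection = _BK[rule_id]
    return Rule(
        rule_id=rule_id,
        design=design,
        statistic_fn=lambda b: closed_test_statistic(b, method, intersection),
    )


def optimal_rule(design: Design, scenario: ScenarioFamily) -> Rule:
    """Bayes-optimal rule for a scenario family.  Flagged
    pseudo-optimal when some stage-1 coefficient is negative, in which
    case null calibration does not guarantee strong FWER control."""
    if scenario.n_arms != design.n_arms:
        raise ValueError("scenario and design disagree on the number of arms")
    rid = {
        "single": "optimal_single",
        "permutation": "optimal_permutation",
        "ordered": "optimal_ordered",
    }[scenario.kind]
    if scenario.kind == "single":
        gamma = scenario.gammas[0]
        fn = lambda b: optimal_single_statistic(b, gamma, design)
    else:
        fn = lambda b: optimal_family_statistic(b, scenario, design)
    pseudo = min_fwer_coefficient(scenario.gammas, design.n_arms) < 0.0
    return Rule(
        rule_id=rid,
        design=design,
        statistic_fn=fn,
        pseudo_optimal=pseudo,
        scenario=scenario,
    )


def build_rule(rule_id: str, design: Design, scenario: ScenarioFamily | None = None) -> Rule:
    """Construct any rule by identifier (optimal rules need a scenario)."""
    if rule_id == "conventional":
        return conventional_rule(design)
    if rule_id == "tse":
        return tse_rule(design)
    if rule_id in _BK:
        return bk_rule(design, rule_id)
    if rule_id in ("optimal_single", "optimal_permutation", "optimal_ordered"):
        if scenario is None:
            raise ValueError(f"rule {rule_id!r} needs a scenario family")
        return optimal_rule(design, scenario)
    raise ValueError(f"unknown rule {rule_id!r}")


def evaluate_rule(rule: Rule, batch: TrialBatch) -> Decision:
    """Apply a calibrated rule to a batch (stopped trials map to A_0)."""
    return rule.decide(batch)
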