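"""Operating characteristics: power, relative efficiency, sample-size
allocation, and the value of stage-1 data.

Power is the probability of *selecting the truly best arm and rejecting
its null hypothesis* — a rule gets no credit for rejecting on a
second-best arm.  For permutation-randomized scenarios each replicate is
judged against its own arrangement's best arm, which makes the estimate
the power averaged over the K! permutations.

Relative efficiency of a rule against a benchmark is 100 / rho, where
rho is the common factor by which both group sizes must be inflated
(recalibrating the rule at every trial size) for the rule to match the
benchmark's power.  All searches reuse one standard-normal reservoir
(common random numbers), so power differences and root-finding curves
are smooth at desk-scale replication counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize

from .calibration import calibrate
from .design import Design, ScenarioFamily
from .rules import Rule, conventional_rule, tse_rule
from .simulate import BaseDraws, base_draws, realize

__all__ = [
    "PowerEstimate",
    "EfficiencyResult",
    "AllocationResult",
    "PhaseIIValueResult",
    "estimate_power",
    "relative_efficiency",
    "optimize_m1",
    "phase2_value",
]

RuleFactory = Callable[[Design], Rule]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Distinct sub-stream seeds (< 2^31) derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % 2**31 for s in state]


@dataclass(frozen=True)
class PowerEstimate:
    """pr{select the best arm and reject its hypothesis}, with the
    decomposition into selection and conditional rejection."""

    power: float
    se: float
    p_select: float
    p_reject_given_select: float
    replications: int
    rule_id: str


@dataclass(frozen=True)
class EfficiencyResult:
    rule_id: str
    benchmark_id: str
    benchmark_power: float
    rho: float

    @property
    def efficiency(self) -> float:
        return 100.0 / self.rho


@dataclass(frozen=True)
class AllocationResult:
    """Power-maximizing stage-1 group size under a fixed total
    ``N = (K+1) m1 + 2 m2``."""

    total_n: int
    m1_grid: np.ndarray
    m2_grid: np.ndarray
    power: np.ndarray
    power_smoothed: np.ndarray
    p_select: np.ndarray
    p_reject_given_select: np.ndarray
    m1_opt: int

    @property
    def m2_opt(self) -> float:
        return float(self.m2_grid[self.m1_grid == self.m1_opt][0])


@dataclass(frozen=True)
class PhaseIIValueResult:
    """Worth of the stage-1 data on the selected arm and control,
    expressed via the matched conventional stage-2 size m2_tilde."""

    m1: int
    m2: float
    rule_power: float
    m2_tilde: float

    @property
    def r_star(self) -> float:
        """Percentage value of the stage-1 observations on the selected
        arm and control relative to extra stage-2 observations:
        ``100 * 2 (m2_tilde - m2) / (2 m1) = 100 (m2_tilde - m2) / m1``
        (both counts tally observations over the two arms involved)."""
        return 100.0 * (self.m2_tilde - self.m2) / self.m1


def _scenario_thetas(
    scenario, design: Design, draws: BaseDraws
) -> np.ndarray:
    if isinstance(scenario, ScenarioFamily):
        if draws.perms is None:
            raise ValueError("permutation-randomized scenarios need permuted draws")
        return scenario.theta_ord[draws.perms]
    return np.asarray(scenario, dtype=float)


def estimate_power(
    rule: Rule,
    scenario,
    replications: int = 200_000,
    seed: int | None = None,
    draws: BaseDraws | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of a calibrated rule under a scenario (a
    :class:`ScenarioFamily`, permutation-randomized per replicate, or an
    explicit effect vector)."""
    design = rule.design
    if draws is None:
        draws = base_draws(design.n_arms, replications, seed,
                           permuted=isinstance(scenario, ScenarioFamily))
    theta = _scenario_thetas(scenario, design, draws)
    batch = realize(design, draws, theta)
    i_max = batch.i_max
    reject = rule.rejects(batch)
    select_best = batch.selected == i_max
    success = reject & select_best
    n = batch.replications
    power = float(success.mean())
    p_sel = float(select_best.mean())
    return PowerEstimate(
        power=power,
        se=float(np.sqrt(power * (1.0 - power) / n)),
        p_select=p_sel,
        p_reject_given_select=power / p_sel if p_sel > 0 else np.nan,
        replications=n,
        rule_id=rule.rule_id,
    )


def _calibrated_power(
    factory: RuleFactory,
    design: Design,
    scenario,
    null_draws: BaseDraws,
    power_draws: BaseDraws,
) -> float:
    rule = factory(design)
    if rule.critical is None:
        calibrate(rule, draws=null_draws)
    return estimate_power(rule, scenario, draws=power_draws).power


def relative_efficiency(
    factory: RuleFactory,
    benchmark: Rule,
    scenario,
    replications: int = 200_000,
    seed: int = 0,
    bracket: tuple[float, float] = (0.4, 2.5),
    xtol: float = 2e-3,
) -> EfficiencyResult:
    """Relative efficiency 100 / rho of the rule built by ``factory``
    against a calibrated ``benchmark`` at the benchmark's design.

    rho solves ``power_factory(rho * m1, rho * m2) = power_benchmark``
    with the rule recalibrated at every scaled design; the root search
    is bracketed and uses common random numbers so the power curve is
    effectively monotone in rho.
    """
    design = benchmark.design
    is_family = isinstance(scenario, ScenarioFamily)
    s_null, s_pow = _child_seeds(seed, 2)
    null_draws = base_draws(design.n_arms, replications, s_null)
    power_draws = base_draws(design.n_arms, replications, s_pow, permuted=is_family)
    target = estimate_power(benchmark, scenario, draws=power_draws).power

    def gap(rho: float) -> float:
        return (
            _calibrated_power(factory, design.scaled(rho), scenario,
                              null_draws, power_draws)
            - target
        )

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo > 0.0 or g_hi < 0.0:
        raise ValueError(
            f"rho bracket {bracket} does not contain the matching sample size"
        )
    rho = optimize.brentq(gap, lo, hi, xtol=xtol)
    probe = factory(design)
    return EfficiencyResult(
        rule_id=probe.rule_id,
        benchmark_id=benchmark.rule_id,
        benchmark_power=target,
        rho=float(rho),
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows."""
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        out[i] = y[lo:hi].mean()
    return out


def optimize_m1(
    factory: RuleFactory,
    total_n: int,
    scenario,
    design_template: Design,
    m1_grid=None,
    replications: int = 150_000,
    seed: int = 0,
    smooth_window: int = 7,
) -> AllocationResult:
    """Direct search for the power-maximizing integer ``m1`` subject to
    ``(K+1) m1 + 2 m2 = total_n`` (``m2`` real-valued).

    Every grid point recalibrates the rule and estimates power with the
    same pseudo-random reservoir, and the reported optimum is the argmax
    of a moving-average smoothed power curve (the true curve has a flat
    maximum, so smoothing suppresses Monte-Carlo jitter without moving
    the optimum materially).
    """
    K = design_template.n_arms
    if m1_grid is None:
        m1_max = int((total_n - 2) // (K + 1))
        m1_grid = np.arange(1, m1_max + 1)
    m1_grid = np.asarray(m1_grid, dtype=int)
    m2_grid = (total_n - (K + 1) * m1_grid) / 2.0
    keep = m2_grid > 0
    m1_grid, m2_grid = m1_grid[keep], m2_grid[keep]
    if m1_grid.size == 0:
        raise ValueError("no feasible m1 on the grid")

    is_family = isinstance(scenario, ScenarioFamily)
    s_null, s_pow = _child_seeds(seed, 2)
    null_draws = base_draws(K, replications, s_null)
    power_draws = base_draws(K, replications, s_pow, permuted=is_family)

    power = np.empty(m1_grid.size)
    p_sel = np.empty(m1_grid.size)
    p_rej = np.empty(m1_grid.size)
    for j, (m1, m2) in enumerate(zip(m1_grid, m2_grid)):
        design = design_template.with_sizes(m1=float(m1), m2=float(m2))
        rule = factory(design)
        if rule.critical is None:
            calibrate(rule, draws=null_draws)
        est = estimate_power(rule, scenario, draws=power_draws)
        power[j], p_sel[j], p_rej[j] = est.power, est.p_select, est.p_reject_given_select
    smoothed = _smooth(power, smooth_window)
    m1_opt = int(m1_grid[int(np.argmax(smoothed))])
    return AllocationResult(
        total_n=total_n,
        m1_grid=m1_grid,
        m2_grid=m2_grid,
        power=power,
        power_smoothed=smoothed,
        p_select=p_sel,
        p_reject_given_select=p_rej,
        m1_opt=m1_opt,
    )


def phase2_value(
    total_n: int,
    scenario,
    design_template: Design,
    replications: int = 150_000,
    seed: int = 0,
    m1_m2: tuple[int, float] | None = None,
    max_inflation: float = 40.0,
    rule_factory: RuleFactory = tse_rule,
    smooth_window: int = 7,
    calibration_replications: int | None = None,
    allocation_replications: int | None = None,
) -> PhaseIIValueResult:
    """How much the stage-1 data are worth in the final analysis.

    With ``(m1, m2)`` maximizing the rule's power under the budget
    ``total_n`` (or supplied directly), computes the rule's power ``P`` and root-finds
    the real-valued ``m2_tilde`` at which a *conventional* analysis —
    selection still based on the ``m1`` stage-1 observations, final test
    on stage-2 data alone — attains the same power.  The percentage
    value of the stage-1 data is ``r* = 100 (m2_tilde - m2) / (2 m1)``.
    """
    if m1_m2 is None:
        # the power maximum is flat in m1, so the allocation search can
        # run at a lower replication count than the matched comparison
        alloc = optimize_m1(rule_factory, total_n, scenario, design_template,
                            replications=allocation_replications or replications,
                            seed=seed, smooth_window=smooth_window)
        m1, m2 = alloc.m1_opt, alloc.m2_opt
    else:
        m1, m2 = m1_m2
    design = design_template.with_sizes(m1=float(m1), m2=float(m2))

    is_family = isinstance(scenario, ScenarioFamily)
    _, s_null, s_pow = _child_seeds(seed, 3)
    # the matched size m2_tilde is read off against an *analytic*
    # conventional critical, so calibration error in the combined rule's
    # critical feeds straight into m2_tilde; a larger null ensemble for
    # the calibration step keeps that error subdominant
    calib_reps = calibration_replications or max(replications, 2_000_000)
    null_draws = base_draws(design.n_arms, calib_reps, s_null)
    power_draws = base_draws(design.n_arms, replications, s_pow, permuted=is_family)

    rule = rule_factory(design)
    if rule.critical is None:
        calibrate(rule, draws=null_draws)
    target = estimate_power(rule, scenario, draws=power_draws).power

    def gap(m2_tilde: float) -> float:
        d = design.with_sizes(m2=m2_tilde)
        conv = conventional_rule(d)  # analytic critical, m2-independent
        return estimate_power(conv, scenario, draws=power_draws).power - target

    lo = 1e-6
    hi = max_inflation * m2
    if gap(hi) < 0.0:
        raise ValueError("conventional test cannot reach the TSE power in bracket")
    if gap(lo) >= 0.0:
        m2_tilde = lo
    else:
        m2_tilde = optimize.brentq(gap, lo, hi, xtol=1e-3 * m2)
    return PhaseIIValueResult(
        m1=int(m1), m2=float(m2), rule_power=float(target), m2_tilde=float(m2_tilde)
    )
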