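"""Critical-value calibration: familywise error rate alpha at theta = 0.

All six decision rules (and the optimal rules) are calibrated by the
same convention: the critical value is chosen so that the probability of
rejecting the selected hypothesis under ``theta = (0, ..., 0)`` —
accounting for the futility gate — equals alpha.

The default method generates one fixed null ensemble, computes each
replicate's *threshold statistic* once (for the closed tests this is the
minimum over intersections of the combined statistic, so the whole
FWER-versus-critical curve comes from a single ensemble), and places the
critical value at the empirical quantile whose rejection fraction is the
largest value not exceeding alpha.  The result is deterministic given
the seed.  A Robbins-Monro stochastic-approximation mode
(``c_{n+1} = c_n + (a / n)(I(reject) - alpha)``) is provided as an
alternative and agrees with the quantile method within Monte-Carlo
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Design
from .rules import Rule
from .simulate import BaseDraws, TrialBatch, simulate_batch

__all__ = ["CalibrationResult", "estimate_fwer", "calibrate"]


@dataclass(frozen=True)
class CalibrationResult:
    """A calibrated critical value with its Monte-Carlo provenance."""

    rule_id: str
    critical: float
    alpha: float
    replications: int
    seed: int | None
    fwer_estimate: float
    fwer_se: float
    method: str

    def as_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "critical": self.critical,
            "alpha": self.alpha,
            "replications": self.replications,
            "seed": self.seed,
            "fwer_estimate": self.fwer_estimate,
            "fwer_se": self.fwer_se,
            "method": self.method,
        }


def _null_batch(
    design: Design,
    replications: int,
    seed: int | None,
    draws: BaseDraws | None,
) -> TrialBatch:
    from .simulate import base_draws, realize

    if draws is None:
        if seed is None:
            raise ValueError("either a seed or pre-made draws are required")
        draws = base_draws(design.n_arms, replications, seed)
    return realize(design, draws, np.zeros(design.n_arms))


def estimate_fwer(
    rule: Rule,
    design: Design | None = None,
    replications: int = 200_000,
    seed: int | None = None,
    theta: np.ndarray | None = None,
    critical: float | None = None,
    draws: BaseDraws | None = None,
) -> tuple[float, float]:
    """Familywise error rate of a calibrated rule by simulation.

    Under ``theta = 0`` every rejection is a familywise error; under a
    general ``theta`` only rejections of a true null (selected arm with
    ``theta[i*] <= 0``) count.  Returns the estimate and its binomial
    standard error.
    """
    design = design or rule.design
    critical = rule.critical if critical is None else critical
    if critical is None:
        raise ValueError("no critical value available")
    if theta is None:
        batch = _null_batch(design, replications, seed, draws)
    else:
        batch = simulate_batch(design, np.asarray(theta, dtype=float),
                               replications, seed, draws=draws)
    reject = rule.statistic(batch) >= critical
    true_null = batch.theta_selected <= 0.0
    err = reject & true_null
    n = batch.replications
    fwer = float(err.mean())
    return fwer, float(np.sqrt(fwer * (1.0 - fwer) / n))


def _quantile_critical(stat: np.ndarray, alpha: float) -> tuple[float, float]:
    """Critical value giving the largest rejection fraction <= alpha,
    placed midway between the bracketing order statistics."""
    n = stat.size
    k = int(np.floor(alpha * n))  # number of rejections allowed
    if k < 1:
        raise ValueError("alpha is unreachable at this replication count")
    part = np.partition(stat, [n - k - 1, n - k])
    critical = 0.5 * (part[n - k - 1] + part[n - k])
    if not np.isfinite(critical):
        raise ValueError("degenerate statistic distribution at the quantile")
    attained = float(np.count_nonzero(stat >= critical)) / n
    return float(critical), attained


def _robbins_monro(
    stat: np.ndarray, alpha: float, c0: float, a: float | None = None,
    n_offset: int = 1_000,
) -> float:
    """One pass of stochastic approximation over the statistic stream:
    ``c <- c + a / (n0 + n) * (I{reject} - alpha)``.  The gain is scaled
    to the statistic's upper-tail spread and damped by ``n0`` so the
    early iterates (where the 1/n schedule is otherwise wild) stay near
    the warm start."""
    if a is None:
        spread = np.subtract(*np.percentile(stat[np.isfinite(stat)], [97.5, 50.0]))
        a = max(float(spread), 1.0) / max(alpha, 1e-3)
    c = c0
    for n, s in enumerate(stat, start=1):
        c += (a / (n_offset + n)) * (float(s >= c) - alpha)
    return float(c)


def calibrate(
    rule: Rule,
    replications: int = 200_000,
    seed: int | None = None,
    alpha: float | None = None,
    method: str = "quantile",
    draws: BaseDraws | None = None,
    check_seed: int | None = None,
) -> CalibrationResult:
    """Calibrate ``rule.critical`` so the null FWER equals alpha.

    Analytic rules (the conventional test) pass through unchanged with
    an exact record.  ``draws`` may supply a shared null reservoir so
    several rules are calibrated from one ensemble (common random
    numbers).  With ``check_seed`` the result is re-validated on an
    independent ensemble and the re-estimated FWER is reported.
    """
    design = rule.design
    alpha = design.alpha if alpha is None else alpha
    if rule.analytic and rule.critical is not None:
        return CalibrationResult(
            rule_id=rule.rule_id,
            critical=rule.critical,
            alpha=alpha,
            replications=0,
            seed=None,
            fwer_estimate=alpha,
            fwer_se=0.0,
            method="analytic",
        )
    if replications < 10_000:
        import warnings

        warnings.warn("fewer than 1e4 replications: calibration SE is large")
    batch = _null_batch(design, replications, seed, draws)
    stat = rule.statistic(batch)
    n = stat.size
    if method == "quantile":
        critical, attained = _quantile_critical(stat, alpha)
    elif method == "robbins_monro":
        c0, _ = _quantile_critical(stat[: max(n // 10, 10_000)], alpha)
        critical = _robbins_monro(stat, alpha, c0)
        attained = float(np.count_nonzero(stat >= critical)) / n
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    rule.critical = critical
    se = float(np.sqrt(alpha * (1.0 - alpha) / n))
    if check_seed is not None:
        attained, se = estimate_fwer(
            rule, design, replications=replications, seed=check_seed
        )
    return CalibrationResult(
        rule_id=rule.rule_id,
        critical=critical,
        alpha=alpha,
        replications=n,
        seed=seed if seed is not None else draws.seed,
        fwer_estimate=attained,
        fwer_se=se,
        method=method,
    )
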