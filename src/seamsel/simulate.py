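"""Monte-Carlo generation of two-stage select-the-best trials.

Stage-1 effect estimates are produced by drawing ``K + 1`` independent
arm means (variance ``sigma^2 / m1`` each) and differencing against the
control; this induces the equicorrelated covariance ``V`` exactly.  The
best arm is selected (argmax, ties to the lowest index), the futility
gate ``theta_hat1[i*] >= ell`` decides continuation, and continuing
trials receive an independent stage-2 estimate with variance
``2 sigma^2 / m2``.

Simulation is column-oriented: a :class:`TrialBatch` holds arrays over
replicates.  The raw standard-normal draws live in :class:`BaseDraws`
and are reused unchanged across designs and effect vectors, so that
rule comparisons, efficiency root-finding and sample-size grid searches
are coupled by common random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

from .design import Design, ScenarioFamily

__all__ = [
    "BaseDraws",
    "TrialBatch",
    "base_draws",
    "realize",
    "simulate_batch",
    "continuation_probability",
]

#: Replicates are generated in chunks beyond this to bound peak memory.
CHUNK_REPLICATES = 2_000_000


@dataclass(frozen=True)
class BaseDraws:
    """Standard-normal reservoir shared across coupled simulations.

    ``arms`` (R, K) and ``control`` (R,) feed the stage-1 arm means;
    ``stage2`` (R,) feeds the stage-2 estimate of the selected arm;
    ``perms`` (R, K), present when requested, holds one uniform
    permutation per replicate for permutation-randomized scenarios.
    """

    arms: np.ndarray
    control: np.ndarray
    stage2: np.ndarray
    perms: np.ndarray | None = None
    seed: int | None = None

    @property
    def replications(self) -> int:
        return self.arms.shape[0]

    @property
    def n_arms(self) -> int:
        return self.arms.shape[1]


def base_draws(
    n_arms: int,
    replications: int,
    seed: int,
    permuted: bool = False,
) -> BaseDraws:
    """Generate the standard-normal reservoir for ``replications`` trials.

    Separate child streams (via ``SeedSequence.spawn``) are used for the
    stage-1 arms, the control, the stage-2 estimate and the permutations,
    so each component is reproducible independently of the others.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_arms = np.random.default_rng(streams[0])
    rng_ctrl = np.random.default_rng(streams[1])
    rng_s2 = np.random.default_rng(streams[2])

    if replications * n_arms > CHUNK_REPLICATES * 8:
        # chunked fill keeps transient allocations bounded
        arms = np.empty((replications, n_arms))
        for lo in range(0, replications, CHUNK_REPLICATES):
            hi = min(lo + CHUNK_REPLICATES, replications)
            arms[lo:hi] = rng_arms.standard_normal((hi - lo, n_arms))
    else:
        arms = rng_arms.standard_normal((replications, n_arms))
    control = rng_ctrl.standard_normal(replications)
    stage2 = rng_s2.standard_normal(replications)
    perms = None
    if permuted:
        rng_perm = np.random.default_rng(streams[3])
        perms = np.argsort(rng_perm.random((replications, n_arms)), axis=1)
    return BaseDraws(arms=arms, control=control, stage2=stage2, perms=perms, seed=seed)


@dataclass
class TrialBatch:
    """Column-oriented ensemble of simulated trials.

    ``theta_hat2`` and ``z2`` are NaN for trials stopped at the futility
    gate; downstream rule statistics map stopped trials to ``-inf`` so a
    stopped trial can never reject.
    """

    design: Design
    theta: np.ndarray  # (K,) or (R, K)
    theta_hat1: np.ndarray  # (R, K)
    selected: np.ndarray  # (R,) int
    continued: np.ndarray  # (R,) bool
    theta_hat2: np.ndarray  # (R,)
    z1: np.ndarray = field(repr=False, default=None)  # (R, K)
    z2: np.ndarray = field(repr=False, default=None)  # (R,)

    def __post_init__(self) -> None:
        d = self.design
        if self.z1 is None:
            self.z1 = self.theta_hat1 * (np.sqrt(d.m1) / (d.sigma * np.sqrt(2.0)))
        if self.z2 is None:
            self.z2 = self.theta_hat2 * (np.sqrt(d.m2) / (d.sigma * np.sqrt(2.0)))

    @property
    def replications(self) -> int:
        return self.theta_hat1.shape[0]

    @property
    def selected_estimate(self) -> np.ndarray:
        """Stage-1 estimate of the selected arm, per replicate."""
        rows = np.arange(self.replications)
        return self.theta_hat1[rows, self.selected]

    @property
    def z1_selected(self) -> np.ndarray:
        rows = np.arange(self.replications)
        return self.z1[rows, self.selected]

    @property
    def theta_selected(self) -> np.ndarray:
        """True effect of the selected arm (supports per-replicate theta)."""
        if self.theta.ndim == 1:
            return self.theta[self.selected]
        rows = np.arange(self.replications)
        return self.theta[rows, self.selected]

    @property
    def i_max(self) -> np.ndarray:
        """Index of the truly best arm per replicate; requires a unique
        maximum (the power functional is undefined otherwise)."""
        theta = np.atleast_2d(self.theta)
        order = np.sort(theta, axis=1)
        if np.any(order[:, -1] == order[:, -2]):
            raise ValueError("theta has a non-unique maximum; power is undefined")
        idx = np.argmax(theta, axis=1)
        return idx if self.theta.ndim > 1 else np.full(self.replications, idx[0])


def realize(
    design: Design,
    draws: BaseDraws,
    theta: np.ndarray,
) -> TrialBatch:
    """Map the standard-normal reservoir to a trial ensemble under
    ``theta`` (a length-K vector or an (R, K) per-replicate matrix)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != design.n_arms or draws.n_arms != design.n_arms:
        raise ValueError("theta / draws do not match the design's arm count")
    se1 = design.sigma / np.sqrt(design.m1)
    theta_hat1 = theta + se1 * (draws.arms - draws.control[:, None])
    selected = np.argmax(theta_hat1, axis=1)  # ties break to the lowest index
    rows = np.arange(theta_hat1.shape[0])
    best = theta_hat1[rows, selected]
    continued = best >= design.futility_threshold
    if theta.ndim == 1:
        theta_sel = theta[selected]
    else:
        theta_sel = theta[rows, selected]
    theta_hat2 = theta_sel + design.sigma * np.sqrt(2.0 / design.m2) * draws.stage2
    theta_hat2 = np.where(continued, theta_hat2, np.nan)
    return TrialBatch(
        design=design,
        theta=theta,
        theta_hat1=theta_hat1,
        selected=selected,
        continued=continued,
        theta_hat2=theta_hat2,
    )


def simulate_batch(
    design: Design,
    scenario,
    replications: int,
    seed: int,
    permutation_randomized: bool = False,
    draws: BaseDraws | None = None,
) -> TrialBatch:
    """Simulate an ensemble of trials.

    ``scenario`` is either an explicit effect vector or a
    :class:`~seamsel.design.ScenarioFamily`.  With
    ``permutation_randomized`` (or a permutation/ordered family) each
    replicate receives an independently drawn uniform permutation of the
    shape vector, matching the averaged-power objective of the
    permutation-family rules.
    """
    if isinstance(scenario, ScenarioFamily):
        permutation_randomized = True
        theta_base = scenario.theta_ord
    else:
        theta_base = np.asarray(scenario, dtype=float)
    if draws is None:
        draws = base_draws(
            design.n_arms, replications, seed, permuted=permutation_randomized
        )
    if permutation_randomized:
        if draws.perms is None:
            raise ValueError("draws lack permutations for a randomized scenario")
        theta = theta_base[draws.perms]
    else:
        theta = theta_base
    return realize(design, draws, theta)


def continuation_probability(design: Design) -> float:
    """Probability under ``theta = 0`` that the trial passes the futility
    gate, by one-dimensional quadrature over the control-arm variate:

    ``1 - int phi(u) Phi(u + ell * sqrt(m1) / sigma)^K du``.

    For ``ell = 0`` this equals ``K / (K + 1)`` (exchangeability of the
    ``K + 1`` iid arm means: the trial stops iff the control mean is the
    overall maximum).
    """
    K = design.n_arms
    shift = design.futility_threshold * np.sqrt(design.m1) / design.sigma
    if shift == 0.0:
        return K / (K + 1.0)

    def integrand(u):
        return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi) * special.ndtr(u + shift) ** K

    stop, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-10)
    return 1.0 - stop
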