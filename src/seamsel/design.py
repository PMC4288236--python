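"""Structural parameters of a two-stage select-the-best trial.

A seamless phase II/III design compares ``K`` experimental arms with a
common control.  In stage 1, ``m1`` patients per arm (including control)
yield effect estimates ``theta_hat1[i]`` of the treatment effects
``theta[i] = mu[i] - mu[0]``.  The arm with the largest estimate is
selected; if its estimate falls below the futility threshold ``ell`` the
trial stops without rejecting anything.  Otherwise stage 2 randomizes
``m2`` further patients to the selected arm and control, and a final
decision rule tests the selected arm's one-sided null hypothesis
``H_{0,i*}: theta[i*] <= 0`` at familywise level ``alpha``.

This module holds the design container, the families of treatment-effect
configurations used to derive Bayes-optimal rules, the stage-1 covariance
structure induced by the shared control arm, and the coefficient check
that decides whether an optimal rule controls the familywise error rate
strongly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np

__all__ = [
    "Design",
    "ScenarioFamily",
    "make_scenario",
    "stage1_covariance",
    "min_fwer_coefficient",
    "MAX_ENUMERATED_ARMS",
]

#: Permutation families are enumerated explicitly; beyond this many arms the
#: (K-1)! term count is no longer desk-scale and construction is refused.
MAX_ENUMERATED_ARMS = 8


@dataclass(frozen=True)
class Design:
    """Structural parameters of the two-stage design.

    Parameters
    ----------
    n_arms : int
        Number of experimental arms ``K`` (>= 2 for a selection design;
        ``K = 1`` is permitted as a degenerate case for sanity checks).
    m1, m2 : float
        Per-arm sample sizes in stages 1 and 2.  Real values are allowed:
        under the known-variance normal model fractional group sizes are
        well defined, and the efficiency and sample-size-matching searches
        need continuity.
    futility_threshold : float
        Stage-1 stopping threshold ``ell`` on the effect-estimate scale;
        the trial continues iff ``max_i theta_hat1[i] >= ell``.
    sigma : float
        Known standard deviation of individual responses.
    alpha : float
        One-sided familywise error level.
    """

    n_arms: int
    m1: float
    m2: float
    futility_threshold: float = 0.0
    sigma: float = 1.0
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")
        if not self.m1 > 0 or not self.m2 > 0:
            raise ValueError("stage sample sizes m1, m2 must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")

    @property
    def K(self) -> int:
        return self.n_arms

    @property
    def stage_weights(self) -> tuple[float, float]:
        """Combination weights ``w_i = sqrt(m_i / (m1 + m2))``."""
        total = self.m1 + self.m2
        return math.sqrt(self.m1 / total), math.sqrt(self.m2 / total)

    def scaled(self, rho: float) -> "Design":
        """Design with both group sizes inflated by a common factor."""
        if not rho > 0:
            raise ValueError("scale factor must be positive")
        return replace(self, m1=rho * self.m1, m2=rho * self.m2)

    def with_sizes(self, m1: float | None = None, m2: float | None = None) -> "Design":
        return replace(
            self,
            m1=self.m1 if m1 is None else m1,
            m2=self.m2 if m2 is None else m2,
        )


def stage1_covariance(design: Design) -> tuple[np.ndarray, np.ndarray]:
    """Covariance ``V`` of the stage-1 effect estimates and its inverse.

    The shared control arm induces ``V[i, i] = 2 sigma^2 / m1`` and
    ``V[i, j] = sigma^2 / m1`` for ``i != j``.  The inverse has the closed
    form ``(m1 / sigma^2) (I - J / (K + 1))`` with ``J`` the all-ones
    matrix; both are returned.
    """
    K = design.n_arms
    unit = design.sigma**2 / design.m1
    V = unit * (np.eye(K) + np.ones((K, K)))
    V_inv = (1.0 / unit) * (np.eye(K) - np.ones((K, K)) / (K + 1))
    return V, V_inv


def _validate_gammas(gammas: tuple[float, ...], kind: str, n_arms: int) -> None:
    if kind == "single":
        if len(gammas) != 1:
            raise ValueError("single-shape families take exactly one gamma")
        if not 0.0 <= gammas[0] < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        return
    if len(gammas) != n_arms - 1:
        raise ValueError(
            f"{kind} families need K-1 = {n_arms - 1} gammas, got {len(gammas)}"
        )
    arr = np.asarray(gammas, dtype=float)
    if np.any(arr < 0.0) or np.any(arr >= 1.0):
        raise ValueError("gammas must lie in [0, 1)")
    if np.any(np.diff(arr) <= 0.0):
        raise ValueError("gammas must be strictly increasing")


@dataclass(frozen=True)
class ScenarioFamily:
    """A family of treatment-effect vectors ``theta = shape * delta``.

    Three kinds are supported.

    ``single``
        ``theta`` is a permutation of ``(gamma*delta, ..., gamma*delta,
        delta)`` for one common ``gamma``; a Bayes prior puts mass
        ``1/(K+1)`` on ``theta = 0`` and on each arrangement ``xi_i``
        (best arm at position ``i``).

    ``permutation``
        ``theta`` ranges over the set ``Q`` of ``K!`` permutations of
        ``(gamma_1, ..., gamma_{K-1}, 1) * delta`` with strictly
        increasing gammas; the prior splits mass ``1/(K+1)`` evenly over
        the ``(K-1)!`` members of each subset ``Q_i`` (best arm at ``i``)
        and puts ``1/(K+1)`` on ``theta = 0``.

    ``ordered``
        As ``permutation``, except the whole mass of ``Q_K`` is
        re-allocated to the single dose-ordered vector
        ``theta_ord = (gamma_1, ..., gamma_{K-1}, 1) * delta``, encoding
        a belief that effects increase with dose unless the peak falls
        short of the top dose.
    """

    n_arms: int
    kind: str
    gammas: tuple[float, ...]
    delta: float

    def __post_init__(self) -> None:
        if self.kind not in ("single", "permutation", "ordered"):
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.n_arms < 2:
            raise ValueError("scenario families need at least 2 arms")
        _validate_gammas(self.gammas, self.kind, self.n_arms)
        if self.kind != "single" and self.n_arms > MAX_ENUMERATED_ARMS:
            raise ValueError(
                f"permutation families are enumerated only for K <= {MAX_ENUMERATED_ARMS}"
            )
        if self.delta < 0:
            raise ValueError("delta must be nonnegative (0 only for null calibration)")

    @property
    def K(self) -> int:
        return self.n_arms

    @cached_property
    def shape(self) -> np.ndarray:
        """Ordered shape vector ``(gamma_1, ..., gamma_{K-1}, 1)``."""
        K = self.n_arms
        if self.kind == "single":
            out = np.full(K, self.gammas[0])
        else:
            out = np.empty(K)
            out[:-1] = self.gammas
        out[-1] = 1.0
        return out

    @property
    def theta_ord(self) -> np.ndarray:
        """The dose-ordered effect vector ``shape * delta``."""
        return self.shape * self.delta

    def arrangement(self, i_best: int) -> np.ndarray:
        """Representative theta with the best arm at index ``i_best``
        (single-shape families only have one arrangement per position)."""
        if self.kind != "single":
            raise ValueError("arrangement() is unique only for single-shape families")
        theta = np.full(self.n_arms, self.gammas[0] * self.delta)
        theta[i_best] = self.delta
        return theta

    def support_shapes(self, i_best: int) -> tuple[np.ndarray, np.ndarray]:
        """Shape vectors with the maximum at ``i_best`` and their prior
        weights, on the scale where a single permutation-family member
        has weight 1.

        Returns ``(shapes, log_weights)`` with ``shapes`` of shape
        ``(n_terms, K)``.  For ``single`` there is one term; for
        ``permutation`` there are ``(K-1)!`` equally weighted terms; for
        ``ordered`` the ``i_best = K-1`` block collapses to ``theta_ord``
        carrying the whole ``(K-1)!``-fold mass.
        """
        K = self.n_arms
        if self.kind == "single":
            shape = np.full(K, self.gammas[0])
            shape[i_best] = 1.0
            return shape[None, :], np.zeros(1)
        if self.kind == "ordered" and i_best == K - 1:
            return self.shape[None, :], np.array([math.lgamma(K)])  # log (K-1)!
        rest = [g for g in self.gammas]
        shapes = []
        for perm in itertools.permutations(rest):
            shape = np.empty(K)
            shape[i_best] = 1.0
            idx = [j for j in range(K) if j != i_best]
            shape[idx] = perm
            shapes.append(shape)
        shapes_arr = np.array(shapes)
        return shapes_arr, np.zeros(len(shapes))

    @property
    def n_permutations(self) -> int:
        """Size of the full permutation set Q (``K!``)."""
        return math.factorial(self.n_arms)

    def prior_masses(self) -> dict[str, float]:
        """Prior mass accounting: mass on ``theta = 0`` and per block."""
        K = self.n_arms
        return {
            "null": 1.0 / (K + 1),
            "per_best_arm_block": 1.0 / (K + 1),
            "per_permutation": 1.0 / ((K + 1) * math.factorial(K - 1)),
        }

    def random_thetas(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` independent uniform permutations of the shape
        vector, scaled by delta (one row per replicate)."""
        K = self.n_arms
        perms = np.argsort(rng.random((size, K)), axis=1)
        return self.theta_ord[perms]


def make_scenario(
    n_arms: int,
    gammas,
    delta: float,
    kind: str = "permutation",
) -> ScenarioFamily:
    """Build a :class:`ScenarioFamily`, collapsing degenerate cases.

    A ``permutation`` request whose gammas are all equal is collapsed to
    the ``single`` kind: all ``(K-1)!`` terms of the optimal statistic
    coincide and the multiplicity factors out into the critical value.
    """
    if np.isscalar(gammas):
        gammas = (float(gammas),)
    gammas = tuple(float(g) for g in np.atleast_1d(gammas))
    if kind == "permutation" and len(gammas) > 1 and len(set(gammas)) == 1:
        gammas = (gammas[0],)
        kind = "single"
    if kind != "single" and len(gammas) == 1 and n_arms > 2:
        # a lone gamma with K > 2 can only describe a single-shape family
        kind = "single"
    return ScenarioFamily(n_arms=n_arms, kind=kind, gammas=gammas, delta=float(delta))


def min_fwer_coefficient(gammas, n_arms: int) -> float:
    """Smallest stage-1 coefficient appearing in any optimal-rule term.

    Each term of the optimal statistics is a linear form
    ``lambda(phi)' theta_hat1`` with
    ``lambda(phi) = (m1/sigma^2) (phi - 1 * sum(phi) / (K+1))``.  Strong
    familywise-error control from null calibration requires every
    coefficient to be nonnegative.  The minimum over all permutations
    ``phi`` and components ``j``, reported here on the delta-free scale
    (i.e. up to the positive factor ``m1 * delta / sigma^2``), is::

        min_j shape[j] - sum(shape) / (K + 1)

    For equally spaced gammas this is positive exactly when
    ``gamma_1 > K / (K + 2)``; families with a negative minimum yield
    "pseudo-optimal" rules that only bound the attainable power.
    """
    if np.isscalar(gammas):
        gammas = (float(gammas),)
    gammas = tuple(float(g) for g in np.atleast_1d(gammas))
    K = n_arms
    if len(gammas) == 1:
        shape = np.full(K, gammas[0])
        shape[-1] = 1.0
    else:
        if len(gammas) != K - 1:
            raise ValueError(f"need 1 or K-1 = {K - 1} gammas")
        shape = np.append(np.asarray(gammas, dtype=float), 1.0)
    return float(shape.min() - shape.sum() / (K + 1))
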