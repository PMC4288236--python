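"""Closed testing with stage-wise combination tests.

The four combination decision rules reject the selected arm's hypothesis
``H_{0,i*}`` iff every intersection hypothesis ``H_{0,I}`` with
``i* in I`` is rejected by an alpha-level combination test of the
stage-1 and stage-2 p-values for ``I``.  Stage-1 intersection p-values
use either Simes' rule or a Dunnett many-to-one test exploiting the
equicorrelation 1/2 induced by the common control; the stage-2 p-value
for any ``I`` containing ``i*`` is the one-sided normal p-value of
``Z_{2,i*}`` (only the selected arm has stage-2 data).

Since both combination functions decrease in the stage-1 p-value, the
closed test reduces to comparing the combination evaluated at the
*largest* stage-1 intersection p-value over supersets of ``{i*}``
against the critical value.  For Dunnett p-values that maximum is always
attained at the full index set (``i*`` carries the maximal stage-1
statistic, and the p-value grows with the intersection size); for Simes
the ``2^(K-1)`` supersets are enumerated.  Both reductions are checked
against a brute-force full-closure oracle in the test suite.

Scale conventions: the inverse chi-square statistic is exposed as
``-ln(p1 * p2)`` (larger = more evidence), whose unadjusted alpha-level
reference point is half the upper-alpha quantile of a chi-square with 4
degrees of freedom; the inverse normal statistic is
``w1 * qnorm(1 - p1) + w2 * qnorm(1 - p2)`` on the z scale.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import special, stats

from .simulate import TrialBatch

__all__ = [
    "marginal_pvalue",
    "simes_pvalue",
    "dunnett_pvalue",
    "combine",
    "stage1_floor_pvalue",
    "closed_test_statistic",
    "closed_test_reject",
    "intersection_table",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(140)
_DUNNETT_CHUNK = 100_000


def marginal_pvalue(z):
    """One-sided normal p-value ``1 - Phi(z)``."""
    return special.ndtr(-np.asarray(z, dtype=float))


def simes_pvalue(pvals, axis: int = -1):
    """Simes combination of a collection of p-values.

    With order statistics ``p_(1) <= ... <= p_(n)`` returns
    ``min_j n * p_(j) / j`` capped at 1.  Accepts arrays; the
    combination runs along ``axis``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.shape == () or p.shape[axis] == 0:
        raise ValueError("simes_pvalue needs a nonempty collection")
    p_sorted = np.sort(p, axis=axis)
    n = p.shape[axis]
    ranks_shape = [1] * p.ndim
    ranks_shape[axis] = n
    ranks = np.arange(1, n + 1, dtype=float).reshape(ranks_shape)
    return np.minimum(1.0, (n * p_sorted / ranks).min(axis=axis))


def _dunnett_p_scalarized(t: np.ndarray, n: int) -> np.ndarray:
    """``1 - int phi(u) Phi(u + sqrt(2) t)^n du`` by Gauss-Hermite
    quadrature (absolute accuracy well below 1e-8 for desk-scale t)."""
    u = np.sqrt(2.0) * _GH_NODES  # integral against the N(0,1) density
    w = _GH_WEIGHTS / np.sqrt(np.pi)
    out = np.empty_like(t, dtype=float)
    for lo in range(0, t.size, _DUNNETT_CHUNK):
        hi = min(lo + _DUNNETT_CHUNK, t.size)
        block = special.ndtr(u[None, :] + np.sqrt(2.0) * t[lo:hi, None]) ** n
        out[lo:hi] = 1.0 - block @ w
    return np.clip(out, 0.0, 1.0)


def dunnett_pvalue(z_values, n: int | None = None):
    """Dunnett intersection p-value for stage-1 statistics in ``I``.

    ``z_values`` are the standardized stage-1 statistics of the arms in
    the intersection (equicorrelated at 1/2 via the common control); the
    p-value is the null probability that the maximum of ``n`` such
    statistics exceeds ``t = max(z_values)``.  Alternatively pass a
    (vector of) maxima ``z_values`` with explicit set size ``n``.
    """
    z = np.atleast_1d(np.asarray(z_values, dtype=float))
    if n is None:
        if z.size == 0:
            raise ValueError("dunnett_pvalue needs a nonempty set")
        t = np.array([z.max()])
        out = _dunnett_p_scalarized(t, z.size)
        return float(out[0])
    scalar = np.isscalar(z_values) or np.ndim(z_values) == 0
    out = _dunnett_p_scalarized(z.ravel(), n).reshape(z.shape)
    return float(out[0]) if scalar else out


def combine(p1, p2, method: str, w1: float | None = None, w2: float | None = None):
    """Combination statistic for stage-wise p-values.

    ``inverse_chisq`` returns ``-ln(p1 * p2)``; ``inverse_normal``
    returns ``w1 * qnorm(1 - p1) + w2 * qnorm(1 - p2)`` and requires
    weights with ``w1^2 + w2^2 = 1``.  Larger values mean more evidence
    in both conventions.  A zero p-value saturates to ``+inf``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if method == "inverse_chisq":
        with np.errstate(divide="ignore"):
            return -(np.log(p1) + np.log(p2))
    if method == "inverse_normal":
        if w1 is None or w2 is None:
            raise ValueError("inverse_normal needs weights w1, w2")
        if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-9:
            raise ValueError("inverse normal weights must satisfy w1^2 + w2^2 = 1")
        return w1 * stats.norm.isf(p1) + w2 * stats.norm.isf(p2)
    raise ValueError(f"unknown combination method {method!r}")


def _simes_floor(z1: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Max over supersets ``I`` of {i*} of the Simes stage-1 p-value.

    Because ``i*`` carries the smallest stage-1 p-value, supersets of
    ``{i*}`` correspond (after sorting each replicate's p-values) to
    subsets of the remaining columns joined with the first; enumeration
    over the 2^(K-1) sorted column patterns covers them all.
    """
    K = z1.shape[1]
    p_sorted = np.sort(marginal_pvalue(z1), axis=1)  # column 0 is p_{i*}
    floor = np.zeros(z1.shape[0])
    for mask in itertools.product((False, True), repeat=K - 1):
        cols = [0] + [j + 1 for j, keep in enumerate(mask) if keep]
        sub = p_sorted[:, cols]  # already sorted ascending
        n = len(cols)
        simes = (n * sub / np.arange(1, n + 1)).min(axis=1)
        np.maximum(floor, np.minimum(simes, 1.0), out=floor)
    return floor


def stage1_floor_pvalue(batch: TrialBatch, intersection: str) -> np.ndarray:
    """Largest stage-1 intersection p-value over sets containing the
    selected arm — the binding constraint of the closed test."""
    if intersection == "simes":
        return _simes_floor(batch.z1, batch.selected)
    if intersection == "dunnett":
        K = batch.design.n_arms
        return dunnett_pvalue(batch.z1_selected, n=K)
    raise ValueError(f"unknown intersection test {intersection!r}")


def closed_test_statistic(
    batch: TrialBatch, method: str, intersection: str
) -> np.ndarray:
    """Per-replicate threshold statistic of the closed test: the minimum
    over intersections ``I`` containing ``i*`` of the combined statistic.
    Rejection of ``H_{0,i*}`` at critical ``C`` is ``statistic >= C``.
    Stopped trials map to ``-inf``.
    """
    out = np.full(batch.replications, -np.inf)
    cont = batch.continued
    if not np.any(cont):
        return out
    sub = _subset_batch(batch, cont)
    p1 = stage1_floor_pvalue(sub, intersection)
    p2 = marginal_pvalue(sub.z2)
    if method == "inverse_normal":
        w1, w2 = batch.design.stage_weights
        out[cont] = combine(p1, p2, method, w1, w2)
    else:
        out[cont] = combine(p1, p2, method)
    return out


def _subset_batch(batch: TrialBatch, mask: np.ndarray) -> TrialBatch:
    theta = batch.theta if batch.theta.ndim == 1 else batch.theta[mask]
    return TrialBatch(
        design=batch.design,
        theta=theta,
        theta_hat1=batch.theta_hat1[mask],
        selected=batch.selected[mask],
        continued=batch.continued[mask],
        theta_hat2=batch.theta_hat2[mask],
        z1=batch.z1[mask],
        z2=batch.z2[mask],
    )


def closed_test_reject(
    batch: TrialBatch, method: str, intersection: str, critical: float
) -> np.ndarray:
    """Closed-testing decision for ``H_{0,i*}`` per replicate."""
    return closed_test_statistic(batch, method, intersection) >= critical


def intersection_table(batch: TrialBatch, replicate: int, method: str,
                       intersection: str):
    """Full intersection table (I, P1, P2, combined) for one trial —
    a debugging aid; the decision path never materializes this."""
    import pandas as pd

    if not batch.continued[replicate]:
        raise ValueError("trial stopped at the futility gate; no final test")
    K = batch.design.n_arms
    i_star = int(batch.selected[replicate])
    z1 = batch.z1[replicate]
    p2 = float(marginal_pvalue(batch.z2[replicate]))
    w1, w2 = batch.design.stage_weights
    rows = []
    for r in range(1, K + 1):
        for I in itertools.combinations(range(K), r):
            if i_star not in I:
                continue
            if intersection == "simes":
                p1 = float(simes_pvalue(marginal_pvalue(z1[list(I)])))
            else:
                p1 = float(dunnett_pvalue(z1[list(I)]))
            if method == "inverse_normal":
                comb = float(combine(p1, p2, method, w1, w2))
            else:
                comb = float(combine(p1, p2, method))
            rows.append({"I": I, "p1": p1, "p2": p2, "combined": comb})
    return pd.DataFrame(rows)
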