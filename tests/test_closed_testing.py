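import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from seamsel import Design, simulate_batch
from seamsel.closed_testing import (
    closed_test_reject,
    closed_test_statistic,
    combine,
    dunnett_pvalue,
    intersection_table,
    marginal_pvalue,
    simes_pvalue,
)


def test_marginal_pvalue_values():
    assert marginal_pvalue(0.0) == pytest.approx(0.5)
    assert marginal_pvalue(1.959964) == pytest.approx(0.025, abs=1e-6)
    assert marginal_pvalue(-40.0) == pytest.approx(1.0)


def test_simes_examples():
    assert simes_pvalue([0.01, 0.04]) == pytest.approx(0.02)
    assert simes_pvalue([0.37]) == pytest.approx(0.37)
    assert simes_pvalue([0.5, 0.5, 0.5]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        simes_pvalue([])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
def test_simes_bounded_by_smallest_pvalue(pvals):
    s = simes_pvalue(pvals)
    p_min = min(pvals)
    assert p_min - 1e-12 <= s <= min(1.0, len(pvals) * p_min) + 1e-12


def test_dunnett_examples():
    # |I| = 1 reduces to the marginal p-value
    assert dunnett_pvalue([1.959964]) == pytest.approx(0.025, abs=1e-6)
    # t = 0: pr{max of n equicorrelated statistics > 0} by exchangeability
    # of the n + 1 underlying arm means
    assert dunnett_pvalue([0.0, 0.0]) == pytest.approx(2 / 3, abs=1e-8)
    assert dunnett_pvalue(np.zeros(5)) == pytest.approx(5 / 6, abs=1e-8)
    with pytest.raises(ValueError):
        dunnett_pvalue([])


@pytest.mark.parametrize("n", [2, 5])
@pytest.mark.parametrize("t", [-1.5, 0.3, 2.2, 4.0])
def test_dunnett_quadrature_accuracy(n, t):
    # Gauss-Hermite result vs adaptive quadrature, absolute 1e-8
    def integrand(u):
        return stats.norm.pdf(u) * stats.norm.cdf(u + np.sqrt(2) * t) ** n

    ref, _ = integrate.quad(integrand, -np.inf, np.inf, epsabs=1e-12)
    assert dunnett_pvalue(np.array(t), n=n) == pytest.approx(1 - ref, abs=1e-8)


def test_combine_examples():
    assert combine(0.05, 0.05, "inverse_chisq") == pytest.approx(-np.log(0.0025), abs=1e-4)
    # unadjusted alpha = 0.025 reference on the -ln(p1 p2) scale is half
    # the chi-square(4) upper quantile
    assert stats.chi2.isf(0.025, 4) / 2 == pytest.approx(5.5717, abs=1e-4)
    w = 1 / np.sqrt(2)
    assert combine(0.025, 0.025, "inverse_normal", w, w) == pytest.approx(
        np.sqrt(2) * 1.959964, abs=1e-4
    )
    with pytest.raises(ValueError):
        combine(0.1, 0.1, "inverse_normal", 0.9, 0.9)


def test_combine_saturates_at_zero_pvalue():
    assert np.isposinf(combine(0.0, 0.1, "inverse_chisq"))


@settings(derandomize=True, max_examples=100)
@given(
    st.floats(1e-5, 0.999), st.floats(1e-5, 0.999), st.floats(1e-5, 0.999)
)
def test_combined_statistics_decrease_in_pvalues(p1a, p1b, p2):
    lo, hi = sorted([p1a, p1b])
    w = 1 / np.sqrt(2)
    for method in ("inverse_chisq", "inverse_normal"):
        kw = {"w1": w, "w2": w} if method == "inverse_normal" else {}
        assert combine(lo, p2, method, **kw) >= combine(hi, p2, method, **kw)


def _brute_force_statistic(batch, method, intersection):
    """Direct closure: min over all I containing i* of the combined
    statistic, evaluating every intersection p-value from scratch."""
    K = batch.design.n_arms
    w1, w2 = batch.design.stage_weights
    out = np.full(batch.replications, -np.inf)
    for r in range(batch.replications):
        if not batch.continued[r]:
            continue
        i_star = batch.selected[r]
        p2 = marginal_pvalue(batch.z2[r])
        best = np.inf
        for size in range(1, K + 1):
            for I in itertools.combinations(range(K), size):
                if i_star not in I:
                    continue
                z = batch.z1[r, list(I)]
                if intersection == "simes":
                    p1 = simes_pvalue(marginal_pvalue(z))
                else:
                    p1 = dunnett_pvalue(z)
                if method == "inverse_normal":
                    val = combine(p1, p2, method, w1, w2)
                else:
                    val = combine(p1, p2, method)
                best = min(best, val)
        out[r] = best
    return out


@pytest.mark.parametrize(
    "method,intersection",
    [
        ("inverse_normal", "dunnett"),
        ("inverse_normal", "simes"),
        ("inverse_chisq", "simes"),
        ("inverse_chisq", "dunnett"),
    ],
)
def test_closed_test_matches_brute_force_closure(method, intersection):
    design = Design(n_arms=4, m1=10.0, m2=30.0, sigma=2.0)
    batch = simulate_batch(design, np.array([0.0, 0.5, -0.3, 1.0]), 2_000, seed=21)
    fast = closed_test_statistic(batch, method, intersection)
    slow = _brute_force_statistic(batch, method, intersection)
    cont = batch.continued
    np.testing.assert_allclose(fast[cont], slow[cont], atol=1e-8)
    assert np.all(fast[~cont] == -np.inf)
    for crit in (1.5, 2.0):
        np.testing.assert_array_equal(
            closed_test_reject(batch, method, intersection, crit),
            slow >= crit,
        )


def test_statistic_monotone_in_stage2(design5):
    batch = simulate_batch(design5, np.zeros(5), 2_000, seed=5)
    bumped = simulate_batch(design5, np.zeros(5), 2_000, seed=5)
    bumped.theta_hat2 = bumped.theta_hat2 + 1.0
    bumped.z2 = bumped.theta_hat2 * np.sqrt(design5.m2) / (design5.sigma * np.sqrt(2))
    for method, intersection in (("inverse_normal", "dunnett"), ("inverse_chisq", "simes")):
        lo = closed_test_statistic(batch, method, intersection)
        hi = closed_test_statistic(bumped, method, intersection)
        cont = batch.continued
        assert np.all(hi[cont] >= lo[cont])


def test_intersection_table_contents(design5):
    batch = simulate_batch(design5, np.zeros(5), 50, seed=1)
    r = int(np.flatnonzero(batch.continued)[0])
    table = intersection_table(batch, r, "inverse_normal", "dunnett")
    assert len(table) == 2 ** 4  # all I containing i*
    i_star = batch.selected[r]
    assert all(i_star in I for I in table["I"])
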