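"""Funnel control limits: exact-CDF oracles, asymptotics, nesting, flags."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strokecost import funnel
from strokecost.funnel import (
    FLAG_INSIDE,
    FLAG_OUT95,
    FLAG_OUT998,
    binomial_limit,
    flag_units,
    mean_limits,
    poisson_limit,
    proportion_limits,
    ratio_limits,
)

# --- independent brute-force oracles (log-space CDF enumeration) -----------


def _binom_cdf_table(n, theta):
    log_pmf = [
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + k * math.log(theta) + (n - k) * math.log1p(-theta)
        for k in range(n + 1)
    ]
    pmf = [math.exp(v) for v in log_pmf]
    cdf, acc = [], 0.0
    for v in pmf:
        acc += v
        cdf.append(acc)
    return cdf


def _poisson_cdf_table(mu, kmax):
    pmf = [math.exp(-mu + k * math.log(mu) - math.lgamma(k + 1)) for k in range(kmax + 1)]
    cdf, acc = [], 0.0
    for v in pmf:
        acc += v
        cdf.append(acc)
    return cdf


def _oracle_limit(cdf_table, p, denom):
    # atoms at k + 1/2: continuity-interpolated CDF inversion
    for r, f in enumerate(cdf_table):
        if f > p:
            f_prev = cdf_table[r - 1] if r > 0 else 0.0
            lam = (f - p) / (f - f_prev)
            return max(0.0, (r + 0.5 - lam) / denom)
    raise AssertionError("CDF table too short")


# --- exact-oracle agreement -------------------------------------------------


@pytest.mark.parametrize("alpha", [0.05, 0.002])
def test_binomial_limits_match_enumeration_oracle(alpha):
    """Interpolated binomial limits agree with full CDF enumeration for all
    n <= 50 at both significance levels."""
    theta = 0.15
    for n in range(1, 51):
        table = _binom_cdf_table(n, theta)
        for p in (alpha / 2, 1 - alpha / 2):
            expected = min(1.0, _oracle_limit(table, p, n))
            assert binomial_limit(n, theta, p) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("alpha", [0.05, 0.002])
def test_poisson_limits_match_enumeration_oracle(alpha):
    """Interpolated Poisson limits agree with full CDF enumeration for all
    integer E <= 50 at both significance levels."""
    for e in range(1, 51):
        table = _poisson_cdf_table(float(e), 400)
        for p in (alpha / 2, 1 - alpha / 2):
            expected = _oracle_limit(table, p, float(e))
            assert poisson_limit(float(e), p) == pytest.approx(expected, abs=1e-9)


def test_binomial_n20_explicit_oracle():
    table = _binom_cdf_table(20, 0.15)
    for p in (0.025, 0.975):
        assert binomial_limit(20, 0.15, p) == pytest.approx(
            min(1.0, _oracle_limit(table, p, 20)), abs=1e-12
        )


# --- asymptotics ------------------------------------------------------------


def test_binomial_limits_converge_to_normal():
    n, theta = 100_000, 0.15
    z = stats.norm.ppf(0.975)
    se = math.sqrt(theta * (1 - theta) / n)
    assert binomial_limit(n, theta, 0.025) == pytest.approx(theta - z * se, abs=1e-3)
    assert binomial_limit(n, theta, 0.975) == pytest.approx(theta + z * se, abs=1e-3)


def test_poisson_limits_converge_to_normal():
    e = 100_000.0
    z = stats.norm.ppf(0.975)
    assert poisson_limit(e, 0.025) == pytest.approx(1 - z / math.sqrt(e), abs=1e-3)
    assert poisson_limit(e, 0.975) == pytest.approx(1 + z / math.sqrt(e), abs=1e-3)


def test_proportion_limits_symmetric_at_half():
    curve = proportion_limits([5, 17, 40, 200], 0.5)
    for _, row in curve.grid.iterrows():
        assert row["lower"] + row["upper"] == pytest.approx(1.0, abs=1e-9)


# --- curve invariants --------------------------------------------------------


@pytest.fixture(scope="module")
def curves():
    n_grid = np.arange(1, 400, 7)
    e_grid = np.linspace(0.5, 60, 50)
    return {
        "proportion": proportion_limits(n_grid, 0.15),
        "ratio": ratio_limits(e_grid),
        "mean": mean_limits(n_grid, 3600.0, 4900.0),
    }


def test_bands_bracket_target(curves):
    for name, curve in curves.items():
        grid = curve.grid
        assert (grid["lower"] <= curve.display_target + 1e-12).all(), name
        assert (grid["upper"] >= curve.display_target - 1e-12).all(), name


def test_bands_nest(curves):
    for name, curve in curves.items():
        g = curve.grid.pivot(index="precision", columns="level", values=["lower", "upper"])
        assert (g[("lower", 0.998)] <= g[("lower", 0.95)] + 1e-12).all(), name
        assert (g[("upper", 0.998)] >= g[("upper", 0.95)] - 1e-12).all(), name


def test_band_width_narrows_with_precision(curves):
    """Band width is non-increasing in precision wherever the limits are
    interior (the clamp at 0 makes tiny-n widths artificially narrow)."""
    for name, curve in curves.items():
        for level, sub in curve.grid.groupby("level"):
            sub = sub[sub["lower"] > 0].sort_values("precision")
            width = sub["upper"] - sub["lower"]
            assert (np.diff(width.to_numpy()) <= 1e-9).all(), (name, level)


def test_mean_limits_closed_form():
    curve = mean_limits([1, 4], 100.0, 10.0, alphas=(0.05,))
    row1 = curve.grid[curve.grid["precision"] == 1.0].iloc[0]
    assert row1["upper"] == pytest.approx(100.0 + 1.959964 * 10.0, abs=1e-4)
    row4 = curve.grid[curve.grid["precision"] == 4.0].iloc[0]
    # quadrupling n halves the half-width
    assert (row4["upper"] - 100.0) == pytest.approx((row1["upper"] - 100.0) / 2, rel=1e-12)


def test_log_scale_mean_limits():
    curve = mean_limits([10], math.log(2000.0), 1.0, alphas=(0.05,), log_scale=True)
    row = curve.grid.iloc[0]
    z = stats.norm.ppf(0.975)
    assert row["upper"] == pytest.approx(2000.0 * math.exp(z / math.sqrt(10)))
    assert curve.display_target == pytest.approx(2000.0)


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        proportion_limits([10], 1.2)
    with pytest.raises(ValueError):
        ratio_limits([0.0])
    with pytest.raises(ValueError):
        mean_limits([10], 0.0, -1.0)
    with pytest.raises(ValueError):
        proportion_limits([10], 0.5, alphas=(1.5,))


# --- flagging ----------------------------------------------------------------


def test_flags_match_pointwise_recomputation():
    rng = np.random.default_rng(99)
    theta = 0.2
    ns = rng.integers(10, 400, size=60)
    values = rng.binomial(ns, rng.uniform(0.05, 0.5, size=60)) / ns
    points = pd.DataFrame({"unit_id": np.arange(60), "precision": ns, "value": values})
    curve = proportion_limits(np.arange(10, 401, 30), theta)
    flagged = flag_units(points, curve)
    for _, row in flagged.iterrows():
        lo95 = binomial_limit(int(row["precision"]), theta, 0.025)
        hi95 = binomial_limit(int(row["precision"]), theta, 0.975)
        lo998 = binomial_limit(int(row["precision"]), theta, 0.001)
        hi998 = binomial_limit(int(row["precision"]), theta, 0.999)
        if lo95 <= row["value"] <= hi95:
            assert row["flag"] == FLAG_INSIDE
        elif lo998 <= row["value"] <= hi998:
            assert row["flag"] == FLAG_OUT95
        else:
            assert row["flag"] == FLAG_OUT998
        if row["flag"] != FLAG_INSIDE:
            assert row["direction"] == ("high" if row["value"] > hi95 else "low")


def test_point_on_limit_counts_inside():
    curve = mean_limits([25], 100.0, 10.0, alphas=(0.05, 0.002))
    hi = curve.limits_at(25, 0.05)[1]
    points = pd.DataFrame({"precision": [25, 25], "value": [hi, hi + 1e-6]})
    flagged = flag_units(points, curve)
    assert flagged["flag"].tolist() == [FLAG_INSIDE, FLAG_OUT95]


def test_outside_998_implies_outside_95():
    curve = proportion_limits([50], 0.15)
    points = pd.DataFrame({"precision": [50], "value": [0.9]})
    assert flag_units(points, curve)["flag"].iloc[0] == FLAG_OUT998


def test_mean_funnel_null_coverage_monte_carlo():
    """In-control units (means drawn at mu0, sigma0) fall outside the 95% band
    about 5% of the time (10^4 replicate units)."""
    rng = np.random.default_rng(42)
    n_units, n_per = 10_000, 30
    mu0, sigma0 = 100.0, 15.0
    means = rng.normal(mu0, sigma0 / math.sqrt(n_per), size=n_units)
    curve = mean_limits([n_per], mu0, sigma0, alphas=(0.05,))
    lo, hi = curve.limits_at(n_per, 0.05)
    outside = ((means < lo) | (means > hi)).mean()
    assert outside == pytest.approx(0.05, abs=0.01)


def test_overdispersion_estimate_near_one_under_null():
    rng = np.random.default_rng(7)
    n_per = 200
    values = rng.binomial(n_per, 0.15, size=500) / n_per
    points = pd.DataFrame({"precision": n_per, "value": values})
    curve = proportion_limits([n_per], 0.15)
    phi = funnel.estimate_overdispersion(points, curve)
    assert 0.5 < phi < 1.5
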