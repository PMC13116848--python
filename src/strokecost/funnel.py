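"""Spiegelhalter funnel-plot control limits for provider comparison.

Three indicator families are supported:

* proportions (e.g. crude 90-day mortality) against unit size n, with exact
  binomial limits;
* standardized event ratios O/E (e.g. standardized mortality) against the
  expected count E, with exact Poisson limits;
* continuous means (e.g. mean 90-day cost) against n, with normal-theory
  limits mu0 +/- z * sigma0 / sqrt(n).

Exact discrete limits use the continuity-interpolated inversion of the
binomial/Poisson CDF: for tail probability p, find the smallest integer r
with F(r) > p, set lambda = (F(r) - p) / (F(r) - F(r - 1)), and take
(r + 1/2 - lambda) as the continuous quantile; dividing by n (or E) puts it
on the indicator scale.  This is linear interpolation of the CDF with the
probability atom of count k placed at k + 1/2 (a continuity correction), so
the limits of a symmetric distribution are symmetric about its mean (e.g.
theta0 = 1/2 at every n) and as n grows they converge to the usual normal
approximation theta0 +/- z * sqrt(theta0 (1 - theta0) / n).

Default limits are the two-sided 95% and 99.8% bands (alpha = 0.05, 0.002).
A point exactly on a limit counts as inside (conservative flagging).  An
optional multiplicative overdispersion inflation (phi-hat from a winsorized
z-score mean square) is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHAS = (0.05, 0.002)

FLAG_INSIDE = "inside"
FLAG_OUT95 = "outside_95"
FLAG_OUT998 = "outside_998"


def _check_alphas(alphas):
    alphas = tuple(sorted(alphas, reverse=True))  # inner band first
    for a in alphas:
        if not 0.0 < a < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {a}")
    return alphas


def _interp_quantile(cdf, p: float) -> float:
    """Continuous inversion of a discrete CDF at tail probability p.

    ``cdf(r)`` must return P(X <= r) for integer r (with cdf(-1) = 0).
    Returns r + 1/2 - lambda where r is the smallest integer with cdf(r) > p
    and lambda interpolates the exceedance within the step; the half-count
    shift places each probability atom at the centre of its unit cell.
    """
    lo, hi = 0, 1
    while cdf(hi) <= p:
        hi *= 2
    while lo < hi:  # first r with cdf(r) > p
        mid = (lo + hi) // 2
        if cdf(mid) > p:
            hi = mid
        else:
            lo = mid + 1
    r = lo
    f_r = cdf(r)
    f_rm1 = cdf(r - 1) if r > 0 else 0.0
    lam = (f_r - p) / (f_r - f_rm1)
    return r + 0.5 - lam


def binomial_limit(n: int, theta0: float, p: float) -> float:
    """One interpolated exact binomial limit, on the proportion scale.

    Clamped to [0, 1]: the continuous inversion can dip below zero in the far
    lower tail when F(0) already exceeds p.
    """
    q = _interp_quantile(lambda r: stats.binom.cdf(r, n, theta0), p) / n
    return min(1.0, max(0.0, q))


def poisson_limit(expected: float, p: float) -> float:
    """One interpolated exact Poisson limit, on the O/E ratio scale (>= 0)."""
    q = _interp_quantile(lambda r: stats.poisson.cdf(r, expected), p) / expected
    return max(0.0, q)


@dataclass(frozen=True)
class FunnelLimitCurve:
    """Control limits of one indicator family over a precision grid.

    ``family`` is one of ``proportion``, ``ratio``, ``mean``; ``target`` the
    in-control indicator value (theta0, 1.0, or mu0); ``sigma0`` the
    between-patient SD for the mean family; ``grid`` a long-format frame with
    columns (level, precision, lower, upper).  ``limits_at`` recomputes exact
    limits at any precision, which is what ``flag_units`` uses — the grid is
    for plotting/export only.
    """

    family: str
    target: float
    alphas: tuple[float, ...]
    grid: pd.DataFrame
    sigma0: float | None = None
    log_scale: bool = False

    def limits_at(self, precision: float, alpha: float) -> tuple[float, float]:
        lo_p, hi_p = alpha / 2.0, 1.0 - alpha / 2.0
        if self.family == "proportion":
            n = int(round(precision))
            return (
                binomial_limit(n, self.target, lo_p),
                binomial_limit(n, self.target, hi_p),
            )
        if self.family == "ratio":
            return (
                poisson_limit(precision, lo_p),
                poisson_limit(precision, hi_p),
            )
        if self.family == "mean":
            z = stats.norm.ppf(hi_p)
            half = z * self.sigma0 / math.sqrt(precision)
            if self.log_scale:
                return math.exp(self.target - half), math.exp(self.target + half)
            return self.target - half, self.target + half
        raise ValueError(f"unknown funnel family {self.family!r}")

    @property
    def display_target(self) -> float:
        return math.exp(self.target) if (self.family == "mean" and self.log_scale) else self.target


def _build_grid(curve_like, precisions, alphas) -> pd.DataFrame:
    rows = []
    for alpha in alphas:
        for prec in precisions:
            lo, hi = curve_like.limits_at(float(prec), alpha)
            rows.append(
                {"level": 1.0 - alpha, "precision": float(prec), "lower": lo, "upper": hi}
            )
    return pd.DataFrame(rows)


def _finish(family, target, precisions, alphas, sigma0=None, log_scale=False):
    curve = FunnelLimitCurve(
        family=family,
        target=target,
        alphas=alphas,
        grid=pd.DataFrame(),
        sigma0=sigma0,
        log_scale=log_scale,
    )
    grid = _build_grid(curve, precisions, alphas)
    return FunnelLimitCurve(
        family=family, target=target, alphas=alphas, grid=grid, sigma0=sigma0, log_scale=log_scale
    )


def proportion_limits(n_grid, theta0: float, alphas=DEFAULT_ALPHAS) -> FunnelLimitCurve:
    """Exact interpolated binomial limits for a proportion indicator."""
    if not 0.0 < theta0 < 1.0:
        raise ValueError(f"theta0 must be in (0, 1), got {theta0}")
    n_grid = np.asarray(n_grid)
    if (n_grid < 1).any():
        raise ValueError("all n must be >= 1")
    return _finish("proportion", float(theta0), n_grid, _check_alphas(alphas))


def ratio_limits(e_grid, alphas=DEFAULT_ALPHAS) -> FunnelLimitCurve:
    """Exact interpolated Poisson limits for a standardized ratio (target 1)."""
    e_grid = np.asarray(e_grid, dtype=float)
    if (e_grid <= 0).any():
        raise ValueError("all expected counts must be positive")
    return _finish("ratio", 1.0, e_grid, _check_alphas(alphas))


def mean_limits(
    n_grid, mu0: float, sigma0: float, alphas=DEFAULT_ALPHAS, log_scale: bool = False
) -> FunnelLimitCurve:
    """Normal-theory limits mu0 +/- z * sigma0/sqrt(n) for a mean indicator.

    With ``log_scale=True``, mu0/sigma0 are interpreted on the log-cost scale
    and the limits are exponentiated back to EUR.
    """
    if sigma0 <= 0:
        raise ValueError(f"sigma0 must be positive, got {sigma0}")
    n_grid = np.asarray(n_grid, dtype=float)
    if (n_grid < 1).any():
        raise ValueError("all n must be >= 1")
    return _finish("mean", float(mu0), n_grid, _check_alphas(alphas), sigma0=float(sigma0),
                   log_scale=log_scale)


def flag_units(points: pd.DataFrame, curve: FunnelLimitCurve) -> pd.DataFrame:
    """Flag each unit against the curve's limits at its own precision.

    ``points`` needs columns ``precision`` and ``value`` (plus any id/label
    columns, which are passed through).  Limits are recomputed exactly at each
    point's precision rather than interpolated from the grid.  Boundary points
    count as inside; ``outside_998`` implies ``outside_95``.
    """
    out = points.copy()
    alphas = curve.alphas  # inner band first
    flags, directions = [], []
    for _, row in out.iterrows():
        prec, value = float(row["precision"]), float(row["value"])
        if prec <= 0:
            raise ValueError("point precision must be positive")
        flag, direction = FLAG_INSIDE, ""
        lo_in, hi_in = curve.limits_at(prec, alphas[0])
        if value > hi_in:
            flag, direction = FLAG_OUT95, "high"
        elif value < lo_in:
            flag, direction = FLAG_OUT95, "low"
        if flag == FLAG_OUT95 and len(alphas) > 1:
            lo_out, hi_out = curve.limits_at(prec, alphas[1])
            if value > hi_out or value < lo_out:
                flag = FLAG_OUT998
        flags.append(flag)
        directions.append(direction)
    out["flag"] = flags
    out["direction"] = directions
    return out


def estimate_overdispersion(points: pd.DataFrame, curve: FunnelLimitCurve,
                            winsor: float = 0.1) -> float:
    """phi-hat from the winsorized mean square of unit z-scores (>= 1 inflates).

    z-scores use the normal approximation of each family at the unit's
    precision; the most extreme ``winsor`` fraction on each side is shrunk to
    the winsorizing quantile before averaging.
    """
    prec = points["precision"].to_numpy(dtype=float)
    value = points["value"].to_numpy(dtype=float)
    if curve.family == "proportion":
        se = np.sqrt(curve.target * (1 - curve.target) / prec)
        z = (value - curve.target) / se
    elif curve.family == "ratio":
        z = (value - 1.0) * np.sqrt(prec)
    else:
        z = (value - curve.display_target) / (curve.sigma0 / np.sqrt(prec))
    lo, hi = np.quantile(z, [winsor, 1.0 - winsor])
    z = np.clip(z, lo, hi)
    return float(np.mean(z**2))


def plot_funnel(points: pd.DataFrame, curve: FunnelLimitCurve, path=None, ax=None,
                label_col: str | None = "unit_label"):
    """Render a funnel plot (matplotlib) with dotted 95%/99.8% limit lines."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    styles = {0: ("green", "95%"), 1: ("red", "99.8%")}
    for i, alpha in enumerate(curve.alphas):
        sub = curve.grid[curve.grid["level"] == 1.0 - alpha].sort_values("precision")
        color, lbl = styles.get(i, ("grey", f"{100 * (1 - alpha):.1f}%"))
        ax.plot(sub["precision"], sub["lower"], linestyle=":", color=color, label=f"{lbl} limits")
        ax.plot(sub["precision"], sub["upper"], linestyle=":", color=color)
    ax.axhline(curve.display_target, color="black", linewidth=0.8)
    if label_col and label_col in points.columns:
        for lbl, sub in points.groupby(label_col):
            ax.scatter(sub["precision"], sub["value"], s=14, label=str(lbl))
    else:
        ax.scatter(points["precision"], points["value"], s=14)
    ax.set_xlabel("precision (n or expected events)")
    ax.set_ylabel("indicator value")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
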