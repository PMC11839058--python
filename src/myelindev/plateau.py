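"""Derivative confidence bands and plateau detection.

A trajectory is said to plateau when the first derivative of the fitted
age smooth becomes statistically indistinguishable from zero and stays so
through the end of the observed age range.  The derivative is computed
analytically from the basis derivatives, and uncertainty is propagated by
posterior simulation: coefficient vectors are drawn from
N(beta_hat, V_beta) and the 95% *simultaneous* band is

    d_hat(a) +/- m* se(a),   m* = level-quantile of max_a |(d_i(a) - d_hat(a)) / se(a)|

so the band is valid jointly over the whole age grid (m* exceeds the
pointwise 1.96).  The plateau age is the earliest grid age from which the
band contains zero everywhere onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import SmoothFit

#: flags attached to plateau ages
FLAG_PLATEAU = "plateau"
FLAG_ABSENT = "no-plateau"  # band excludes zero at the range end
FLAG_NO_GROWTH = "no-growth"  # band never excludes zero anywhere


@dataclass
class DerivativeBand:
    """First derivative of a smooth fit with a simultaneous confidence band."""

    age_grid: np.ndarray
    derivative: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    m_star: float  # simultaneous critical multiplier
    level: float
    n_draws: int


def derivative_band(
    fit: SmoothFit,
    age_grid,
    n_draws: int = 10000,
    level: float = 0.95,
    seed: int = 0,
) -> DerivativeBand:
    """Simultaneous confidence band for the fitted first derivative.

    Draws ``n_draws`` coefficient vectors from the Gaussian posterior
    N(beta_hat, V_beta), standardizes the derivative deviations by the
    pointwise standard error and takes the ``level`` quantile of the
    maximum absolute deviation over the grid as the critical multiplier.
    Reproducible under a fixed seed.
    """
    age_grid = np.asarray(age_grid, dtype=float)
    D = fit.deriv_design(age_grid)
    d_hat = D @ fit.coef
    cov_d = D @ fit.cov @ D.T
    se = np.sqrt(np.maximum(np.diag(cov_d), 0.0))
    if np.all(se == 0):  # noise-free fit: band collapses onto the derivative
        return DerivativeBand(age_grid, d_hat, d_hat.copy(), d_hat.copy(), 0.0, level, n_draws)

    # draw only the derivative-relevant coefficients
    active = np.flatnonzero(np.any(D != 0, axis=0))
    Da = D[:, active]
    cov_a = fit.cov[np.ix_(active, active)]
    # guard against tiny asymmetries / negative eigenvalues
    w, V = np.linalg.eigh(0.5 * (cov_a + cov_a.T))
    if np.any(w < -1e-8 * max(w.max(), 1e-300)):
        raise ValueError("coefficient covariance is not positive semi-definite")
    root = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, len(active))) @ root.T  # deviations from beta_hat
    dev = draws @ Da.T  # (n_draws, grid)
    se_safe = np.where(se > 0, se, np.inf)
    max_dev = np.max(np.abs(dev) / se_safe[None, :], axis=1)
    m_star = float(np.quantile(max_dev, level))
    return DerivativeBand(
        age_grid=age_grid,
        derivative=d_hat,
        lower=d_hat - m_star * se,
        upper=d_hat + m_star * se,
        m_star=m_star,
        level=level,
        n_draws=n_draws,
    )


def plateau_age(band: DerivativeBand):
    """Earliest age from which growth is never again significant.

    Growth is significant at an age when the simultaneous band lies
    entirely above zero (lower bound > 0).  The plateau age is the first
    grid age after the *last* significant-growth age -- a terminal-state
    rule, robust to mid-range dips of the band.  The criterion is
    one-sided in the growth direction: a band that ends significantly
    *below* zero still marks the end of growth.  (The two-sided variant --
    requiring the band to contain zero through the range end -- is
    equivalent whenever the fitted derivative does not overshoot negative,
    but a low-rank smooth fitted to a hard-saturating trajectory
    systematically does overshoot at the range end, which would erase
    every real plateau as an artifact.)

    Returns ``(age, flag)``: ``"plateau"`` for a regular plateau,
    ``"no-plateau"`` (age = NaN) when growth is still significant at the
    maximum age, and ``"no-growth"`` (age = grid minimum) when growth is
    never significant anywhere.
    """
    sig_growth = band.lower > 0.0
    if sig_growth[-1]:
        return float("nan"), FLAG_ABSENT
    if not np.any(sig_growth):
        return float(band.age_grid[0]), FLAG_NO_GROWTH
    last_sig = np.max(np.flatnonzero(sig_growth))
    return float(band.age_grid[last_sig + 1]), FLAG_PLATEAU


def plateau_table(bands: dict) -> pd.DataFrame:
    """Apply :func:`plateau_age` to a dict of unit -> DerivativeBand."""
    rows = []
    for unit, band in bands.items():
        a, flag = plateau_age(band)
        rows.append({"unit": unit, "plateau_age": a, "flag": flag})
    return pd.DataFrame(rows)


def plateau_summary(
    plateaus: pd.DataFrame,
    groups: pd.DataFrame,
    eligible: pd.DataFrame | None = None,
) -> dict:
    """Group-level plateau proportions, mean timing and one-way ANOVA.

    ``plateaus`` has columns ``unit, plateau_age, flag``; ``groups`` maps
    ``unit -> group``.  ``eligible`` (optional, columns ``unit, eligible``)
    marks units with a significant overall age effect: ineligible units are
    excluded from timing means and the ANOVA but stay in the proportion
    denominators, and both counts are reported.
    """
    df = plateaus.merge(groups[["unit", "group"]], on="unit", validate="one_to_one")
    if eligible is not None:
        df = df.merge(eligible[["unit", "eligible"]], on="unit", how="left")
        df["eligible"] = df["eligible"].fillna(True)
    else:
        df["eligible"] = True
    df["has_plateau"] = df["flag"] == FLAG_PLATEAU

    per_group = {}
    timing_groups = []
    for g, sub in df.groupby("group", sort=True):
        n_total = len(sub)
        timed = sub[sub["has_plateau"] & sub["eligible"]]
        per_group[g] = {
            "n_units": int(n_total),
            "n_eligible": int(sub["eligible"].sum()),
            "n_plateaued": int(sub["has_plateau"].sum()),
            "proportion_plateaued": float(sub["has_plateau"].mean()) if n_total else 0.0,
            "mean_plateau_age": float(timed["plateau_age"].mean()) if len(timed) else float("nan"),
        }
        if len(timed) >= 2:
            timing_groups.append(timed["plateau_age"].to_numpy())
        elif len(timed) == 0:
            warnings.warn(f"group {g!r} has no eligible plateaued units", stacklevel=2)

    if len(timing_groups) >= 2:
        F, p = one_way_anova(timing_groups)
    else:
        F, p = float("nan"), float("nan")
    return {"groups": per_group, "anova_F": F, "anova_p": p}


def proportion_by_cutoff(plateaus: pd.DataFrame, groups: pd.DataFrame, cutoff: float) -> dict:
    """Per-group proportion of units that have plateaued by ``cutoff``.

    A unit counts as plateaued by the cutoff when its plateau age is
    defined (``plateau`` or ``no-growth`` -- the latter plateaued at or
    before the window start) and does not exceed the cutoff; ``no-plateau``
    units never count.  Denominator = all units in the group.
    """
    df = plateaus.merge(groups[["unit", "group"]], on="unit", validate="one_to_one")
    hit = (df["flag"] != FLAG_ABSENT) & (df["plateau_age"] <= cutoff)
    return {g: float(h.mean()) for g, h in hit.groupby(df["group"], sort=True)}


def one_way_anova(samples) -> tuple:
    """One-way ANOVA F and p across the given groups of values.

    Degenerate within-group variance with a real between-group difference
    yields a large finite F (with a warning) rather than inf/NaN.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    df_between = len(samples) - 1
    df_within = sum(len(s) for s in samples) - len(samples)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance: F reported as large finite", stacklevel=2)
        return 1e12, 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return float(F), p
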