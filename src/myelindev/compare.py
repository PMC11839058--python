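"""Cross-species trajectory comparison and depth/group contrasts.

Macaque brain development runs roughly four times faster than human
development, so macaque and human trajectories are overlaid after a 4:1
age rescaling (human age = 4 x macaque age).  Because T1w/T2w units are
arbitrary and scanner-dependent, absolute levels are never compared across
species: trajectories are first baseline-adjusted, i.e. shifted so the
fitted value at a species-specific reference age (1 y macaque, 4 y human
by default) is exactly zero.

``estimate_scaling`` is an added recovery harness: it searches for the
time-compression factor s that best superimposes the baseline-adjusted
trajectories, which on synthetic data with known compression should
recover the generating factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .gam import SmoothFit
from .plateau import one_way_anova


@dataclass
class SpeciesScaling:
    """Macaque-to-human time mapping: human_age = factor * macaque_age."""

    factor: float = 4.0
    human_baseline_age: float = 4.0
    macaque_baseline_age: float = 1.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("scaling factor must be > 0")


def rescale_age(ages, scaling: SpeciesScaling, direction: str):
    """Map ages between species' time axes (invertible).

    ``direction`` is ``"macaque_to_human"`` (multiply by the factor) or
    ``"human_to_macaque"`` (divide).
    """
    ages = np.asarray(ages, dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be strictly positive")
    if direction == "macaque_to_human":
        return ages * scaling.factor
    if direction == "human_to_macaque":
        return ages / scaling.factor
    raise ValueError("direction must be 'macaque_to_human' or 'human_to_macaque'")


def baseline_adjust(fit: SmoothFit, baseline_age: float, ages=None) -> np.ndarray:
    """Fitted trajectory minus its value at ``baseline_age`` (y = 0 there).

    Evaluated at ``ages`` (default: the fit's 200-point age grid).  The
    baseline must lie inside the fitted age range.
    """
    lo, hi = fit.age_range
    if not lo <= baseline_age <= hi:
        raise ValueError(f"baseline age {baseline_age} outside fitted range [{lo}, {hi}]")
    if ages is None:
        ages = np.linspace(lo, hi, 200)
    ages = np.asarray(ages, dtype=float)
    return fit.predict(ages) - fit.predict(np.array([baseline_age]))[0]


def _overlap_mismatch(h_fit, m_fit, s, a0, a1, n_eval, m_in_human_time):
    """Mean-centered squared curve difference and signal variance over the
    human-time overlap [a0, a1]."""
    grid = np.linspace(a0, a1, n_eval)
    h = h_fit.predict(grid)
    if m_in_human_time:  # macaque fit performed on rescaled ages
        m = m_fit.predict(grid)
    else:  # macaque fit lives in macaque time
        lo_m, hi_m = m_fit.age_range
        m = m_fit.predict(np.clip(grid / s, lo_m, hi_m))
    diff = (h - h.mean()) - (m - m.mean())
    return float(np.mean(diff**2)), float(np.var(h) + np.var(m)) / 2.0


def estimate_scaling(
    human: dict,
    macaque: dict,
    candidate_range=(1.0, 8.0),
    *,
    grid_step: float = 0.125,
    full_weight: float = 0.4,
    min_overlap_frac: float = 0.05,
    n_eval: int = 80,
) -> float:
    """Estimate the macaque->human time-compression factor s.

    ``human`` and ``macaque`` map unit labels either to fitted
    :class:`~myelindev.gam.SmoothFit` trajectories or to observation tables
    (columns ``age`` and ``value``/``ratio``, optionally ``sex``); units are
    matched by label.  For each candidate s the species are compared over
    the overlap of the human range with the rescaled macaque range, after
    mean-centering within the window (the level-free analogue of baseline
    adjustment), normalizing the squared difference by the window signal
    variance (summed over units).

    The objective combines two complementary terms.  The *windowed* term
    (table inputs only) refits each species on the shared window, so both
    curves carry the same smoothing bias -- this term is unbiased but, fed
    only in-window data, cannot rule out degenerate large-s alignments
    where both restricted fits collapse to near-linear curves.  The
    *full-window* term compares the fits to each species' complete data,
    which retain that global shape information but are biased by the
    asymmetric windows.  Their weighted sum (``full_weight``) is searched
    on a grid of step ``grid_step`` with bounded local refinement;
    deterministic.  Candidates whose overlap is shorter than
    ``min_overlap_frac`` of the human range are rejected (a sliver of
    overlap makes any two centered curves coincide trivially).
    """
    units = sorted(set(human) & set(macaque))
    if not units:
        raise ValueError("no shared units between species")
    lo, hi = candidate_range
    if not 0 < lo < hi <= 10:
        raise ValueError("candidate_range must lie within (0, 10]")

    from .gam import SmoothFit, fit_gam

    table_mode = not isinstance(next(iter(human.values())), SmoothFit)

    def as_fit(obj):
        if isinstance(obj, SmoothFit):
            return obj
        df = obj.rename(columns={"ratio": "value"})
        return fit_gam(df[[c for c in ("age", "value", "sex") if c in df.columns]])

    full_h = {u: as_fit(human[u]) for u in units}
    full_m = {u: as_fit(macaque[u]) for u in units}

    def windowed_term(s, u, a0, a1):
        h, m = human[u], macaque[u]
        h_age = np.asarray(h["age"], float)
        m_age = np.asarray(m["age"], float)
        hm = h[(h_age >= a0) & (h_age <= a1)]
        mm = m[(m_age * s >= a0) & (m_age * s <= a1)]
        if len(hm) < 12 or len(mm) < 12:
            return None
        if hm["age"].nunique() < 4 or mm["age"].nunique() < 4:
            return None
        try:
            fh = as_fit(hm)
            fm = as_fit(mm.assign(age=np.asarray(mm["age"], float) * s))
        except (ValueError, RuntimeError):
            return None
        g0 = max(fh.age_range[0], fm.age_range[0])
        g1 = min(fh.age_range[1], fm.age_range[1])
        if g1 <= g0:
            return None
        return _overlap_mismatch(fh, fm, s, g0, g1, n_eval, m_in_human_time=True)

    def objective(s):
        num_w = den_w = num_f = den_f = 0.0
        cnt_w = cnt_f = 0
        for u in units:
            h_lo, h_hi = full_h[u].age_range
            m_lo, m_hi = full_m[u].age_range
            a0, a1 = max(h_lo, s * m_lo), min(h_hi, s * m_hi)
            if a1 - a0 < min_overlap_frac * (h_hi - h_lo):
                continue
            nf, df_ = _overlap_mismatch(full_h[u], full_m[u], s, a0, a1, n_eval,
                                        m_in_human_time=False)
            num_f += nf
            den_f += df_
            cnt_f += 1
            if table_mode:
                out = windowed_term(s, u, a0, a1)
                if out is not None:
                    num_w += out[0]
                    den_w += out[1]
                    cnt_w += 1
        if cnt_f == 0 or den_f < 1e-12:
            return np.inf
        val = full_weight * num_f / den_f if table_mode else num_f / den_f
        if table_mode:
            if cnt_w == 0 or den_w < 1e-12:
                return np.inf
            val += num_w / den_w
        return val

    cand = np.arange(lo, hi + grid_step / 2, grid_step)
    vals = np.array([objective(s) for s in cand])
    if not np.any(np.isfinite(vals)):
        raise ValueError("empty overlap after rescaling for every candidate factor")
    best = int(np.argmin(vals))
    bl = cand[max(best - 1, 0)]
    bh = cand[min(best + 1, len(cand) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(bl, bh), method="bounded",
                                   options={"xatol": 1e-4})
    return float(res.x) if res.fun <= vals[best] else float(cand[best])


def depth_slope_anova(slopes, axis=None) -> dict:
    """One-way ANOVA of per-parcel slopes across depth bins, per S-A group.

    ``slopes`` is a DataFrame with columns ``parcel, depth_bin, slope``;
    ``axis`` (optional) maps ``parcel -> group`` -- without it a single
    ``all`` group is used.  Returns ``{group: {"F": ..., "p": ...}}``.
    """
    df = slopes.copy()
    if axis is not None:
        df = df.merge(axis[["parcel", "group"]], on="parcel")
    else:
        df["group"] = "all"
    out = {}
    for g, sub in df.groupby("group", sort=True):
        samples = [b["slope"].to_numpy() for _, b in sub.groupby("depth_bin", sort=True)]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) < 2:
            warnings.warn(f"group {g!r} degenerate for depth ANOVA", stacklevel=2)
            out[g] = {"F": float("nan"), "p": float("nan")}
            continue
        F, p = one_way_anova(samples)
        out[g] = {"F": F, "p": p}
    return out
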