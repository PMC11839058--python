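"""Penalized smooth age-trajectory models.

Per parcel (and per depth bin) the ratio is modeled as

    y = b0 + b_sex * sex + f(age) + (subject intercept) + e

where ``f`` is a low-rank thin-plate regression spline of age with maximum
basis complexity k = 3: after the identifiability constraint the smooth
contributes one unpenalized linear term and exactly one curvature term
whose coefficient carries the wiggliness penalty.  The smoothing parameter
``lambda`` (and, for longitudinal designs, the subject random-intercept
variance) is selected by restricted maximum likelihood (REML), optimized
over log-lambda.  The penalty null space spans {1, age}, so constants and
straight lines are reproduced exactly at every lambda.

Basis construction follows the standard 1-D thin-plate spline recipe:
radial basis eta(r) = r^3 / 12 at the unique observed ages, eigen-restricted
to the leading k terms, with the polynomial-orthogonality constraint
absorbed so that the retained penalty is positive semi-definite.

Age effects are quantified as the difference in R^2 between the full model
and a reduced model without the age smooth (signed by the mean fitted first
derivative), tested by a deviance-difference chi-squared statistic on the
effective-degrees-of-freedom difference, with Benjamini-Hochberg FDR
control across parcels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests

_LOGLAM_BOUNDS = (-15.0, 25.0)
_REML_TOL = 1e-8


def _eta(r):
    return np.abs(r) ** 3 / 12.0


def _eta_deriv(d):
    # d/dx |x - knot|^3 / 12
    return d * np.abs(d) / 4.0


@dataclass
class SmoothBasis:
    """Rank-k thin-plate age smooth (penalized part only).

    ``design(ages)`` evaluates the penalized basis functions, ``deriv``
    their analytic first derivatives; ``penalty`` is the (k-2) x (k-2)
    wiggliness penalty in those coordinates.
    """

    knots: np.ndarray
    delta_map: np.ndarray  # (n_knots, k-2): radial coefficients per basis fn
    penalty: np.ndarray  # (k-2, k-2), positive semi-definite
    k: int

    def design(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return _eta(ages[:, None] - self.knots[None, :]) @ self.delta_map

    def deriv(self, ages) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        return _eta_deriv(ages[:, None] - self.knots[None, :]) @ self.delta_map


def build_smooth_basis(ages, k: int = 3, max_knots: int = 200) -> SmoothBasis:
    """Construct the rank-k thin-plate regression spline basis.

    Knots are the unique observed ages (quantile-thinned above
    ``max_knots``).  The basis is the span of the k leading eigenvectors of
    the radial kernel matrix, restricted to coefficient vectors orthogonal
    to the polynomial space {1, age}; with k = 3 this leaves exactly one
    penalized basis function.
    """
    x = np.unique(np.asarray(ages, dtype=float))
    if x.size < k:
        raise ValueError(f"need at least k={k} distinct ages, got {x.size}")
    if x.size > max_knots:
        x = np.quantile(x, np.linspace(0, 1, max_knots))
        x = np.unique(x)
    E = _eta(x[:, None] - x[None, :])
    evals, evecs = linalg.eigh(E)
    order = np.argsort(np.abs(evals))[::-1][:k]
    d_k = evals[order]
    U_k = evecs[:, order]
    T = np.column_stack([np.ones_like(x), x])
    C = T.T @ U_k  # (2, k)
    Z = linalg.null_space(C)  # (k, k-2)
    if Z.shape[1] != k - 2:
        raise ValueError("degenerate constraint: could not absorb the polynomial space")
    penalty = (Z * d_k[:, None]).T @ Z
    penalty = 0.5 * (penalty + penalty.T)
    # delta = U_k Z b are the radial coefficients; T' delta = 0 by construction,
    # which guarantees b' penalty b = delta' E delta >= 0
    return SmoothBasis(knots=x, delta_map=U_k @ Z, penalty=penalty, k=k)


# ---------------------------------------------------------------------------
# model fit


@dataclass
class SmoothFit:
    """Fitted penalized smooth model."""

    coef: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance sigma2 * (X'X + S_lam)^-1
    lam: dict  # smoothing parameters by penalty name
    sigma2: float
    edf: float  # total effective degrees of freedom
    edf_fixed: float  # edf excluding subject random intercepts
    rss: float  # residual sum of squares of the penalized fit
    r2: float  # 1 - RSS/TSS on fixed-effects fitted values
    reml: float  # -2 * restricted log-likelihood at the optimum
    n: int
    basis: SmoothBasis | None
    age_mean: float
    age_range: tuple
    include_age: bool
    include_sex: bool
    col_age: int | None
    col_sex: int | None
    sl_pen: slice | None
    sl_subj: slice | None
    fitted_fixed: np.ndarray = field(repr=False, default=None)

    # -- prediction -------------------------------------------------------
    def _fixed_design(self, ages, sex=0.0):
        ages = np.asarray(ages, dtype=float)
        p = len(self.coef)
        X = np.zeros((ages.size, p))
        X[:, 0] = 1.0
        if self.col_sex is not None:
            X[:, self.col_sex] = sex
        if self.include_age:
            X[:, self.col_age] = ages - self.age_mean
            X[:, self.sl_pen] = self.basis.design(ages)
        return X

    def predict(self, ages, sex=0.0) -> np.ndarray:
        """Fixed-effects fitted values at ``ages`` (sex contrast at 0 =
        balanced average by default; subject intercepts excluded)."""
        return self._fixed_design(ages, sex) @ self.coef

    def deriv_design(self, ages) -> np.ndarray:
        """Design matrix of the first derivative d fit / d age."""
        ages = np.asarray(ages, dtype=float)
        p = len(self.coef)
        D = np.zeros((ages.size, p))
        if self.include_age:
            D[:, self.col_age] = 1.0
            D[:, self.sl_pen] = self.basis.deriv(ages)
        return D

    def derivative(self, ages) -> np.ndarray:
        return self.deriv_design(ages) @ self.coef


def _sex_contrast(values) -> np.ndarray:
    values = np.asarray(values)
    if values.dtype.kind in "OUS":
        return np.where(values == "M", 0.5, -0.5)
    return values.astype(float)


def _reml_neg2(loglams, XtX, Xty, yty, n, Mp, pens):
    """-2 x restricted log-likelihood (constants dropped are kept: full form),
    profiled over sigma^2.  ``pens`` is a list of (full-size penalty, rank,
    logdet+ of the unit penalty)."""
    A = XtX.copy()
    logdet_S = 0.0
    for ll, (S, rank, logdet_unit) in zip(loglams, pens):
        A += np.exp(ll) * S
        logdet_S += rank * ll + logdet_unit
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None, None
    beta = linalg.cho_solve((c, low), Xty, check_finite=False)
    rss_pen = max(yty - Xty @ beta, 1e-300)
    sigma2 = rss_pen / (n - Mp)
    logdet_A = 2.0 * np.sum(np.log(np.diag(c)))
    neg2 = (n - Mp) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_A - logdet_S
    return neg2, beta, sigma2


def fit_gam(
    data: pd.DataFrame,
    k: int = 3,
    random_intercepts: bool = False,
    include_age: bool = True,
    include_sex: bool | None = None,
    lam: float | dict | None = None,
) -> SmoothFit:
    """Fit the penalized smooth trajectory model by REML.

    ``data`` needs columns ``age`` and ``value``; ``sex`` ({F, M} or a
    numeric contrast) and ``subject`` (ids, required with
    ``random_intercepts``) are used when present.  ``include_age=False``
    fits the nested reduced model without the age smooth.  Passing ``lam``
    fixes the smoothing parameter(s) instead of selecting them by REML
    (useful for null-space checks).
    """
    age = np.asarray(data["age"], dtype=float)
    y = np.asarray(data["value"], dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations")
    if include_sex is None:
        include_sex = "sex" in data.columns
    if random_intercepts and "subject" not in data.columns:
        raise ValueError("random_intercepts requires a 'subject' column")

    cols = [np.ones(n)]
    names = ["intercept"]
    col_sex = None
    if include_sex:
        cols.append(_sex_contrast(data["sex"]))
        names.append("sex")
        col_sex = len(cols) - 1
    basis = None
    col_age = None
    sl_pen = None
    age_mean = float(age.mean())
    if include_age:
        basis = build_smooth_basis(age, k=k)
        cols.append(age - age_mean)
        col_age = len(cols) - 1
        pen_block = basis.design(age)
        sl_pen = slice(len(cols), len(cols) + pen_block.shape[1])
        cols.extend(pen_block.T)
        names.extend([f"s(age).{i}" for i in range(pen_block.shape[1])])

    sl_subj = None
    n_subj = 0
    if random_intercepts:
        codes, _ = pd.factorize(data["subject"], sort=True)
        n_subj = codes.max() + 1
        Zs = np.zeros((n, n_subj))
        Zs[np.arange(n), codes] = 1.0
        sl_subj = slice(len(cols), len(cols) + n_subj)
        cols.extend(Zs.T)
        names.extend([f"subj.{i}" for i in range(n_subj)])

    X = np.column_stack(cols)
    p = X.shape[1]
    if np.linalg.matrix_rank(X[:, : (sl_subj.start if sl_subj else p)]) < (
        sl_subj.start if sl_subj else p
    ):
        raise ValueError("rank-deficient fixed-effects design")

    # penalties embedded at full size
    pens = []
    pen_names = []
    if include_age:
        S = np.zeros((p, p))
        S[sl_pen, sl_pen] = basis.penalty
        w = np.linalg.eigvalsh(basis.penalty)
        w = w[w > 1e-12 * w.max()] if w.max() > 0 else w
        pens.append((S, len(w), float(np.sum(np.log(w)))))
        pen_names.append("smooth")
    if random_intercepts:
        S = np.zeros((p, p))
        S[sl_subj, sl_subj] = np.eye(n_subj)
        pens.append((S, n_subj, 0.0))
        pen_names.append("subject")

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Mp = p - sum(r for _, r, _ in pens)

    if not pens:
        loglams = []
        neg2 = np.nan
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = float(np.sum((y - X @ beta) ** 2)) / max(n - p, 1)
        A = XtX
    else:
        if lam is not None:
            if np.isscalar(lam):
                lamvals = [float(lam)] * len(pens)
            else:
                lamvals = [float(lam[nm]) for nm in pen_names]
            loglams = [np.log(max(v, 1e-300)) for v in lamvals]
        elif len(pens) == 1:
            res = optimize.minimize_scalar(
                lambda ll: _reml_neg2([ll], XtX, Xty, yty, n, Mp, pens)[0],
                bounds=_LOGLAM_BOUNDS,
                method="bounded",
                options={"xatol": _REML_TOL},
            )
            loglams = [float(res.x)]
        else:
            res = optimize.minimize(
                lambda lls: _reml_neg2(lls, XtX, Xty, yty, n, Mp, pens)[0],
                x0=np.zeros(len(pens)),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
            )
            if not np.all(np.isfinite(res.x)):
                raise RuntimeError("REML optimization did not converge: " + str(res))
            loglams = list(res.x)
        neg2, beta, sigma2 = _reml_neg2(loglams, XtX, Xty, yty, n, Mp, pens)
        if beta is None:
            raise RuntimeError("REML solve failed at the selected smoothing parameters")
        A = XtX + sum(np.exp(ll) * S for ll, (S, _, _) in zip(loglams, pens))

    Ainv = linalg.inv(A)
    cov = sigma2 * Ainv
    hat_diag = np.einsum("ij,ji->i", Ainv, XtX)
    edf = float(np.sum(hat_diag))
    fixed_cols = np.arange(p) if sl_subj is None else np.arange(sl_subj.start)
    edf_fixed = float(np.sum(hat_diag[fixed_cols]))

    fitted_all = X @ beta
    rss = float(np.sum((y - fitted_all) ** 2))
    fitted_fixed = X[:, fixed_cols] @ beta[fixed_cols]
    tss = float(np.sum((y - y.mean()) ** 2))
    rss_fixed = float(np.sum((y - fitted_fixed) ** 2))
    r2 = 1.0 - rss_fixed / tss if tss > 0 else 0.0

    return SmoothFit(
        coef=beta,
        cov=cov,
        lam={nm: float(np.exp(ll)) for nm, ll in zip(pen_names, loglams)},
        sigma2=float(sigma2),
        edf=edf,
        edf_fixed=edf_fixed,
        rss=rss,
        r2=r2,
        reml=float(neg2) if np.isfinite(np.asarray(neg2, float)) else np.nan,
        n=n,
        basis=basis,
        age_mean=age_mean,
        age_range=(float(age.min()), float(age.max())),
        include_age=include_age,
        include_sex=include_sex,
        col_age=col_age,
        col_sex=col_sex,
        sl_pen=sl_pen,
        sl_subj=sl_subj,
        fitted_fixed=fitted_fixed,
    )


# ---------------------------------------------------------------------------
# age effects


@dataclass
class AgeEffect:
    """Signed partial R^2 of the age smooth with its significance."""

    r2_partial: float
    sign: int  # +1 / -1 from the mean fitted first derivative
    p_value: float
    mean_slope: float
    statistic: float  # scaled deviance difference
    df: float
    q_value: float | None = None

    @property
    def signed_r2(self) -> float:
        return self.sign * self.r2_partial


def age_effect(full: SmoothFit, reduced: SmoothFit, age_grid) -> AgeEffect:
    """Full-vs-reduced comparison of nested smooth fits.

    ``r2_partial`` is R^2(full) - R^2(reduced); the sign is that of the
    mean first derivative over ``age_grid``.  Significance comes from the
    deviance (residual sum of squares) difference divided by the full
    model's residual scale.  The reference degrees of freedom are the age
    smooth's *maximal* dimension (k - 1: its linear part plus the penalized
    basis functions), not the data-chosen effective-df difference: because
    REML selects lambda adaptively, the effective-df reference is
    anticonservative under the null, while the fixed maximal dimension --
    the space the penalized fit actually searches -- restores nominal
    calibration.  The Gaussian scale is estimated, so the statistic is
    referred to an F distribution on (df, n - edf) rather than the
    asymptotic chi-squared.
    """
    if not full.include_age or reduced.include_age:
        raise ValueError("expected a full fit with age and a reduced fit without")
    if full.n != reduced.n:
        raise ValueError("full and reduced fits use different data")
    r2_partial = full.r2 - reduced.r2
    dev = max(reduced.rss - full.rss, 0.0)
    scale = full.rss / (full.n - full.edf)
    # age-smooth dimension: linear term + penalized basis functions
    df = 1.0 + (full.sl_pen.stop - full.sl_pen.start)
    if scale <= 0.0:  # perfect (noise-free) fit
        stat = np.inf if dev > 0 else 0.0
        p = 0.0 if dev > 0 else 1.0
    else:
        stat = dev / scale
        p = float(stats.f.sf(stat / df, df, full.n - full.edf))
    slope = float(np.mean(full.derivative(age_grid)))
    sign = 1 if slope >= 0 else -1
    return AgeEffect(
        r2_partial=float(r2_partial),
        sign=sign,
        p_value=p,
        mean_slope=slope,
        statistic=float(stat),
        df=float(df),
    )


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mean_slope(fit: SmoothFit, age_grid) -> float:
    """Mean analytic first derivative of the fitted smooth over the grid."""
    age_grid = np.asarray(age_grid, dtype=float)
    lo, hi = fit.age_range
    tol = 1e-8 * max(1.0, hi - lo)
    if age_grid.min() < lo - tol or age_grid.max() > hi + tol:
        raise ValueError("age grid extends outside the observed age range")
    return float(np.mean(fit.derivative(age_grid)))


def default_age_grid(fit: SmoothFit, n: int = 200) -> np.ndarray:
    return np.linspace(fit.age_range[0], fit.age_range[1], n)


def slope_vs_axis(slopes: pd.DataFrame, axis: pd.DataFrame) -> dict:
    """Regress per-parcel developmental slopes on the S-A axis rank.

    ``slopes`` has columns ``parcel`` and ``slope`` (e.g. mean GAM first
    derivatives, or deep-minus-superficial slope differences).  Returns the
    smooth-fit R^2 and p (same rank-3 machinery as the age models, with the
    axis rank in the role of age) alongside the plain linear-regression R^2
    and the linear slope sign.
    """
    merged = slopes.merge(axis[["parcel", "rank"]], on="parcel")
    if len(merged) < 5:
        raise ValueError("need >= 5 parcels")
    x = merged["rank"].to_numpy(float)
    yv = merged["slope"].to_numpy(float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate axis: all ranks equal")
    df = pd.DataFrame({"age": x, "value": yv})
    full = fit_gam(df, include_sex=False)
    red = fit_gam(df, include_age=False, include_sex=False)
    eff = age_effect(full, red, np.linspace(x.min(), x.max(), 200))
    lin = stats.linregress(x, yv)
    return {
        "r2_smooth": full.r2,
        "p": eff.p_value,
        "r2_linear": float(lin.rvalue**2),
        "p_linear": float(lin.pvalue),
        "linear_sign": int(np.sign(lin.slope)) if lin.slope != 0 else 0,
    }
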