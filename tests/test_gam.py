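"""Penalized smooth fits, REML, age effects, FDR, slopes."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from myelindev import gam, synthetic


def _df(age, y, sex=None, subject=None):
    d = {"age": age, "value": y}
    if sex is not None:
        d["sex"] = sex
    if subject is not None:
        d["subject"] = subject
    return pd.DataFrame(d)


@pytest.fixture()
def ages(rng):
    return rng.uniform(5, 35, 80)


class TestSmoothBasis:
    def test_k3_has_exactly_one_penalized_function(self, ages):
        basis = gam.build_smooth_basis(ages, k=3)
        assert basis.design(ages).shape[1] == 1
        assert basis.penalty.shape == (1, 1) and basis.penalty[0, 0] > 0

    def test_penalized_column_orthogonal_to_polynomials_at_knots(self, ages):
        basis = gam.build_smooth_basis(ages, k=3)
        # delta coefficients orthogonal to {1, x}: guarantees PSD penalty
        T = np.column_stack([np.ones_like(basis.knots), basis.knots])
        np.testing.assert_allclose(T.T @ basis.delta_map, 0.0, atol=1e-8)

    def test_deriv_matches_finite_difference(self, ages):
        basis = gam.build_smooth_basis(ages, k=3)
        grid = np.linspace(6, 34, 40)
        h = 1e-4
        fd = (basis.design(grid + h) - basis.design(grid - h)) / (2 * h)
        np.testing.assert_allclose(basis.deriv(grid), fd, atol=1e-6)

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            gam.build_smooth_basis([1.0, 1.0, 2.0], k=3)


class TestFitGam:
    @pytest.mark.parametrize("lam", [0.0, 1.0, 1e6])
    def test_null_space_exactness_constant_and_line(self, ages, lam):
        for y in (np.full_like(ages, 3.7), 2.0 + 0.5 * ages):
            fit = gam.fit_gam(_df(ages, y), lam=lam)
            np.testing.assert_allclose(fit.predict(ages), y, atol=1e-6)

    def test_linear_data_mean_slope(self, ages, rng):
        sex = rng.choice(["F", "M"], ages.size)
        y = 2.0 + 0.5 * ages + 0.1 * np.where(sex == "M", 0.5, -0.5)
        fit = gam.fit_gam(_df(ages, y, sex))
        assert gam.mean_slope(fit, gam.default_age_grid(fit)) == pytest.approx(0.5, abs=1e-6)

    def test_duplicated_rows_leave_curve_essentially_unchanged(self, ages, rng):
        # REML's selected penalty rescales only approximately under row
        # duplication, so identity holds to fitting precision, not exactly
        y = np.sin(ages / 6) + rng.normal(0, 0.1, ages.size)
        # unpenalized fit: exactly invariant
        g1 = gam.fit_gam(_df(ages, y), lam=0.0)
        g2 = gam.fit_gam(_df(np.tile(ages, 2), np.tile(y, 2)), lam=0.0)
        grid = gam.default_age_grid(g1, 50)
        np.testing.assert_allclose(g1.predict(grid), g2.predict(grid), atol=1e-8)
        # REML-selected penalty: invariant to fitting precision
        f1 = gam.fit_gam(_df(ages, y))
        f2 = gam.fit_gam(_df(np.tile(ages, 2), np.tile(y, 2)))
        np.testing.assert_allclose(f1.predict(grid), f2.predict(grid), atol=0.02)

    def test_pure_noise_shrinks_toward_null_space(self):
        edfs = []
        for rep in range(40):
            rng = np.random.default_rng(rep)
            age = rng.uniform(5, 35, 60)
            y = rng.normal(0, 1, 60)
            fit = gam.fit_gam(_df(age, y))
            edfs.append(fit.edf_fixed)
        # null space is {intercept, age}: 2 fixed df; median extra edf small
        assert np.median(edfs) - 2 < 0.45

    def test_random_intercepts_recover_subject_structure(self, rng):
        subj = np.repeat(np.arange(12), 5)
        age = rng.uniform(1, 3, 60)
        u = rng.normal(0, 0.5, 12)
        y = 1.0 + 0.2 * age + u[subj] + rng.normal(0, 0.05, 60)
        fit = gam.fit_gam(_df(age, y, subject=subj.astype(str)), random_intercepts=True)
        assert fit.lam["subject"] < 1.0  # large subject variance => small ridge
        resid_sd = np.sqrt(fit.sigma2)
        assert resid_sd < 0.15  # subject variance not dumped into residual

    def test_deterministic(self, ages, rng):
        y = rng.normal(0, 1, ages.size)
        f1 = gam.fit_gam(_df(ages, y))
        f2 = gam.fit_gam(_df(ages, y))
        np.testing.assert_array_equal(f1.coef, f2.coef)

    def test_missing_subject_column_rejected(self, ages):
        with pytest.raises(ValueError, match="subject"):
            gam.fit_gam(_df(ages, ages), random_intercepts=True)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestMgcvCrossCheck:
    def test_fit_matches_mgcv_reml(self, tmp_path):
        """Dual route: same model fitted by mgcv (thin-plate, k=3, REML)."""
        rng = np.random.default_rng(42)
        n = 80
        age = rng.uniform(5, 35, n)
        sex = rng.choice(["F", "M"], n)
        y = 1.2 + 0.6 * (1 - np.exp(-0.25 * age)) + 0.05 * np.where(sex == "M", 0.5, -0.5)
        y = y + rng.normal(0, 0.06, n)
        dat = tmp_path / "dat.csv"
        pd.DataFrame({"age": age, "sex": sex, "y": y}).to_csv(dat, index=False)
        fit = gam.fit_gam(_df(age, y, sex))
        grid = np.linspace(age.min(), age.max(), 9)
        script = f"""
        library(mgcv)
        d <- read.csv("{dat}")
        d$sexc <- ifelse(d$sex == "M", .5, -.5)
        m <- gam(y ~ sexc + s(age, k=3, bs="tp"), data=d, method="REML")
        pred <- predict(m, newdata=data.frame(age=seq(min(d$age), max(d$age), length.out=9), sexc=0))
        cat(sum(m$edf), m$sig2, pred, sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.split()]
        assert fit.edf_fixed == pytest.approx(vals[0], abs=1e-4)
        assert fit.sigma2 == pytest.approx(vals[1], rel=1e-4)
        np.testing.assert_allclose(fit.predict(grid), vals[2:], atol=1e-5)


class TestAgeEffect:
    def test_noise_free_increasing_linear_r2_one(self, ages):
        # no sex column: a random sex draw carries chance correlation with
        # age, leaving the reduced model a sliver of spurious R^2
        y = 1.0 + 0.5 * ages
        full = gam.fit_gam(_df(ages, y))
        red = gam.fit_gam(_df(ages, y), include_age=False)
        eff = gam.age_effect(full, red, gam.default_age_grid(full))
        assert eff.r2_partial == pytest.approx(1.0, abs=1e-6)
        assert eff.sign == 1 and eff.p_value < 1e-10

    def test_decreasing_mirror_has_same_magnitude_negative_sign(self, ages, rng):
        sex = rng.choice(["F", "M"], ages.size)
        up, dn = 1.0 + 0.5 * ages, 1.0 - 0.5 * ages
        effs = []
        for y in (up, dn):
            full = gam.fit_gam(_df(ages, y, sex))
            red = gam.fit_gam(_df(ages, y, sex), include_age=False)
            effs.append(gam.age_effect(full, red, gam.default_age_grid(full)))
        assert effs[0].sign == 1 and effs[1].sign == -1
        assert effs[0].r2_partial == pytest.approx(effs[1].r2_partial, abs=1e-9)

    def test_null_data_p_near_uniform_and_r2_near_zero(self, ages, rng):
        y = rng.normal(0, 1, ages.size)
        full = gam.fit_gam(_df(ages, y))
        red = gam.fit_gam(_df(ages, y), include_age=False)
        eff = gam.age_effect(full, red, gam.default_age_grid(full))
        assert 0 <= eff.r2_partial < 0.2 and eff.p_value > 1e-4

    def test_r2_partial_never_exceeds_one(self, ages, rng):
        y = 1.0 + 0.5 * ages + rng.normal(0, 0.01, ages.size)
        full = gam.fit_gam(_df(ages, y))
        red = gam.fit_gam(_df(ages, y), include_age=False)
        eff = gam.age_effect(full, red, gam.default_age_grid(full))
        assert eff.r2_partial <= 1.0

    def test_mismatched_fits_rejected(self, ages):
        full = gam.fit_gam(_df(ages, ages))
        with pytest.raises(ValueError):
            gam.age_effect(full, full, ages)


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        assert gam.fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_stepup_arithmetic_by_hand(self):
        q = gam.fdr_correct([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8], rtol=1e-12)

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(gam.fdr_correct([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(0, 1, 50)
        q = gam.fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gam.fdr_correct([0.5, 1.5])


class TestMeanSlope:
    def test_constant_fit_zero(self, ages):
        fit = gam.fit_gam(_df(ages, np.full_like(ages, 2.0)))
        assert gam.mean_slope(fit, gam.default_age_grid(fit)) == pytest.approx(0.0, abs=1e-9)

    def test_saturating_curve_fundamental_theorem(self, ages):
        # mean derivative over [lo, hi] must equal (f(hi)-f(lo))/(hi-lo)
        y = 1.2 + 0.6 * (1 - np.exp(-0.2 * ages))
        fit = gam.fit_gam(_df(ages, y))
        lo, hi = fit.age_range
        grid = np.linspace(lo, hi, 2001)
        expected = (fit.predict([hi])[0] - fit.predict([lo])[0]) / (hi - lo)
        assert gam.mean_slope(fit, grid) == pytest.approx(expected, rel=1e-4)

    def test_grid_outside_range_rejected(self, ages):
        fit = gam.fit_gam(_df(ages, ages))
        with pytest.raises(ValueError):
            gam.mean_slope(fit, np.array([0.0, 50.0]))


class TestSlopeVsAxis:
    def _axis(self, n):
        return pd.DataFrame({"parcel": np.arange(n), "rank": np.arange(1, n + 1)})

    def test_constant_slopes_r2_zero(self):
        slopes = pd.DataFrame({"parcel": np.arange(20), "slope": np.full(20, 0.3)})
        out = gam.slope_vs_axis(slopes, self._axis(20))
        assert out["r2_smooth"] == pytest.approx(0.0, abs=1e-9)
        assert out["r2_linear"] == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_slopes_r2_one(self):
        slopes = pd.DataFrame({"parcel": np.arange(20), "slope": -0.01 * np.arange(20)})
        out = gam.slope_vs_axis(slopes, self._axis(20))
        assert out["r2_linear"] == pytest.approx(1.0, abs=1e-9)
        assert out["r2_smooth"] == pytest.approx(1.0, abs=1e-6)
        assert out["linear_sign"] == -1

    def test_degenerate_axis_rejected(self):
        slopes = pd.DataFrame({"parcel": np.arange(6), "slope": np.arange(6.0)})
        axis_df = pd.DataFrame({"parcel": np.arange(6), "rank": np.ones(6, int)})
        with pytest.raises(ValueError, match="degenerate"):
            gam.slope_vs_axis(slopes, axis_df)
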