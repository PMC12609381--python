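"""Regression, revolution-test, allometry and group-comparison tests."""

import numpy as np
import pandas as pd
import pytest

from ovogeom.epe_model import EPEParams
from ovogeom.geometry import shape_metrics, surface_area, volume_closed_form
from ovogeom.scaling_analysis import (allometric_fits, group_compare,
                                      ols_with_ci, relative_error_summary,
                                      revolution_test)


def normal_equations_oracle(x, y, ci_level=0.95):
    """Textbook simple-linear-regression formulas, independent of the package."""
    from scipy import stats
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    se = np.sqrt(np.sum(resid ** 2) / (n - 2) / sxx)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, n - 2)
    r = np.corrcoef(x, y)[0, 1]
    return slope, intercept, slope - tcrit * se, slope + tcrit * se, r * r


def frame(v_pred, v_obs=None, s=None, l=None, w=None, cultivar="x"):
    n = len(v_pred)
    return pd.DataFrame({
        "fruit_id": [f"f{i}" for i in range(n)],
        "cultivar": cultivar if isinstance(cultivar, list) else [cultivar] * n,
        "rmse_adj": np.full(n, 0.02),
        "v_pred": v_pred,
        "v_obs": np.full(n, np.nan) if v_obs is None else v_obs,
        "s": np.ones(n) if s is None else s,
        "l": np.ones(n) if l is None else l,
        "w": np.ones(n) if w is None else w,
        "w_over_l": np.ones(n),
    })


class TestOlsWithCi:
    def test_exact_line(self):
        x = np.arange(10.0)
        reg = ols_with_ci(x, 2 * x)
        assert reg.slope == pytest.approx(2.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)
        assert reg.slope_ci_high - reg.slope_ci_low == pytest.approx(0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.5, 5.0, 7.5])
        y = np.array([2.1, 3.9, 7.4, 9.6, 15.2])
        reg = ols_with_ci(x, y)
        slope, intercept, lo, hi, r2 = normal_equations_oracle(x, y)
        assert reg.slope == pytest.approx(slope, abs=1e-12)
        assert reg.intercept == pytest.approx(intercept, abs=1e-12)
        assert reg.slope_ci_low == pytest.approx(lo, abs=1e-12)
        assert reg.slope_ci_high == pytest.approx(hi, abs=1e-12)
        assert reg.r_squared == pytest.approx(r2, abs=1e-12)

    def test_log_base_invariance(self, rng):
        """Slope/CI/r2 from log10 regression equal those from ln regression."""
        x = rng.uniform(1, 30, 40)
        y = 3.0 * x ** 0.65 * np.exp(rng.normal(0, 0.05, 40))
        reg = ols_with_ci(x, y, scale="log10")
        slope, _, lo, hi, r2 = normal_equations_oracle(np.log(x), np.log(y))
        assert reg.slope == pytest.approx(slope, rel=1e-10)
        assert (reg.slope_ci_low, reg.slope_ci_high) == pytest.approx((lo, hi),
                                                                      rel=1e-10)
        assert reg.r_squared == pytest.approx(r2, rel=1e-10)

    def test_isometric_family_exponent_two_thirds(self, egg_params):
        ks = np.linspace(0.5, 2.0, 30)
        v = [volume_closed_form(egg_params.scaled(k)) for k in ks]
        s = [surface_area(egg_params.scaled(k)) for k in ks]
        reg = ols_with_ci(v, s, scale="log10")
        assert reg.slope == pytest.approx(2 / 3, abs=1e-10)

    def test_ci_coverage(self, rng):
        """95% slope CI covers the true unit slope in ~95% of replicates."""
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.uniform(0, 10, 100)
            y = x + rng.normal(0, 0.1, 100)
            reg = ols_with_ci(x, y)
            hits += reg.slope_ci_low <= 1.0 <= reg.slope_ci_high
        assert 0.92 < hits / reps < 0.98

    def test_errors(self):
        with pytest.raises(ValueError):
            ols_with_ci([1, 2], [1, 2])
        with pytest.raises(ValueError):
            ols_with_ci([1.0] * 5, [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            ols_with_ci([-1, 2, 3], [1, 2, 3], scale="log10")


class TestRevolutionTest:
    def test_unbiased_noise_accepts_unit_slope(self, rng):
        v_obs = rng.uniform(5, 30, 300)
        v_pred = v_obs * (1 + rng.normal(0, 0.02, 300))
        verdict = revolution_test(frame(v_pred, v_obs))
        assert verdict.strict
        assert verdict.banded

    def test_systematic_bias_rejected(self, rng):
        v_obs = rng.uniform(5, 30, 100)
        verdict = revolution_test(frame(1.5 * v_obs, v_obs))
        assert not verdict.strict
        assert not verdict.banded

    def test_banded_verdict_with_tight_ci(self, rng):
        """A slope of ~0.94 with a tight CI fails strict but passes banded."""
        v_obs = rng.uniform(5, 30, 500)
        v_pred = 0.94 * v_obs * (1 + rng.normal(0, 0.01, 500))
        verdict = revolution_test(frame(v_pred, v_obs))
        assert not verdict.strict
        assert verdict.banded

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            revolution_test(frame(np.array([1.0, 2.0]), np.array([1.0, 2.0])))


class TestRelativeError:
    def test_perfect_prediction(self, rng):
        v = rng.uniform(5, 20, 50)
        assert relative_error_summary(frame(v, v))["median_pct"] == 0.0

    def test_constant_five_percent(self, rng):
        v = rng.uniform(5, 20, 50)
        out = relative_error_summary(frame(1.05 * v, v))
        assert out["median_pct"] == pytest.approx(5.000, abs=1e-9)

    def test_half_normal_median(self, rng):
        """2% multiplicative noise gives median |error| ~ 0.675 * 2%."""
        v = rng.uniform(5, 30, 20000)
        out = relative_error_summary(frame(v * (1 + rng.normal(0, 0.02, len(v))), v))
        assert out["median_pct"] == pytest.approx(100 * 0.02 * 0.6744897, rel=0.05)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            relative_error_summary(frame(np.array([]), np.array([])))


class TestAllometricFits:
    def test_isometric_family(self, egg_params):
        """One shape at many sizes: S~V 2/3, V~LW2 1, S~LW2 2/3."""
        rows = []
        for k in np.linspace(0.6, 1.8, 25):
            g = shape_metrics(egg_params.scaled(k))
            rows.append({"fruit_id": str(k), "cultivar": "iso",
                         "rmse_adj": 0.0, "v_pred": g.v_pred, "s": g.s,
                         "l": g.l, "w": g.w, "w_over_l": g.w_over_l,
                         "v_obs": g.v_pred})
        fits = allometric_fits(pd.DataFrame(rows)).set_index("relation")
        assert fits.loc["s_vs_v_obs", "exponent"] == pytest.approx(2 / 3, abs=1e-9)
        assert fits.loc["v_pred_vs_lw2", "exponent"] == pytest.approx(1.0, abs=1e-9)
        assert fits.loc["s_vs_lw2", "exponent"] == pytest.approx(2 / 3, abs=1e-9)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            allometric_fits(frame(np.array([])))


class TestGroupCompare:
    def test_well_separated_groups_get_different_letters(self, rng):
        df = frame(np.ones(100),
                   cultivar=["g1"] * 50 + ["g2"] * 50)
        df["rmse_adj"] = np.r_[rng.normal(10, 1, 50), rng.normal(20, 1, 50)]
        gc = group_compare(df, "rmse_adj")
        assert gc.anova_p < 1e-6
        assert set(gc.letters["g1"]).isdisjoint(gc.letters["g2"])

    def test_null_groups_share_a_letter_usually(self, rng):
        same = 0
        reps = 30
        for _ in range(reps):
            df = frame(np.ones(60), cultivar=["g1"] * 30 + ["g2"] * 30)
            df["rmse_adj"] = rng.normal(5, 1, 60)
            gc = group_compare(df, "rmse_adj")
            same += bool(set(gc.letters["g1"]) & set(gc.letters["g2"]))
        assert same >= 25  # ~95% expected at alpha = 0.05

    def test_three_group_letter_pattern(self, rng):
        df = frame(np.ones(150),
                   cultivar=["lo"] * 50 + ["mid"] * 50 + ["hi"] * 50)
        df["rmse_adj"] = np.r_[rng.normal(0, 1, 50), rng.normal(0.2, 1, 50),
                               rng.normal(8, 1, 50)]
        gc = group_compare(df, "rmse_adj")
        assert set(gc.letters["lo"]) & set(gc.letters["mid"])
        assert set(gc.letters["hi"]).isdisjoint(gc.letters["lo"])

    def test_cv_of_constant_group_is_zero(self):
        df = frame(np.ones(20), cultivar=["g1"] * 10 + ["g2"] * 10)
        df["rmse_adj"] = np.r_[np.full(10, 3.0), np.arange(10, dtype=float)]
        gc = group_compare(df, "rmse_adj")
        assert gc.cv_percent["g1"] == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(frame(np.ones(10)), "rmse_adj")
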