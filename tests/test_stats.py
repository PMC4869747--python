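"""Stiffness-fraction fits, ANCOVA and the modulation model."""

import numpy as np
import pandas as pd
import pytest

from fibermech.stats import (
    LinearFitResult,
    bin_cells,
    compare_fits_ancova,
    derived_quantities,
    fit_modulation_model,
    fit_stiffness_model,
)
from fibermech.synthetic import (
    ACTIN_CSK,
    ACTIN_MODULATION,
    MYOSIN_CSK,
    simulate_modulation_cohort,
    simulate_stiffness_cohort,
)


def _table1_fit(e0, alpha, se0=0.1, sea=1.0, n=100):
    return LinearFitResult(e0_kpa=e0, alpha_kpa=alpha, se_e0=se0,
                           se_alpha=sea, p_model=0.001, r2=0.9, n=n)


class TestBinning:
    def test_thirty_records_bin_ten_gives_three_points(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 30, seed=0)
        binned = bin_cells(df, 10)
        assert len(binned) == 3
        assert (binned["n"] == 10).all()

    def test_binning_preserves_grand_mean(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 40, seed=1)
        binned = bin_cells(df, 10)
        assert binned["e_kpa"].mean() == pytest.approx(df["e_kpa"].mean())

    def test_binned_and_unbinned_slopes_agree_within_errors(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 100, seed=2)
        full = fit_stiffness_model(df)
        binned = fit_stiffness_model(bin_cells(df, 10))
        gap = abs(full.alpha_kpa - binned.alpha_kpa)
        assert gap < 2 * (full.se_alpha + binned.se_alpha)

    def test_fewer_records_than_bin_rejected(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 5, seed=0)
        with pytest.raises(ValueError):
            bin_cells(df, 10)


class TestStiffnessFit:
    def test_exact_linear_points_give_unit_r2(self):
        f = np.linspace(0.05, 0.3, 12)
        df = pd.DataFrame({"fraction": f, "e_kpa": 0.4 + 9.0 * f})
        fit = fit_stiffness_model(df)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.e0_kpa == pytest.approx(0.4)
        assert fit.alpha_kpa == pytest.approx(9.0)

    def test_degenerate_fractions_rejected(self):
        df = pd.DataFrame({"fraction": [0.1] * 5, "e_kpa": range(5)})
        with pytest.raises(ValueError):
            fit_stiffness_model(df)

    def test_slope_t_equals_model_f_for_single_predictor(self):
        import statsmodels.api as sm
        df = simulate_stiffness_cohort(ACTIN_CSK, 60, seed=3)
        x = sm.add_constant(df["fraction"].to_numpy())
        fit = sm.OLS(df["e_kpa"].to_numpy(), x).fit()
        assert fit.tvalues[1] ** 2 == pytest.approx(fit.fvalue, rel=1e-9)

    def test_parameter_recovery_within_confidence_intervals(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 100, seed=4)
        fit = fit_stiffness_model(df)
        lo, hi = fit.ci_e0()
        assert lo <= ACTIN_CSK.e0_kpa <= hi
        lo, hi = fit.ci_alpha()
        assert lo <= ACTIN_CSK.alpha_kpa <= hi


class TestAncova:
    def test_identical_cohorts_not_distinguished(self):
        df = simulate_stiffness_cohort(ACTIN_CSK, 80, seed=5)
        res = compare_fits_ancova(df, df.copy())
        assert res["p_slope"] > 0.9
        assert res["p_joint"] > 0.9

    def test_label_swap_symmetry(self):
        a = simulate_stiffness_cohort(ACTIN_CSK, 60, seed=6)
        b = simulate_stiffness_cohort(MYOSIN_CSK, 60, seed=7, protein="myosin")
        r1 = compare_fits_ancova(a, b)
        r2 = compare_fits_ancova(b, a)
        assert r1["p_slope"] == pytest.approx(r2["p_slope"])
        assert r1["p_joint"] == pytest.approx(r2["p_joint"])

    def test_scheffe_adjustment_is_conservative(self):
        a = simulate_stiffness_cohort(ACTIN_CSK, 80, seed=8)
        b = simulate_stiffness_cohort(MYOSIN_CSK, 80, seed=9, protein="myosin")
        res = compare_fits_ancova(a, b)
        assert res["p_slope_scheffe"] >= res["p_slope"]
        assert res["p_intercept_scheffe"] >= res["p_intercept"]


class TestModulationModel:
    def test_no_architecture_effect_selects_constant_model(self):
        rng = np.random.default_rng(10)
        n = 120
        df = pd.DataFrame({
            "fraction": rng.uniform(0.02, 0.3, n),
            "fa": rng.normal(0.22, 0.05, n),
            "ft": rng.normal(113, 20, n),
            "rl": rng.normal(0.7, 0.05, n),
        })
        fit = _table1_fit(0.37, 9.48)
        df["e_kpa"] = fit.predict(df["fraction"])  # E/E_fit identically 1
        mod = fit_modulation_model(df, fit)
        assert mod.terms == ()
        assert mod.coefficients["a"] == pytest.approx(1.0, abs=1e-9)

    def test_actin_like_cohort_recovers_fa_rl_terms_and_signs(self):
        df = simulate_modulation_cohort(ACTIN_CSK, ACTIN_MODULATION, 80, seed=3000)
        fit = fit_stiffness_model(df)
        mod = fit_modulation_model(df, fit)
        assert set(mod.terms) == {"fa", "rl"}
        assert mod.coefficients["b"] < 0  # aligned fibers reinforce
        assert mod.coefficients["d"] > 0  # peripheral fibers reinforce

    def test_forced_term_set_reports_all_coefficients(self):
        df = simulate_modulation_cohort(ACTIN_CSK, ACTIN_MODULATION, 80, seed=3001)
        fit = fit_stiffness_model(df)
        mod = fit_modulation_model(df, fit, terms=("fa", "ft", "rl"))
        assert set(mod.coefficients) == {"a", "b", "c", "d"}
        assert set(mod.normalizers) == {"FA", "FT", "RL"}

    def test_normalized_regressors_average_one(self):
        df = simulate_modulation_cohort(ACTIN_CSK, ACTIN_MODULATION, 200, seed=3002)
        fit = fit_stiffness_model(df)
        mod = fit_modulation_model(df, fit, terms=("fa", "ft", "rl"))
        for col, key in (("fa", "FA"), ("ft", "FT"), ("rl", "RL")):
            assert (df[col] / mod.normalizers[key]).mean() == pytest.approx(1.0)


class TestDerivedQuantities:
    def test_printed_parameters_reproduce_discussion_numbers(self):
        actin = _table1_fit(0.37, 9.48)
        myosin = _table1_fit(0.50, 14.67)
        actin_nr = _table1_fit(1.14, 6.52)
        out = derived_quantities(actin, myosin, actin_nr)
        assert out["myosin_actin_slope"] == pytest.approx(9.48 / 14.67)
        assert out["critical_actin_pct"] == pytest.approx(
            100 * (1.14 - 0.37) / (9.48 - 6.52))

    def test_equal_slopes_have_no_crossing(self):
        actin = _table1_fit(0.37, 9.48)
        out = derived_quantities(actin, _table1_fit(0.5, 14.67),
                                 _table1_fit(1.14, 9.48))
        assert not out["has_crossing"]
        assert np.isnan(out["critical_actin_pct"])
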