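"""Bottom-effect cone correction model and force-curve fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermech.afm import (
    ForceCurve,
    IndentationFit,
    NoContactError,
    baseline_correct,
    becc_force,
    find_contact_point,
    fit_modulus,
    pool_cell,
)
from fibermech.synthetic import SyntheticCurveSpec, render_curve


def reference_becc(e, theta_deg, delta, h):
    """Independent evaluation of the thin-sample cone force, written out
    term by term (the oracle for the packaged implementation)."""
    t = math.tan(math.radians(theta_deg))
    base = 8.0 * e * t * delta * delta / (3.0 * math.pi)
    c1 = 1.7795 * (2.0 * t / math.pi**2) * (delta / h)
    c2 = 16.0 * 1.7795**2 * t * t * (delta / h) ** 2
    return base * (1.0 + c1 + c2)


class TestBeccForce:
    def test_zero_indentation_gives_zero_force(self):
        assert becc_force(1000.0, 20.0, 0.0, 4e-6) == 0.0

    def test_half_space_limit_value(self):
        # 1 kPa cone, 20 deg, 1 um indentation, effectively infinite sample
        f = becc_force(1000.0, 20.0, 1e-6, 1.0)
        assert f * 1e9 == pytest.approx(0.309, abs=5e-4)

    def test_thin_sample_value(self):
        f = becc_force(1000.0, 20.0, 1e-6, 4e-6)
        assert f * 1e9 == pytest.approx(0.449, abs=5e-4)

    @given(
        e=st.floats(100.0, 1e5),
        theta=st.floats(10.0, 45.0),
        delta=st.floats(1e-8, 2e-6),
        h=st.floats(5e-7, 2e-5),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_independent_evaluation(self, e, theta, delta, h):
        assert becc_force(e, theta, delta, h) == pytest.approx(
            reference_becc(e, theta, delta, h), rel=1e-12)

    def test_half_space_limit_agrees_with_cone_closed_form(self):
        # delta/h < 0.01 -> the bracketed correction contributes < 0.1 %
        e, theta, delta, h = 2000.0, 20.0, 1e-8, 1.1e-6
        cone = 8 * e * math.tan(math.radians(theta)) * delta**2 / (3 * math.pi)
        assert becc_force(e, theta, delta, h) == pytest.approx(cone, rel=1e-3)

    def test_monotone_in_modulus_indentation_and_inverse_height(self):
        deltas = np.linspace(1e-8, 1.5e-6, 12)
        f1 = becc_force(1000.0, 20.0, deltas, 4e-6)
        assert np.all(np.diff(f1) > 0)
        for d in (2e-7, 1e-6):
            e_grid = [becc_force(e, 20.0, d, 4e-6) for e in (300, 1000, 3000)]
            assert e_grid[0] < e_grid[1] < e_grid[2]
            h_grid = [becc_force(1000.0, 20.0, d, h) for h in (1e-6, 2e-6, 8e-6)]
            assert h_grid[0] > h_grid[1] > h_grid[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            becc_force(1000.0, 20.0, 1e-6, -1.0)
        with pytest.raises(ValueError):
            becc_force(1000.0, 95.0, 1e-6, 4e-6)
        with pytest.raises(ValueError):
            becc_force(1000.0, 20.0, -1e-6, 4e-6)


class TestForceCurve:
    def test_non_monotone_ramp_rejected(self):
        z = np.array([0.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ForceCurve(z, np.zeros(4), 0.1, 20.0, 100.0)

    def test_retract_ordered_ramp_is_normalized_to_approach_order(self):
        z = np.linspace(100.0, 0.0, 60)
        c = ForceCurve(z, np.arange(60.0), 0.1, 20.0, 200.0)
        assert c.z_nm[0] < c.z_nm[-1]
        assert c.d_nm[0] == 59.0

    def test_baseline_tilt_removed(self):
        spec = SyntheticCurveSpec(e_pa=1000, h_um=4, z_cp_nm=2500)
        curve = render_curve(spec)
        tilted = ForceCurve(curve.z_nm, curve.d_nm + 5.0 + 0.002 * curve.z_nm,
                            curve.k_n_per_m, curve.theta_deg, curve.z_glass_nm)
        fixed = baseline_correct(tilted)
        n0 = len(fixed) // 4
        assert abs(fixed.d_nm[:n0].mean()) < 1e-9


class TestContactPointSearch:
    @pytest.mark.parametrize("e_pa,h_um", [(300, 1), (1000, 4), (10000, 8)])
    def test_noiseless_round_trip(self, e_pa, h_um):
        spec = SyntheticCurveSpec(e_pa=e_pa, h_um=h_um, z_cp_nm=1500.0)
        fit = find_contact_point(render_curve(spec))
        dz = spec.ramp_nm / (spec.n_samples - 1)
        assert abs(fit.z_cp_nm - 1500.0) <= dz + 1e-9
        assert fit.e_pa == pytest.approx(e_pa, rel=0.01)
        assert fit.h_um == pytest.approx(h_um, rel=0.02)
        assert fit.accepted

    def test_matches_exhaustive_bruteforce_scan(self):
        spec = SyntheticCurveSpec(e_pa=800.0, h_um=3.0, z_cp_nm=1200.0,
                                  ramp_nm=3000.0, n_samples=80,
                                  noise_nm=1.0, seed=3)
        curve = render_curve(spec)
        best = find_contact_point(curve)
        work = baseline_correct(curve)
        n_keep = max(10, math.ceil(0.10 * len(work)))
        brute = None
        for i in range(len(work) - n_keep):
            z_cp = work.z_nm[i]
            if work.z_glass_nm - z_cp <= 0:
                continue
            try:
                e, r2, h, _ = fit_modulus(work, z_cp)
            except NoContactError:
                continue
            if brute is None or r2 >= brute[1]:
                brute = (z_cp, r2, e)
        assert best.z_cp_nm == brute[0]
        assert best.e_pa == pytest.approx(brute[2])

    def test_pure_baseline_curve_raises(self):
        rng = np.random.default_rng(0)
        z = np.linspace(0, 5000, 300)
        curve = ForceCurve(z, rng.normal(0, 1.0, 300), 0.1, 20.0, 6000.0)
        with pytest.raises(NoContactError):
            find_contact_point(curve)

    def test_doubling_deflection_doubles_modulus(self):
        spec = SyntheticCurveSpec(e_pa=1000, h_um=4, z_cp_nm=2000)
        curve = render_curve(spec)
        e1, _, _, _ = fit_modulus(curve, 2000.0)
        doubled = ForceCurve(curve.z_nm, 2 * curve.d_nm, curve.k_n_per_m,
                             curve.theta_deg, curve.z_glass_nm)
        # doubling d changes delta too; instead double the spring constant,
        # which doubles force at identical kinematics
        stiffer = ForceCurve(curve.z_nm, curve.d_nm, 2 * curve.k_n_per_m,
                             curve.theta_deg, curve.z_glass_nm)
        e2, _, _, _ = fit_modulus(stiffer, 2000.0)
        assert e2 == pytest.approx(2 * e1, rel=1e-9)
        del doubled

    def test_median_modulus_unbiased_under_noise(self):
        recovered = []
        for seed in range(40):
            spec = SyntheticCurveSpec(e_pa=1000.0, h_um=4.0, z_cp_nm=2000.0,
                                      noise_nm=2.0, seed=seed)
            recovered.append(find_contact_point(render_curve(spec)).e_pa)
        assert np.median(recovered) == pytest.approx(1000.0, rel=0.05)


class TestPooling:
    def test_median_pooling_by_height_class(self):
        fits = [IndentationFit(0, 1000.0, 0.9, 3.0, True),
                IndentationFit(0, 2000.0, 0.9, 3.5, True),
                IndentationFit(0, 5000.0, 0.9, 6.0, True)]
        e_csk, e_nr = pool_cell(fits)
        assert e_csk == pytest.approx(1500.0)
        assert e_nr == pytest.approx(5000.0)

    def test_rejected_fit_excluded_from_both_pools(self):
        fits = [IndentationFit(0, 1000.0, 0.9, 3.0, True),
                IndentationFit(0, 9000.0, 0.60, 3.0, False)]
        e_csk, _ = pool_cell(fits)
        assert e_csk == pytest.approx(1000.0)

    def test_heights_between_thresholds_belong_to_neither_pool(self):
        fits = [IndentationFit(0, 1000.0, 0.9, 4.5, True)]
        e_csk, e_nr = pool_cell(fits)
        assert math.isnan(e_csk) and math.isnan(e_nr)
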