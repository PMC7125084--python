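"""Mechanistic Coulomb erosion model: shear, geometry, gamma, erosion fraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from rhizocohere import mechanistic as mech
from rhizocohere.errors import BareSoilUnerodedWarning, CalibrationError


def spatial_fraction_oracle(tau, rld_t, params, geom):
    """Independent spatial oracle for the eroded fraction of one period.

    Works directly on the sinusoidal reinforced-depth profile: locates the
    cohesion/shear crossing by root finding (no arccos closed form) and
    measures the eroded interval.
    """
    g = mech.gamma(rld_t, params)
    tau_eff = tau + params.friction_mu * params.normal_stress
    r, R = geom.r * 1000.0, geom.R * 1000.0
    L = 1.0  # result is independent of the period length

    def depth(x):
        return 0.5 * (R + r) + 0.5 * (R - r) * math.cos(2 * math.pi * x / L)

    def excess(x):  # shear minus local cohesion
        return tau_eff - params.c_bare * (1.0 + g * depth(x))

    if excess(0.0) > 0:  # eroded even at the tap root
        return 1.0
    if excess(L / 2.0) <= 0:  # intact even midway between plants
        return 0.0
    x_star = brentq(excess, 0.0, L / 2.0, xtol=1e-15)
    return (L - 2.0 * x_star) / L


class TestBedShear:
    def test_reference_value(self, flume):
        assert mech.bed_shear_stress(flume) == pytest.approx(21.6, abs=0.05)

    def test_linear_in_flow_rate(self, flume):
        doubled = mech.FlumeConfig(Q=2 * flume.Q)
        assert mech.bed_shear_stress(doubled) == pytest.approx(
            2 * mech.bed_shear_stress(flume)
        )

    def test_operating_velocity_range_matches_measured_stresses(self):
        """Across measured surface velocities the stress spans ~13-24 Pa."""
        taus = [mech.bed_shear_stress(mech.FlumeConfig(V=v)) for v in (0.9, 1.7)]
        assert 12.5 <= min(taus) <= max(taus) <= 24.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            mech.FlumeConfig(V=0.0)


class TestRootVolume:
    def test_kite_volume_cone_pair(self, geometry):
        assert geometry.kite_volume == pytest.approx(2.62e-4, rel=1e-2)

    def test_dense_planting_fills_rooted_slab(self, geometry):
        # occupied volume saturates at box area x D => RLD_T = RLD * depth/D
        assert mech.true_rld(20.0, geometry) == pytest.approx(
            20.0 * geometry.box_depth / geometry.D
        )

    def test_sparse_planting_concentrates_roots(self):
        geom = mech.RootGeometry(plant_count=1)
        assert mech.true_rld(10.0, geom) > 10.0

    def test_zero_rld(self, geometry):
        assert mech.true_rld(0.0, geometry) == 0.0


class TestGamma:
    def test_zero_at_zero(self):
        assert mech.gamma(0.0, mech.MechParams()) == 0.0

    def test_initial_slope_is_m1(self):
        params = mech.MechParams()
        rld_t = 0.0005  # km m^-3 -> 0.5 m m^-3, deep in the linear regime
        slope = mech.gamma(rld_t, params) / (rld_t * 1000.0)
        assert slope == pytest.approx(params.m1, rel=1e-3)

    def test_saturates_at_m_max(self):
        params = mech.MechParams()
        assert mech.gamma(1e6, params) == pytest.approx(params.m_max, rel=1e-6)

    @settings(deadline=None, max_examples=40)
    @given(x=st.floats(0.0, 1e4))
    def test_bounded_by_linear_and_ceiling(self, x):
        params = mech.MechParams()
        g = mech.gamma(x, params)
        assert 0.0 <= g <= min(params.m1 * x * 1000.0, params.m_max) + 1e-12


class TestCohesionExtremes:
    def test_no_roots_no_enhancement(self, geometry):
        params = mech.MechParams()
        c_min, c_max = mech.cohesion_extremes(0.0, params, geometry)
        assert c_min == c_max == params.c_bare

    def test_uniform_when_depths_equal(self):
        geom = mech.RootGeometry(r=0.05, R=0.05)
        c_min, c_max = mech.cohesion_extremes(10.0, mech.MechParams(), geom)
        assert c_min == pytest.approx(c_max)

    def test_direct_evaluation(self):
        # gamma == 0.02 mm^-1 via the linear regime: m1=2e-5 per m m^-3 at 1 km m^-3
        params = mech.MechParams(m1=2e-5, m2=2e-8, c_bare=1.0)
        geom = mech.RootGeometry(r=0.025, R=0.050)
        c_min, c_max = mech.cohesion_extremes(1.0, params, geom)
        assert c_min == pytest.approx(1.5, rel=1e-4)
        assert c_max == pytest.approx(2.0, rel=1e-4)


class TestErosionFraction:
    def test_bare_soil_limit(self, geometry):
        params = mech.MechParams()  # tau >> c_bare by default
        assert mech.erosion_fraction(21.6, 0.0, params, geometry) == 1.0

    def test_subcritical_bare_soil_warns(self, geometry):
        params = mech.MechParams(c_bare=100.0)
        with pytest.warns(BareSoilUnerodedWarning):
            assert mech.erosion_fraction(21.6, 0.0, params, geometry) == 0.0

    def test_half_eroded_at_midpoint(self, geometry):
        """u at the mean reinforced depth erodes exactly half the period."""
        params = mech.MechParams()
        rld_t = 10.0
        g = mech.gamma(rld_t, params)
        u_target = 0.5 * (geometry.R + geometry.r) * 1000.0
        tau = params.c_bare * (1.0 + g * u_target)
        assert mech.erosion_fraction(tau, rld_t, params, geometry) == pytest.approx(0.5)

    def test_clamping_limits(self, geometry):
        params = mech.MechParams()
        rld_t = 10.0
        g = mech.gamma(rld_t, params)
        tau_hi = params.c_bare * (1.0 + g * (geometry.R * 1000.0 + 1.0))
        tau_lo = params.c_bare * (1.0 + g * (geometry.r * 1000.0 - 1.0))
        assert mech.erosion_fraction(tau_hi, rld_t, params, geometry) == 1.0
        assert mech.erosion_fraction(tau_lo, rld_t, params, geometry) == 0.0

    def test_matches_spatial_oracle_on_random_parameters(self, geometry, flume, rng):
        """Closed-form eroded fraction equals spatial root-finding on the
        cohesion profile for 100 random parameter sets."""
        tau0 = mech.bed_shear_stress(flume)
        for _ in range(100):
            params = mech.MechParams(
                m1=10 ** rng.uniform(-3.5, -1.5),
                m2=10 ** rng.uniform(-6, -3),
                c_bare=10 ** rng.uniform(-3, -1),
            )
            geom = mech.RootGeometry(r=rng.uniform(0.01, 0.05), R=0.05)
            rld_t = rng.uniform(0.0, 80.0)
            tau = tau0 * rng.uniform(0.5, 1.5)
            closed = mech.erosion_fraction(tau, rld_t, params, geom)
            oracle = spatial_fraction_oracle(tau, rld_t, params, geom)
            assert closed == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_gamma_and_tau(self, geometry):
        params = mech.MechParams()
        tau = 21.6
        vals = [mech.erosion_fraction(tau, x, params, geometry) for x in (5.0, 10.0, 20.0)]
        assert vals[0] >= vals[1] >= vals[2]
        more_shear = mech.erosion_fraction(2 * tau, 10.0, params, geometry)
        assert more_shear >= mech.erosion_fraction(tau, 10.0, params, geometry)


class TestErosionCurve:
    def test_unity_at_zero_rld(self, geometry, flume):
        curve = mech.erosion_curve([0.0], mech.MechParams(), geometry, flume)
        assert curve[0] == 1.0

    def test_monotone_non_increasing(self, geometry, flume):
        grid = np.linspace(0, 56, 30)
        curve = mech.erosion_curve(grid, mech.MechParams(), geometry, flume)
        assert np.all(np.diff(curve) <= 1e-12)

    def test_hairless_parameters_plateau_near_observed(self, geometry, flume):
        """Saturated enhancement for the hairless line leaves a residual
        erosion plateau around 0.27 of bare soil."""
        params = mech.MechParams(m1=3.815e-3, m2=3.815e-3 / 88.0)
        plateau = mech.erosion_curve([120.0], params, geometry, flume)[0]
        assert plateau == pytest.approx(0.268, abs=0.01)


class TestCalibration:
    def test_noiseless_recovery(self, geometry, flume):
        true = mech.MechParams(m1=5.45e-3, m2=5.45e-3 / 139.0)
        grid = np.linspace(0, 56, 20)
        obs = list(zip(grid, mech.erosion_curve(grid, true, geometry, flume)))
        fitted, err = mech.calibrate_M(obs, geometry, flume)
        assert err < 1e-6
        assert fitted.m1 == pytest.approx(true.m1, rel=0.01)
        assert fitted.m_max == pytest.approx(true.m_max, rel=0.01)

    def test_genotype_ordering_preserved(self, geometry, flume):
        grid = np.linspace(0, 56, 20)
        fitted_mmax = {}
        for name, m1, m_max in [("a", 5.45e-3, 139.0), ("b", 3.815e-3, 88.0)]:
            true = mech.MechParams(m1=m1, m2=m1 / m_max)
            obs = list(zip(grid, mech.erosion_curve(grid, true, geometry, flume)))
            fitted_mmax[name] = mech.calibrate_M(obs, geometry, flume)[0].m_max
        assert fitted_mmax["a"] > fitted_mmax["b"]

    def test_noisy_recovery_within_parameter_range_width(self, geometry, flume):
        """5% multiplicative noise still pins the hairless saturation value
        within its calibrated range width (80-97)."""
        true = mech.MechParams(m1=3.815e-3, m2=3.815e-3 / 88.0)
        grid = np.linspace(0, 56, 20)
        curve = mech.erosion_curve(grid, true, geometry, flume)
        noisy = curve * np.random.default_rng(42).normal(1.0, 0.05, curve.size)
        fitted, _ = mech.calibrate_M(list(zip(grid, np.clip(noisy, 0, None))), geometry, flume)
        assert abs(fitted.m_max - 88.0) <= 17.0

    def test_underdetermined_rejected(self, geometry, flume):
        with pytest.raises(CalibrationError):
            mech.calibrate_M([(10.0, 0.5)], geometry, flume)
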