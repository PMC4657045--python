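"""Closed-form mechanics: geometry, energy, foundation model, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mtbuckle.mechanics as mech
from mtbuckle import units
from mtbuckle.mechanics import (DomainError, FilamentMechanics,
                                FoundationSpec, StraightFilamentError)

positive = st.floats(min_value=1e-6, max_value=1e6)


@pytest.mark.parametrize("lam, expected", [
    (2 * math.pi, 1.0),
    (21.14, 2 * math.pi / 21.14),
    (3.11, 2 * math.pi / 3.11),
])
def test_wave_number(lam, expected):
    assert mech.wave_number(lam) == pytest.approx(expected, rel=1e-12)


def test_wave_number_rejects_nonpositive():
    with pytest.raises(DomainError):
        mech.wave_number(0.0)


@pytest.mark.parametrize("lam, amp, expected", [
    (2 * math.pi, 1.0, 1.0),
    (21.14, 2.16, 1.0 / (2.16 * (2 * math.pi / 21.14) ** 2)),
    (3.11, 0.72, 1.0 / (0.72 * (2 * math.pi / 3.11) ** 2)),
])
def test_radius_of_curvature_min_radius_of_sinusoid(lam, amp, expected):
    r = mech.radius_of_curvature(lam, amp)
    assert r == pytest.approx(expected, rel=1e-12)
    # independent oracle: max |y''| of y = A sin(qx) on a dense grid
    q = 2 * math.pi / lam
    x = np.linspace(0, lam, 20001)
    y2 = -amp * q * q * np.sin(q * x)
    assert r == pytest.approx(1.0 / np.abs(y2).max(), rel=1e-6)


def test_radius_of_curvature_straight_filament_is_distinct_error():
    with pytest.raises(StraightFilamentError):
        mech.radius_of_curvature(10.0, 0.0)


class TestBendingEnergy:
    """E_bend = EI·L/(2R²); the reported per-length values pin the form."""

    def test_reported_sparse_kinesin_low_strain(self, mt_mechanics):
        f = mech.bending_energy_per_length(mt_mechanics, 4.18 * units.UM)
        # 0.47 pN is printed to two decimals; match at that precision
        assert round(f / units.PN, 2) == pytest.approx(0.47, abs=1e-12)

    def test_reported_sparse_kinesin_high_strain(self, mt_mechanics):
        f = mech.bending_energy_per_length(mt_mechanics, 0.54 * units.UM)
        assert f / units.PN == pytest.approx(27.99, rel=5e-3)

    def test_dense_kinesin_values_use_softened_modulus(self):
        soft = FilamentMechanics(7.15 * units.MPA, 32.82e-32)
        f = mech.bending_energy_per_length(soft, 0.23 * units.UM)
        assert f / units.PN == pytest.approx(22.18, rel=2e-2)

    def test_straight_rod_stores_nothing(self, mt_mechanics):
        assert mech.bending_energy(mt_mechanics, 1e12, 30 * units.UM) == \
            pytest.approx(0.0, abs=1e-30)

    def test_quadratic_in_inverse_radius(self, mt_mechanics):
        f1 = mech.bending_energy_per_length(mt_mechanics, 2.0)
        f2 = mech.bending_energy_per_length(mt_mechanics, 1.0)
        assert f2 == pytest.approx(4 * f1, rel=1e-12)


class TestFoundationModel:
    def test_foundation_modulus_division(self):
        assert mech.foundation_modulus(1.0, 1.0) == 1.0
        got = mech.foundation_modulus(1e-3, 95 * units.NM)
        assert got == pytest.approx(1.0526e4, rel=1e-3)
        assert mech.foundation_modulus(1.0, 2.0) == \
            pytest.approx(0.5 * mech.foundation_modulus(1.0, 1.0))

    def test_wavelength_trivial_scale(self):
        m = FilamentMechanics(1.0, 1.0)
        assert mech.buckling_wavelength(m, 1.0) == \
            pytest.approx(2 * math.pi, rel=1e-12)

    def test_wavelength_round_trip_at_reported_value(self, mt_mechanics):
        lam = 21.14 * units.UM
        ec = mech.foundation_modulus_from_wavelength(mt_mechanics, lam)
        assert ec == pytest.approx(0.1274, rel=1e-3)
        assert mech.buckling_wavelength(mt_mechanics, ec) == \
            pytest.approx(lam, rel=1e-12)

    @given(ei=positive, ec=positive)
    @settings(max_examples=100, deadline=None)
    def test_wavelength_modulus_round_trip(self, ei, ec):
        m = FilamentMechanics(ei, 1.0)
        lam = mech.buckling_wavelength(m, ec)
        assert mech.foundation_modulus_from_wavelength(m, lam) == \
            pytest.approx(ec, rel=1e-10)

    def test_wavelength_monotonicity(self):
        m1, m2 = FilamentMechanics(1.0, 1.0), FilamentMechanics(2.0, 1.0)
        assert mech.buckling_wavelength(m2, 1.0) > \
            mech.buckling_wavelength(m1, 1.0)
        assert mech.buckling_wavelength(m1, 2.0) < \
            mech.buckling_wavelength(m1, 1.0)

    def test_critical_force_reported_scale(self, mt_mechanics):
        f = mech.critical_force(mt_mechanics, 0.1274)
        assert f / units.PN == pytest.approx(2.89, rel=2e-3)

    @given(ei=positive, ec=positive)
    @settings(max_examples=50, deadline=None)
    def test_critical_force_is_min_over_wavenumber(self, ei, ec):
        m = FilamentMechanics(ei, 1.0)
        fc = mech.critical_force(m, ec)
        q_star = (ec / ei) ** 0.25
        qs = np.geomspace(q_star / 100, q_star * 100, 20001)
        brute = np.min(ei * qs ** 2 + ec / qs ** 2)
        assert fc == pytest.approx(brute, rel=1e-6)

    def test_critical_force_ratio_matches_wavelength_square(self,
                                                            mt_mechanics):
        """The reported ~46x rise of F_c between the sparse and dense
        conditions equals the (λ1/λ2)² prediction of the foundation model."""
        fc = lambda lam_um: mech.critical_force(
            mt_mechanics,
            mech.foundation_modulus_from_wavelength(mt_mechanics,
                                                    lam_um * units.UM))
        ratio = fc(3.11) / fc(21.14)
        assert ratio == pytest.approx((21.14 / 3.11) ** 2, rel=1e-12)
        assert ratio == pytest.approx(73.8 / 1.6, rel=0.01)

    def test_combined_forms_equal_composition(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ei, i2, k, ld = rng.uniform(0.1, 10, size=4)
            m = FilamentMechanics(ei, i2)
            ec = mech.foundation_modulus(k, ld)
            assert mech.combined_wavelength(m, k, ld) == \
                pytest.approx(mech.buckling_wavelength(m, ec), rel=1e-12)
            assert mech.combined_critical_force(m, k, ld) == \
                pytest.approx(mech.critical_force(m, ec), rel=1e-12)

    def test_loglog_derivatives_quarter_and_half(self):
        """∂logλ/∂logL_d = 1/4 and ∂logF_c/∂logL_d = -1/2 exactly."""
        m = FilamentMechanics(3.0, 2.0)
        k = 0.7
        for ld in (0.01, 1.0, 100.0):
            h = 1e-6
            dlam = (math.log(mech.combined_wavelength(m, k, ld * (1 + h)))
                    - math.log(mech.combined_wavelength(m, k, ld * (1 - h))))
            dfc = (math.log(mech.combined_critical_force(m, k, ld * (1 + h)))
                   - math.log(mech.combined_critical_force(m, k,
                                                           ld * (1 - h))))
            dlog = math.log1p(h) - math.log1p(-h)
            assert dlam / dlog == pytest.approx(0.25, abs=1e-6)
            assert dfc / dlog == pytest.approx(-0.5, abs=1e-6)


class TestCalibration:
    @pytest.mark.parametrize("density_per_um2, spacing_nm", [
        (1.0, 1000), (112, 95), (381, 51), (749, 36), (1800, 24),
        (2982, 18),
    ])
    def test_spacing_from_density(self, density_per_um2, spacing_nm):
        got = mech.spacing_from_density(density_per_um2 * units.PER_UM2)
        assert round(got / units.NM) == pytest.approx(spacing_nm, abs=1)

    def test_density_from_fluorescence_linear(self):
        assert mech.density_from_fluorescence(0.0) == 0.0
        one = mech.density_from_fluorescence(1.0)
        assert one / units.PER_UM2 == pytest.approx(27.4)
        assert mech.density_from_fluorescence(100.0) == \
            pytest.approx(100 * one)
        with pytest.raises(DomainError):
            mech.density_from_fluorescence(-1.0)

    def test_sauerbrey_counts_molecules(self):
        # 1 Hz shift at 17.7 ng·cm^-2·Hz^-1 of a 120 kDa protein
        c = 17.7e-9 * 1e4  # kg m^-2 Hz^-1
        molar = 120.0  # kg/mol
        got = mech.sauerbrey_mass_density(1.0, c, molar)
        expect = c * units.AVOGADRO / molar
        assert got == pytest.approx(expect, rel=1e-12)
        assert mech.sauerbrey_mass_density(-1.0, c, molar) == got  # |Δf|


class TestTypes:
    def test_flexural_rigidity_is_product(self, mt_mechanics):
        assert mt_mechanics.flexural_rigidity == \
            pytest.approx(49.75e6 * 32.82e-32, rel=1e-12)

    def test_foundation_spec_consistency(self):
        f = FoundationSpec(1e-3, 95 * units.NM)
        assert f.foundation_modulus == \
            pytest.approx(f.spring_stiffness / f.spacing, rel=1e-12)
        g = FoundationSpec.from_modulus(f.foundation_modulus, f.spacing)
        assert g.spring_stiffness == pytest.approx(1e-3, rel=1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(DomainError):
            FilamentMechanics(-1.0, 1.0)
        with pytest.raises(DomainError):
            FoundationSpec(1.0, 0.0)

    def test_unit_consistency_dimensionless_ratio(self):
        """Evaluating in a different consistent unit system only rescales
        the output by the length unit."""
        sL, sF = 1e6, 1e12  # lengths in μm, forces in pN
        m_si = FilamentMechanics(49.75e6, 32.82e-32)
        lam_si = mech.buckling_wavelength(m_si, 0.1274)
        m_um = FilamentMechanics(49.75e6 * sF / sL ** 2,
                                 32.82e-32 * sL ** 4)
        lam_um = mech.buckling_wavelength(m_um, 0.1274 * sF / sL ** 2)
        assert lam_um == pytest.approx(lam_si * sL, rel=1e-9)
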