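"""Closed-form photoselection model: examples, invariants and MC oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvflim import photoselection as ps
from conftest import mc_excitation_weight, mc_isotropic_anisotropy

MAGIC = ps.MAGIC_ANGLE_DEG


class TestAbsorptionFactors:
    @pytest.mark.parametrize(
        "nu, expected",
        [(0.0, 0.0), (90.0, 0.5), (54.7356, 1.0 / 3.0)],
    )
    def test_sector_Z(self, nu, expected):
        assert ps.absorption_sector_Z(ps.OrientationAngle(nu)) == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize(
        "nu, expected",
        [(0.0, 1.0), (90.0, 0.0), (54.7356, 1.0 / 3.0)],
    )
    def test_sector_Y(self, nu, expected):
        assert ps.absorption_sector_Y(ps.OrientationAngle(nu)) == pytest.approx(
            expected, abs=1e-6
        )

    def test_conservation_on_fine_grid(self):
        """A_Y + 2 A_Z = 1 exactly: the dipole couples to some polarization."""
        for nu in np.arange(0.0, 90.0 + 1e-9, 0.1):
            o = ps.OrientationAngle(float(nu))
            assert ps.absorption_sector_Y(o) + 2 * ps.absorption_sector_Z(o) == pytest.approx(
                1.0, abs=1e-12
            )

    @pytest.mark.parametrize("nu,psi", [(54.7356, 45.0), (38.0, 90.0), (38.0, 0.0)])
    def test_against_monte_carlo_azimuth_oracle(self, nu, psi):
        mean, se = mc_excitation_weight(nu, psi)
        closed = ps.ring_excitation_weight(ps.OrientationAngle(nu), psi)
        # azimuth-independent geometries have zero MC variance; allow epsilon
        assert abs(closed - mean) < 3.0 * se + 1e-12


class TestRingWeight:
    def test_reduces_to_sector_factors(self):
        o = ps.OrientationAngle(33.0)
        assert ps.ring_excitation_weight(o, 0.0) == pytest.approx(ps.absorption_sector_Y(o))
        assert ps.ring_excitation_weight(o, 90.0) == pytest.approx(ps.absorption_sector_Z(o))

    @pytest.mark.parametrize(
        "nu, psi, expected", [(90.0, 45.0, 0.25), (0.0, 45.0, 0.5)]
    )
    def test_point_values(self, nu, psi, expected):
        assert ps.ring_excitation_weight(ps.OrientationAngle(nu), psi) == pytest.approx(expected)
        mean, se = mc_excitation_weight(nu, psi)
        assert abs(expected - mean) < 3.0 * se + 1e-12

    def test_magic_angle_ring_is_uniform_and_uniquely_so(self):
        psi = np.arange(0.0, 360.0, 1.0)
        w = ps.ring_excitation_weight(ps.OrientationAngle(MAGIC), psi)
        assert np.ptp(w) < 1e-12
        for nu in (30.0, 50.0, 54.0, 56.0, 80.0):
            w = ps.ring_excitation_weight(ps.OrientationAngle(nu), psi)
            assert np.ptp(w) > 1e-4


class TestSectorRatioInversion:
    @pytest.mark.parametrize(
        "nu, expected",
        [
            (54.7356, 1.0),
            (45.0, 0.5),
            (38.0, (1 - math.cos(math.radians(38)) ** 2) / (2 * math.cos(math.radians(38)) ** 2)),
        ],
    )
    def test_predicted_ratio_equal_lifetimes(self, nu, expected):
        r = ps.predicted_sector_ratio(ps.OrientationAngle(nu), 2.5, 2.5)
        assert r == pytest.approx(expected, abs=2e-4)

    def test_predicted_ratio_rejects_in_plane(self):
        with pytest.raises(ValueError, match="unbounded"):
            ps.predicted_sector_ratio(ps.OrientationAngle(90.0))

    @pytest.mark.parametrize(
        "R, T, nu_expected, tol",
        [(1.0, 1.0, 54.74, 0.01), (0.5, 1.0, 45.0, 1e-9), (1e6, 1.0, 90.0, 0.1)],
    )
    def test_inversion_checkpoints(self, R, T, nu_expected, tol):
        res = ps.invert_orientation(R, T, 1.0)
        assert res.nu_deg == pytest.approx(nu_expected, abs=tol)

    def test_inversion_rejects_non_physical_ratio(self):
        with pytest.raises(ValueError, match="non-physical sector ratio"):
            ps.invert_orientation(0.0)
        with pytest.raises(ValueError, match="non-physical sector ratio"):
            ps.invert_orientation(-2.0)
        with pytest.raises(ValueError):
            ps.invert_orientation(1.0, tau_Z_ns=-1.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        nu=st.floats(0.01, 89.99),
        T=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_round_trip_is_identity(self, nu, T):
        o = ps.OrientationAngle(nu)
        R = ps.predicted_sector_ratio(o, T, 1.0)
        back = ps.invert_orientation(R, T, 1.0)
        assert back.nu_deg == pytest.approx(nu, rel=1e-9, abs=1e-9)
        # result invariant: forward-evaluating at the recovered angle returns R
        assert ps.predicted_sector_ratio(
            ps.OrientationAngle(back.nu_deg), T, 1.0
        ) == pytest.approx(R, rel=1e-9)

    def test_recovered_angle_increases_with_ratio(self):
        for T in (0.5, 1.0, 2.0):
            nus = [ps.invert_orientation(R, T, 1.0).nu_deg for R in np.geomspace(0.05, 50, 40)]
            assert np.all(np.diff(nus) > 0)

    def test_poisson_uncertainty_scales_with_counts(self):
        lo = ps.invert_orientation(0.5, F_Z=1e4, F_Y=2e4)
        hi = ps.invert_orientation(0.5, F_Z=1e6, F_Y=2e6)
        assert hi.sigma_nu_deg < lo.sigma_nu_deg
        assert hi.sigma_nu_deg == pytest.approx(lo.sigma_nu_deg / 10.0, rel=1e-6)


class TestEmissionDipoleOffset:
    @pytest.mark.parametrize(
        "r0, beta, tol",
        [(0.4, 0.0, 1e-9), (0.397, 4.05, 0.01), (0.1, 45.0, 1e-9)],
    )
    def test_beta_from_r0(self, r0, beta, tol):
        assert ps.beta_from_fundamental_anisotropy(r0).beta_deg == pytest.approx(beta, abs=tol)

    @pytest.mark.parametrize("r0", [-0.25, 0.41, 1.0])
    def test_rejects_non_physical_r0(self, r0):
        with pytest.raises(ValueError, match="non-physical fundamental anisotropy"):
            ps.beta_from_fundamental_anisotropy(r0)


class TestPolarizedEmissionFractions:
    def test_single_dipole_along_excitation_is_fully_polarized(self):
        f_par, f_perp = ps.polarized_emission_fractions(ps.OrientationAngle(0.0), 0.0)
        assert ps.emission_anisotropy(f_par, f_perp) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_ensemble_recovers_classic_limit(self):
        f_par, f_perp = ps.polarized_emission_fractions(None, 37.0)
        r_mc = mc_isotropic_anisotropy()
        r = ps.emission_anisotropy(f_par, f_perp)
        assert r == pytest.approx(0.4, abs=1e-6)
        assert r == pytest.approx(r_mc, abs=2e-3)  # MC oracle, ~3 sigma at 1e6 draws

    def test_side_sectors_more_anisotropic_for_tilted_dipoles(self):
        """nu = 38 deg: membrane fragments on the Y axis (left/right) show the
        higher anisotropy, the signature of a roughly vertical dipole."""
        o = ps.OrientationAngle(38.0)
        r_side = ps.emission_anisotropy(*ps.polarized_emission_fractions(o, 0.0))
        r_pole = ps.emission_anisotropy(*ps.polarized_emission_fractions(o, 90.0))
        assert r_side > r_pole

    def test_beta_depolarizes(self):
        o = ps.OrientationAngle(0.0)
        r0 = ps.emission_anisotropy(*ps.polarized_emission_fractions(o, 0.0, beta_deg=0.0))
        r1 = ps.emission_anisotropy(*ps.polarized_emission_fractions(o, 0.0, beta_deg=15.0))
        assert r1 < r0

    def test_aperture_average_matches_numeric_mask_integral(self):
        o = ps.OrientationAngle(38.0)
        psi = 80.0 + 20.0 * (np.arange(20000) + 0.5) / 20000  # midpoint rule
        numeric = np.mean(ps.ring_excitation_weight(o, psi))
        assert ps.aperture_averaged_weight(o, "Z", 20.0) == pytest.approx(numeric, rel=1e-6)
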