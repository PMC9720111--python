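"""Plate-model optics: transmissivity, interface averages, forward spectra."""
import numpy as np
import pytest
from scipy.integrate import quad

from conftest import random_biophysics
from leafspec.radiative_transfer import (
    AbsorptionLibrary,
    carotenoid_absorption,
    forward_model,
    fresnel_average_transmissivity,
    plate_transmissivity,
    total_absorption,
)
from leafspec.types import LeafBiophysics, default_grid


def theta_quadrature(k: float) -> float:
    """Independent oracle: angular integral of Beer attenuation over the
    isotropic incidence hemisphere (radiance-weighted)."""
    val, _ = quad(
        lambda th: np.exp(-k / np.cos(th)) * 2.0 * np.sin(th) * np.cos(th),
        0.0, np.pi / 2, limit=200,
    )
    return val


def tav_quadrature(alpha_deg: float, n: float) -> float:
    """Independent oracle: Fresnel transmission averaged over the cone."""
    a = np.deg2rad(alpha_deg)

    def trans(th):
        st, ct = np.sin(th), np.cos(th)
        sr = st / n
        cr = np.sqrt(1.0 - sr ** 2)
        rs = ((ct - n * cr) / (ct + n * cr)) ** 2
        rp = ((n * ct - cr) / (n * ct + cr)) ** 2
        return 1.0 - (rs + rp) / 2.0

    num, _ = quad(lambda th: trans(th) * np.sin(th) * np.cos(th), 0.0, a, limit=200)
    den, _ = quad(lambda th: np.sin(th) * np.cos(th), 0.0, a, limit=200)
    return num / den


class TestPlateTransmissivity:
    def test_limits(self):
        assert plate_transmissivity(0.0) == 1.0
        assert plate_transmissivity(50.0) < 1e-10
        # at k=1 the formula reduces to E1(1)
        assert plate_transmissivity(1.0) == pytest.approx(0.2193839343955203, abs=1e-12)

    @pytest.mark.parametrize("k", [0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0])
    def test_matches_quadrature_oracle(self, k):
        assert plate_transmissivity(k) == pytest.approx(theta_quadrature(k), abs=1e-8)

    def test_strictly_decreasing_and_bounded(self):
        k = np.linspace(0.0, 12.0, 400)
        theta = plate_transmissivity(k)
        assert np.all(np.diff(theta) < 0)
        assert np.all((theta > 0) & (theta <= 1))

    def test_negative_absorption_rejected(self):
        with pytest.raises(ValueError):
            plate_transmissivity(-0.1)


class TestFresnelAverage:
    def test_no_interface_is_unity(self):
        assert fresnel_average_transmissivity(40.0, 1.0) == 1.0
        assert fresnel_average_transmissivity(90.0, 1.0) == 1.0

    @pytest.mark.parametrize(
        "alpha,n", [(90.0, 1.5), (90.0, 1.4), (40.0, 1.3), (40.0, 1.6), (5.0, 1.45)]
    )
    def test_matches_angular_integration(self, alpha, n):
        assert fresnel_average_transmissivity(alpha, n) == pytest.approx(
            tav_quadrature(alpha, n), abs=1e-8
        )

    def test_decreasing_in_refractive_index(self):
        assert fresnel_average_transmissivity(40.0, 1.3) > fresnel_average_transmissivity(40.0, 1.6)

    def test_invalid_cone_rejected(self):
        with pytest.raises(ValueError):
            fresnel_average_transmissivity(0.0, 1.4)
        with pytest.raises(ValueError):
            fresnel_average_transmissivity(-10.0, 1.4)


class TestAbsorption:
    def test_carotenoid_end_members_and_linearity(self, library):
        v = carotenoid_absorption(8.0, 0.0, library)
        z = carotenoid_absorption(8.0, 1.0, library)
        mid = carotenoid_absorption(8.0, 0.5, library)
        np.testing.assert_array_equal(v, 8.0 * library.k_car_v)
        np.testing.assert_array_equal(z, 8.0 * library.k_car_z)
        np.testing.assert_allclose(mid, (v + z) / 2.0, rtol=1e-14)
        with pytest.raises(ValueError):
            carotenoid_absorption(8.0, 1.2, library)

    def test_total_absorption_zero_and_linearity(self, library):
        zero = LeafBiophysics(cab=0, ccar=0, canth=0, cx=0, cbrown=0, cw=0, cm=0)
        assert np.all(total_absorption(zero, library) == 0)
        p1 = LeafBiophysics(n=1.8, cab=30, ccar=6, canth=2, cx=0.4,
                            cbrown=0.1, cw=0.01, cm=0.005)
        p2 = LeafBiophysics(n=1.8, cab=60, ccar=12, canth=4, cx=0.4,
                            cbrown=0.2, cw=0.02, cm=0.01)
        np.testing.assert_allclose(
            total_absorption(p2, library), 2.0 * total_absorption(p1, library),
            rtol=1e-12,
        )

    def test_single_constituent(self, library):
        p = LeafBiophysics(n=2.0, cab=10, ccar=0, canth=0, cx=0, cbrown=0, cw=0, cm=0)
        np.testing.assert_allclose(
            total_absorption(p, library), 10.0 * library.k_ab / 2.0, rtol=1e-14
        )


def _transparent_library():
    grid = default_grid()
    m = len(grid)
    zeros = np.zeros(m)
    return AbsorptionLibrary(
        grid=grid, n_refr=np.ones(m), k_ab=zeros, k_car_v=zeros, k_car_z=zeros,
        k_anth=zeros, k_brown=zeros, k_w=zeros, k_m=zeros,
    )


class TestForwardModel:
    def test_transparent_slab(self):
        lib = _transparent_library()
        p = LeafBiophysics(n=2.3, cab=0, ccar=0, canth=0, cx=0, cbrown=0, cw=0, cm=0)
        spec = forward_model(p, lib)
        np.testing.assert_allclose(spec.reflectance, 0.0, atol=1e-12)
        np.testing.assert_allclose(spec.transmittance, 1.0, atol=1e-12)

    def test_zero_absorber_with_interfaces_conserves_energy(self, library):
        p = LeafBiophysics(n=1.7, cab=0, ccar=0, canth=0, cx=0, cbrown=0, cw=0, cm=0)
        spec = forward_model(p, library)
        np.testing.assert_allclose(
            spec.reflectance + spec.transmittance, 1.0, atol=1e-9
        )

    def test_energy_conservation_random_draws(self, library):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            spec = forward_model(random_biophysics(rng), library)
            assert np.all(spec.reflectance >= 0)
            assert np.all(spec.transmittance >= 0)
            assert np.all(spec.reflectance + spec.transmittance <= 1.0 + 1e-12)

    def test_single_plate_matches_geometric_series(self, library):
        """n=1 output equals an independent multiple-reflection summation."""
        p = LeafBiophysics(n=1.0, cab=40, ccar=8, canth=3, cx=0.5,
                           cbrown=0.05, cw=0.01, cm=0.004)
        spec = forward_model(p, library)
        tau = plate_transmissivity(total_absorption(p, library))
        nr = library.n_refr
        talf = fresnel_average_transmissivity(40.0, nr)
        t12 = fresnel_average_transmissivity(90.0, nr)
        t21 = t12 / nr ** 2
        r21 = 1.0 - t21
        # truncated geometric series over internal bounces
        refl = (1.0 - talf).copy()
        tran = np.zeros_like(tau)
        for j in range(200):
            bounce = (r21 * tau) ** (2 * j)
            tran += talf * tau * t21 * bounce
            refl += talf * tau * r21 * tau * t21 * bounce
        np.testing.assert_allclose(spec.transmittance, tran, atol=1e-10)
        np.testing.assert_allclose(spec.reflectance, refl, atol=1e-10)

    def test_transmittance_decreasing_in_chlorophyll(self, library):
        peak = int(np.argmax(library.k_ab))
        t_vals = []
        for cab in [10.0, 20.0, 40.0, 80.0]:
            p = LeafBiophysics(cab=cab, ccar=cab / 5.4)
            t_vals.append(forward_model(p, library).transmittance[peak])
        assert np.all(np.diff(t_vals) < 0)

    def test_nir_reflectance_increasing_in_structure(self, library):
        nir = library.grid.wavelengths > 780.0
        r_vals = []
        for n in [1.0, 1.5, 2.0, 2.5, 3.0]:
            p = LeafBiophysics(n=n)
            r_vals.append(forward_model(p, library).reflectance[nir].mean())
        assert np.all(np.diff(r_vals) > 0)

    def test_continuity_in_structure_parameter(self, library):
        p_lo = LeafBiophysics(n=1.999)
        p_hi = LeafBiophysics(n=2.001)
        s_lo = forward_model(p_lo, library)
        s_hi = forward_model(p_hi, library)
        assert np.max(np.abs(s_lo.reflectance - s_hi.reflectance)) < 1e-3
        assert np.max(np.abs(s_lo.transmittance - s_hi.transmittance)) < 1e-3
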